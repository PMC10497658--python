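# Methods

## Scope and physical model

The package quantifies two biomechanical measures of the craniocervical
junction and their cohort-level relationship:

1. **Unsteady resistance to CSF flow** in the upper cervical spinal canal,
   summarized as the integrated longitudinal impedance (ILI).
2. **Cardiac-induced brain tissue displacement** decoded from cine DENSE
   magnitude/phase images, summarized as a per-region peak ROI displacement.

### Oscillatory duct-flow surrogate for the impedance

CSF flow in the canal is laminar (peak Re of a few hundred), oscillatory,
and — over a short segment with slowly varying cross-section — close to
fully developed. Each segmented slice is therefore treated as an infinite
duct of that cross-section: for a harmonic axial pressure gradient
`G e^{iωt}` the velocity field solves the complex Helmholtz problem

    iωρ u = G + μ ∇²u,   u = 0 on the walls,

on the slice raster. Integrating `u` over the lumen gives the slice mobility
`M(ω) = Q/G`; slices are in series, so the segment impedance is the line
integral `Z_L(ω) = ∫ dz / M(z, ω)` (trapezoid along z, endpoints
interpolated). ILI is the trapezoidal integral of `|Z_L(f)|` over 1–8 Hz
evaluated on a uniform grid of ≥ 29 frequencies; the unit
dyn·s/cm⁵ × Hz = dyn/cm⁵ is what identifies the band reduction as a
frequency integral rather than a sum over harmonics. When `Z_L` is available
only at cardiac harmonics (the time-trace route), `|Z_L|` is linearly
interpolated onto the band endpoints, with linear extension below the
fundamental (1.44 Hz at 86.3 bpm, just above the 1 Hz edge).

Assumptions deliberately inherited from the fully developed regime: no
entrance or advective effects, rigid walls, static geometry averaged over
the cycle. These are the same idealizations a 3-D rigid-wall simulation with
long flow extensions approaches; wall motion is known to raise ILI magnitude
by roughly a fifth and is out of scope. A corollary used throughout: the
model is linear, so `Z_L` and ILI are independent of the flow waveform's
shape and amplitude, and no startup cycles are needed.

### Numerical treatment

* **Helmholtz solve.** Second-order central differences on the mask grid;
  at fluid pixels bordering the wall the stencil is shortened so the no-slip
  boundary sits half a pixel beyond the last fluid centre (Shortley–Weller
  with d = h/2), consistent with the 0.5-level isocontour used for the
  perimeter. The sparse complex system is solved by a direct factorization
  with deterministic ordering, so results are bit-reproducible for a fixed
  grid. Observed accuracy on closed forms: < 2% for Womersley numbers up to
  20 at ~80 pixels per radius; the steady limit converges to the Poiseuille
  values at ~1%/0.4% (annulus/pipe) at the resolutions the tests use.
  Harmonics with a flow Fourier coefficient below 10⁻⁸ of the largest are
  dropped rather than divided.
* **Closed forms.** Circular pipe: Womersley's `J₀/J₁` solution. Concentric
  annulus: the modified-Bessel basis `I₀(sr), K₀(sr)` with `s² = iωρ/μ`,
  each basis function normalized at the opposite wall. The usual `J₀/Y₀`
  complex-argument form is analytically equivalent but numerically singular
  at cardiac frequencies (both functions grow exponentially across the gap);
  the I/K basis keeps the 2×2 boundary system well conditioned to Womersley
  numbers beyond 50.
* **Geometry metrics.** Area is foreground-pixel count × pixel area. The
  wetted perimeter sums all 0.5-level marching-squares isocontours (both
  cord and dura walls are wetted) after a circular moving average of the
  contour vertices (window 9): a raw binary-mask isocontour is a staircase
  that overestimates smooth walls by up to ~5%, while the smoothed polygon
  is accurate to ~0.1–0.8% and converges under grid refinement. Disjoint
  lumen components below 10 pixels are dropped with a warning; larger ones
  are retained.
* **Units.** All hydrodynamics in CGS (cm, g, s, dyn), matching the
  dyn/cm⁵ convention for ILI; lengths at I/O boundaries are mm.

### DENSE decoding chain

Phase unwrapping uses a reliability-sorting 2-D algorithm within each region
per frame. A spatial unwrap leaves a global 2π multiple per frame
undetermined; it is anchored temporally: frame 0's region median is brought
into (−π, π] (early-cycle displacement is small) and each later frame is
shifted so its mean change from the previous frame is below π (guaranteed at
34 ms cine sampling of smooth cardiac motion). Displacement is
`u = φ/(2π k_e)` per encoded direction; "displacement" maps and summaries
use the Euclidean norm of the (AP, CC) pair. Noise filtering applies a
Hamming windowed-sinc FIR kernel (normalized cutoff 0.15, 17 taps)
separably along rows and columns, restricted to each region's support by
normalized convolution so background zeros and neighbouring regions do not
bleed across the segmentation boundary. Regions are eroded by 2 voxels
(configurable) before summarization. The ROI rule: per-pixel temporal peak
magnitude, a disc of 30 mm² centred at the largest peak (shifted minimally
if the disc would leave the region), and the temporal maximum of the disc's
spatial-mean magnitude as the reported scalar; a max-pixel variant is
exposed via `statistic="max"`. The mean was chosen as the default reduction
because it is markedly less noise-sensitive at realistic SNR, and the
wording that defines the scalar admits both readings.

## Synthetic-data generators

The generators emulate the four input classes with known ground truth; they
are first-class, tested code.

* **Canal geometry.** A (possibly eccentric) annulus: dura radius 0.95 cm,
  cord radius 0.40 cm, 25 slices over 60 mm, rasterized at 0.3 mm (fine
  enough that the steady impedance of the default canal matches the annular
  Poiseuille closed form within ~1%). A *crowding index* c ∈ (−1, 1) scales
  the lumen gap by (1 − c) at the FM, relaxing linearly to nominal at
  25 mm — positive values emulate tonsillar crowding, negative values the
  roomier canals of healthy subjects (the range was widened below 0 so one
  latent variable spans both groups). Lumen positivity and a minimum cord
  radius of 0.05 cm are enforced.
* **Flow waveform.** Zero-mean truncated-harmonic pulse, 86.3 bpm, 100
  samples per cycle (6.95 ms steps), default peak 2.5 cm³/s — a typical
  cervical CSF stroke; the impedance results do not depend on this choice by
  linearity.
* **DENSE phantom.** Separable truth field `u(x,t) = s(x) p(t)` with a
  smooth periodic pulse and either a uniform pattern or a Gaussian bump
  (default σ = 18 mm). The default pattern scale is deliberately
  organ-scale/near-uniform: the prescribed FIR filter's passband edge is a
  ~12 mm wavelength at 0.9 mm pixels, so sharper patterns are attenuated by
  the pipeline itself (a property of the prescribed filter, listed under
  limitations), and the physical validation phantoms this emulates moved as
  near-rigid blocks. Phases are `2π k_e u` wrapped to (−π, π];
  complex-channel Gaussian noise at magnitude SNR 20 is added to both
  encoded channels before phase extraction. Region labels (an elliptical
  "cerebellum" and a smaller "brainstem") and ground-truth maps/summaries
  accompany every series. With a 900 µm peak (beyond the 833 µm
  half-encoding-wavelength) the phantom exercises genuine wrapping.
* **Cohort.** Group sizes 32/18. Per subject a target ILI is drawn from a
  log-normal matched to the group reference moments (485 ± 184 patients /
  244 ± 38 controls, dyn/cm⁵), inverted through the monotone crowding → ILI
  map, and the recorded ILI is recomputed forward through the impedance
  module. Cerebellar displacement shares the latent with correlation chosen
  analytically so the expected Pearson r is 0.75 (patients); brainstem
  displacement is independent log-normal noise (234 ± 101 / 154 ± 44 µm), so
  no brainstem correlation is induced — the qualitative contrast the
  analysis should recover. Targets falling outside the achievable ILI range
  of the crowding map are clamped (warning when more than 10% clip).
  Coupling modes: `"none"` decouples displacement entirely; `"graded"`
  builds a mixture — a low-motion pool uniform on [60, 210] µm independent
  of ILI, and a coupled pool on a linear ILI → displacement line with
  additive noise of 12 µm (4 µm above 250 µm) — so subset correlations
  strengthen as a displacement cutoff rises, the structure the cutoff
  analysis is designed to detect. Measurement is either a cheap
  latent + 5 µm Gaussian error model (default) or per-subject DENSE
  phantoms measured through the full image pipeline (`measurement="dense"`,
  used by the end-to-end pipeline). Symptom flags are Bernoulli at the
  observed prevalences and independent of the measures; pain scores are
  optional independent covariates.

**What passing tests do and do not show.** The generators share the
pipeline's *forward model* (annular ducts, linear phase encoding, Gaussian
noise). Recovery therefore validates the numerics and the statistical
logic — not segmentation quality, sequence artifacts (off-resonance,
gating jitter, through-plane motion), wall compliance, or anatomy beyond an
annulus. Real-data performance claims are outside what this test bed can
establish.

## Statistical choices

Two-sided tests throughout; no multiple-testing correction by default
(Bonferroni optional), mirroring common practice for exploratory
biomechanics cohorts. The cutoff subset rule is strict (`> c`), with ties at
the cutoff counted in the output. Degenerate inputs follow explicit
conventions: both groups constant and equal → t = 0, p = 1; zero-variance
correlation input → error; Shapiro–Wilk limited to 3 ≤ n ≤ 5000.

## Problem sizes

Default test and acceptance workloads are sized for a single CPU: 64×64
phantom grids with 20 frames, 25-slice canals at 0.3 mm, 29-frequency
spectra, 20-seed cohort replications, and 50-phantom accuracy estimates.
The cutoff-logic check runs its generator at 200 patients because the
property it asserts (monotone nested correlations) is a population-level
ordering that small-sample correlation noise obscures for any generator.

## Known limitations

* The fully developed, rigid-wall surrogate omits entrance/advective
  effects and wall motion; reported ILI for strongly moving anatomy will be
  underestimated.
* Raster-wall quantization makes slice impedance accurate only to a few
  percent at scan-like resolutions; the closed-form annular path avoids
  this where geometry permits.
* The prescribed FIR noise filter attenuates displacement patterns sharper
  than ~12 mm wavelength, biasing peak summaries low for focal motion.
* Lateral (through-plane) displacement, k-space reconstruction, and gating
  correction are out of scope; frames are assumed uniformly spaced.
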