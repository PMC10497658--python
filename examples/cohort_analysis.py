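"""Cohort-level statistics on a synthetic patient/control cohort.

Generates 32 patients with crowded canals and 18 controls: each subject's
crowding index drives ILI (through the oscillatory-flow impedance model) and,
for patients, cerebellar displacement; brainstem displacement is independent
noise.  Group contrasts (Welch), ILI-displacement correlations, and the
displacement-cutoff subset analysis are then computed.
"""

import warnings

from csfm.cohort import analyze_cohort
from csfm.synthetic import CohortParams, make_cohort

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    records, truth = make_cohort(CohortParams(n_cmi=32, n_control=18, seed=1))
    tables = analyze_cohort(records, cutoffs=(150.0, 200.0, 250.0))

gs = tables["group_summary"].set_index("measure")
ili = gs.loc["ili_dyn_cm5"]
print(
    f"ILI: patients {ili['mean_CMI']:.0f} +/- {ili['sd_CMI']:.0f}, "
    f"controls {ili['mean_control']:.0f} +/- {ili['sd_control']:.0f} dyn/cm^5, "
    f"Welch p = {ili['welch_p']:.2g}"
)

corr = tables["correlations"]
for _, row in corr[corr.group == "CMI"].iterrows():
    region = row["measure"].replace("disp_", "").replace("_um", "")
    print(f"patients, ILI vs {region:10s}: r = {row.r:+.2f}  p = {row.p:.2g}  (n={row.n})")

print("\ncutoff subset analysis (patients, cerebellum):")
print(tables["cutoff_table"][["cutoff_um", "n", "r", "p"]].to_string(index=False))
print("\nthe induced cerebellar coupling is recovered; the brainstem shows none.")
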