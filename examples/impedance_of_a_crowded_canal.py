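"""Longitudinal impedance and ILI of a crowded versus a normal canal.

Tonsillar crowding narrows the CSF pathway over the first 25 mm below the
foramen magnum.  This script computes the impedance spectrum Z_L(f) of the
0-25 mm segment for a normal and a 60%-crowded canal and integrates |Z_L|
over 1-8 Hz to obtain ILI (dyn/cm^5).  Crowding raises the unsteady flow
resistance, the mechanism linking altered geometry to tissue motion.
"""

import numpy as np

from csfm.impedance import compute_ili, pressure_drop_spectrum
from csfm.synthetic import GeometryParams, make_annular_profile, replace_params

base = GeometryParams()
freqs = np.linspace(1.0, 8.0, 29)

for label, crowding in (("normal canal   ", 0.0), ("crowded canal  ", 0.6)):
    profile = make_annular_profile(replace_params(base, crowding_factor=crowding))
    spec = pressure_drop_spectrum(profile, frequencies=freqs, segment=(0.0, 25.0))
    ili = compute_ili(spec, band=(1.0, 8.0))
    z1, z8 = abs(spec.Z[0]), abs(spec.Z[-1])
    print(
        f"{label} |Z_L(1 Hz)| = {z1:6.1f}  |Z_L(8 Hz)| = {z8:6.1f} dyn*s/cm^5"
        f"   ILI = {ili.ili:6.1f} dyn/cm^5"
    )

print("\nILI rises with crowding because every harmonic sees a narrower duct;")
print("the 1-8 Hz integral weights the inertance-dominated upper band most.")
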