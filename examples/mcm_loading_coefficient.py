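"""Mcm2 helicase loading on the Xi via the double-ROI coefficient.

For one late-G1 cell: segment-free ground-truth masks give the Xi (ROI1)
and a seeded congruent control region (ROI2) on the maximum projection;
the coefficient is the DAPI-normalised Mcm2 ratio ROI1/ROI2.
"""

import xirep as xr
from xirep.segmentation import control_roi

for preset, coef_true in (("scramble", 4.44), ("mh2a1_kd", 2.77)):
    image, gt = xr.make_nucleus_image(
        preset, seed=7, n_xi=1,
        channels=("DAPI", "H3K27me3", "Mcm2"),
        mcm_xi_coefficient=coef_true,
    )
    xi = gt.xi_mask(0).projected()
    roi2 = control_roi(
        gt.nucleus_mask(0).projected(), xi,
        gt.chromocenter_mask(0).projected(), seed=7,
    )
    coef = xr.loading_coefficient(image, "Mcm2", xi, roi2)
    print(f"{preset:10s}  planted {coef_true:.2f}  recovered {coef:.2f}")

print(
    "\nThe coefficient is the Xi's Mcm2 enrichment over a same-sized"
    "\nnucleoplasmic region (DAPI-normalised): ~4.4 at the end of G1 in"
    "\ncontrol, only ~2.8 after macroH2A1 knockdown -- fewer licensed"
    "\norigins get loaded with helicase on the Xi."
)
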