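"""macroH2A1-Mcm2 interaction read out as PLA spots per nucleus.

Counts prominence->40 maxima on maximum projections and derives the
Xi spot density fold over the control nuclear average.
"""

import numpy as np

import xirep as xr

cells = []
for i in range(10):
    image, gt = xr.make_nucleus_image(
        "scramble", seed=500 + i, n_xi=1, channels=("DAPI", "PLA"),
        fixed_counts=True,
    )
    cells.append(xr.pla_measurements(image, gt.nucleus_mask(0), gt.xi_mask(0)))

counts = [c.counts["pla_spots_nucleus"] for c in cells]
ref = float(np.mean([xr.pla_density(c, "nucleus") for c in cells]))
fold = float(np.mean([xr.pla_density(c, "xi") / ref for c in cells]))
print(f"nuclear spots per cell: {np.mean(counts):.1f}")
print(f"Xi density fold over nuclear average: {fold:.2f}")

print(
    "\nEach spot is one in-situ macroH2A1-Mcm2 proximity event (<40 nm);"
    "\n~20 spots per control nucleus, and the spot density per DNA amount"
    "\nis ~2.5-fold higher inside the Xi, where both proteins concentrate."
)
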