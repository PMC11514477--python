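"""DNA-halo radius and circularity, plus an X-FISH radial profile.

Chromatin loops extrude from the extracted nuclear scaffold; the halo
radius R = sqrt(Ah/pi) proxies loop size and hence inter-origin distance.
"""

import numpy as np

import xirep as xr
from xirep.halo import segment_halo

for label, factor, irregularity in (
    ("scramble", 1.35, 0.05), ("mh2a1_kd", 2.2 * 1.35, 0.35)
):
    image, truth = xr.make_halo_image(
        scaffold_radius=5.0, halo_radius_factor=factor,
        irregularity=irregularity, seed=11,
    )
    m = xr.measure_halo(image)
    print(
        f"{label:10s}  R = {m.R_um:5.2f} um (truth {truth['R_um']:5.2f}),"
        f"  circularity = {m.circularity:.3f}"
    )

# FISH signal relative to the scaffold border
image, _ = xr.make_halo_image(
    5.0, 2.5, 0.0, seed=12, fish_band_um=(1.0, 3.0)
)
_, scaffold = segment_halo(image)
profile = xr.fish_line_profile(image, scaffold, seed=12)
peak = profile.distances_um[np.nanargmax(profile.intensities_norm)]
print(f"X-FISH profile peak at {peak:.1f} um from the scaffold border")

print(
    "\nA >2-fold larger, less circular halo after macroH2A1 knockdown"
    "\nmeans longer, more irregular chromatin loops (larger inter-origin"
    "\ndistances); the FISH profile locates the X territory relative to"
    "\nthe scaffold."
)
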