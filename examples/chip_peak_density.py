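"""macroH2A ChIP-peak density per chromosome (peaks/Mb).

Builds a toy peak set with X enrichment and computes per-chromosome
densities with the conservation-normalised variant.
"""

import numpy as np
import pandas as pd

import xirep as xr
from xirep.genomics import PeakSet

rng = np.random.default_rng(0)
sizes = {f"chr{i}": 150_000_000 for i in range(1, 6)}
sizes["chrX"] = 171_030_000

rows = []
for chrom, length in sizes.items():
    n = 60 if chrom != "chrX" else 140  # X carries ~2x the autosomal density
    for s in rng.integers(0, length - 1000, size=n):
        rows.append((chrom, int(s), int(s) + 500))
peaks = PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), "macroH2A1")

table = xr.peak_density(peaks, sizes)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
auto = table[table["chrom"] != "chrX"]["density_per_mb"].mean()
x = table.set_index("chrom").loc["chrX", "density_per_mb"]
print(f"\nchrX / autosome density ratio: {x / auto:.2f}")
print(
    "A ratio near 2 reproduces the female-line signature: macroH2A"
    "\nenrichment concentrates on the (inactive) X chromosome."
)
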