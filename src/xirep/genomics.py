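"""ChIP-peak density per chromosome.

Downstream-only genomics: given already-called peak intervals (BED) and a
chromosome-sizes table, compute peaks per megabase per chromosome
(optionally normalised by the total peak count, so that
``sum_c density_c * Mb_c = 1``), and intersect several peak sets into the
reproducibly enriched intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "PeakSet",
    "read_bed",
    "read_chrom_sizes",
    "peak_density",
    "reproducible_peaks",
]


@dataclass
class PeakSet:
    """A set of genomic intervals in 0-based half-open coordinates.

    ``intervals`` is a DataFrame with columns ``chrom``, ``start``, ``end``.
    """

    intervals: pd.DataFrame
    source_label: str = "peaks"

    def __post_init__(self) -> None:
        df = self.intervals
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise InvalidParameterError(f"intervals missing columns {sorted(missing)}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise InvalidParameterError("every interval needs start < end")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


def read_bed(path: str | Path, source_label: str | None = None) -> PeakSet:
    """Read a BED3+ file (0-based half-open, as standard)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return PeakSet(df, source_label or path.stem)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom / length TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    sizes = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    if any(v <= 0 for v in sizes.values()):
        raise InvalidParameterError("chromosome lengths must be > 0")
    return sizes


def peak_density(
    peaks: PeakSet, sizes: dict[str, int], normalize: bool = False
) -> pd.DataFrame:
    """Peaks per megabase per chromosome.

    ``density_c = count_c / (length_c / 1e6)``; with ``normalize`` the
    density is further divided by the total peak count, which makes the
    densities conserve ``sum_c density_c * Mb_c = 1``.  Chromosomes absent
    from ``sizes`` raise with the offenders listed; chromosomes present in
    ``sizes`` but without peaks report density 0.
    """
    if any(v <= 0 for v in sizes.values()):
        raise InvalidParameterError("chromosome lengths must be > 0")
    counts = peaks.intervals.groupby("chrom").size()
    unknown = sorted(set(counts.index) - set(sizes))
    if unknown:
        raise InvalidParameterError(
            f"peaks on chromosomes missing from sizes table: {unknown}"
        )
    rows = []
    total = len(peaks)
    for chrom, length in sizes.items():
        n = int(counts.get(chrom, 0))
        mb = length / 1e6
        dens = n / mb
        if normalize:
            if total == 0:
                raise InvalidParameterError("cannot normalise an empty peak set")
            dens /= total
        rows.append(
            {"chrom": chrom, "n_peaks": n, "length_mb": mb, "density_per_mb": dens}
        )
    return pd.DataFrame(rows)


def _merge_overlapping(df: pd.DataFrame) -> pd.DataFrame:
    """Merge strictly overlapping intervals within one set (zero-length
    touching intervals stay separate); output sorted by (chrom, start)."""
    rows = []
    for chrom, grp in df.groupby("chrom"):
        cur_s = cur_e = None
        for s, e in grp.sort_values("start")[["start", "end"]].itertuples(index=False):
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s < cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_e is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def _intersect_two(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int
) -> pd.DataFrame:
    """Sweep-line intersection of two interval tables per chromosome.

    Inputs are merged within each set first (the two-pointer sweep requires
    internally disjoint lists); zero-length touching does not count as
    overlap.
    """
    a = _merge_overlapping(a)
    b = _merge_overlapping(b)
    out = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ai = a[a["chrom"] == chrom].sort_values("start").to_numpy()
        bi = b[b["chrom"] == chrom].sort_values("start").to_numpy()
        i = j = 0
        while i < len(ai) and j < len(bi):
            s = max(ai[i][1], bi[j][1])
            e = min(ai[i][2], bi[j][2])
            if e - s >= max(min_overlap_bp, 1):
                out.append((chrom, int(s), int(e)))
            if ai[i][2] <= bi[j][2]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def reproducible_peaks(
    peaksets: list[PeakSet], min_overlap_bp: int = 1
) -> PeakSet:
    """Intervals reproducibly enriched in every peak set.

    Folds pairwise sweep-line intersections across all sets; the output
    intervals are the common intersections, each overlapping every input by
    at least ``min_overlap_bp``.
    """
    if len(peaksets) < 2:
        raise InvalidParameterError("need >= 2 peak sets")
    if min_overlap_bp < 1:
        raise InvalidParameterError("min_overlap_bp must be >= 1")
    current = peaksets[0].intervals
    for ps in peaksets[1:]:
        if current.empty:
            break
        current = _intersect_two(current, ps.intervals, min_overlap_bp)
    label = "&".join(ps.source_label for ps in peaksets)
    return PeakSet(current, source_label=label)
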