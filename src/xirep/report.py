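"""Group statistics and report assembly.

Condition comparisons use the rank-based two-sample test (Mann-Whitney /
Wilcoxon rank-sum; a paired signed-rank variant is available for matched
samples).  Significance stars follow the banding: * for p < 0.05,
** for p < 0.005, *** for p < 0.0005, n.s. otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, NormalizationAnchorError

__all__ = ["significance_stars", "group_compare", "build_report"]


def significance_stars(p: float) -> str:
    """Star label for a p-value: bands [0.05, 0.005, 0.0005)."""
    if not 0 <= p <= 1:
        raise InvalidParameterError(f"p-value {p} outside [0, 1]")
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def group_compare(
    a, b, paired: bool = False, exact_max_n: int = 25
) -> tuple[float, float, str]:
    """Rank-based two-sample comparison: ``(statistic, p, stars)``.

    Unpaired uses the Mann-Whitney U (exact p for combined n <=
    ``exact_max_n`` without ties, normal approximation with tie correction
    otherwise); ``paired=True`` uses the Wilcoxon signed-rank test on
    matched samples.  Each sample needs >= 3 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InvalidParameterError("each sample needs >= 3 values")
    if paired:
        if len(a) != len(b):
            raise InvalidParameterError("paired samples must match in length")
        if np.allclose(a, b):
            return 0.0, 1.0, "n.s."
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        method = (
            "exact"
            if (len(a) + len(b) <= exact_max_n and len(np.unique(np.r_[a, b])) == len(a) + len(b))
            else "asymptotic"
        )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), p, significance_stars(p)


def build_report(
    cells: pd.DataFrame,
    control: str | None = None,
    value_col: str = "value",
    group_cols: tuple[str, ...] = ("metric", "condition"),
) -> pd.DataFrame:
    """Summarise a tidy per-cell table into per-(metric, condition) rows.

    Input columns: the ``group_cols`` plus ``value_col``.  Each output row
    carries N, mean, median, SD, SEM (= SD/sqrt(N)) and the 95% normal CI.
    With ``control`` set, each non-control condition is compared with the
    control of the same metric (rank-based p and stars); a missing control
    raises.  The assembly is deterministic: rows sorted by the group keys.
    """
    required = set(group_cols) | {value_col}
    if not required <= set(cells.columns):
        raise InvalidParameterError(f"cells table needs columns {sorted(required)}")
    cond_col = group_cols[-1]
    if control is not None and control not in set(cells[cond_col]):
        raise NormalizationAnchorError(f"control condition {control!r} missing")
    rows = []
    for keys, grp in cells.groupby(list(group_cols), sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        n = len(vals)
        sd = vals.std(ddof=1) if n > 1 else 0.0
        sem = sd / np.sqrt(n) if n else np.nan
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row.update(
            n=n,
            mean=vals.mean(),
            median=float(np.median(vals)),
            sd=sd,
            sem=sem,
            ci95_lo=vals.mean() - 1.96 * sem,
            ci95_hi=vals.mean() + 1.96 * sem,
        )
        if control is not None and row[cond_col] != control:
            sel = cells
            for c, k in zip(group_cols[:-1], (keys if isinstance(keys, tuple) else (keys,))[:-1]):
                sel = sel[sel[c] == k]
            ctrl_vals = sel[sel[cond_col] == control][value_col].to_numpy(dtype=float)
            if len(ctrl_vals) >= 3 and n >= 3:
                _, p, stars = group_compare(ctrl_vals, vals)
                row.update(p_vs_control=p, stars=stars)
        rows.append(row)
    return pd.DataFrame(rows)
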