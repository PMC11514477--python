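"""Replication timing arithmetic: live-imaging persistence and onset,
growth/doubling-time bookkeeping, S-phase duration, and the fork-speed /
compensation model.

The fork-speed model estimates the average DNA synthesis rate per fork on a
chromosome replicated by ``N`` simultaneously active origins over ``T``
minutes:

    speed = L / (T * forks * waves),   forks = N * 2 if bidirectional

where ``L`` is the chromosome length in base pairs and ``waves`` allows the
origins to fire in successive activation waves (w waves mean w-fold more
origins in total and w-fold slower forks for the same total duration).
The compensation index ``(N_kd / N_ctrl) * relative_speed`` is ~1 when a
change in origin number is exactly offset by the change in fork speed,
leaving total replication duration unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AmbiguityError, InvalidParameterError, UndefinedRatioError

__all__ = [
    "GrowthSeries",
    "ForkSpeedModel",
    "MOUSE_X_LENGTH_BP",
    "XI_PATTERN_LABELS",
    "S_PHASE_LABELS",
    "xi_persistence_minutes",
    "cohort_persistence_minutes",
    "xi_onset_minutes",
    "growth_rate_per_hour",
    "doubling_time",
    "sphase_duration",
    "fork_speed",
    "round_to_sig",
    "compensation_index",
    "percent_change",
]

#: Length of the mouse X chromosome in base pairs.
MOUSE_X_LENGTH_BP = 171_030_000

#: Frame labels counted as the synchronous Xi replication pattern.
XI_PATTERN_LABELS = frozenset({"mid_xi", "xi_pattern"})
#: Frame labels counted as S phase.
S_PHASE_LABELS = frozenset({"early", "mid_xi", "xi_pattern", "late"})


@dataclass(frozen=True)
class GrowthSeries:
    """Cell counts over time (hours); t strictly increasing, n positive."""

    t_h: tuple[float, ...]
    n: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.t_h) != len(self.n) or len(self.t_h) < 2:
            raise InvalidParameterError("need >= 2 matched (t, n) points")
        if any(b <= a for a, b in zip(self.t_h, self.t_h[1:])):
            raise InvalidParameterError("time points must strictly increase")
        if any(v <= 0 for v in self.n):
            raise InvalidParameterError("counts must be positive")


@dataclass(frozen=True)
class ForkSpeedModel:
    """Arithmetic replication model of one chromosome.

    ``length_bp``: chromosome size; ``duration_min``: total replication
    duration; ``n_origins``: simultaneously active origins; ``waves``:
    successive origin-activation waves (>= 1).
    """

    length_bp: float
    duration_min: float
    n_origins: float
    bidirectional: bool = True
    waves: int = 1

    def __post_init__(self) -> None:
        if min(self.length_bp, self.duration_min, self.n_origins) <= 0:
            raise InvalidParameterError("model quantities must be positive")
        if self.waves < 1:
            raise InvalidParameterError("waves must be >= 1")

    @property
    def forks(self) -> float:
        return self.n_origins * (2 if self.bidirectional else 1)


# ---------------------------------------------------------------------------
# live-imaging timing
# ---------------------------------------------------------------------------


def _pattern_runs(labels: Sequence[str]) -> list[tuple[int, int]]:
    """Contiguous (start, stop) runs of Xi-pattern frames."""
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if lab in XI_PATTERN_LABELS:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def xi_persistence_minutes(
    labels: Sequence[str], frame_interval_min: float
) -> tuple[float, bool]:
    """Duration of the synchronous Xi replication pattern in one cell.

    Returns ``(minutes, censored)`` where minutes is the single contiguous
    Xi-pattern run length times the frame interval (0 if the pattern never
    appears) and ``censored`` flags runs touching the first or last frame
    (their true duration is unknown).  Two or more disjoint runs raise
    :class:`AmbiguityError` rather than being merged.
    """
    if frame_interval_min <= 0:
        raise InvalidParameterError("frame_interval_min must be > 0")
    runs = _pattern_runs(labels)
    if len(runs) > 1:
        raise AmbiguityError(f"{len(runs)} disjoint Xi-pattern runs in sequence")
    if not runs:
        return 0.0, False
    start, stop = runs[0]
    censored = start == 0 or stop == len(labels)
    return (stop - start) * frame_interval_min, censored


def cohort_persistence_minutes(
    sequences: Sequence[Sequence[str]],
    frame_interval_min: float,
    exclude_censored: bool = True,
) -> tuple[float, list[float]]:
    """Mean Xi-pattern persistence over a cohort of live sequences.

    Frame-censored runs (pattern present in the first or last frame) are
    excluded from the mean by default.  Returns ``(mean, per_cell_minutes)``
    over the retained cells.
    """
    durations = []
    for seq in sequences:
        minutes, censored = xi_persistence_minutes(seq, frame_interval_min)
        if censored and exclude_censored:
            continue
        durations.append(minutes)
    if not durations:
        raise InvalidParameterError("no uncensored sequences in cohort")
    return float(np.mean(durations)), durations


def xi_onset_minutes(labels: Sequence[str], frame_interval_min: float) -> float:
    """Minutes from S-phase start to the first Xi-pattern frame."""
    if frame_interval_min <= 0:
        raise InvalidParameterError("frame_interval_min must be > 0")
    s_start = next((i for i, l in enumerate(labels) if l in S_PHASE_LABELS), None)
    xi_start = next((i for i, l in enumerate(labels) if l in XI_PATTERN_LABELS), None)
    if s_start is None or xi_start is None:
        raise InvalidParameterError("sequence must contain S-phase and Xi-pattern frames")
    if xi_start < s_start:
        raise InvalidParameterError("Xi pattern precedes the S-phase start")
    return (xi_start - s_start) * frame_interval_min


# ---------------------------------------------------------------------------
# growth arithmetic
# ---------------------------------------------------------------------------


def growth_rate_per_hour(series: GrowthSeries) -> float:
    """Exponential growth rate ``log2(nx/n0)/t`` in doublings per hour,
    computed from the first and last points of the series."""
    n0, nx = series.n[0], series.n[-1]
    dt = series.t_h[-1] - series.t_h[0]
    if nx <= n0:
        raise UndefinedRatioError("population did not grow; rate undefined")
    return math.log2(nx / n0) / dt


def doubling_time(series: GrowthSeries) -> float:
    """Population doubling time in hours: the reciprocal of the growth rate
    (time for the count to double)."""
    return 1.0 / growth_rate_per_hour(series)


def sphase_duration(doubling_time_h: float, fraction_s: float) -> float:
    """S-phase duration: doubling time times the fraction of cells in S.
    (Under steady exponential growth the time spent in a phase is
    proportional to the fraction of cells observed in it.)"""
    if doubling_time_h <= 0:
        raise InvalidParameterError("doubling_time_h must be > 0")
    if not 0 <= fraction_s <= 1:
        raise InvalidParameterError("fraction_s must lie in [0, 1]")
    return doubling_time_h * fraction_s


# ---------------------------------------------------------------------------
# fork-speed model
# ---------------------------------------------------------------------------


def fork_speed(model: ForkSpeedModel) -> float:
    """Average fork speed in nucleotides per minute:
    ``L / (T * forks * waves)``.  Full precision; round for presentation
    with :func:`round_to_sig`."""
    return model.length_bp / (model.duration_min * model.forks * model.waves)


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0:
        return 0.0
    return float(round(x, sig - 1 - int(math.floor(math.log10(abs(x))))))


def compensation_index(
    n_kd: float, n_ctrl: float, speed_kd_rel: float
) -> float:
    """Origin-number x fork-speed compensation: ``(n_kd/n_ctrl) * s_rel``.

    ~1 means the change in simultaneously active origins is offset by the
    change in fork speed, leaving total replication duration unchanged;
    values away from 1 mean the duration itself changes.
    """
    if min(n_kd, n_ctrl, speed_kd_rel) <= 0:
        raise InvalidParameterError("all inputs must be positive")
    return (n_kd / n_ctrl) * speed_kd_rel


def percent_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise UndefinedRatioError("zero reference")
    return 100.0 * (value - reference) / reference
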