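"""Ratio and level statistics computed per cell.

All quantities here are ratios of region sum intensities (``RawIntDen``
style), so they are invariant to the global intensity scale:

* EdU/PCNA progression ratio -- nucleotides incorporated during a labelling
  pulse per unit of replisome signal; faster forks incorporate more EdU per
  PCNA.
* loading coefficient -- DAPI-normalised target (Mcm2/ORC1/Cdc6/Cdt1) sum
  in the Xi (ROI1) divided by the DAPI-normalised sum in an equal-sized
  control region outside the Xi (ROI2); computed on maximum-intensity
  projections.
* PLA spot density -- spots per DAPI sum intensity, control-normalised;
  the Xi fold is the normalised Xi density.
* RPA coefficient-of-variation curves -- cV = sigma/mu of the RPA signal
  per frame, normalised to the pretreatment frame; focal RPA accumulation
  (helicase/polymerase uncoupling) drives cV up.
* Xi relative area, histone/protein levels and the DAPI-SD decondensation
  proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InconsistencyError,
    InvalidParameterError,
    NormalizationAnchorError,
    UndefinedCvError,
    UndefinedRatioError,
)
from .image import RegionMask, VoxelImage

__all__ = [
    "CellRecord",
    "CvCurve",
    "LoadingCurve",
    "region_sum",
    "measure_cell",
    "edu_pcna_ratio",
    "control_normalize",
    "rpa_cv_curve",
    "loading_coefficient",
    "loading_curve",
    "pla_density",
    "xi_relative_area",
    "histone_level",
    "dapi_sd",
]


@dataclass
class CellRecord:
    """Per-cell measurement row.

    ``region_sums`` maps ``(region, channel)`` to a sum intensity;
    ``region_areas`` maps region to μm² (2D) or μm³; ``counts`` holds
    integer metrics such as ``"pla_spots_nucleus"``; ``derived`` collects
    computed ratios.
    """

    cell_id: int | str
    condition: str = "unknown"
    time_point: float | None = None
    region_sums: dict = field(default_factory=dict)
    region_areas: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def get_sum(self, region: str, channel: str) -> float:
        try:
            val = self.region_sums[(region, channel)]
        except KeyError:
            raise InvalidParameterError(
                f"cell {self.cell_id}: no sum for region={region!r}, "
                f"channel={channel!r}"
            ) from None
        if val < 0:
            raise InvalidParameterError("region sums must be >= 0")
        return float(val)


@dataclass
class CvCurve:
    """Coefficient-of-variation time course, pretreatment-normalised."""

    time_points: list[float]
    cv_raw: list[float]
    cv_norm: list[float]
    condition: str = "unknown"

    def __post_init__(self) -> None:
        if not (len(self.time_points) == len(self.cv_raw) == len(self.cv_norm)):
            raise InvalidParameterError("curve arrays must have equal length")


@dataclass
class LoadingCurve:
    """Per-condition G1 loading trajectory, anchored to control at t1."""

    time_points: list[float]
    values: list[float]
    condition: str
    target: str = "Mcm2"
    scope: str = "xi"


# ---------------------------------------------------------------------------


def region_sum(image: VoxelImage, channel: str, mask: RegionMask) -> float:
    """Exact sum of channel intensities over the true voxels of the mask."""
    mask.check_alignment(image)
    return float(image.channel(channel)[mask.mask].sum())


def measure_cell(
    image: VoxelImage,
    regions: dict[str, RegionMask],
    cell_id: int | str = 0,
    condition: str = "unknown",
    time_point: float | None = None,
    channels: list[str] | None = None,
) -> CellRecord:
    """Build a :class:`CellRecord` with sums of every channel over every
    region, plus region areas/volumes."""
    channels = list(channels or image.channel_names)
    rec = CellRecord(cell_id=cell_id, condition=condition, time_point=time_point)
    for rname, rmask in regions.items():
        rec.region_areas[rname] = rmask.area_or_volume
        for ch in channels:
            rec.region_sums[(rname, ch)] = region_sum(image, ch, rmask)
    return rec


def edu_pcna_ratio(cell: CellRecord, region: str = "xi") -> float:
    """Replication progression rate proxy: sum(EdU)/sum(PCNA) over a region.

    More nucleotide incorporated per replisome in a fixed pulse means
    faster fork progression.  Normalise across a population with
    :func:`control_normalize`.
    """
    edu = cell.get_sum(region, "EdU")
    pcna = cell.get_sum(region, "PCNA")
    if pcna == 0:
        raise UndefinedRatioError(f"cell {cell.cell_id}: zero PCNA sum in {region}")
    return edu / pcna


def control_normalize(
    values: np.ndarray | list[float],
    conditions: np.ndarray | list[str],
    control: str = "scramble",
) -> np.ndarray:
    """Divide per-cell values by the mean of the control condition."""
    values = np.asarray(values, dtype=float)
    conditions = np.asarray(conditions)
    sel = conditions == control
    if not sel.any():
        raise NormalizationAnchorError(f"no cells with control condition {control!r}")
    ref = values[sel].mean()
    if ref == 0:
        raise UndefinedRatioError("control mean is zero")
    return values / ref


def rpa_cv_curve(
    frames: list[VoxelImage],
    masks: list[RegionMask],
    channel: str = "RPA",
    time_points: list[float] | None = None,
    condition: str = "unknown",
    ddof: int = 0,
) -> CvCurve:
    """Per-frame coefficient of variation cV = sigma/mu of the RPA signal
    inside the mask, normalised to the pretreatment frame (index 0).

    ``ddof=0`` (population standard deviation) by default; set 1 for the
    sample convention.  A zero mean in any frame, or a zero pretreatment
    cV, raises :class:`UndefinedCvError`.
    """
    if len(frames) < 2:
        raise InvalidParameterError("need >= 2 frames (pretreatment + follow-up)")
    if len(frames) != len(masks):
        raise InvalidParameterError("one mask per frame required")
    cv_raw = []
    for t, (img, m) in enumerate(zip(frames, masks)):
        m.check_alignment(img)
        vals = img.channel(channel)[m.mask]
        mu = float(vals.mean())
        if mu == 0:
            raise UndefinedCvError(f"frame {t}: zero mean intensity")
        cv_raw.append(float(vals.std(ddof=ddof)) / mu)
    if cv_raw[0] == 0:
        raise UndefinedCvError("pretreatment cV is zero; cannot normalise")
    tps = list(time_points) if time_points is not None else list(range(len(frames)))
    return CvCurve(tps, cv_raw, [c / cv_raw[0] for c in cv_raw], condition)


def loading_coefficient(
    image: VoxelImage,
    target_channel: str,
    xi: RegionMask,
    roi2: RegionMask,
    dapi_channel: str = "DAPI",
) -> float:
    """Helicase/pre-RC loading coefficient on the maximum-intensity
    projection:

    ``[sum(target, ROI1)/sum(DAPI, ROI1)] / [sum(target, ROI2)/sum(DAPI, ROI2)]``

    with ROI1 the Xi and ROI2 the congruent control region outside it.
    Masks may be 3D (their Z-footprint is used) or already-projected 2D
    ROIs.  Any zero of the four sums raises :class:`UndefinedRatioError`.
    """
    for m in (xi, roi2):
        if m.mask.shape[1:] != image.shape[1:]:
            raise InvalidParameterError(
                "ROI footprint does not match the image XY shape"
            )
    t_mip = image.max_projection(target_channel)
    d_mip = image.max_projection(dapi_channel)
    m1 = xi.mask.any(axis=0)
    m2 = roi2.mask.any(axis=0)
    sums = {
        "target_roi1": float(t_mip[m1].sum()),
        "dapi_roi1": float(d_mip[m1].sum()),
        "target_roi2": float(t_mip[m2].sum()),
        "dapi_roi2": float(d_mip[m2].sum()),
    }
    for k, v in sums.items():
        if v == 0:
            raise UndefinedRatioError(f"zero {k} sum")
    return (sums["target_roi1"] / sums["dapi_roi1"]) / (
        sums["target_roi2"] / sums["dapi_roi2"]
    )


def loading_curve(
    cells: pd.DataFrame,
    target: str = "Mcm2",
    scope: str = "xi",
    control: str = "scramble",
    value_col: str = "coefficient",
    anchor_time: float | None = None,
) -> dict[str, LoadingCurve]:
    """Aggregate per-cell loading coefficients into per-condition G1 curves,
    normalised by the control mean at the first (anchor) time point.

    ``cells`` needs columns ``condition``, ``time_point`` and ``value_col``.
    The returned control curve therefore starts at 1 by construction.
    """
    required = {"condition", "time_point", value_col}
    if not required <= set(cells.columns):
        raise InvalidParameterError(f"cells table needs columns {sorted(required)}")
    if cells["time_point"].nunique() < 2:
        raise InvalidParameterError("need >= 2 time points for a curve")
    t1 = anchor_time if anchor_time is not None else cells["time_point"].min()
    anchor = cells[(cells["condition"] == control) & (cells["time_point"] == t1)]
    if anchor.empty:
        raise NormalizationAnchorError(
            f"no control ({control!r}) cells at anchor time {t1}"
        )
    ref = anchor[value_col].mean()
    if ref == 0:
        raise UndefinedRatioError("control anchor mean is zero")
    out = {}
    means = (
        cells.groupby(["condition", "time_point"])[value_col]
        .mean()
        .unstack("time_point")
        .sort_index(axis=1)
    )
    for cond, row in means.iterrows():
        out[cond] = LoadingCurve(
            time_points=list(row.index),
            values=list(row.to_numpy() / ref),
            condition=str(cond),
            target=target,
            scope=scope,
        )
    return out


def pla_density(cell: CellRecord, region: str = "nucleus") -> float:
    """PLA spot density: spot count divided by the DAPI sum intensity of the
    region (spots per DNA amount).  Normalise a population with
    :func:`control_normalize` on nuclear densities; the Xi fold of a cell is
    its normalised Xi density."""
    key = f"pla_spots_{region}"
    if key not in cell.counts:
        raise InvalidParameterError(f"cell {cell.cell_id}: missing count {key!r}")
    dapi = cell.get_sum(region, "DAPI")
    if dapi == 0:
        raise UndefinedRatioError(f"cell {cell.cell_id}: zero DAPI sum in {region}")
    return float(cell.counts[key]) / dapi


def xi_relative_area(cell: CellRecord) -> float:
    """Xi share of nuclear DNA: sum(DAPI, Xi)/sum(DAPI, nucleus), in (0, 1].
    A decondensed Xi spreads over more projected area and a larger share."""
    xi = cell.get_sum("xi", "DAPI")
    nuc = cell.get_sum("nucleus", "DAPI")
    if nuc == 0:
        raise UndefinedRatioError("zero nuclear DAPI sum")
    if xi > nuc:
        raise InconsistencyError("Xi DAPI sum exceeds nuclear DAPI sum")
    return xi / nuc


def histone_level(
    cell: CellRecord, channel: str, region: str, control_mean: float
) -> float:
    """Control-normalised level of a histone mark or chromatin protein:
    region sum divided by the control-population mean of the same sum."""
    if control_mean <= 0:
        raise UndefinedRatioError("control mean must be > 0")
    return cell.get_sum(region, channel) / control_mean


def dapi_sd(image: VoxelImage, nucleus: RegionMask, channel: str = "DAPI") -> float:
    """Standard deviation of DAPI intensities inside the nucleus: a proxy
    for chromatin condensation (uniform, decondensed chromatin -> low SD)."""
    if nucleus.is_empty:
        raise InvalidParameterError("empty nucleus mask")
    nucleus.check_alignment(image)
    return float(image.channel(channel)[nucleus.mask].std(ddof=0))
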