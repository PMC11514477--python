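"""Mask generation and cell gating.

Nucleus and Xi masks come from triangle auto-thresholding of the DAPI and
H3K27me3 channels (the Xi territory is the H3K27me3-enriched cluster inside
the nucleus); control regions congruent to the Xi are placed at seeded
random positions in the remaining nucleoplasm, excluding chromocenters.
DNA-content gating (G1 selection) and the rule-based S-phase pattern call
operate downstream of these masks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import (
    DegenerateHistogramError,
    InsufficientPopulationError,
    InvalidParameterError,
    PlacementError,
)
from .image import RegionMask, VoxelImage

__all__ = [
    "triangle_threshold_value",
    "triangle_threshold",
    "segment_nucleus",
    "segment_xi",
    "chromocenter_mask",
    "control_roi",
    "gate_g1",
    "classify_sphase_pattern",
]

_STRUCT3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def _triangle_bin(counts: np.ndarray) -> int:
    """Index of the triangle-method threshold bin for a histogram.

    Geometric construction: draw the line from the histogram peak to the far
    end of its longer tail; the threshold bin maximises the perpendicular
    distance from the histogram profile to that line.  The histogram is
    mirrored when the long tail lies left of the peak, so the computation
    always runs peak-to-right-tail.
    """
    counts = np.asarray(counts, dtype=float)
    nz = np.nonzero(counts)[0]
    if len(nz) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two occupied bins"
        )
    peak = int(np.argmax(counts))
    lo, hi = nz[0], nz[-1]
    flipped = (peak - lo) > (hi - peak)
    if flipped:
        counts = counts[::-1]
        peak = len(counts) - 1 - peak
        hi = len(counts) - 1 - lo
    # line from (peak, h_peak) to (hi, 0); distance of (i, h_i) to it
    dx = hi - peak
    dy = counts[peak]  # - 0
    norm = np.hypot(dx, dy)
    idx = np.arange(peak, hi + 1)
    # perpendicular distance (positive where the histogram dips below the line)
    dist = (dx * (counts[peak] - counts[idx]) - dy * (idx - peak)) / norm
    best = int(idx[np.argmax(dist)])
    if flipped:
        best = len(counts) - 1 - best
    return best


def triangle_threshold_value(
    values: np.ndarray, n_bins: int = 256
) -> float:
    """Triangle-method threshold of an intensity sample (256-bin histogram).

    Returns the intensity at the centre of the selected bin; voxels strictly
    above it are foreground.
    """
    values = np.asarray(values).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateHistogramError("constant image (single intensity)")
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    best = _triangle_bin(counts)
    return float(0.5 * (edges[best] + edges[best + 1]))


def triangle_threshold(
    image: VoxelImage,
    channel: str,
    within: RegionMask | None = None,
    largest_component: bool = False,
) -> RegionMask:
    """Binary mask of voxels above the triangle threshold of one channel.

    The threshold is computed on a 256-bin histogram over the whole stack
    (or over ``within`` if given).  A constant image raises
    :class:`DegenerateHistogramError` rather than returning a full or empty
    mask.
    """
    data = image.channel(channel)
    sample = data[within.mask] if within is not None else data
    if sample.size == 0:
        raise InvalidParameterError("empty restriction mask")
    thr = triangle_threshold_value(sample)
    mask = data > thr
    if within is not None:
        mask &= within.mask
    if largest_component and mask.any():
        lab, n = ndimage.label(mask, structure=_STRUCT3D)
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return RegionMask(mask, "total", image.voxel_size)


def segment_nucleus(
    image: VoxelImage,
    min_volume_um3: float = 50.0,
    max_volume_um3: float | None = None,
    channel: str = "DAPI",
) -> list[RegionMask]:
    """Segment nuclei: triangle threshold on DAPI, hole filling, connected
    components above a minimum volume (26-connectivity in 3D).

    Components exceeding ``max_volume_um3`` (e.g. touching nuclei in crowded
    fields) are returned with label ``"nucleus_review"`` instead of being
    merged silently.  An effectively empty field yields an empty list.
    """
    try:
        raw = triangle_threshold(image, channel)
    except DegenerateHistogramError:
        return []
    filled = ndimage.binary_fill_holes(raw.mask)
    lab, n = ndimage.label(filled, structure=_STRUCT3D)
    out: list[RegionMask] = []
    vx = image.voxel_volume_um3 if not image.is_2d else image.pixel_area_um2
    for i in range(1, n + 1):
        comp = lab == i
        vol = comp.sum() * vx
        if vol < min_volume_um3:
            continue
        label = "nucleus"
        if max_volume_um3 is not None and vol > max_volume_um3:
            label = "nucleus_review"
        out.append(RegionMask(comp, label, image.voxel_size))
    # deterministic order: by centroid along X
    out.sort(key=lambda m: np.argwhere(m.mask)[:, 2].mean())
    return out


def segment_xi(
    image: VoxelImage,
    nucleus: RegionMask,
    min_volume_um3: float = 0.5,
    channel: str = "H3K27me3",
) -> list[RegionMask]:
    """Segment Xi territories inside one nucleus from H3K27me3 enrichment.

    The triangle threshold is computed on the in-nucleus histogram; each
    supra-threshold connected cluster above ``min_volume_um3`` is one Xi
    copy, so the length of the returned list is the Xi copy number.  Cells
    with homogeneous H3K27me3 (no supra-threshold cluster, or a degenerate
    in-nucleus histogram) return an empty list.
    """
    if nucleus.is_empty:
        raise InvalidParameterError("nucleus mask is empty")
    nucleus.check_alignment(image)
    try:
        raw = triangle_threshold(image, channel, within=nucleus)
    except DegenerateHistogramError:
        return []
    lab, n = ndimage.label(raw.mask, structure=_STRUCT3D)
    vx = image.voxel_volume_um3 if not image.is_2d else image.pixel_area_um2
    out = []
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() * vx < min_volume_um3:
            continue
        out.append(RegionMask(comp & nucleus.mask, "xi", image.voxel_size))
    out.sort(key=lambda m: np.argwhere(m.mask)[:, 2].mean())
    return out


def chromocenter_mask(
    image: VoxelImage,
    nucleus: RegionMask,
    quantile: float = 0.98,
    channel: str = "DAPI",
) -> RegionMask:
    """High-quantile DAPI mask standing in for constitutive heterochromatin
    (chromocenters) when no major-satellite channel is available."""
    nucleus.check_alignment(image)
    data = image.channel(channel)
    vals = data[nucleus.mask]
    thr = float(np.quantile(vals, quantile))
    return RegionMask((data > thr) & nucleus.mask, "chromocenter", image.voxel_size)


def control_roi(
    nucleus: RegionMask,
    xi: RegionMask,
    chromocenters: RegionMask | None = None,
    seed: int = 0,
    max_attempts: int = 5000,
) -> RegionMask:
    """Place a control region congruent to the Xi elsewhere in the nucleus.

    The Xi mask is rigidly translated to a seeded random offset such that
    the copy lies fully inside the nucleus and does not intersect the Xi or
    the chromocenters; translation preserves the voxel count exactly.
    Raises :class:`PlacementError` when no admissible offset is found within
    ``max_attempts`` draws.
    """
    if xi.is_empty:
        raise InvalidParameterError("xi mask is empty")
    if nucleus.mask.shape != xi.mask.shape:
        raise InvalidParameterError("nucleus and xi masks are misaligned")
    allowed = nucleus.mask & ~xi.mask
    if chromocenters is not None:
        allowed &= ~chromocenters.mask
    if allowed.sum() < xi.n_voxels:
        raise PlacementError(
            "nucleus minus Xi/chromocenters cannot host a congruent region"
        )
    idx = np.argwhere(xi.mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    shape = np.array(xi.mask.shape)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        shift = np.array(
            [
                rng.integers(-lo[d], shape[d] - 1 - hi[d] + 1)
                for d in range(3)
            ]
        )
        if not shift.any():
            continue
        moved = idx + shift
        if allowed[moved[:, 0], moved[:, 1], moved[:, 2]].all():
            out = np.zeros_like(xi.mask)
            out[moved[:, 0], moved[:, 1], moved[:, 2]] = True
            return RegionMask(out, "control_roi", nucleus.voxel_size)
    raise PlacementError(
        f"no admissible control-ROI placement in {max_attempts} attempts"
    )


def gate_g1(
    cells: pd.DataFrame,
    half_width_frac: float = 0.15,
    dapi_col: str = "dapi_sum",
    edu_col: str = "edu_positive",
    n_bins: int = 64,
) -> pd.DataFrame:
    """Select G1 cells by DNA content: EdU-negative cells whose DAPI sum
    falls in a window around the lowest mode (2C peak) of the population
    histogram.

    The window is ``mode * (1 +/- half_width_frac)``.  Fewer than 10 cells
    raise :class:`InsufficientPopulationError` (a mode cannot be fitted).
    """
    if len(cells) < 10:
        raise InsufficientPopulationError(
            f"need >= 10 cells to locate the 2C mode, got {len(cells)}"
        )
    vals = cells[dapi_col].to_numpy(dtype=float)
    counts, edges = np.histogram(vals, bins=n_bins)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), sigma=1.0)
    peaks, _ = find_peaks(smooth)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
    mode = 0.5 * (edges[peaks[0]] + edges[peaks[0] + 1])  # lowest-DAPI mode
    lo, hi = mode * (1 - half_width_frac), mode * (1 + half_width_frac)
    keep = (~cells[edu_col].astype(bool)) & (vals >= lo) & (vals <= hi)
    return cells.loc[keep].copy()


def classify_sphase_pattern(
    image: VoxelImage,
    nucleus: RegionMask,
    xi_masks: list[RegionMask],
    chromocenters: RegionMask | None = None,
    mid_fraction: float = 0.4,
    late_fraction: float = 0.4,
    min_focal_fraction: float = 1e-4,
) -> str:
    """Rule-based replication-pattern call from the EdU (or PCNA) channel.

    Focal signal is the background-subtracted supra-threshold intensity
    inside the nucleus, ``(I - thr)+`` with thr the triangle threshold of
    the in-nucleus histogram (the subtraction keeps barely-supra-threshold
    nucleoplasmic signal from swamping bright foci).  The call is ``non_S``
    when focal signal is absent, ``mid_xi`` when at least ``mid_fraction``
    of it overlaps the Xi masks, ``late`` when it concentrates on
    chromocenters, ``early`` otherwise.  The thresholds are stand-ins for a
    call that was made by eye in the emulated workflow; accuracy on
    synthetic data is measured, not guaranteed.
    """
    for ch in ("EdU", "PCNA"):
        if image.has_channel(ch):
            channel = ch
            break
    else:
        raise InvalidParameterError("need an EdU or PCNA channel")
    nucleus.check_alignment(image)
    data = image.channel(channel)
    in_nuc = data[nucleus.mask]
    try:
        thr = triangle_threshold_value(in_nuc)
    except DegenerateHistogramError:
        return "non_S"
    # robust noise floor: keeps shot noise of diffuse nucleoplasmic signal
    # sitting at the threshold from masquerading as focal structure
    med = float(np.median(in_nuc))
    mad = float(np.median(np.abs(in_nuc - med)))
    thr = max(thr, med + 3.0 * 1.4826 * mad)
    focal = (data > thr) & nucleus.mask
    if focal.sum() < min_focal_fraction * nucleus.n_voxels:
        return "non_S"
    excess = np.where(focal, data - thr, 0.0)
    total = float(excess.sum())
    if total <= 0:
        return "non_S"
    xi_union = np.zeros_like(focal)
    for m in xi_masks:
        xi_union |= m.mask
    if float(excess[xi_union].sum()) / total >= mid_fraction:
        return "mid_xi"
    if chromocenters is not None:
        if float(excess[chromocenters.mask].sum()) / total >= late_fraction:
            return "late"
    return "early"
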