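"""Replication-focus and fluorescent-spot detection.

The 3D picker follows the local-maxima paradigm: after optional smoothing
and linear contrast stretching, every focus is represented by one and only
one maximum centre -- a voxel or a connected plateau of equal-intensity
voxels strictly brighter than all 26-neighbourhood surroundings -- and the
focus body is grown from the centre outward to the surrounding minima (or
down to ``centre - tolerance``), keeping the brightest ``fraction_f``
percent of its voxels.  Touching foci are separated by marker-controlled
watershed seeded at the maxima.  2D proximity-ligation (PLA) spots are
counted on maximum-intensity projections by topographic prominence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import InvalidParameterError
from .image import RegionMask, VoxelImage
from .segmentation import triangle_threshold_value

__all__ = [
    "FociParams",
    "Focus",
    "find_plateau_maxima",
    "pick_foci_3d",
    "count_nano_rfi",
    "pla_spot_count",
    "pla_measurements",
]

_STRUCT3D = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FociParams:
    """Picker parameters.

    ``background`` (intensity floor around foci) and ``tolerance`` (minimum
    intensity range inside a focus) default to data-driven values when left
    ``None``: the triangle threshold of the channel inside the search mask,
    and 10% of the in-mask dynamic range, both measured on the preprocessed
    image.  ``fraction_f`` is the brightest percentage of each focus body
    kept for volume bookkeeping.
    """

    background: float | None = None
    tolerance: float | None = None
    minimum_voxels: int = 1
    fraction_f: float = 50.0
    min_volume_um3: float = 0.0
    separate_touching: bool = True
    smooth: bool = True
    contrast_stretch: bool = True

    def __post_init__(self) -> None:
        if self.background is not None and self.background < 0:
            raise InvalidParameterError("background must be >= 0")
        if self.tolerance is not None and self.tolerance <= 0:
            raise InvalidParameterError("tolerance must be > 0")
        if not 0 < self.fraction_f <= 100:
            raise InvalidParameterError("fraction_f must lie in (0, 100]")
        if self.minimum_voxels < 1:
            raise InvalidParameterError("minimum_voxels must be >= 1")
        if self.min_volume_um3 < 0:
            raise InvalidParameterError("min_volume_um3 must be >= 0")


@dataclass(frozen=True)
class Focus:
    """One detected focus: its unique maximum centre and body statistics."""

    center_um: tuple[float, float, float]
    center_vox: tuple[int, int, int]
    volume_um3: float
    peak_intensity: float
    sum_intensity: float
    region_label: str = "xi"


def find_plateau_maxima(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    background: float = -np.inf,
) -> list[tuple[int, int, int]]:
    """Plateau-aware 3D local maxima (26-connectivity) above ``background``.

    A maximum centre is a voxel or connected group of equal-intensity voxels
    strictly brighter than every surrounding voxel (voxels outside ``mask``
    do not count as surroundings).  Each plateau contributes exactly one
    centre: the voxel nearest the plateau centroid, ties broken
    lexicographically by (z, y, x).
    """
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    work = np.where(mask, data, -np.inf)
    dil = ndimage.grey_dilation(work, footprint=_STRUCT3D, mode="constant", cval=-np.inf)
    cand = (work == dil) & mask & (work > background)
    lab, n = ndimage.label(cand, structure=_STRUCT3D)
    centers: list[tuple[int, int, int]] = []
    slices = ndimage.find_objects(lab)
    for i, sl in enumerate(slices, start=1):
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, data.shape)
        )
        local_lab = lab[sl] == i
        local = work[sl]
        value = local[local_lab].flat[0]
        ring = ndimage.binary_dilation(local_lab, structure=_STRUCT3D) & ~local_lab
        ring_in_mask = ring & mask[sl]
        # a focus must have a dimmer edge inside the search region: a
        # plateau spanning the whole mask is background, not a maximum
        if not ring_in_mask.any():
            continue
        # candidacy already guarantees no brighter neighbour; an equal-valued
        # neighbour outside the component means the plateau extends into a
        # region that is itself adjacent to something brighter -> not a max
        if np.any(local[ring] == value):
            continue
        idx = np.argwhere(local_lab)
        centroid = idx.mean(axis=0)
        d2 = ((idx - centroid) ** 2).sum(axis=1)
        best = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))[0]
        z, y, x = idx[best]
        centers.append((int(z + sl[0].start), int(y + sl[1].start), int(x + sl[2].start)))
    centers.sort()
    return centers


def _preprocess(data: np.ndarray, params: FociParams) -> np.ndarray:
    out = np.asarray(data, dtype=float)
    if params.smooth:
        out = ndimage.gaussian_filter(out, sigma=1.0)
    if params.contrast_stretch:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo) * 65535.0
    return out


def pick_foci_3d(
    image: VoxelImage,
    channel: str,
    mask: RegionMask,
    params: FociParams | None = None,
    region_label: str = "xi",
) -> list[Focus]:
    """Detect foci in a 3D stack by plateau-aware local maxima.

    Pipeline: (i) Gaussian smoothing (kernel 1 voxel) and linear contrast
    stretch; (ii) plateau maxima above ``background`` within ``mask``;
    (iii) body growth by watershed from each centre over the
    supra-background terrain, cut at ``centre - tolerance`` and reduced to
    the brightest ``fraction_f`` percent; (iv) drop bodies smaller than
    ``minimum_voxels``.  With ``separate_touching`` (default) the watershed
    splits merged bodies at their saddle; otherwise each focus takes the
    whole connected supra-cut component containing its centre (bodies of
    touching foci may then overlap).

    An empty mask yields an empty list.
    """
    params = params or FociParams()
    mask.check_alignment(image)
    if mask.is_empty:
        return []
    data = _preprocess(image.channel(channel), params)
    in_mask = data[mask.mask]
    if params.background is None:
        try:
            background = triangle_threshold_value(in_mask)
        except Exception:
            return []  # constant in-mask signal: nothing focal
    else:
        background = params.background
    if params.tolerance is None:
        rng_dyn = float(in_mask.max() - in_mask.min())
        if rng_dyn == 0:
            return []
        tolerance = 0.1 * rng_dyn
    else:
        tolerance = params.tolerance

    centers = find_plateau_maxima(data, mask.mask, background)
    if not centers:
        return []
    terrain = mask.mask & (data > background)
    markers = np.zeros(data.shape, dtype=np.int32)
    for i, c in enumerate(centers, start=1):
        markers[c] = i
    if params.separate_touching:
        body_lab = watershed(-data, markers=markers, mask=terrain, connectivity=3)
    else:
        comp_lab, _ = ndimage.label(terrain, structure=_STRUCT3D)
        body_lab = None

    vx_vol = image.voxel_volume_um3
    vs = image.voxel_size
    foci: list[Focus] = []
    for i, c in enumerate(centers, start=1):
        peak = float(data[c])
        if params.separate_touching:
            body = body_lab == i
        else:
            body = comp_lab == comp_lab[c]
        body &= data >= (peak - tolerance)
        n_body = int(body.sum())
        if n_body == 0:
            continue
        n_keep = max(1, int(np.ceil(params.fraction_f / 100.0 * n_body)))
        vals = np.sort(data[body])[::-1][:n_keep]
        if n_keep < params.minimum_voxels:
            continue
        vol = n_keep * vx_vol
        if vol < params.min_volume_um3:
            continue
        foci.append(
            Focus(
                center_um=tuple(float(ci * v) for ci, v in zip(c, vs)),
                center_vox=c,
                volume_um3=vol,
                peak_intensity=peak,
                sum_intensity=float(vals.sum()),
                region_label=region_label,
            )
        )
    return foci


def count_nano_rfi(
    foci: list[Focus],
    xi: RegionMask,
    min_volume_um3: float = 0.0002,
) -> int:
    """Count nano replication foci: centre inside the Xi mask and body
    volume at least ``min_volume_um3`` (default 0.0002 μm³, the cut that
    removes unspecific background signals)."""
    if min_volume_um3 < 0:
        raise InvalidParameterError("min_volume_um3 must be >= 0")
    n = 0
    for f in foci:
        z, y, x = f.center_vox
        if xi.mask[z, y, x] and f.volume_um3 >= min_volume_um3:
            n += 1
    return n


def pla_spot_count(
    image: VoxelImage,
    nucleus: RegionMask,
    prominence: float = 40.0,
    channel: str = "PLA",
    smooth_sigma_px: float = 1.0,
) -> int:
    """Count PLA spots on the maximum-intensity projection.

    Spots are 2D local maxima with topographic prominence above the given
    value, inside the projected nucleus mask; maxima touching the frame
    border are excluded (``exclude edge maxima``).  Each connected plateau
    of surviving maxima counts once.  A light Gaussian pre-smoothing
    (1-pixel kernel by default, 0 to disable) suppresses single-pixel shot
    noise riding on bright spots that would otherwise split one spot into
    several maxima.
    """
    if prominence <= 0:
        raise InvalidParameterError("prominence must be > 0")
    if not image.has_channel(channel):
        raise InvalidParameterError(f"image has no {channel!r} channel")
    nucleus.check_alignment(image)
    mip = image.max_projection(channel).astype(float)
    if smooth_sigma_px > 0:
        mip = ndimage.gaussian_filter(mip, sigma=smooth_sigma_px)
    nuc2d = nucleus.mask.any(axis=0)
    peaks = h_maxima(mip, prominence)
    lab, n = ndimage.label(peaks, structure=np.ones((3, 3), dtype=bool))
    count = 0
    for i in range(1, n + 1):
        idx = np.argwhere(lab == i)
        if (
            idx[:, 0].min() == 0
            or idx[:, 1].min() == 0
            or idx[:, 0].max() == mip.shape[0] - 1
            or idx[:, 1].max() == mip.shape[1] - 1
        ):
            continue  # edge maximum
        cz = tuple(np.round(idx.mean(axis=0)).astype(int))
        if nuc2d[cz]:
            count += 1
    return count


def pla_measurements(
    image: VoxelImage,
    nucleus: RegionMask,
    xi: RegionMask,
    prominence: float = 40.0,
    cell_id: int | str = 0,
    condition: str = "unknown",
):
    """Projection-consistent PLA bookkeeping for one cell.

    The PLA analysis runs entirely on the maximum-intensity projection:
    spot counts are maxima inside the projected nucleus / Xi footprints,
    and the matching DNA amounts are MIP DAPI sums over the same 2D
    regions.  Returns a :class:`~xirep.metrics.CellRecord` ready for
    :func:`~xirep.metrics.pla_density` (counts ``pla_spots_nucleus`` /
    ``pla_spots_xi``; sums ``(region, 'DAPI')``).
    """
    from .metrics import CellRecord  # local import: metrics imports nothing here

    nucleus.check_alignment(image)
    xi.check_alignment(image)
    dapi_mip = image.max_projection("DAPI")
    rec = CellRecord(cell_id=cell_id, condition=condition)
    for region, mask in (("nucleus", nucleus), ("xi", xi)):
        proj = mask.mask.any(axis=0)
        rec.region_sums[(region, "DAPI")] = float(dapi_mip[proj].sum())
        rec.region_areas[region] = float(proj.sum()) * image.pixel_area_um2
        rec.counts[f"pla_spots_{region}"] = pla_spot_count(
            image, mask, prominence
        )
    return rec
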