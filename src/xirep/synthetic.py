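"""Synthetic-microscopy generator with ground truth and condition presets.

Every input the quantification pipeline consumes can be generated here at
desk scale: multichannel nucleus stacks with an H3K27me3-marked Xi
territory, SIM-scale Xi volumes with planted replication nano-foci,
time-lapse S-phase label sequences, DNA-halo images, PLA spot fields and
cell-growth tables.  Each generator returns the rendered data together with
a :class:`GroundTruth` record (planted focus positions, region geometry,
exact noise-free channel sums) so that recovery of every pipeline metric
can be tested against known truth.

The three condition presets (``scramble`` control, ``mh2a1_kd`` and
``mh2a2_kd`` knockdowns) carry the effect sizes of the biological system
they emulate: macroH2A1 depletion lowers the number of simultaneously
active Xi origins (95 vs 138 foci per Xi) while speeding forks up 43%,
macroH2A2 depletion keeps origin numbers (140) but shortens the Xi
replication window from ~80 to ~52 minutes at 20-minute frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image import RegionMask, VoxelImage

__all__ = [
    "NoiseModel",
    "ConditionPreset",
    "PRESETS",
    "get_preset",
    "GroundTruth",
    "make_nucleus_image",
    "make_xi_foci_volume",
    "make_timelapse_labels",
    "make_halo_image",
    "make_growth_table",
    "make_cell_cycle_table",
    "make_rpa_series",
]


# ---------------------------------------------------------------------------
# noise and presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise applied after rendering.

    ``kind`` is one of ``none``, ``gaussian`` (additive, ``sigma`` counts) or
    ``poisson`` (shot noise; intensities are treated as expected photon
    counts scaled by ``gain``).
    """

    kind: str = "poisson"
    sigma: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.gain <= 0:
            raise ValueError("sigma must be >= 0 and gain > 0")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return img
        if self.kind == "gaussian":
            out = img + rng.normal(0.0, self.sigma, size=img.shape)
            return np.clip(out, 0.0, None)
        lam = np.clip(img / self.gain, 0.0, None)
        out = np.zeros(lam.shape, dtype=np.float32)
        nz = lam > 0
        out[nz] = rng.poisson(lam[nz])
        return out * self.gain


NO_NOISE = NoiseModel(kind="none")


@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition and its planted effect sizes.

    All relative factors are expressed against the ``scramble`` control,
    whose factors are therefore 1 by construction.  ``xi_persistence_frames``
    and ``xi_onset_frames`` are discrete distributions over frame counts
    (at the live-imaging interval of 20 min/frame).
    """

    name: str
    foci_per_xi_mean: float
    xi_persistence_frames: Mapping[int, float]
    xi_onset_frames: Mapping[int, float]
    edu_pcna_xi_factor: float
    mcm_loading_final: float
    pla_nuclear_mean: float
    pla_xi_density_fold: float
    halo_radius_factor: float
    halo_irregularity: float = 0.0
    mcm2_xi_reduction: float = 0.0
    mcm2_phospho_xi_reduction: float = 0.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.foci_per_xi_mean < 0 or self.pla_nuclear_mean < 0:
            raise ValueError("counts must be >= 0")
        for f in (
            self.edu_pcna_xi_factor,
            self.mcm_loading_final,
            self.pla_xi_density_fold,
            self.halo_radius_factor,
        ):
            if f <= 0:
                raise ValueError("relative factors must be > 0")
        for frac in (self.mcm2_xi_reduction, self.mcm2_phospho_xi_reduction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("reduction fractions must lie in [0, 1]")
        for dist in (self.xi_persistence_frames, self.xi_onset_frames):
            if not dist:
                raise ValueError("frame distributions must be non-empty")
            if any(k < 0 for k in dist) or any(p < 0 for p in dist.values()):
                raise ValueError("frame distributions must be non-negative")
            if not math.isclose(sum(dist.values()), 1.0, rel_tol=1e-9):
                raise ValueError("frame distribution weights must sum to 1")

    def with_noise(self, noise: NoiseModel) -> "ConditionPreset":
        return replace(self, noise_model=noise)


#: Condition presets.  The scramble preset is the normalisation reference;
#: knockdown presets carry the condition-dependent effect sizes: foci per Xi
#: 138/140/95, Xi-pattern persistence ~80/52/80 min at 20-min frames,
#: EdU:PCNA progression-rate factors 1.43/1.37, final G1 Mcm2 loading
#: coefficients 4.44/2.77/4.24, PLA spots per nucleus 19.8/18.2/2 with Xi
#: density folds 2.5/2.3, a >2-fold halo radius for the macroH2A1 knockdown
#: and its 25% / 41% Xi reductions of Mcm2 / Mcm2-phosphoS108.
PRESETS: dict[str, ConditionPreset] = {
    "scramble": ConditionPreset(
        name="scramble",
        foci_per_xi_mean=138.0,
        xi_persistence_frames={4: 1.0},
        xi_onset_frames={12: 0.5, 13: 0.5},
        edu_pcna_xi_factor=1.0,
        mcm_loading_final=4.44,
        pla_nuclear_mean=19.8,
        pla_xi_density_fold=2.5,
        halo_radius_factor=1.0,
        halo_irregularity=0.05,
    ),
    "mh2a1_kd": ConditionPreset(
        name="mh2a1_kd",
        foci_per_xi_mean=95.0,
        xi_persistence_frames={4: 1.0},
        xi_onset_frames={10: 0.25, 11: 0.5, 12: 0.25},
        edu_pcna_xi_factor=1.43,
        mcm_loading_final=2.77,
        pla_nuclear_mean=2.0,
        pla_xi_density_fold=1.0,
        halo_radius_factor=2.2,
        halo_irregularity=0.35,
        mcm2_xi_reduction=0.25,
        mcm2_phospho_xi_reduction=0.41,
    ),
    "mh2a2_kd": ConditionPreset(
        name="mh2a2_kd",
        foci_per_xi_mean=140.0,
        xi_persistence_frames={2: 0.4, 3: 0.6},
        xi_onset_frames={12: 0.5, 13: 0.5},
        edu_pcna_xi_factor=1.37,
        mcm_loading_final=4.24,
        pla_nuclear_mean=18.2,
        pla_xi_density_fold=2.3,
        halo_radius_factor=1.0,
        halo_irregularity=0.05,
    ),
}


def get_preset(name: str, noise: NoiseModel | None = None) -> ConditionPreset:
    """Look up a preset by name, optionally overriding its noise model."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return preset if noise is None else preset.with_noise(noise)


# ---------------------------------------------------------------------------
# ground truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator knows about what it rendered.

    ``geometry`` holds, per cell, the nucleus/Xi/chromocenter ellipsoids in
    physical micrometres; masks can be re-rasterised exactly with
    :meth:`nucleus_mask` / :meth:`xi_mask`.  ``true_sums`` holds noise-free
    per-region per-channel intensity sums; ``planted_foci`` the EdU focus
    centres (z, y, x in μm), sigmas and amplitudes; ``pla_spots`` per-cell
    planted spot counts and centres.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    geometry: list[dict]
    planted_foci: list[np.ndarray]
    foci_sigma_um: tuple[float, float, float]
    true_sums: list[dict]
    pla_spots: list[dict]
    stages: list[str]

    @property
    def n_cells(self) -> int:
        return len(self.geometry)

    def _mask_from_ellipsoids(self, ellipsoids) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for center_um, semi_um in ellipsoids:
            mask |= _ellipsoid_mask(self.shape, self.voxel_size, center_um, semi_um)
        return mask

    def nucleus_mask(self, cell: int = 0) -> RegionMask:
        geo = self.geometry[cell]
        m = self._mask_from_ellipsoids([geo["nucleus"]])
        return RegionMask(m, "nucleus", self.voxel_size)

    def xi_mask(self, cell: int = 0) -> RegionMask:
        geo = self.geometry[cell]
        m = self._mask_from_ellipsoids(geo["xi"])
        return RegionMask(m, "xi", self.voxel_size)

    def chromocenter_mask(self, cell: int = 0) -> RegionMask:
        geo = self.geometry[cell]
        m = self._mask_from_ellipsoids(geo.get("chromocenters", []))
        return RegionMask(m, "chromocenter", self.voxel_size)

    def to_json_payload(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size_um_zyx": list(self.voxel_size),
            "geometry": [
                {
                    k: [[list(map(float, c)), list(map(float, s))] for c, s in v]
                    if k != "nucleus"
                    else [list(map(float, v[0])), list(map(float, v[1]))]
                    for k, v in geo.items()
                }
                for geo in self.geometry
            ],
            "planted_foci_um": [f.tolist() for f in self.planted_foci],
            "true_sums": self.true_sums,
            "pla_spots": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
                for d in self.pla_spots
            ],
            "stages": self.stages,
        }


# ---------------------------------------------------------------------------
# low-level geometry / rendering helpers
# ---------------------------------------------------------------------------


def _ellipsoid_mask(shape, voxel_size, center_um, semi_um) -> np.ndarray:
    """Rasterise an axis-aligned ellipsoid given in physical μm coordinates."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    coords = (zz * voxel_size[0], yy * voxel_size[1], xx * voxel_size[2])
    d2 = sum(
        ((c - c0) / s) ** 2 for c, c0, s in zip(coords, center_um, semi_um)
    )
    return d2 <= 1.0


def _sample_points_in_ellipsoid(
    rng: np.random.Generator,
    n: int,
    center_um: Sequence[float],
    semi_um: Sequence[float],
    min_sep_lateral_um: float = 0.0,
    min_sep_axial_um: float | None = None,
    margin_um: float = 0.0,
    max_attempts: int = 500_000,
) -> np.ndarray:
    """Dart-throw ``n`` points into an ellipsoid with a minimum separation.

    Separation uses a resolution-scaled norm: two points conflict when
    ``(dz/axial)^2 + (dy/lateral)^2 + (dx/lateral)^2 < 1``, reflecting the
    poorer axial resolution of optical sectioning.  Raises if the requested
    density cannot be placed within ``max_attempts`` darts.
    """
    if min_sep_axial_um is None:
        min_sep_axial_um = min_sep_lateral_um
    center = np.asarray(center_um, dtype=float)
    semi = np.asarray(semi_um, dtype=float) - margin_um
    if np.any(semi <= 0):
        raise ValueError("margin larger than ellipsoid semi-axes")
    pts: list[np.ndarray] = []
    if min_sep_lateral_um > 0:
        scale = np.array([min_sep_axial_um, min_sep_lateral_um, min_sep_lateral_um])
    else:
        scale = None
    accepted = np.empty((0, 3))
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could only place {len(pts)}/{n} points with the requested "
                "separation; enlarge the region or relax the spacing"
            )
        attempts += 1
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u**2).sum() > 1.0:
            continue
        p = center + u * semi
        if scale is not None and len(pts):
            d = (accepted - p) / scale
            if np.min((d**2).sum(axis=1)) < 1.0:
                continue
        pts.append(p)
        accepted = np.asarray(pts)
    return np.asarray(pts).reshape(n, 3)


def _add_gaussian_spots(
    arr: np.ndarray,
    voxel_size: Sequence[float],
    centers_um: np.ndarray,
    sigma_um: Sequence[float],
    amplitudes: np.ndarray | float,
) -> None:
    """Add isotropic-in-μm Gaussian spots (peak amplitude) into ``arr`` in place."""
    vs = np.asarray(voxel_size, dtype=float)
    sig_vox = np.asarray(sigma_um, dtype=float) / vs
    half = np.ceil(4.0 * sig_vox).astype(int)
    amps = np.broadcast_to(np.atleast_1d(amplitudes), (len(centers_um),))
    for c_um, amp in zip(centers_um, amps):
        c_vox = np.asarray(c_um) / vs
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, arr.shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        d2 = (
            ((zz - c_vox[0]) / sig_vox[0]) ** 2
            + ((yy - c_vox[1]) / sig_vox[1]) ** 2
            + ((xx - c_vox[2]) / sig_vox[2]) ** 2
        )
        arr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(-0.5 * d2)


def _draw_from_distribution(
    rng: np.random.Generator, dist: Mapping[int, float], n: int, deterministic: bool
) -> np.ndarray:
    """Draw ``n`` values from a discrete distribution.

    With ``deterministic=True`` the cohort composition follows the weights by
    largest-remainder allocation (a 40/60 mixture of 10 cells is exactly
    4 + 6), then the order is shuffled; otherwise values are drawn i.i.d.
    """
    keys = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    if not deterministic:
        return rng.choice(keys, size=n, p=probs)
    quota = probs * n
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    values = np.repeat(keys, counts)
    rng.shuffle(values)
    return values


def _stochastic_round(rng: np.random.Generator, x: float) -> int:
    """Round to a neighbouring integer with probability equal to the fraction
    (keeps cohort means unbiased when planting small expected counts)."""
    lo = math.floor(x)
    return lo + int(rng.random() < (x - lo))


# ---------------------------------------------------------------------------
# nucleus images (confocal scale)
# ---------------------------------------------------------------------------

#: Default confocal sampling: 50 nm XY pixels, 290 nm Z step.
CONFOCAL_VOXEL_UM = (0.29, 0.05, 0.05)

_CELL_BOX_UM = (6.1, 11.2, 11.2)  # (z, y, x) extent reserved per cell
_NUCLEUS_SEMI_UM = (2.5, 5.0, 5.0)
_XI_SEMI_UM = (1.25, 1.25, 1.25)
_CHROMOCENTER_R_UM = 0.55

# Noise-free channel budgets (arbitrary 16-bit-like counts).  Only ratios
# matter downstream; sums are large enough that shot noise contributes <1%
# relative error on region sums.
_LEVELS = {
    "dapi_base": 2000.0,
    "dapi_chromocenter_factor": 2.5,
    "h3k27me3_nucleus": 30.0,
    "h3k27me3_xi": 200.0,
    "edu_xi_sum": 3.0e5,
    "pcna_xi_sum": 2.0e5,
    "edu_nucleus_out_sum": 3.0e6,
    "pcna_nucleus_out_sum": 2.0e6,
    "mcm_base": 3000.0,
    "mcm_xi_coefficient_control": 2.0,
    "pla_background": 10.0,
    "pla_amplitude": 300.0,
    "fish_xi": 150.0,
}

_FOCUS_SIGMA_FACTOR = 2.0  # sigma = 2x lateral voxel size (resolution-limited)


def make_nucleus_image(
    preset: ConditionPreset | str,
    n_cells: int = 1,
    seed: int = 0,
    voxel_size: Sequence[float] = CONFOCAL_VOXEL_UM,
    channels: Sequence[str] = ("DAPI", "H3K27me3", "EdU", "PCNA"),
    n_xi: int | None = None,
    fixed_counts: bool = False,
    stage: str = "mid_xi",
    mcm_xi_coefficient: float | None = None,
    mcm_phospho_xi_coefficient: float | None = None,
    cell_brightness_cv: float = 0.15,
    n_chromocenters: int = 4,
    crowded: bool = False,
) -> tuple[VoxelImage, GroundTruth]:
    """Render a multichannel confocal-scale field of one or more nuclei.

    Each nucleus is a ~10 μm ellipsoid carrying one or two ~2.5 μm Xi
    territories with elevated H3K27me3.  Replication (EdU) foci are
    isotropic Gaussian spots planted inside the Xi (``stage='mid_xi'``),
    across the nucleoplasm (``'early'``), at chromocenters (``'late'``) or
    absent (``'non_S'``); PCNA foci share the EdU centres.  Channel sums
    respect the preset's relative factors exactly before noise: the Xi
    EdU:PCNA sum ratio is ``edu_pcna_xi_factor`` times the control ratio,
    Mcm2/Mcm2pS108 Xi enrichment is reduced by the preset's reduction
    fractions, and PLA spots are planted at the preset nuclear mean with the
    preset Xi density fold.

    At this confocal sampling individual Xi replication foci are not
    mutually resolvable (the real system needs 3D-SIM for that), so foci are
    planted with a 2-sigma spacing; their role here is intensity
    bookkeeping, not focus counting.  Use :func:`make_xi_foci_volume` for
    the resolvable-regime nano-foci volumes.

    ``n_xi=None`` draws two Xi copies with probability 0.95 (else one),
    matching the near-tetraploid karyotype frequency of the emulated line.

    Returns the image and a :class:`GroundTruth` with exact noise-free
    region/channel sums, planted focus centres and geometry.
    """
    preset = get_preset(preset) if isinstance(preset, str) else preset
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError("voxel_size must be three positive numbers")
    if stage not in ("mid_xi", "early", "late", "non_S"):
        raise ValueError(f"unknown stage {stage!r}")
    known = ("DAPI", "H3K27me3", "EdU", "PCNA", "Mcm2", "Mcm2pS108", "PLA", "FISH")
    channels = tuple(channels)
    for ch in channels:
        if ch not in known:
            raise ValueError(f"unknown channel {ch!r}; choose from {known}")

    rng = np.random.default_rng(seed)
    box_vox = tuple(int(round(b / v)) for b, v in zip(_CELL_BOX_UM, vs))
    shape = (box_vox[0], box_vox[1], box_vox[2] * n_cells)
    data = np.zeros((len(channels), *shape), dtype=np.float32)

    sigma_um = tuple(_FOCUS_SIGMA_FACTOR * vs[2] for _ in range(3))
    min_sep = 0.0 if crowded else 2.0 * sigma_um[2]

    geometry, planted, true_sums, pla_spots, stages = [], [], [], [], []

    for ci in range(n_cells):
        x_off = ci * _CELL_BOX_UM[2]
        jitter = rng.uniform(0.95, 1.05)
        nuc_center = (
            _CELL_BOX_UM[0] / 2,
            _CELL_BOX_UM[1] / 2,
            x_off + _CELL_BOX_UM[2] / 2,
        )
        nuc_semi = tuple(s * jitter for s in _NUCLEUS_SEMI_UM)
        nuc = _ellipsoid_mask(shape, vs, nuc_center, nuc_semi)

        # Xi copies placed off-centre inside the nucleus.
        k_xi = n_xi if n_xi is not None else (2 if rng.random() < 0.95 else 1)
        xi_list = []
        ang = rng.uniform(0, 2 * np.pi)  # copies sit on opposite sides
        for j in range(k_xi):
            r_off = 0.55 * nuc_semi[1]
            c = (
                nuc_center[0],
                nuc_center[1] + r_off * np.sin(ang + j * np.pi),
                nuc_center[2] + r_off * np.cos(ang + j * np.pi),
            )
            xi_list.append((c, _XI_SEMI_UM))
        xi = np.zeros(shape, dtype=bool)
        for c, s in xi_list:
            xi |= _ellipsoid_mask(shape, vs, c, s)
        xi &= nuc

        # chromocenters: bright DAPI blobs outside the Xi
        cc_list = []
        cc = np.zeros(shape, dtype=bool)
        for _ in range(n_chromocenters):
            for _try in range(100):
                c = _sample_points_in_ellipsoid(
                    rng, 1, nuc_center, nuc_semi, margin_um=_CHROMOCENTER_R_UM + 0.2
                )[0]
                if all(
                    sum(((c[i] - xc[i]) / (xs[i] + _CHROMOCENTER_R_UM)) ** 2 for i in range(3)) > 1
                    for xc, xs in xi_list
                ):
                    break
            cc_list.append((tuple(c), (_CHROMOCENTER_R_UM,) * 3))
            cc |= _ellipsoid_mask(shape, vs, tuple(c), (_CHROMOCENTER_R_UM,) * 3)
        cc &= nuc & ~xi

        brightness = float(np.exp(rng.normal(0.0, cell_brightness_cv))) if cell_brightness_cv > 0 else 1.0

        # ---- plant EdU/PCNA foci ------------------------------------------
        if stage == "non_S":
            centers = np.empty((0, 3))
        else:
            if fixed_counts:
                n_foci_total = int(round(preset.foci_per_xi_mean)) * (
                    len(xi_list) if stage == "mid_xi" else 1
                )
            else:
                lam = preset.foci_per_xi_mean * (len(xi_list) if stage == "mid_xi" else 1)
                n_foci_total = int(rng.poisson(lam))
            if stage == "mid_xi":
                per_copy = np.full(len(xi_list), n_foci_total // len(xi_list))
                per_copy[: n_foci_total % len(xi_list)] += 1
                parts = [
                    _sample_points_in_ellipsoid(
                        rng, int(m), c, s, min_sep_lateral_um=min_sep, margin_um=2 * sigma_um[2]
                    )
                    for m, (c, s) in zip(per_copy, xi_list)
                ]
                centers = np.concatenate(parts) if parts else np.empty((0, 3))
            elif stage == "early":
                centers = _sample_points_in_ellipsoid(
                    rng, n_foci_total, nuc_center, nuc_semi,
                    min_sep_lateral_um=min_sep, margin_um=0.3,
                )
            else:  # late: foci at chromocenters
                if not cc_list:
                    raise ValueError("late stage needs n_chromocenters >= 1")
                parts = []
                for m in range(n_foci_total):
                    c, s = cc_list[m % len(cc_list)]
                    parts.append(
                        _sample_points_in_ellipsoid(rng, 1, c, s, margin_um=0.05)
                    )
                centers = np.concatenate(parts) if parts else np.empty((0, 3))

        # ---- render channels ----------------------------------------------
        chan_arrays = {}
        if "DAPI" in channels:
            a = np.zeros(shape, dtype=np.float32)
            a[nuc] = _LEVELS["dapi_base"]
            a[cc] = _LEVELS["dapi_base"] * _LEVELS["dapi_chromocenter_factor"]
            chan_arrays["DAPI"] = a
        if "H3K27me3" in channels:
            a = np.zeros(shape, dtype=np.float32)
            a[nuc] = _LEVELS["h3k27me3_nucleus"]
            a[xi] = _LEVELS["h3k27me3_xi"]
            chan_arrays["H3K27me3"] = a

        def _focal_channel(target_xi_sum: float, target_out_sum: float) -> np.ndarray:
            """Foci at the planted centres, rescaled so the Xi (or nuclear)
            sum hits its target exactly; diffuse nucleoplasmic floor."""
            a = np.zeros(shape, dtype=np.float32)
            if len(centers):
                _add_gaussian_spots(a, vs, centers, sigma_um, 1.0)
            out_region = nuc & ~xi
            if stage == "mid_xi":
                s_xi = float(a[xi].sum())
                if s_xi > 0:
                    a *= target_xi_sum / s_xi
                n_out = int(out_region.sum())
                if n_out:
                    a[out_region] += target_out_sum / n_out
            else:
                s_nuc = float(a[nuc].sum())
                total = target_xi_sum + target_out_sum
                if s_nuc > 0:
                    a *= total / s_nuc
            return a

        if "EdU" in channels:
            chan_arrays["EdU"] = _focal_channel(
                _LEVELS["edu_xi_sum"] * preset.edu_pcna_xi_factor,
                _LEVELS["edu_nucleus_out_sum"],
            )
        if "PCNA" in channels:
            chan_arrays["PCNA"] = _focal_channel(
                _LEVELS["pcna_xi_sum"], _LEVELS["pcna_nucleus_out_sum"]
            )
        if "Mcm2" in channels:
            coef = (
                mcm_xi_coefficient
                if mcm_xi_coefficient is not None
                else _LEVELS["mcm_xi_coefficient_control"] * (1.0 - preset.mcm2_xi_reduction)
            )
            a = np.zeros(shape, dtype=np.float32)
            a[nuc] = _LEVELS["mcm_base"]
            a[xi] = _LEVELS["mcm_base"] * coef
            chan_arrays["Mcm2"] = a
        if "Mcm2pS108" in channels:
            coef = (
                mcm_phospho_xi_coefficient
                if mcm_phospho_xi_coefficient is not None
                else _LEVELS["mcm_xi_coefficient_control"]
                * (1.0 - preset.mcm2_phospho_xi_reduction)
            )
            a = np.zeros(shape, dtype=np.float32)
            a[nuc] = _LEVELS["mcm_base"]
            a[xi] = _LEVELS["mcm_base"] * coef
            chan_arrays["Mcm2pS108"] = a

        spots_rec = {"n_total": 0, "n_xi": 0, "centers_um": np.empty((0, 3))}
        if "PLA" in channels:
            a = np.zeros(shape, dtype=np.float32)
            a[nuc] = _LEVELS["pla_background"]
            n_tot = (
                int(round(preset.pla_nuclear_mean))
                if fixed_counts
                else int(rng.poisson(preset.pla_nuclear_mean))
            )
            # The PLA workflow is projection-based (counts and DAPI sums on
            # maximum-intensity projections), so the Xi density fold is
            # planted in projected geometry: spots whose (y, x) falls in the
            # projected Xi footprint, over MIP DAPI sums.  Non-Xi spots are
            # kept out of the Xi column so the planted fold is exact.
            dapi = chan_arrays.get("DAPI")
            if dapi is None:
                raise ValueError("PLA channel requires DAPI for density bookkeeping")
            dapi_mip = dapi.max(axis=0)
            xi_proj = xi.any(axis=0)
            nuc_proj = nuc.any(axis=0)
            d_xi = float(dapi_mip[xi_proj].sum())
            d_nuc = float(dapi_mip[nuc_proj].sum())
            frac_xi = preset.pla_xi_density_fold * (d_xi / d_nuc)
            n_xi_spots = min(_stochastic_round(rng, frac_xi * n_tot), n_tot)
            sigma_pla = (0.30, 0.15, 0.15)
            placed = []
            if n_xi_spots and xi_list:
                per = [n_xi_spots // len(xi_list)] * len(xi_list)
                for j in range(n_xi_spots % len(xi_list)):
                    per[j] += 1
                for m, (c, s) in zip(per, xi_list):
                    if m:
                        placed.append(
                            _sample_points_in_ellipsoid(
                                rng, m, c, s,
                                min_sep_lateral_um=0.8, min_sep_axial_um=1.0,
                                margin_um=0.2,
                            )
                        )
            n_out = n_tot - n_xi_spots
            if n_out:
                # rejection-sample points outside the Xi *column* (their
                # projections must not land in the Xi footprint)
                pts = []
                while len(pts) < n_out:
                    p = _sample_points_in_ellipsoid(
                        rng, 1, nuc_center, nuc_semi, margin_um=0.4
                    )[0]
                    if any(
                        sum(((p[i] - xc[i]) / xs[i]) ** 2 for i in (1, 2)) <= 1
                        for xc, xs in xi_list
                    ):
                        continue
                    if pts and np.min(
                        ((np.asarray(pts)[:, 1:] - p[1:]) ** 2).sum(axis=1)
                    ) < 0.8**2:
                        continue  # keep spots resolvable in the XY projection
                    pts.append(p)
                placed.append(np.asarray(pts))
            centers_pla = np.concatenate(placed) if placed else np.empty((0, 3))
            _add_gaussian_spots(a, vs, centers_pla, sigma_pla, _LEVELS["pla_amplitude"])
            chan_arrays["PLA"] = a
            spots_rec = {"n_total": n_tot, "n_xi": n_xi_spots, "centers_um": centers_pla}
        if "FISH" in channels:
            a = np.zeros(shape, dtype=np.float32)
            a[xi] = _LEVELS["fish_xi"]
            chan_arrays["FISH"] = a

        # per-cell brightness scatter applies to all channels jointly
        for name, arr in chan_arrays.items():
            arr *= brightness
            data[channels.index(name)] += arr

        true_sums.append(
            {
                region: {
                    name: float(arr[reg_mask].sum())
                    for name, arr in chan_arrays.items()
                }
                for region, reg_mask in (("nucleus", nuc), ("xi", xi))
            }
        )
        geometry.append(
            {
                "nucleus": (nuc_center, nuc_semi),
                "xi": xi_list,
                "chromocenters": cc_list,
            }
        )
        planted.append(centers)
        pla_spots.append(spots_rec)
        stages.append(stage)

    noisy = preset.noise_model.apply(data, rng).astype(np.float32)
    image = VoxelImage(noisy, channels, vs)
    gt = GroundTruth(
        shape=shape,
        voxel_size=vs,
        geometry=geometry,
        planted_foci=planted,
        foci_sigma_um=sigma_um,
        true_sums=true_sums,
        pla_spots=pla_spots,
        stages=stages,
    )
    return image, gt


# ---------------------------------------------------------------------------
# SIM-scale Xi nano-foci volumes (resolvable regime)
# ---------------------------------------------------------------------------

#: Default 3D-SIM-scale sampling: 40 nm XY pixels, 125 nm Z sections.
SIM_VOXEL_UM = (0.125, 0.04, 0.04)
_SIM_XI_SEMI_UM = (1.45, 1.5, 1.5)


def make_xi_foci_volume(
    preset: ConditionPreset | str,
    seed: int = 0,
    n_foci: int | None = None,
    fixed_counts: bool = True,
    voxel_size: Sequence[float] = SIM_VOXEL_UM,
    xi_semi_um: Sequence[float] = _SIM_XI_SEMI_UM,
    amplitude: float = 400.0,
    background: float = 20.0,
    crowded: bool = False,
) -> tuple[VoxelImage, RegionMask, np.ndarray]:
    """Render one super-resolution-scale Xi volume with planted nano-foci.

    Foci are isotropic Gaussian spots (sigma = 2x the lateral voxel size)
    planted inside an Xi ellipsoid with a default minimum pairwise spacing of
    4 sigma laterally (wider axially, matching the poorer axial resolution)
    so that each focus is individually resolvable; ``crowded=True`` removes
    the spacing constraint to stress the separator.  ``n_foci`` defaults to
    the preset mean (rounded when ``fixed_counts``, else Poisson-drawn).

    Returns the single-channel ``EdU`` image (with the preset's noise
    applied), the Xi :class:`RegionMask`, and the planted centres in μm.
    """
    preset = get_preset(preset) if isinstance(preset, str) else preset
    vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in vs):
        raise ValueError("voxel_size must be positive")
    rng = np.random.default_rng(seed)
    if n_foci is None:
        n_foci = (
            int(round(preset.foci_per_xi_mean))
            if fixed_counts
            else int(rng.poisson(preset.foci_per_xi_mean))
        )
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")

    sigma = _FOCUS_SIGMA_FACTOR * vs[2]
    sigma_um = (sigma, sigma, sigma)
    margin = 0.4
    semi = tuple(float(s) for s in xi_semi_um)
    shape = tuple(
        int(np.ceil(2 * (s + margin) / v)) for s, v in zip(semi, vs)
    )
    center = tuple(s + margin for s in semi)

    lateral_sep = 0.0 if crowded else 4.0 * sigma
    axial_sep = 0.0 if crowded else max(4.0 * sigma, 0.45)
    centers = _sample_points_in_ellipsoid(
        rng, n_foci, center, semi,
        min_sep_lateral_um=lateral_sep, min_sep_axial_um=axial_sep,
        margin_um=2 * sigma,
    )
    arr = np.full(shape, background, dtype=np.float32)
    _add_gaussian_spots(arr, vs, centers, sigma_um, amplitude)
    noisy = preset.noise_model.apply(arr[None], rng).astype(np.float32)
    image = VoxelImage(noisy, ("EdU",), vs)
    xi_mask = RegionMask(_ellipsoid_mask(shape, vs, center, semi), "xi", vs)
    return image, xi_mask, centers


# ---------------------------------------------------------------------------
# time-lapse label sequences
# ---------------------------------------------------------------------------


def make_timelapse_labels(
    preset: ConditionPreset | str,
    n_cells: int,
    frame_interval_min: float = 20.0,
    seed: int = 0,
    deterministic: bool = True,
    total_s_frames: int = 27,
    pre_frames: int = 3,
    post_frames: int = 3,
) -> list[list[str]]:
    """Generate per-cell S-phase stage label sequences for live imaging.

    Each sequence runs non_S -> early -> mid_xi -> late -> non_S; the
    mid_xi (synchronous Xi pattern) run length and its onset (frames from
    S-phase start) are drawn from the preset's distributions.  The total
    S-phase span is held constant across conditions (the emulated system
    shows unchanged overall S duration).  With ``deterministic=True`` the
    cohort composition follows the distribution weights exactly.
    """
    preset = get_preset(preset) if isinstance(preset, str) else preset
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    persist = _draw_from_distribution(
        rng, preset.xi_persistence_frames, n_cells, deterministic
    )
    onset = _draw_from_distribution(rng, preset.xi_onset_frames, n_cells, deterministic)
    sequences = []
    for k, o in zip(persist, onset):
        late = total_s_frames - int(o) - int(k)
        if late < 1:
            raise ValueError(
                "total_s_frames too short for the drawn onset + persistence"
            )
        seq = (
            ["non_S"] * pre_frames
            + ["early"] * int(o)
            + ["mid_xi"] * int(k)
            + ["late"] * late
            + ["non_S"] * post_frames
        )
        sequences.append(seq)
    return sequences


# ---------------------------------------------------------------------------
# DNA halo images
# ---------------------------------------------------------------------------


def make_halo_image(
    scaffold_radius: float = 5.0,
    halo_radius_factor: float = 2.0,
    irregularity: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    fish_band_um: tuple[float, float] | None = None,
    scaffold_level: float = 1000.0,
    halo_level: float = 120.0,
    background: float = 5.0,
    noise: NoiseModel = NO_NOISE,
) -> tuple[VoxelImage, dict]:
    """Render a 2D DNA-halo preparation: bright scaffold disc + dim halo.

    The halo's outer boundary is a radially perturbed circle,
    ``r(theta) = rs + (f - 1) * rs * (1 + g(theta))`` with ``g`` a smooth
    random angular perturbation of amplitude ``irregularity``; amplitude 1
    or more would let the boundary touch/cross the scaffold and raises.
    ``fish_band_um=(a, b)`` concentrates the FISH channel in a radial band
    ``a..b`` μm outside the scaffold border.

    Returns the image (channels DAPI[, FISH]) and a ground-truth dict with
    the exact analytic areas, radius and boundary-polygon circularity.
    """
    if scaffold_radius <= 0:
        raise ValueError("scaffold_radius must be > 0")
    if halo_radius_factor < 1:
        raise ValueError("halo_radius_factor must be >= 1")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    if halo_radius_factor > 1 and irregularity >= 1:
        raise ValueError(
            "irregularity >= 1 lets the halo boundary intersect the scaffold"
        )
    rng = np.random.default_rng(seed)
    rs = float(scaffold_radius)
    r_out_nominal = rs * halo_radius_factor

    # smooth periodic perturbation, normalised to unit max amplitude
    n_modes = 5
    amps = rng.normal(size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)

    def g(theta: np.ndarray) -> np.ndarray:
        if irregularity == 0:
            return np.zeros_like(theta)
        raw = sum(
            a * np.cos((k + 2) * theta + p)
            for k, (a, p) in enumerate(zip(amps, phases))
        )
        scale = np.max(np.abs(raw)) or 1.0
        return irregularity * raw / scale

    def r_outer(theta: np.ndarray) -> np.ndarray:
        return rs + (r_out_nominal - rs) * (1.0 + g(theta))

    half_um = r_out_nominal * (1 + irregularity) + 2.0
    n_pix = int(np.ceil(2 * half_um / pixel_size_um))
    yy, xx = np.mgrid[:n_pix, :n_pix]
    cy = cx = (n_pix - 1) / 2.0
    dy = (yy - cy) * pixel_size_um
    dx = (xx - cx) * pixel_size_um
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    img = np.full((n_pix, n_pix), background, dtype=np.float32)
    halo = (rr > rs) & (rr <= r_outer(theta))
    img[halo] = halo_level
    img[rr <= rs] = scaffold_level

    chans = [img]
    names = ["DAPI"]
    if fish_band_um is not None:
        a, b = fish_band_um
        if not 0 <= a < b:
            raise ValueError("fish_band_um must satisfy 0 <= a < b")
        fish = np.full((n_pix, n_pix), 2.0, dtype=np.float32)
        band = (rr >= rs + a) & (rr <= rs + b)
        fish[band] = 200.0
        chans.append(fish)
        names.append("FISH")

    data = np.stack(chans)[:, None]
    data = noise.apply(data, rng).astype(np.float32)
    image = VoxelImage(data, tuple(names), (1.0, pixel_size_um, pixel_size_um))

    # analytic ground truth from a dense boundary polygon
    th = np.linspace(0, 2 * np.pi, 1441)[:-1]
    r_th = r_outer(th)
    px, py = r_th * np.cos(th), r_th * np.sin(th)
    area_total = 0.5 * abs(
        np.sum(px * np.roll(py, -1) - np.roll(px, -1) * py)
    )
    perim = float(
        np.sum(np.hypot(np.diff(np.append(px, px[0])), np.diff(np.append(py, py[0]))))
    )
    as_true = math.pi * rs**2
    ah_true = max(0.0, area_total - as_true)  # polygonal area of the
    # discretised boundary can undershoot the analytic circle by O(n^-2)
    truth = {
        "As_um2": as_true,
        "At_um2": area_total,
        "Ah_um2": ah_true,
        "R_um": math.sqrt(ah_true / math.pi),
        "circularity": min(1.0, 4 * math.pi * area_total / perim**2),
        "scaffold_radius_um": rs,
        "fish_band_um": fish_band_um,
    }
    return image, truth


# ---------------------------------------------------------------------------
# growth tables and cell-cycle populations
# ---------------------------------------------------------------------------


def make_growth_table(
    n0: int, doubling_time_h: float, days: int, points_per_day: int = 1
) -> pd.DataFrame:
    """Exponential growth counts ``n(t) = n0 * 2^(t / Td)`` rounded to cells.

    Returns a table with columns ``t_h`` and ``count`` sampled every
    ``24 / points_per_day`` hours from 0 through ``days`` days inclusive.
    """
    if n0 <= 0 or doubling_time_h <= 0:
        raise ValueError("n0 and doubling_time_h must be > 0")
    if days < 1 or points_per_day < 1:
        raise ValueError("days and points_per_day must be >= 1")
    t = np.linspace(0.0, 24.0 * days, days * points_per_day + 1)
    counts = np.rint(n0 * np.power(2.0, t / doubling_time_h)).astype(np.int64)
    return pd.DataFrame({"t_h": t, "count": counts})


def make_cell_cycle_table(
    n: int,
    seed: int = 0,
    s_fraction: float = 0.35,
    g2_fraction: float = 0.15,
    dapi_cv: float = 0.05,
) -> pd.DataFrame:
    """Per-cell DNA-content table for G1 gating tests.

    DAPI sum intensities are bimodal (2C around 1.0, 4C around 2.0, S-phase
    in between and EdU-positive).  Columns: ``cell_id``, ``dapi_sum``,
    ``edu_positive``, ``true_phase``.
    """
    if not 0 <= s_fraction + g2_fraction < 1:
        raise ValueError("phase fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    phases = rng.choice(
        ["G1", "S", "G2"],
        size=n,
        p=[1 - s_fraction - g2_fraction, s_fraction, g2_fraction],
    )
    dapi = np.empty(n)
    edu = np.zeros(n, dtype=bool)
    g1 = phases == "G1"
    s = phases == "S"
    g2 = phases == "G2"
    dapi[g1] = rng.normal(1.0, dapi_cv, g1.sum())
    dapi[s] = rng.uniform(1.15, 1.85, s.sum())
    dapi[g2] = rng.normal(2.0, 2 * dapi_cv, g2.sum())
    edu[s] = True
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "dapi_sum": np.abs(dapi) * 1e6,
            "edu_positive": edu,
            "true_phase": phases,
        }
    )


def make_rpa_series(
    n_frames: int = 6,
    accumulating: bool = True,
    seed: int = 0,
    size: int = 96,
    n_foci: int = 12,
    base_amplitude: float = 60.0,
    background: float = 50.0,
    noise: NoiseModel = NO_NOISE,
) -> tuple[list[VoxelImage], list[RegionMask]]:
    """Time-lapse RPA frames over one nucleus disc.

    ``accumulating=True`` grows the focal RPA amplitude linearly over frames
    (the polymerase-stalled, helicase-uncoupled regime); otherwise the
    amplitude stays flat (vehicle control).  Frame 0 is pretreatment in both
    cases (identical base amplitude).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames (pretreatment + follow-up)")
    rng = np.random.default_rng(seed)
    vs = (1.0, 0.1, 0.1)
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    radius_um = size * vs[1] * 0.4
    nucleus = (np.hypot(yy - c, xx - c) * vs[1]) <= radius_um
    centers = _sample_points_in_ellipsoid(
        rng, n_foci,
        (0.0, c * vs[1], c * vs[2]),
        (1.0, radius_um, radius_um),
        min_sep_lateral_um=0.5,
        margin_um=0.3,
    )
    frames, masks = [], []
    for t in range(n_frames):
        amp = base_amplitude * (1.0 + (1.5 * t if accumulating else 0.0))
        arr = np.zeros((size, size), dtype=np.float32)
        arr[nucleus] = background
        img3 = arr[None]
        _add_gaussian_spots(img3, vs, centers, (0.4, 0.2, 0.2), amp)
        img3 = noise.apply(img3[None], rng)[0].astype(np.float32)
        frames.append(VoxelImage(img3[None], ("RPA",), vs))
        masks.append(RegionMask(nucleus, "nucleus", vs))
    return frames, masks
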