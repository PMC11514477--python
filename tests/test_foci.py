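"""Focus picking: exhaustive plateau-maxima oracle equivalence, planted-spot
recovery, affine invariance, volume/prominence monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xirep as xr
from xirep.foci import FociParams, find_plateau_maxima
from xirep.image import RegionMask, VoxelImage
from xirep.synthetic import _add_gaussian_spots


def plateau_maxima_bruteforce(vol: np.ndarray, background: float) -> int:
    """Independent exhaustive oracle: enumerate every voxel, test
    plateau-maximality against all 26 neighbours, merge equal-valued
    plateau components by BFS, count surviving components.  A plateau with
    no surrounding voxel at all (covering the whole volume) is background,
    not a focus."""
    vol = np.asarray(vol, dtype=float)
    nz, ny, nx = vol.shape
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    visited = np.zeros(vol.shape, dtype=bool)
    count = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if visited[z, y, x] or vol[z, y, x] <= background:
                    continue
                v = vol[z, y, x]
                # BFS over the equal-valued plateau containing this voxel
                stack, is_max, has_edge = [(z, y, x)], True, False
                visited[z, y, x] = True
                while stack:
                    cz, cy, cx = stack.pop()
                    for dz, dy, dx in offsets:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if not (0 <= pz < nz and 0 <= py < ny and 0 <= px < nx):
                            continue
                        w = vol[pz, py, px]
                        if w > v:
                            is_max = False
                        elif w < v:
                            has_edge = True
                        elif not visited[pz, py, px]:
                            visited[pz, py, px] = True
                            stack.append((pz, py, px))
                count += is_max and has_edge
    return count


def _volume_image(vol, voxel_size=(1.0, 1.0, 1.0)):
    return VoxelImage(np.asarray(vol, float)[None], ("EdU",), voxel_size)


def _full_mask(vol, voxel_size=(1.0, 1.0, 1.0)):
    return RegionMask(np.ones(np.shape(vol), dtype=bool), "xi", voxel_size)


class TestPlateauMaxima:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_equal_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 13, size=3))
        # small integer intensities produce many plateaus and ties
        vol = rng.integers(0, 6, size=shape).astype(float)
        centers = find_plateau_maxima(vol, background=0.0)
        assert len(centers) == plateau_maxima_bruteforce(vol, 0.0)

    def test_pick_foci_counts_equal_oracle_on_32cubed(self):
        rng = np.random.default_rng(7)
        vol = rng.integers(1, 8, size=(32, 32, 32)).astype(float)
        params = FociParams(
            background=0.5, tolerance=100.0, smooth=False,
            contrast_stretch=False, fraction_f=100.0,
        )
        picked = xr.pick_foci_3d(_volume_image(vol), "EdU", _full_mask(vol), params)
        assert len(picked) == plateau_maxima_bruteforce(vol, 0.5)

    def test_single_plateau_has_single_center(self):
        vol = np.zeros((5, 7, 7))
        vol[2, 2:5, 2:5] = 9.0  # 3x3 plateau
        centers = find_plateau_maxima(vol, background=0.0)
        assert centers == [(2, 3, 3)]  # voxel nearest the centroid

    def test_flat_image_has_no_foci(self):
        vol = np.full((6, 6, 6), 4.0)
        img = _volume_image(vol)
        picked = xr.pick_foci_3d(
            img, "EdU", _full_mask(vol),
            FociParams(background=0.0, tolerance=1.0, smooth=False, contrast_stretch=False),
        )
        assert picked == []


class TestPickFoci:
    def _planted(self, n=10, seed=0, amplitude=200.0, shape=(20, 48, 48)):
        rng = np.random.default_rng(seed)
        vs = (0.125, 0.04, 0.04)
        vol = np.full(shape, 5.0, dtype=float)
        # well-separated grid positions
        pts = []
        for i in range(n):
            pts.append(
                (
                    (4 + 6 * (i // 5)) * vs[0],
                    (6 + 8 * (i % 5)) * vs[1],
                    (10 + 6 * (i // 5) + 8 * (i % 5)) * vs[2] % (shape[2] * vs[2] * 0.9),
                )
            )
        pts = np.asarray(pts)
        _add_gaussian_spots(vol, vs, pts, (0.08, 0.08, 0.08), amplitude)
        return VoxelImage(vol[None], ("EdU",), vs), RegionMask(
            np.ones(shape, dtype=bool), "xi", vs
        ), pts

    def test_recovers_planted_spots_exactly(self):
        img, mask, pts = self._planted()
        foci = xr.pick_foci_3d(img, "EdU", mask)
        assert len(foci) == 10
        got = np.array([f.center_um for f in foci])
        # each planted center matched within one voxel diagonal
        for p in pts:
            d = np.abs(got - p) / np.array(img.voxel_size)
            assert (d <= 1.0 + 1e-9).all(axis=1).any()

    def test_detection_invariant_under_affine_intensity_map(self):
        img, mask, _ = self._planted(seed=3)
        params = FociParams(
            background=20.0, tolerance=50.0, smooth=False, contrast_stretch=False
        )
        base = xr.pick_foci_3d(img, "EdU", mask, params)
        a, b = 3.5, 40.0
        img2 = VoxelImage(img.data * a + b, img.channel_names, img.voxel_size)
        params2 = FociParams(
            background=20.0 * a + b, tolerance=50.0 * a,
            smooth=False, contrast_stretch=False,
        )
        mapped = xr.pick_foci_3d(img2, "EdU", mask, params2)
        assert len(mapped) == len(base)
        assert [f.center_vox for f in mapped] == [f.center_vox for f in base]

    def test_empty_mask_returns_empty(self):
        img, _, _ = self._planted()
        empty = RegionMask(np.zeros(img.shape, dtype=bool), "xi", img.voxel_size)
        assert xr.pick_foci_3d(img, "EdU", empty) == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FociParams(fraction_f=0.0)
        with pytest.raises(ValueError):
            FociParams(tolerance=-1.0)
        with pytest.raises(ValueError):
            FociParams(minimum_voxels=0)


class TestCountNanoRfi:
    def _focus(self, center_vox, volume):
        return xr.Focus(
            center_um=tuple(float(c) for c in center_vox),
            center_vox=center_vox, volume_um3=volume,
            peak_intensity=1.0, sum_intensity=1.0,
        )

    def test_volume_filter_arithmetic(self):
        xi = RegionMask(np.ones((4, 8, 8), dtype=bool), "xi", (1, 1, 1))
        foci = [self._focus((1, i % 8, i // 8), 0.01) for i in range(10)]
        foci += [self._focus((2, 3, 3), 0.0001), self._focus((2, 4, 4), 0.0001)]
        assert xr.count_nano_rfi(foci, xi, 0.0002) == 10

    def test_foci_outside_xi_not_counted(self):
        m = np.zeros((4, 8, 8), dtype=bool)
        m[0, :2, :2] = True
        xi = RegionMask(m, "xi", (1, 1, 1))
        foci = [self._focus((3, 7, 7), 1.0)]
        assert xr.count_nano_rfi(foci, xi) == 0

    def test_raising_min_volume_never_increases_count(self):
        rng = np.random.default_rng(0)
        xi = RegionMask(np.ones((4, 8, 8), dtype=bool), "xi", (1, 1, 1))
        foci = [
            self._focus((int(rng.integers(4)), int(rng.integers(8)), int(rng.integers(8))),
                        float(rng.uniform(0, 0.01)))
            for _ in range(30)
        ]
        counts = [xr.count_nano_rfi(foci, xi, v) for v in np.linspace(0, 0.01, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_poisson_noise_recovery_for_knockdown_preset(self):
        # fixed 95 planted foci per Xi volume under shot noise
        counts = []
        for s in range(5):
            img, xi, _ = xr.make_xi_foci_volume("mh2a1_kd", seed=900 + s, n_foci=95)
            foci = xr.pick_foci_3d(img, "EdU", xi)
            counts.append(xr.count_nano_rfi(foci, xi))
        assert abs(np.mean(counts) - 95) <= 3


class TestPlaSpotCount:
    def _field(self, n_spots, amplitude=200.0, size=96):
        rng = np.random.default_rng(1)
        vs = (1.0, 0.1, 0.1)
        img = np.full((size, size), 10.0)
        pts = np.stack(
            [
                np.zeros(n_spots),
                rng.uniform(15, size - 15, n_spots) * vs[1],
                rng.uniform(15, size - 15, n_spots) * vs[2],
            ],
            axis=1,
        )
        # enforce projected separation
        keep = []
        for p in pts:
            if all(np.hypot(p[1] - q[1], p[2] - q[2]) > 1.0 for q in keep):
                keep.append(p)
        vol = img[None]
        _add_gaussian_spots(vol, vs, np.asarray(keep), (0.3, 0.2, 0.2), amplitude)
        image = VoxelImage(vol[None], ("PLA",), vs)
        nucleus = RegionMask(np.ones((1, size, size), dtype=bool), "nucleus", vs)
        return image, nucleus, len(keep)

    def test_planted_spots_counted_at_default_prominence(self):
        image, nucleus, n = self._field(5)
        assert xr.pla_spot_count(image, nucleus, prominence=40) == n

    def test_high_prominence_suppresses_all(self):
        image, nucleus, _ = self._field(5)
        assert xr.pla_spot_count(image, nucleus, prominence=300) == 0

    def test_prominence_monotonicity(self):
        image, nucleus, _ = self._field(12, amplitude=150.0)
        counts = [
            xr.pla_spot_count(image, nucleus, prominence=p)
            for p in (20, 40, 80, 120, 200)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_edge_maxima_excluded(self):
        vs = (1.0, 0.1, 0.1)
        img = np.full((1, 32, 32), 10.0)
        img[0, 0, 16] = 500.0  # maximum on the frame border
        img[0, 16, 16] = 500.0
        image = VoxelImage(img[None], ("PLA",), vs)
        nucleus = RegionMask(np.ones((1, 32, 32), dtype=bool), "nucleus", vs)
        assert xr.pla_spot_count(image, nucleus, prominence=40) == 1

    def test_missing_channel_rejected(self):
        img = VoxelImage(np.ones((1, 1, 8, 8)), ("DAPI",), (1, 1, 1))
        m = RegionMask(np.ones((1, 8, 8), dtype=bool), "nucleus", (1, 1, 1))
        with pytest.raises(ValueError):
            xr.pla_spot_count(img, m)
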