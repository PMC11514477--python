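"""Ratio/level metrics: closed-form identities, scale invariance, control
normalisation, and generator-contrast checks."""

import numpy as np
import pandas as pd
import pytest

import xirep as xr
from xirep.errors import (
    InconsistencyError,
    NormalizationAnchorError,
    UndefinedCvError,
    UndefinedRatioError,
)
from xirep.image import RegionMask, VoxelImage
from xirep.metrics import CellRecord


def _record(sums, counts=None):
    return CellRecord(cell_id=0, region_sums=sums, counts=counts or {})


class TestRegionSum:
    def test_uniform_region(self):
        img = VoxelImage(np.full((1, 1, 10, 10), 5.0), ("DAPI",), (1, 1, 1))
        m = np.zeros((1, 10, 10), dtype=bool)
        m[0, :10, :10] = True
        assert xr.region_sum(img, "DAPI", RegionMask(m, "nucleus", (1, 1, 1))) == 500.0

    def test_empty_mask_is_zero(self):
        img = VoxelImage(np.full((1, 1, 4, 4), 9.0), ("DAPI",), (1, 1, 1))
        m = RegionMask(np.zeros((1, 4, 4), dtype=bool), "xi", (1, 1, 1))
        assert xr.region_sum(img, "DAPI", m) == 0.0

    def test_misaligned_shapes_rejected(self):
        img = VoxelImage(np.ones((1, 1, 4, 4)), ("DAPI",), (1, 1, 1))
        m = RegionMask(np.ones((1, 5, 5), dtype=bool), "xi", (1, 1, 1))
        with pytest.raises(ValueError):
            xr.region_sum(img, "DAPI", m)


class TestEdUPcnaRatio:
    def test_arithmetic(self):
        rec = _record({("xi", "EdU"): 300.0, ("xi", "PCNA"): 150.0})
        assert xr.edu_pcna_ratio(rec, "xi") == 2.0

    def test_zero_pcna_rejected(self):
        rec = _record({("xi", "EdU"): 300.0, ("xi", "PCNA"): 0.0})
        with pytest.raises(UndefinedRatioError):
            xr.edu_pcna_ratio(rec, "xi")

    def test_control_population_self_normalises_to_one(self):
        vals = np.array([1.2, 1.5, 1.8, 1.5])
        conds = ["scramble"] * 4
        assert xr.control_normalize(vals, conds).mean() == pytest.approx(1.0)

    def test_missing_control_rejected(self):
        with pytest.raises(NormalizationAnchorError):
            xr.control_normalize([1.0], ["mh2a1_kd"], control="scramble")

    def test_joint_rescaling_invariance(self):
        rec = _record({("xi", "EdU"): 300.0, ("xi", "PCNA"): 150.0})
        scaled = _record({("xi", "EdU"): 300.0 * 7, ("xi", "PCNA"): 150.0 * 7})
        assert xr.edu_pcna_ratio(rec) == xr.edu_pcna_ratio(scaled)


class TestRpaCvCurve:
    def _two_level_frames(self, amplitudes, background=100.0, frac=0.1):
        """Frames where `frac` of nucleus voxels sit at background+A: the
        population cV has the closed form sqrt(f(1-f))*A / (b + f*A)."""
        frames, masks = [], []
        n = 100
        for a in amplitudes:
            img = np.full((1, n, n), background)
            k = int(frac * n * n)
            img[0].flat[:k] = background + a
            frames.append(VoxelImage(img[None], ("RPA",), (1, 1, 1)))
            masks.append(RegionMask(np.ones((1, n, n), dtype=bool), "nucleus", (1, 1, 1)))
        return frames, masks

    @staticmethod
    def _cv_closed_form(a, b=100.0, f=0.1):
        mu = b + f * a
        sigma = np.sqrt(f * (1 - f)) * a
        return sigma / mu

    def test_matches_two_level_closed_form(self):
        amps = [10.0, 30.0, 60.0, 120.0]
        frames, masks = self._two_level_frames(amps)
        curve = xr.rpa_cv_curve(frames, masks)
        for got, a in zip(curve.cv_raw, amps):
            assert got == pytest.approx(self._cv_closed_form(a), rel=1e-9)
        expect_norm = [self._cv_closed_form(a) / self._cv_closed_form(amps[0]) for a in amps]
        assert curve.cv_norm == pytest.approx(expect_norm)
        assert curve.cv_norm[0] == 1.0

    def test_growing_spots_give_increasing_cv(self):
        frames, masks = self._two_level_frames([10, 20, 40, 80])
        curve = xr.rpa_cv_curve(frames, masks)
        assert all(b > a for a, b in zip(curve.cv_norm, curve.cv_norm[1:]))

    def test_constant_frames_not_normalisable(self):
        frames, masks = self._two_level_frames([0.0, 0.0])
        with pytest.raises(UndefinedCvError):
            xr.rpa_cv_curve(frames, masks)

    def test_accumulating_vs_static_series(self):
        acc_frames, acc_masks = xr.make_rpa_series(5, accumulating=True, seed=2)
        dmso_frames, dmso_masks = xr.make_rpa_series(5, accumulating=False, seed=2)
        acc = xr.rpa_cv_curve(acc_frames, acc_masks)
        dmso = xr.rpa_cv_curve(dmso_frames, dmso_masks)
        assert acc.cv_norm[-1] > dmso.cv_norm[-1]
        assert dmso.cv_norm[-1] == pytest.approx(1.0, abs=1e-6)


class TestLoadingCoefficient:
    def _uniform_cell(self, xi_factor=1.0, target_value=50.0, n=64):
        data = np.zeros((2, 1, n, n))
        nuc = np.zeros((1, n, n), dtype=bool)
        nuc[0, 4:-4, 4:-4] = True
        xi = np.zeros_like(nuc)
        xi[0, 8:16, 8:16] = True
        data[0][nuc] = 100.0  # DAPI
        data[1][nuc] = target_value
        data[1][xi] = target_value * xi_factor
        img = VoxelImage(data, ("DAPI", "Mcm2"), (1, 0.1, 0.1))
        return img, RegionMask(nuc, "nucleus", (1, 0.1, 0.1)), RegionMask(xi, "xi", (1, 0.1, 0.1))

    def test_uniform_field_identity_over_seeded_rois(self):
        img, nuc, xi = self._uniform_cell(1.0)
        for seed in range(50):
            roi2 = xr.control_roi(nuc, xi, seed=seed)
            assert xr.loading_coefficient(img, "Mcm2", xi, roi2) == pytest.approx(1.0)

    def test_doubled_target_in_xi_gives_two(self):
        img, nuc, xi = self._uniform_cell(2.0)
        roi2 = xr.control_roi(nuc, xi, seed=3)
        assert xr.loading_coefficient(img, "Mcm2", xi, roi2) == pytest.approx(2.0)

    def test_zero_denominator_rejected(self):
        img, nuc, xi = self._uniform_cell(1.0, target_value=0.0)
        roi2 = xr.control_roi(nuc, xi, seed=1)
        with pytest.raises(UndefinedRatioError):
            xr.loading_coefficient(img, "Mcm2", xi, roi2)


class TestLoadingCurve:
    def _cells(self):
        rows = []
        for cond, final in (("scramble", 4.44), ("mh2a1_kd", 2.77)):
            for t in range(1, 9):
                coef = 1.0 + (final - 1.0) * (t - 1) / 7.0
                for i in range(3):
                    rows.append(
                        {"condition": cond, "time_point": float(t), "coefficient": coef}
                    )
        return pd.DataFrame(rows)

    def test_control_anchored_at_one_and_endpoints_recovered(self):
        curves = xr.loading_curve(self._cells())
        assert curves["scramble"].values[0] == pytest.approx(1.0)
        assert curves["scramble"].values[-1] == pytest.approx(4.44)
        assert curves["mh2a1_kd"].values[-1] == pytest.approx(2.77)

    def test_flat_control_stays_at_one(self):
        df = pd.DataFrame(
            {
                "condition": ["scramble"] * 6,
                "time_point": [1, 1, 2, 2, 3, 3],
                "coefficient": [2.0] * 6,
            }
        )
        curves = xr.loading_curve(df)
        assert curves["scramble"].values == pytest.approx([1.0, 1.0, 1.0])

    def test_row_order_invariance(self):
        df = self._cells()
        a = xr.loading_curve(df)
        b = xr.loading_curve(df.sample(frac=1.0, random_state=1))
        assert a["mh2a1_kd"].values == pytest.approx(b["mh2a1_kd"].values)

    def test_missing_anchor_rejected(self):
        df = self._cells()
        df = df[~((df["condition"] == "scramble") & (df["time_point"] == 1.0))]
        with pytest.raises(NormalizationAnchorError):
            xr.loading_curve(df)


class TestPlaDensityAndAreas:
    def test_density_arithmetic(self):
        rec = _record({("nucleus", "DAPI"): 1e6}, {"pla_spots_nucleus": 10})
        assert xr.pla_density(rec, "nucleus") == pytest.approx(1e-5)

    def test_zero_dapi_rejected(self):
        rec = _record({("nucleus", "DAPI"): 0.0}, {"pla_spots_nucleus": 5})
        with pytest.raises(UndefinedRatioError):
            xr.pla_density(rec, "nucleus")

    def test_xi_relative_area_bounds(self):
        rec = _record({("xi", "DAPI"): 100.0, ("nucleus", "DAPI"): 1000.0})
        assert xr.xi_relative_area(rec) == pytest.approx(0.1)
        full = _record({("xi", "DAPI"): 1000.0, ("nucleus", "DAPI"): 1000.0})
        assert xr.xi_relative_area(full) == 1.0
        bad = _record({("xi", "DAPI"): 1100.0, ("nucleus", "DAPI"): 1000.0})
        with pytest.raises(InconsistencyError):
            xr.xi_relative_area(bad)

    def test_decondensed_xi_has_larger_relative_area(self, quiet_scramble):
        # knockdown preset Xi is decondensed -> larger share of DAPI; proxy
        # via generator geometry: compare 1-Xi vs 2-Xi cells instead is not
        # the contrast; here we check the metric responds to planted share
        small = _record({("xi", "DAPI"): 80.0, ("nucleus", "DAPI"): 1000.0})
        large = _record({("xi", "DAPI"): 160.0, ("nucleus", "DAPI"): 1000.0})
        assert xr.xi_relative_area(large) > xr.xi_relative_area(small)


class TestHistoneLevelAndDapiSd:
    def test_level_relative_to_control(self):
        rec = _record({("xi", "Mcm2"): 75.0})
        assert xr.histone_level(rec, "Mcm2", "xi", control_mean=100.0) == 0.75
        with pytest.raises(UndefinedRatioError):
            xr.histone_level(rec, "Mcm2", "xi", control_mean=0.0)

    def test_dapi_sd_closed_forms(self):
        img = np.zeros((1, 1, 10, 10))
        img[0, 0, :5] = 40.0
        img[0, 0, 5:] = 60.0
        vi = VoxelImage(img, ("DAPI",), (1, 1, 1))
        m = RegionMask(np.ones((1, 10, 10), dtype=bool), "nucleus", (1, 1, 1))
        assert xr.dapi_sd(vi, m) == pytest.approx(10.0)  # |a-b|/2
        uni = VoxelImage(np.full((1, 1, 10, 10), 7.0), ("DAPI",), (1, 1, 1))
        assert xr.dapi_sd(uni, m) == 0.0
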