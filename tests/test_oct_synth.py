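import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from ezquant.oct_synth import (
    CohortParams,
    FOLLOW_UP_VISITS,
    LesionSpec,
    simulate_cohort,
    simulate_volume,
)


class TestSimulateVolume:
    def test_no_lesions_is_clean(self, cirrus):
        _, truth = simulate_volume(cirrus, [], noise_sd=0.0, seed=0)
        assert not truth.defect_mask.any()
        assert truth.true_defect_area_mm2 == 0.0
        assert truth.gradable

    def test_identical_seed_identical_volume(self, cirrus):
        lesions = [LesionSpec("ez_defect", (3.0, 3.0), 0.15)]
        v1, t1 = simulate_volume(cirrus, lesions, noise_sd=0.1, seed=42)
        v2, t2 = simulate_volume(cirrus, lesions, noise_sd=0.1, seed=42)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.defect_mask, t2.defect_mask)
        v3, _ = simulate_volume(cirrus, lesions, noise_sd=0.1, seed=43)
        assert not np.array_equal(v1.data, v3.data)

    def test_circular_defect_area_matches_analytic(self, cirrus):
        """Rasterized area within one pixel-area per boundary pixel of
        pi*r^2 for a fovea-centered circle."""
        _, truth = simulate_volume(
            cirrus, [LesionSpec("ez_defect", (3.0, 3.0), 0.2)], seed=0
        )
        analytic = np.pi * 0.2**2
        boundary_px = int(
            (truth.defect_mask & ~binary_erosion(truth.defect_mask)).sum()
        )
        bound = boundary_px * cirrus.en_face_pixel_area_mm2
        assert abs(truth.true_defect_area_mm2 - analytic) <= bound

    def test_large_shadow_makes_scan_ungradable(self, cirrus):
        # severity-1 shadow over roughly half the CSF
        _, truth = simulate_volume(
            cirrus, [LesionSpec("shadow", (3.0, 3.0), 0.37, severity=1.0)], seed=0
        )
        assert truth.blocked_fraction > 0.25
        assert not truth.gradable

    def test_lesion_outside_field_rejected(self, cirrus):
        with pytest.raises(ValueError):
            simulate_volume(cirrus, [LesionSpec("ez_defect", (7.0, 3.0), 0.1)])

    def test_defect_attenuates_ez_band(self, cirrus):
        vol, truth = simulate_volume(
            cirrus, [LesionSpec("ez_defect", (3.0, 3.0), 0.3)], noise_sd=0.0, seed=0
        )
        b, a = np.argwhere(truth.defect_mask)[0]
        b0, a0 = 5, 5  # far from the lesion
        rpe = int(truth.rpe_inner_depth[b, a])
        ez_region = vol.data[b, rpe - 35 : rpe - 25, a]
        healthy = vol.data[b0, rpe - 35 : rpe - 25, a0]
        assert ez_region.max() < 0.5 * healthy.max()


class TestSimulateCohort:
    def test_deterministic_by_seed(self):
        t1 = simulate_cohort(CohortParams(n_participants=50, seed=5))
        t2 = simulate_cohort(CohortParams(n_participants=50, seed=5))
        assert t1.equals(t2)

    def test_baseline_vals_within_eligibility(self):
        table = simulate_cohort(CohortParams(n_participants=200, seed=1))
        bl = table[table["visit"] == "BL"]["vals_letters"].dropna()
        assert bl.between(19, 73).all()

    def test_one_row_per_participant_visit(self):
        table = simulate_cohort(CohortParams(n_participants=30, seed=2))
        assert len(table) == 30 * 5
        assert not table.duplicated(["participant_id", "visit"]).any()

    def test_null_area_effect_gives_no_correlation(self):
        params = CohortParams(
            n_participants=2000, area_slope=0.0, rho=0.0, seed=3,
            missing_rate={}, ungradable_rate={},
        )
        table = simulate_cohort(params)
        rows = table[table["visit"].isin(FOLLOW_UP_VISITS)].dropna(
            subset=["defect_area_mm2", "vals_change"]
        )
        r = np.corrcoef(rows["defect_area_mm2"], rows["vals_change"])[0, 1]
        assert abs(r) < 0.1

    def test_ar1_lag1_autocorrelation_recovered(self):
        params = CohortParams(
            n_participants=2000, rho=0.6, sigma=8.0, seed=4,
            missing_rate={}, ungradable_rate={},
        )
        table = simulate_cohort(params)
        # residuals after removing the known generating mean structure
        rows = table[table["visit"].isin(FOLLOW_UP_VISITS)].copy()
        eff = rows["visit"].map(params.visit_effects).astype(float)
        resid = (
            rows["vals_change"] - eff - params.area_slope * rows["true_area_mm2"]
        ).to_numpy()
        resid = resid.reshape(-1, 4)
        lag1 = np.corrcoef(resid[:, :-1].ravel(), resid[:, 1:].ravel())[0, 1]
        assert lag1 == pytest.approx(0.6, abs=0.1)

    def test_ar1_covariance_structure(self):
        """Empirical cov(eps_i, eps_j) ~ sigma^2 rho^|i-j| at large n."""
        params = CohortParams(
            n_participants=3000, rho=0.5, sigma=8.0, seed=6,
            missing_rate={}, ungradable_rate={},
        )
        table = simulate_cohort(params)
        rows = table[table["visit"].isin(FOLLOW_UP_VISITS)].copy()
        eff = rows["visit"].map(params.visit_effects).astype(float)
        resid = (
            rows["vals_change"] - eff - params.area_slope * rows["true_area_mm2"]
        ).to_numpy().reshape(-1, 4)
        cov = np.cov(resid.T)
        for i in range(4):
            for j in range(4):
                expected = params.sigma**2 * params.rho ** abs(i - j)
                assert cov[i, j] == pytest.approx(expected, rel=0.15, abs=3.0)

    def test_area_distribution_moments(self):
        table = simulate_cohort(CohortParams(n_participants=5000, seed=7))
        m01 = table[(table["visit"] == "M01")]["defect_area_mm2"].dropna()
        assert m01.mean() == pytest.approx(0.07, abs=0.02)
        assert m01.std() == pytest.approx(0.16, abs=0.05)
        assert (m01 == 0).mean() == pytest.approx(0.487, abs=0.05)
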