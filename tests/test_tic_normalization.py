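import numpy as np
import pytest
from scipy import stats

from panffpe import synthetic as syn
from panffpe import tic_normalization as tn
from panffpe.errors import (
    CalibrationRejectedError,
    DegenerateDesignError,
    NoDataError,
    ValidationError,
)
from panffpe.io_formats import SpectrumTICRecord


def _rec(run, idx, level, tic):
    return SpectrumTICRecord(run, idx, level, 0.1 * idx, tic)


class TestSumMS1TIC:
    def test_hand_sum_excludes_ms2(self):
        records = [
            _rec("r", 0, 1, 10.0),
            _rec("r", 1, 2, 999.0),
            _rec("r", 2, 1, 20.0),
            _rec("r", 3, 1, 30.0),
        ]
        assert tn.sum_ms1_tic(records, "r") == 60.0

    def test_single_scan_identity(self):
        assert tn.sum_ms1_tic([_rec("r", 0, 1, 42.0)], "r") == 42.0

    def test_no_ms1_scans_is_an_error_not_zero(self):
        records = [_rec("r", 0, 2, 5.0)]
        with pytest.raises(NoDataError):
            tn.sum_ms1_tic(records, "r")
        with pytest.raises(NoDataError):
            tn.sum_ms1_tic(records, "other_run")

    def test_matches_brute_force_loop_on_synthetic_run(self):
        rng = np.random.default_rng(0)
        records = [
            _rec("big", i, 1 if rng.random() < 0.6 else 2, float(rng.uniform(0, 1e6)))
            for i in range(500)
        ]
        expected = 0.0
        for r in records:  # independent accumulation
            if r.ms_level == 1:
                expected += r.tic
        assert tn.sum_ms1_tic(records, "big") == pytest.approx(expected, rel=1e-12)


class TestFitCalibration:
    def test_exact_line(self):
        curve = tn.fit_calibration([(1, 2), (2, 4), (3, 6)])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.qc_pass

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            tn.fit_calibration([(5, 1), (5, 2), (5, 3)])
        with pytest.raises(DegenerateDesignError):
            tn.fit_calibration([(5, 1)])

    def test_noiseless_synthetic_series_passes_gate(self):
        config = syn.SyntheticConfig(seed=3, cohorts=(("A", 2),), tic_noise_cv=0.0)
        dilution, _, _ = syn.generate_tic_dataset(config)
        sums = tn.sum_ms1_tic_by_run(dilution)
        points = [(ng, sums[f"dilution_{ng:g}ng"]) for ng in config.dilution_points_ng]
        curve = tn.fit_calibration(points, r2_threshold=0.97)
        assert curve.r_squared > 1 - 1e-12
        assert curve.qc_pass

    def test_noisy_fit_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        amounts = np.array([16, 31, 63, 125, 250, 500, 750, 1000], dtype=float)
        tics = 3e8 * amounts * (1 + rng.normal(0, 0.05, amounts.size))
        curve = tn.fit_calibration(list(zip(amounts, tics)))
        # independent oracle: full normal-equation solve
        design = np.column_stack([amounts, np.ones_like(amounts)])
        beta, *_ = np.linalg.lstsq(design, tics, rcond=None)
        assert curve.slope == pytest.approx(beta[0], rel=1e-9)
        assert curve.intercept == pytest.approx(beta[1], rel=1e-9)
        lr = stats.linregress(amounts, tics)
        assert curve.r_squared == pytest.approx(lr.rvalue**2, rel=1e-9)

    def test_r2_invariant_under_tic_rescaling(self):
        rng = np.random.default_rng(6)
        amounts = np.linspace(16, 1000, 8)
        tics = 1e8 * amounts * (1 + rng.normal(0, 0.1, 8))
        c1 = tn.fit_calibration(list(zip(amounts, tics)))
        c2 = tn.fit_calibration(list(zip(amounts, 7.5 * tics)))
        assert c2.r_squared == pytest.approx(c1.r_squared, rel=1e-12)
        assert c2.slope == pytest.approx(7.5 * c1.slope, rel=1e-12)


@pytest.fixture
def good_curve():
    return tn.fit_calibration([(ng, 2e8 * ng + 1e7) for ng in (16, 63, 250, 1000)])


class TestEstimateAmounts:
    def test_on_curve_inversion(self, good_curve):
        tic_250 = good_curve.predict(250.0)
        [loading] = tn.estimate_amounts(good_curve, [("s1", tic_250, 1.0)])
        assert loading.est_amount_ng == pytest.approx(250.0, rel=1e-12)
        assert loading.triage == "ok"

    def test_rejects_failed_calibration(self, good_curve):
        good_curve.r_squared = 0.9
        with pytest.raises(CalibrationRejectedError):
            tn.estimate_amounts(good_curve, [("s1", 1e9, 1.0)])

    def test_below_bottom_point_is_low_yield(self, good_curve):
        tic_low = good_curve.predict(10.0)
        [loading] = tn.estimate_amounts(good_curve, [("s1", tic_low, 1.0)])
        assert loading.triage == "low_yield"

    def test_above_top_point_is_flagged_not_refused(self, good_curve):
        tic_high = good_curve.predict(1500.0)
        [loading] = tn.estimate_amounts(good_curve, [("s1", tic_high, 1.0)])
        assert loading.triage == "above_range"
        assert loading.est_amount_ng == pytest.approx(1500.0, rel=1e-12)

    def test_inverse_then_forward_round_trip(self, good_curve):
        for tic in np.linspace(good_curve.predict(16), good_curve.predict(1000), 13):
            assert good_curve.predict(good_curve.invert(tic)) == pytest.approx(tic, rel=1e-9)

    def test_est_amount_increasing_in_tic(self, good_curve):
        tics = np.linspace(good_curve.predict(20), good_curve.predict(900), 50)
        loadings = tn.estimate_amounts(good_curve, [(f"s{i}", t, 1.0) for i, t in enumerate(tics)])
        amounts = [ld.est_amount_ng for ld in loadings]
        assert np.all(np.diff(amounts) > 0)

    def test_planted_load_recovery(self):
        config = syn.SyntheticConfig(
            seed=21, cohorts=(("A", 60),), tic_noise_cv=0.05, load_cov=0.5
        )
        dilution, samples, truth = syn.generate_tic_dataset(config)
        sums = tn.sum_ms1_tic_by_run(dilution)
        points = [(ng, sums[f"dilution_{ng:g}ng"]) for ng in config.dilution_points_ng]
        curve = tn.fit_calibration(points)
        sample_sums = tn.sum_ms1_tic_by_run(samples)
        loadings = tn.estimate_amounts(
            curve, [(sid, sample_sums[sid], 1.0) for sid in truth.sample_load_ng.index]
        )
        rel_err = np.abs(
            np.array([ld.est_amount_ng for ld in loadings]) - truth.sample_load_ng.values
        ) / truth.sample_load_ng.values
        assert np.median(rel_err) < 0.05


class TestLoadingVolumes:
    def _loading(self, conc):
        return tn.SampleLoading("s", 1.0, conc * 1.0, 1.0, conc)

    def test_volume_for_target(self):
        [out] = tn.compute_loading_volumes([self._loading(100.0)], target_ng=600.0)
        assert out.volume_for_target_ul == pytest.approx(6.0)
        assert out.triage == "ok"

    def test_capacity_bound(self):
        [out] = tn.compute_loading_volumes(
            [self._loading(1.0)], target_ng=600.0, max_volume_ul=20.0
        )
        assert out.triage == "low_yield"

    def test_nonpositive_concentration_never_negative_volume(self):
        [out] = tn.compute_loading_volumes([self._loading(-5.0)], target_ng=600.0)
        assert out.volume_for_target_ul is None
        assert out.triage == "low_yield"

    def test_invalid_target(self):
        with pytest.raises(ValidationError):
            tn.compute_loading_volumes([self._loading(10.0)], target_ng=0.0)

    def test_excluded_fraction_monotone_in_max_volume(self):
        rng = np.random.default_rng(9)
        loadings = [self._loading(c) for c in rng.lognormal(3.0, 1.0, 200)]
        fractions = []
        for max_vol in (2.0, 5.0, 10.0, 20.0, 50.0):
            out = tn.compute_loading_volumes(loadings, 600.0, max_volume_ul=max_vol)
            fractions.append(np.mean([o.triage == "low_yield" for o in out]))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestNormalizationBenefit:
    def test_identical_sums_zero_cov(self):
        report = tn.normalization_benefit({"g": [5.0, 5.0, 5.0]}, {"g": [5.0, 5.0, 5.0]})
        assert report["g"]["cov_before_percent"] == 0.0

    def test_two_sample_hand_computation(self):
        assert tn.cov_percent([90.0, 110.0]) == pytest.approx(10.0)

    def test_group_size_one_undefined(self):
        with pytest.raises(ValidationError):
            tn.cov_percent([1.0])

    def test_synthetic_cov_ratio_at_least_two(self):
        config = syn.SyntheticConfig(
            seed=13, cohorts=(("A", 120),), tic_noise_cv=0.05, load_cov=0.5
        )
        dilution, samples, truth = syn.generate_tic_dataset(config)
        sums = tn.sum_ms1_tic_by_run(dilution)
        curve = tn.fit_calibration(
            [(ng, sums[f"dilution_{ng:g}ng"]) for ng in config.dilution_points_ng]
        )
        sample_sums = tn.sum_ms1_tic_by_run(samples)
        order = list(truth.sample_load_ng.index)
        before = np.array([sample_sums[s] for s in order])
        loadings = tn.estimate_amounts(curve, [(s, sample_sums[s], 1.0) for s in order])
        after = syn.simulate_analytical_sums(
            truth.sample_load_ng.values,
            np.array([ld.est_amount_ng for ld in loadings]),
            600.0,
            config,
        )
        report = tn.normalization_benefit({"A": before}, {"A": after})
        assert report["A"]["cov_ratio"] >= 2.0
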