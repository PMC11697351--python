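import numpy as np
import pandas as pd
import pytest

from panffpe import quant_matrix as qm
from panffpe import synthetic as syn
from panffpe.errors import NoKneeError, ValidationError
from tests.conftest import make_matrix


def planted_knee_curve(k: int, amplitude: float, level: float, slope: float):
    """Analytic curve: linear decline plus a steep drop ending at cutoff k.

    The drop is a quartic ramp whose value and first three derivatives all
    vanish at k, so the curve joins the linear section maximally smoothly
    and k is the well-defined start of the constant-slope region.
    """
    c = np.arange(1, 101, dtype=float)
    ramp = np.clip((k - c) / (k - 1), 0.0, None) ** 4
    counts = level - slope * c + amplitude * ramp
    return qm.CompletenessCurve(cutoffs=np.arange(1, 101), counts=counts)


class TestCompletenessCurve:
    def test_fully_complete_protein(self):
        m = make_matrix({"A": [[10, 10]], "B": [[10, 10]]})
        curve = qm.completeness_curve(m)
        assert (curve.counts == 1).all()

    def test_hand_counts_two_proteins(self):
        values = np.array([[10.0, np.nan, 10.0, np.nan], [10.0, 10.0, 10.0, 10.0]])
        m = make_matrix({"A": values})
        curve = qm.completeness_curve(m)
        assert curve.counts[39] == 2  # 40% cutoff
        assert curve.counts[59] == 1  # 60% cutoff
        assert curve.counts[0] == 2

    def test_counts_match_brute_force(self, two_cohort_config):
        matrix, _, _ = syn.generate_quant_matrix(two_cohort_config)
        curve = qm.completeness_curve(matrix)
        detected = matrix.detected().to_numpy()
        completeness = 100.0 * detected.sum(axis=1) / detected.shape[1]
        for c in range(1, 101):  # O(n·100) recount
            assert curve.counts[c - 1] == np.sum(completeness >= c - 1e-9)

    def test_counts_monotone_and_endpoint(self, two_cohort_config):
        matrix, _, _ = syn.generate_quant_matrix(two_cohort_config)
        curve = qm.completeness_curve(matrix)
        assert (np.diff(curve.counts) <= 0).all()
        assert curve.counts[0] == matrix.detected().any(axis=1).sum()

    def test_per_cohort_max_scope(self):
        # protein quantified in all of A, absent in B: global 50%, cohort-max 100%
        m = make_matrix({"A": [[10, 10]], "B": [[np.nan, np.nan]]})
        assert qm.completeness_curve(m, "global").counts[59] == 0
        assert qm.completeness_curve(m, "per_cohort_max").counts[99] == 1


class TestSelectCutoff:
    def test_linear_curve_selects_first_evaluable(self):
        curve = qm.CompletenessCurve(
            cutoffs=np.arange(1, 101), counts=1000.0 - 5.0 * np.arange(1, 101)
        )
        out = qm.select_completeness_cutoff(curve)
        assert out.selected_cutoff == 5  # first position with a full d2 window

    def test_planted_knee_recovered(self):
        curve = planted_knee_curve(15, 2000.0, 1000.0, 4.0)
        out = qm.select_completeness_cutoff(curve)
        assert abs(out.selected_cutoff - 15) <= 2

    def test_twenty_seeded_constructions_within_two_points(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(10, 26))
            curve = planted_knee_curve(
                k, rng.uniform(500, 3000), rng.uniform(800, 1500), rng.uniform(2, 6)
            )
            out = qm.select_completeness_cutoff(curve)
            assert abs(out.selected_cutoff - k) <= 2

    def test_invariant_under_vertical_scaling(self):
        curve = planted_knee_curve(18, 1500.0, 1200.0, 3.0)
        scaled = qm.CompletenessCurve(cutoffs=curve.cutoffs, counts=42.0 * curve.counts)
        assert (
            qm.select_completeness_cutoff(curve).selected_cutoff
            == qm.select_completeness_cutoff(scaled).selected_cutoff
        )

    def test_no_knee_raises_with_diagnostics(self):
        # slow exponential: |d2| never falls to 1% of its maximum within range
        c = np.arange(1, 101, dtype=float)
        curve = qm.CompletenessCurve(cutoffs=np.arange(1, 101), counts=5000 * np.exp(-c / 50))
        with pytest.raises(NoKneeError, match="d2"):
            qm.select_completeness_cutoff(curve)

    def test_derivatives_defined_on_interior_only(self):
        curve = qm.select_completeness_cutoff(planted_knee_curve(15, 2000, 1000, 4))
        assert np.isnan(curve.d1[:2]).all() and np.isnan(curve.d1[-2:]).all()
        assert np.isnan(curve.d2[:4]).all() and np.isnan(curve.d2[-4:]).all()
        assert (curve.d1[~np.isnan(curve.d1)] <= 0).all()


class TestFilterByCompleteness:
    def test_boundary_inclusive(self):
        # 1 of 5 samples in cohort A = 20%, exactly at the cutoff
        m = make_matrix({"A": [[10, np.nan, np.nan, np.nan, np.nan]]})
        assert qm.filter_by_completeness(m, 20.0).n_proteins == 1

    def test_below_cutoff_everywhere_dropped(self):
        m = make_matrix(
            {"A": [[10, np.nan, np.nan, np.nan, np.nan]], "B": [[np.nan] * 5]}
        )
        assert qm.filter_by_completeness(m, 21.0).n_proteins == 0

    def test_matches_brute_force(self, two_cohort_config):
        matrix, _, _ = syn.generate_quant_matrix(two_cohort_config)
        filtered = qm.filter_by_completeness(matrix, 13.0)
        det = matrix.detected()
        survivors = set()
        for protein in matrix.proteins:
            for cohort in matrix.cohort_names():
                cc = matrix.cohort_columns(cohort)
                if det.loc[protein, cc].sum() / len(cc) >= 0.13 - 1e-12:
                    survivors.add(protein)
                    break
        assert set(filtered.proteins) == survivors

    def test_invalid_cutoff(self):
        m = make_matrix({"A": [[10, 10]]})
        with pytest.raises(ValidationError):
            qm.filter_by_completeness(m, 0.0)


class TestImputation:
    def test_complete_matrix_is_identity(self):
        m = make_matrix({"A": [[10, 11], [12, 13]]})
        imputed, unimputable = qm.impute_downshifted(m, seed=1)
        pd.testing.assert_frame_equal(imputed.lfq, m.lfq)
        assert unimputable == []

    def test_downshift_moments(self):
        # valid log2 values median 20, sd 1; many missing cells to estimate moments
        n_missing = 10_000
        row = np.concatenate([[19.0, 20.0, 21.0], [np.nan] * n_missing])
        m = make_matrix({"A": [row]})
        imputed, _ = qm.impute_downshifted(m, seed=2)
        filled = np.log2(imputed.lfq.to_numpy()[0, 3:])
        assert np.median(filled) == pytest.approx(20.0 - 1.8, abs=0.02)
        assert filled.std(ddof=1) == pytest.approx(0.3, abs=0.01)

    def test_valid_cells_untouched(self, two_cohort_config):
        matrix, _, _ = syn.generate_quant_matrix(two_cohort_config)
        matrix = qm.filter_by_completeness(matrix, 13.0)
        imputed, _ = qm.impute_downshifted(matrix, seed=3)
        valid = matrix.detected().to_numpy()
        assert np.array_equal(
            matrix.lfq.to_numpy()[valid], imputed.lfq.to_numpy()[valid]
        )

    def test_same_seed_bitwise_identical(self, two_cohort_config):
        matrix, _, _ = syn.generate_quant_matrix(two_cohort_config)
        a, _ = qm.impute_downshifted(matrix, seed=9)
        b, _ = qm.impute_downshifted(matrix, seed=9)
        pd.testing.assert_frame_equal(a.lfq, b.lfq)

    def test_protein_with_one_valid_value_flagged(self):
        m = make_matrix({"A": [[10.0, np.nan, np.nan]]})
        imputed, unimputable = qm.impute_downshifted(m, seed=4)
        assert unimputable == ["P1"]
        assert imputed.lfq.isna().to_numpy().sum() == 2


class TestTopN:
    def _matrix_with_ibaq(self, ibaq_by_cohort):
        lfq_blocks, ibaq_blocks, sample_ids, cohorts = [], [], [], {}
        for cohort, block in ibaq_by_cohort.items():
            block = np.asarray(block, dtype=float)
            ids = [f"{cohort}_{i + 1}" for i in range(block.shape[1])]
            sample_ids.extend(ids)
            cohorts.update({s: cohort for s in ids})
            ibaq_blocks.append(block)
            lfq_blocks.append(block * 10)
        proteins = [f"P{i + 1}" for i in range(block.shape[0])]
        lfq = pd.DataFrame(np.concatenate(lfq_blocks, 1), index=proteins, columns=sample_ids)
        ibaq = pd.DataFrame(np.concatenate(ibaq_blocks, 1), index=proteins, columns=sample_ids)
        return qm.QuantMatrix(lfq, pd.Series(cohorts), ibaq=ibaq)

    def test_n_at_least_protein_count_returns_all(self):
        m = self._matrix_with_ibaq({"A": [[1, 2], [3, 4], [5, 6]]})
        assert qm.top_n_by_abundance(m, 10) == ["P1", "P2", "P3"]

    def test_planted_hierarchy_recovered(self):
        # cohort A ranks P1>P2>P3..., cohort B reversed
        a = np.array([[60.0], [50.0], [40.0], [30.0], [20.0]])
        b = a[::-1].copy()
        m = self._matrix_with_ibaq({"A": a, "B": b})
        assert qm.top_n_by_abundance(m, 2) == ["P1", "P2", "P4", "P5"]

    def test_requires_ibaq_layer(self):
        m = make_matrix({"A": [[10, 10]]})
        with pytest.raises(ValidationError):
            qm.top_n_by_abundance(m, 10)


class TestCovMetrics:
    def test_constant_group_zero(self):
        assert qm.cov_metrics({"g": [7.0, 7.0, 7.0]})["g"] == 0.0

    def test_hand_computation_sample_sd(self):
        assert qm.cov_metrics({"g": [90.0, 110.0]})["g"] == pytest.approx(14.142135, rel=1e-6)

    def test_small_group_undefined(self):
        with pytest.raises(ValidationError):
            qm.cov_metrics({"g": [1.0]})

    def test_lognormal_monte_carlo_band(self):
        rng = np.random.default_rng(12)
        sigma = 0.3
        values = rng.lognormal(5.0, sigma, 5000)
        expected = 100.0 * np.sqrt(np.exp(sigma**2) - 1.0)
        assert qm.cov_metrics({"g": values})["g"] == pytest.approx(expected, rel=0.05)


def test_matrix_round_trip(tmp_path, two_cohort_config):
    matrix, _, _ = syn.generate_quant_matrix(two_cohort_config)
    matrix.write(tmp_path / "m.tsv", tmp_path / "s.tsv")
    back = qm.QuantMatrix.read(tmp_path / "m.tsv", tmp_path / "s.tsv")
    assert list(back.proteins) == list(matrix.proteins)
    assert (back.cohorts == matrix.cohorts).all()
    a, b = matrix.lfq.to_numpy(), back.lfq.to_numpy()
    assert np.array_equal(np.isnan(a), np.isnan(b))
    assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)], rtol=1e-12)
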