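"""Descriptor selection, MLR fitting, LOO q², reduction, prediction, ESD."""

import warnings

import numpy as np
import pandas as pd
import pytest

from matqsar.descriptors import DescriptorTable, scale_table
from matqsar.qsar import (
    correction_factor_analysis,
    esd_outliers,
    fit_mlr,
    loo_q2,
    predict,
    reduce_model,
    select_descriptors,
)

import oracles


def table_from(arr, names=None, ids=None, scaled=True):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"d{i}" for i in range(arr.shape[1])]
    ids = ids or [f"c{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, columns=names, index=pd.Index(ids, name="compound_id"))
    maxima = df.abs().max(axis=0) if scaled else None
    return DescriptorTable(values=df, scaled=scaled, scaling_maxima=maxima)


class TestSelectDescriptors:
    def test_descriptor_identical_to_activity_selected_first(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        x = np.column_stack([y, rng.normal(size=20)])
        sel = select_descriptors(table_from(x), y, activity_threshold=0.7)
        assert sel[0] == "d0"

    def test_duplicate_descriptor_pruned(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        x = np.column_stack([y + 0.1 * rng.normal(size=20)] * 2)
        sel = select_descriptors(table_from(x), y)
        assert len(sel) == 1

    def test_planted_correlation_structure(self):
        """Five descriptors with |r|≈{0.9, 0.8 (cross-correlated with the
        first), 0.75, 0.3, 0.1}: selection keeps the 0.9 and 0.75 ones."""
        rng = np.random.default_rng(3)
        n = 400
        y = rng.normal(size=n)

        def corr_with(rho, base=None):
            base = y if base is None else base
            z = (base - base.mean()) / base.std()
            return rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)

        d0 = corr_with(0.9)
        d1 = 0.95 * (d0 - d0.mean()) / d0.std() + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        d2 = corr_with(0.75)
        d3 = corr_with(0.3)
        d4 = corr_with(0.1)
        x = np.column_stack([d0, d1, d2, d3, d4])
        sel = select_descriptors(table_from(x), y, activity_threshold=0.7, cross_threshold=0.7)
        assert "d0" in sel and "d2" in sel
        assert "d1" not in sel and "d3" not in sel and "d4" not in sel

    def test_no_descriptor_passes_warns_and_returns_empty(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="no descriptor"):
            assert select_descriptors(table_from(x), y, activity_threshold=0.99) == []


class TestFitMlr:
    def test_noiseless_coefficients_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 2))
        y = 2.0 * x[:, 0] - 1.0 * x[:, 1] + 0.5
        m = fit_mlr(table_from(x), y, ["d0", "d1"])
        assert np.allclose(m.coefficients, [2.0, -1.0], atol=1e-8)
        assert m.intercept == pytest.approx(0.5, abs=1e-8)
        assert m.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_activity_gives_zero_slopes(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 2))
        m = fit_mlr(table_from(x), np.full(15, 3.0), ["d0", "d1"])
        assert np.allclose(m.coefficients, 0.0, atol=1e-10)
        assert m.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_mlr(table_from(x), y, ["d0", "d1", "d2"])
        ref = oracles.normal_equations_fit(x, y)
        assert m.intercept == pytest.approx(ref[0], abs=1e-8)
        assert np.allclose(m.coefficients, ref[1:], atol=1e-8)

    def test_singular_design_names_dependent_column(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=15)
        x = np.column_stack([a, 2 * a])
        with pytest.raises(ValueError, match="d1"):
            fit_mlr(table_from(x), rng.normal(size=15), ["d0", "d1"])

    def test_r2_invariant_under_affine_rescale_of_y(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(25, 2))
        y = x @ [1.5, -0.7] + 0.3 * rng.normal(size=25)
        m1 = fit_mlr(table_from(x), y, ["d0", "d1"])
        m2 = fit_mlr(table_from(x), 3.0 * y + 10.0, ["d0", "d1"])
        assert m1.r2 == pytest.approx(m2.r2, abs=1e-12)
        assert np.allclose(3.0 * m1.coefficients, m2.coefficients, atol=1e-8)


class TestLooQ2:
    def test_noiseless_linear_data(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(30, 2))
        y = x @ [1.0, 2.0] + 1.0
        assert loo_q2(table_from(x), y, ["d0", "d1"]) > 0.999

    @pytest.mark.parametrize("seed", range(5))
    def test_shortcut_equals_explicit_refits(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 2))
        y = x @ [1.0, -0.5] + rng.normal(size=15)
        fast = loo_q2(table_from(x), y, ["d0", "d1"])
        slow = oracles.loo_q2_bruteforce(x, y)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_pure_noise_q2_below_r2(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            t = table_from(x)
            r2 = fit_mlr(t, y, ["d0", "d1", "d2"]).r2
            q2 = loo_q2(t, y, ["d0", "d1", "d2"])
            wins += q2 < r2
        assert wins == 50  # LOO always at least as pessimistic on noise

    def test_zero_variance_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="variance"):
            loo_q2(table_from(rng.normal(size=(10, 1))), np.ones(10), ["d0"])


class TestReduceModel:
    def test_informative_support_survives_noise_candidates(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            x = rng.normal(size=(n, 8))
            y = x[:, :3] @ [2.0, -1.5, 1.0] + 0.45 * rng.normal(size=n)
            t = table_from(x)
            m = reduce_model(t, y, [f"d{i}" for i in range(8)], max_desc=8)
            hits += set(m.descriptor_names) == {"d0", "d1", "d2"}
        assert hits >= 18  # >= 90% exact support recovery

    def test_single_candidate_unchanged(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(15, 1))
        y = x[:, 0] + 0.1 * rng.normal(size=15)
        m = reduce_model(table_from(x), y, ["d0"])
        assert m.descriptor_names == ("d0",)

    def test_max_desc_enforced(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(30, 5))
        y = x @ rng.normal(size=5) + 0.2 * rng.normal(size=30)
        m = reduce_model(table_from(x), y, [f"d{i}" for i in range(5)], max_desc=2)
        assert len(m.descriptor_names) <= 2

    def test_never_exceeds_one_descriptor_per_five_compounds(self):
        rng = np.random.default_rng(14)
        n = 20
        x = rng.normal(size=(n, 6))
        y = x @ rng.normal(size=6) + 0.2 * rng.normal(size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = reduce_model(table_from(x), y, [f"d{i}" for i in range(6)])
        assert len(m.descriptor_names) <= n // 5


class TestPredict:
    def test_identity_on_training_set(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(20, 2))
        y = x @ [1.0, 1.0] + 0.3 * rng.normal(size=20)
        t = table_from(x)
        m = fit_mlr(t, y, ["d0", "d1"])
        rep = predict(m, t, y)
        assert rep.r2_test == pytest.approx(m.r2, abs=1e-10)

    def test_noiseless_generalization(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(40, 2))
        y = x @ [2.0, -1.0] + 5.0
        t = table_from(x)
        m = fit_mlr(table_from(x[:30]), y[:30], ["d0", "d1"])
        rep = predict(m, table_from(x[30:]), y[30:])
        assert rep.r2_test > 0.999

    def test_hand_computed_three_compound_prediction(self):
        m = fit_mlr(
            table_from([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
            np.array([1.0, 3.0, 0.0, 2.0]),
            ["d0", "d1"],
        )  # exact plane: y = 1 + 2*d0 - 1*d1
        test = table_from([[0.5, 0.5], [1.0, 1.0], [0.0, 0.0]], ids=["p", "q", "r"])
        rep = predict(m, test, np.array([1.5, 2.0, 1.0]))
        assert np.allclose(rep.predicted, [1.5, 2.0, 1.0], atol=1e-10)

    def test_missing_descriptor_column_raises(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        m = fit_mlr(table_from(x), y, ["d0", "d1"])
        bad = table_from(x[:, :1], names=["d0"])
        with pytest.raises(KeyError, match="d1"):
            predict(m, bad, y)


class TestCorrectionFactor:
    def _model(self):
        # y = 1 + 2*d0 - 0.3*d1 fitted exactly
        x = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], dtype=float)
        y = 1.0 + 2.0 * x[:, 0] - 0.3 * x[:, 1]
        return fit_mlr(table_from(x), y, ["d0", "d1"]), x, y

    def test_substitution_preserves_predictions_where_term_equals_constant(self):
        m, x, y = self._model()
        # replace the d1 term by its value when d1 = 1: constant -0.3
        m2 = correction_factor_analysis(m, "d1", -0.3)
        rows = x[:, 1] == 1.0
        t = table_from(x[rows], names=["d0", "d1"])
        assert np.allclose(
            m2.predict_scaled(t.values), m.predict_scaled(t.values), atol=1e-10
        )

    def test_zero_term_shifts_by_constant(self):
        m, x, y = self._model()
        m2 = correction_factor_analysis(m, "d1", -0.3)
        rows = x[:, 1] == 0.0
        t = table_from(x[rows], names=["d0", "d1"])
        shift = m2.predict_scaled(t.values) - m.predict_scaled(t.values)
        assert np.allclose(shift, -0.3, atol=1e-10)

    def test_removing_zero_coefficient_with_zero_constant_is_identity(self):
        x = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [3.0, 1.0]])
        y = 2.0 * x[:, 0] + 1.0  # d1 irrelevant
        m = fit_mlr(table_from(x), y, ["d0", "d1"])
        m2 = correction_factor_analysis(m, "d1", 0.0)
        t = table_from(x, names=["d0", "d1"])
        assert np.allclose(m2.predict_scaled(t.values), m.predict_scaled(t.values), atol=1e-8)

    def test_unknown_descriptor_raises(self):
        m, _, _ = self._model()
        with pytest.raises(KeyError):
            correction_factor_analysis(m, "nope", 0.0)


class TestEsdOutliers:
    def test_identical_values_no_outliers(self):
        with pytest.warns(UserWarning, match="zero variance"):
            flags, _ = esd_outliers([2.0] * 10)
        assert not flags.any()

    def test_gross_outlier_flagged_exactly(self):
        flags, steps = esd_outliers([1.0, 1.1, 0.9, 1.05, 12.0], alpha=0.05, k_max=2)
        assert list(flags) == [False, False, False, False, True]

    def test_false_positive_rate_near_alpha(self):
        false_pos = 0
        n_trials = 1000
        for seed in range(n_trials):
            x = np.random.default_rng(seed).normal(size=30)
            flags, _ = esd_outliers(x, alpha=0.05)
            false_pos += flags.any()
        # generalized ESD holds the family-wise error near alpha
        assert false_pos / n_trials <= 0.08

    def test_k_max_bound(self):
        with pytest.raises(ValueError, match="k_max"):
            esd_outliers(np.arange(6.0), k_max=3)
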