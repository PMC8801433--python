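"""27%-rule discretization and batched logistic regression."""

import numpy as np
import pandas as pd
import pytest

from relapsetrack.errors import ModelError, ValidationError
from relapsetrack.riskmodel import (
    EXCLUDED,
    HIGH,
    LOW,
    ModelBatch,
    build_design,
    discretize_27,
    fit_logistic,
    run_batched_models,
    table5_frame,
)


def newton_logistic_oracle(X, y, tol=1e-12):
    """From-scratch Newton-Raphson logistic MLE (with intercept)."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(100):
        eta = Xc @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Xc.T @ (y - p)
        hess = Xc.T @ (Xc * (p * (1 - p))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestDiscretize:
    def test_uniform_grid_1_to_100(self):
        labels = discretize_27(np.arange(1, 101, dtype=float))
        low = np.nonzero(labels == LOW)[0] + 1
        high = np.nonzero(labels == HIGH)[0] + 1
        assert low.tolist() == list(range(1, 28))
        assert high.tolist() == list(range(74, 101))
        assert (labels == EXCLUDED).sum() == 46

    def test_counts_at_486(self):
        rng = np.random.default_rng(0)
        labels = discretize_27(rng.normal(size=486))
        assert (labels == LOW).sum() == 131
        assert (labels == HIGH).sum() == 131

    def test_conservation(self):
        rng = np.random.default_rng(1)
        for n in (8, 57, 200):
            labels = discretize_27(rng.normal(size=n))
            assert (labels == LOW).sum() + (labels == HIGH).sum() + (labels == EXCLUDED).sum() == n

    def test_all_equal_rejected(self):
        with pytest.raises(ValidationError):
            discretize_27(np.ones(50))

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            discretize_27(np.arange(5, dtype=float))

    def test_stable_tie_break(self):
        times = np.array([5.0, 1.0, 1.0, 2.0, 3.0, 9.0, 8.0, 7.0, 6.0, 4.0])
        labels = discretize_27(times)
        # round(0.27*10)=3 per tail; the two tied 1.0s keep input order.
        assert labels[1] == LOW and labels[2] == LOW
        assert (labels == LOW).sum() == 3 and (labels == HIGH).sum() == 3


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # Counts [[112, 41], [155, 202]] with control coded 1:
        # OR = 202*112 / (155*41).
        rows = (
            [(0, 0)] * 112 + [(0, 1)] * 41 + [(1, 0)] * 155 + [(1, 1)] * 202
        )
        X = pd.DataFrame({"control": [r[0] for r in rows]})
        y = [r[1] for r in rows]
        res = fit_logistic(X, y)
        assert res.coef.loc["control", "or"] == pytest.approx(112 * 202 / (155 * 41), rel=1e-6)

    def test_null_model_balanced_predicts_50(self):
        X = pd.DataFrame(index=range(100))
        y = [0] * 50 + [1] * 50
        res = fit_logistic(X, y)
        assert res.predicted_pct == pytest.approx(50.0)
        assert res.minus2loglik == pytest.approx(2 * 100 * np.log(2), rel=1e-9)
        assert res.nagelkerke_r2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.binomial(1, 0.4, 300)})
        eta = -0.3 + 0.8 * X["x1"] - 0.5 * X["x2"]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        res = fit_logistic(X, y)
        beta = newton_logistic_oracle(X.to_numpy(), y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-6)
        assert res.coef["coef"].to_numpy() == pytest.approx(beta[1:], abs=1e-6)

    def test_label_reversal_inverts_or(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.binomial(1, 0.5, 400)})
        y = rng.binomial(1, 0.3 + 0.4 * X["x"].to_numpy())
        a = fit_logistic(X, y)
        b = fit_logistic(X, 1 - y)
        assert a.coef.loc["x", "or"] == pytest.approx(1 / b.coef.loc["x", "or"], rel=1e-6)

    def test_nagelkerke_in_unit_interval(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = (rng.random(200) < 1 / (1 + np.exp(-2 * X["x"]))).astype(int)
        res = fit_logistic(X, y)
        assert 0.0 <= res.nagelkerke_r2 <= 1.0
        assert res.model_chi2 > 0

    def test_separation_named(self):
        X = pd.DataFrame({"sep": [0, 0, 0, 1, 1, 1], "ok": [1, 0, 1, 0, 1, 0]})
        with pytest.raises(ModelError, match="sep"):
            fit_logistic(X, [0, 0, 0, 1, 1, 1])

    def test_singular_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, 0, 1, 0, 1, 0], "b": [2.0, 0, 2, 0, 2, 0]})
        with pytest.raises(ModelError, match="singular"):
            fit_logistic(X, [0, 1, 0, 1, 1, 0])

    def test_excluded_labels_dropped(self):
        X = pd.DataFrame({"x": [0, 0, 1, 1] * 10})
        y = np.array(([0, 1] * 10) + [EXCLUDED] * 20)
        res = fit_logistic(X, y)
        assert res.n_used == 20


def _risk_frame(n, seed, group_effect=0.0):
    """Cohort-like frame plus survival times with an optional group effect."""
    from relapsetrack.cohort import CohortConfig, RelapseProcess, generate_cohort, simulate_relapse_times

    proc = RelapseProcess(
        mode="weibull_aft", shape=1.5,
        intercepts={"experimental": 250.0 + group_effect, "control": 250.0}, motivation_coeff=0.0,
    )
    cfg = CohortConfig(n_subjects=n, relapse_model=proc, seed=seed)
    cohort = generate_cohort(cfg)
    times = simulate_relapse_times(cohort, proc, seed=seed + 1)
    from relapsetrack.cohort import cohort_to_frame

    return cohort_to_frame(cohort), times


class TestBatchedModels:
    def test_four_nested_models_chi2_nondecreasing(self):
        frame, times = _risk_frame(400, seed=7, group_effect=300.0)
        labels = discretize_27(times)
        results, deltas = run_batched_models(frame, labels)
        assert len(results) == 4 and len(deltas) == 3
        chi2 = [r.model_chi2 for r in results]
        assert all(b >= a - 1e-8 for a, b in zip(chi2, chi2[1:]))
        assert all(f > 0 for _, f in deltas)
        assert len({r.n_used for r in results}) == 1  # shared subject set

    def test_group_or_sign_recovery(self):
        """Control subjects generated to relapse sooner: OR(control) > 1
        under the low=1 coding in nearly every seeded replicate."""
        hits = 0
        for seed in range(20):
            frame, times = _risk_frame(260, seed=100 + 3 * seed, group_effect=350.0)
            labels = discretize_27(times)
            res = fit_logistic(build_design(frame, [("group", "indicator", "control")]), labels)
            hits += res.coef.loc["group[control]", "or"] > 1
        assert hits >= 18

    def test_null_block_adds_little(self):
        # Predictors independent of the outcome: tiny chi-square gain.
        frame, times = _risk_frame(500, seed=55, group_effect=0.0)
        labels = discretize_27(times)
        results, deltas = run_batched_models(frame, labels)
        from scipy import stats

        d_chi2, d_df = deltas[1]  # clinical block on null data
        assert d_chi2 < stats.chi2(d_df).ppf(0.995)

    def test_missing_reference_level_rejected(self):
        frame, times = _risk_frame(100, seed=8)
        frame["marital"] = "married"
        with pytest.raises(ValidationError):
            run_batched_models(frame, discretize_27(times))

    def test_table_format(self):
        frame, times = _risk_frame(300, seed=9, group_effect=250.0)
        results, _ = run_batched_models(frame, discretize_27(times))
        table = table5_frame(results)
        assert list(table.columns) == ["Model I", "Model II", "Model III", "Model IV"]
        for footer in ("Chi-square", "Nag R-square", "-2Log Lik", "Predicted %"):
            assert footer in table.index

    def test_non_nested_batch_rejected(self):
        with pytest.raises(ValidationError):
            ModelBatch(blocks=((("age", "continuous", None),), (("marital", "indicator", "single"),)))
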