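"""Risk-factor modelling: 27%-rule discretization and batched logistic models.

The combined survival times are strongly right-skewed, so rather than a
linear model on the raw times the pipeline applies the upper-and-lower-27%
rule: subjects in the bottom 27% of ranked survival times are labelled
*low* survival (coded 1), the top 27% *high* (coded 0, the reference), and
the middle 46% are excluded from the regression.  Predictor blocks are then
entered in batches -- I sociodemographic, II + drug-abuse history,
III + clinical situation, IV + experimental group -- and each model reports
odds ratios with log-odds SEs, the model chi-square against the null,
Nagelkerke's R^2, -2 log likelihood and classification accuracy at the 0.5
cutoff, plus the chi-square improvement between consecutive models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError, ValidationError

LOW, HIGH, EXCLUDED = 1, 0, -1


def discretize_27(combined_times: Sequence[float], tail_fraction: float = 0.27) -> np.ndarray:
    """Label survival times low (1) / high (0) / excluded (-1) by the 27% rule.

    ``round(tail_fraction * n)`` subjects enter each tail; ranking is
    ascending with ties broken by stable input order.
    """
    times = np.asarray(list(combined_times), dtype=float)
    n = times.size
    if n < 8 or np.unique(times).size < 8:
        raise ValidationError("need at least 8 distinct survival times to discretize")
    if not 0.0 < tail_fraction <= 0.5:
        raise ValidationError(f"tail_fraction must lie in (0, 0.5], got {tail_fraction}")
    n_tail = int(np.floor(tail_fraction * n + 0.5))
    order = np.argsort(times, kind="stable")
    labels = np.full(n, EXCLUDED, dtype=int)
    labels[order[:n_tail]] = LOW
    labels[order[n - n_tail:]] = HIGH
    return labels


@dataclass(frozen=True)
class LogisticModelResult:
    """One fitted logistic model in the printed-table format."""

    coef: pd.DataFrame  # index: predictor; columns: coef, se, or, p
    intercept: float
    model_chi2: float
    df_model: int
    nagelkerke_r2: float
    minus2loglik: float
    predicted_pct: float
    n_used: int


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> Optional[str]:
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if x.min() == x.max():
            continue
        if x[y == 1].size and x[y == 0].size:
            if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
                return col
    return None


def fit_logistic(design: pd.DataFrame, labels: Sequence[int]) -> LogisticModelResult:
    """Maximum-likelihood logistic fit of low-survival (1) vs high (0).

    ``design`` holds the (already dummy-coded) predictors without a
    constant; an intercept is added.  Rows whose label is ``EXCLUDED`` are
    dropped.  Raises on perfect separation (naming the offending predictor
    when identifiable) and on a singular design.
    """
    y = np.asarray(list(labels), dtype=int)
    X = design.reset_index(drop=True)
    keep = y != EXCLUDED
    y = y[keep]
    X = X.loc[keep].astype(float)
    if y.size == 0 or set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1 after exclusion")
    if len(set(np.unique(y))) < 2:
        raise ModelError("labels are all one class")

    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ModelError("singular design matrix (collinear predictors)")
    sep = _check_separation(X, y)
    if sep is not None:
        raise ModelError(f"perfect separation on predictor {sep!r}")

    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparation and friends
        raise ModelError(f"logistic fit failed: {exc}") from exc

    llf = float(fit.llf)
    null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
    lln = float(null.llf)
    n = y.size
    cox_snell = 1.0 - np.exp(2.0 * (lln - llf) / n)
    denom = 1.0 - np.exp(2.0 * lln / n)
    nagelkerke = float(cox_snell / denom) if denom > 0 else 0.0

    pred = (fit.predict(Xc) >= 0.5).astype(int)
    coef = pd.DataFrame(
        {
            "coef": fit.params.drop("const"),
            "se": fit.bse.drop("const"),
            "or": np.exp(fit.params.drop("const")),
            "p": fit.pvalues.drop("const"),
        }
    )
    return LogisticModelResult(
        coef=coef,
        intercept=float(fit.params["const"]),
        model_chi2=float(2.0 * (llf - lln)),
        df_model=int(X.shape[1]),
        nagelkerke_r2=nagelkerke,
        minus2loglik=float(-2.0 * llf),
        predicted_pct=float(100.0 * (pred == y).mean()),
        n_used=int(n),
    )


#: (column, kind, reference-or-None); indicator kind codes 1 for the named level.
_SOCIODEMOGRAPHIC = [
    ("age", "continuous", None),
    ("marital", "indicator", "single"),
    ("household", "dummies", "other_province"),
    ("education", "dummies", "senior_high_plus"),
    ("econ", "indicator", "poor"),
    ("employment", "indicator", "unemployed"),
]
_DRUG_HISTORY = [
    ("age_first_use", "continuous", None),
    ("first_detox", "indicator", "no"),
    ("drug_type", "dummies", "mixed"),
    ("prior_arrest", "indicator", "yes"),
]
_CLINICAL = [
    ("physical", "indicator", "unhealthy"),
    ("hads_total", "continuous", None),
]
_GROUP = [("group", "indicator", "control")]


@dataclass(frozen=True)
class ModelBatch:
    """Strictly nested predictor blocks entered model by model."""

    blocks: tuple = field(
        default_factory=lambda: (
            tuple(_SOCIODEMOGRAPHIC),
            tuple(_SOCIODEMOGRAPHIC + _DRUG_HISTORY),
            tuple(_SOCIODEMOGRAPHIC + _DRUG_HISTORY + _CLINICAL),
            tuple(_SOCIODEMOGRAPHIC + _DRUG_HISTORY + _CLINICAL + _GROUP),
        )
    )

    def __post_init__(self):
        for small, big in zip(self.blocks, self.blocks[1:]):
            if not set(small).issubset(set(big)):
                raise ValidationError("predictor blocks must be strictly nested")


def build_design(frame: pd.DataFrame, block) -> pd.DataFrame:
    """Dummy-code one predictor block against its stated reference levels."""
    cols = {}
    for name, kind, ref in block:
        if name not in frame.columns:
            raise ValidationError(f"cohort frame lacks column {name!r}")
        if kind == "continuous":
            cols[name] = frame[name].astype(float)
            continue
        values = frame[name].astype(str)
        if kind == "indicator":
            if ref not in set(values):
                raise ValidationError(f"reference/indicator level {ref!r} absent from {name!r}")
            cols[f"{name}[{ref}]"] = (values == ref).astype(float)
        else:  # dummies against a reference level
            levels = list(pd.unique(values))
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} absent from {name!r}")
            for lv in levels:
                if lv != ref:
                    cols[f"{name}[{lv}]"] = (values == lv).astype(float)
    return pd.DataFrame(cols, index=frame.index)


def run_batched_models(
    cohort_frame: pd.DataFrame,
    labels: Sequence[int],
    batch: ModelBatch = ModelBatch(),
) -> tuple:
    """Fit the nested models I..IV on the 27%-rule labels.

    Returns ``(results, deltas)`` where ``deltas[j] = (delta_chi2,
    delta_df)`` between model j+1 and model j.  Exclusions apply once, so
    all models share the same subject set.
    """
    labels = np.asarray(list(labels), dtype=int)
    if len(labels) != len(cohort_frame):
        raise ValidationError("labels and cohort frame length mismatch")
    results = []
    for block in batch.blocks:
        X = build_design(cohort_frame.reset_index(drop=True), block)
        results.append(fit_logistic(X, labels))
    deltas = [
        (b.model_chi2 - a.model_chi2, b.df_model - a.df_model)
        for a, b in zip(results, results[1:])
    ]
    return results, deltas


def table5_frame(results: Sequence[LogisticModelResult]) -> pd.DataFrame:
    """Stack model columns "OR (SE)" plus footer statistics."""
    names = [f"Model {'I' * (i + 1)}" if i < 3 else "Model IV" for i in range(len(results))]
    all_predictors = []
    for r in results:
        for p in r.coef.index:
            if p not in all_predictors:
                all_predictors.append(p)
    data = {}
    for name, r in zip(names, results):
        col = {}
        for p in all_predictors:
            if p in r.coef.index:
                col[p] = f"{r.coef.loc[p, 'or']:.3f} ({r.coef.loc[p, 'se']:.3f})"
            else:
                col[p] = ""
        col["Constant"] = f"{r.intercept:.3f}"
        col["Chi-square"] = f"{r.model_chi2:.3f}"
        col["Nag R-square"] = f"{r.nagelkerke_r2:.3f}"
        col["-2Log Lik"] = f"{r.minus2loglik:.3f}"
        col["Predicted %"] = f"{r.predicted_pct:.1f}"
        data[name] = col
    return pd.DataFrame(data)
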