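"""Baseline and outcome descriptive statistics.

Covers the cross-tabulations and summary comparisons the tracking study
reports: Pearson chi-square on group-by-outcome tables (no continuity
correction), relapse rates per arm, pooled-variance two-sample t from
printed group summaries, SOCRATES/HADS scale scoring, and Cronbach's
alpha for item-level internal consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .censoring import COMPLIANT, RELAPSE, ObservedOutcome, _round_half_up
from .errors import ValidationError

#: HADS anxiety subscale item positions (0-based); the remaining 7 assess depression.
HADS_ANXIETY_IDX = (0, 2, 4, 6, 8, 10, 12)
HADS_THRESHOLD = 8


@dataclass(frozen=True)
class GroupSummary:
    """Printed-style summary of one arm: mean(SD), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError(f"SD must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")


def chi_square(table) -> tuple:
    """Pearson chi-square on an r x c count table.

    Returns ``(statistic, df, p)``; uncorrected (no Yates), matching the
    study's printed statistics.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValidationError("contingency table needs non-negative counts with a positive total")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def relapse_rate_table(outcomes: Sequence[ObservedOutcome], groups: Sequence[str]) -> pd.DataFrame:
    """Relapse/compliance counts and rates per arm and overall, with chi-square.

    Rates are percentages rounded half-up to 0.1, as printed.
    """
    if len(outcomes) != len(groups):
        raise ValidationError("groups and outcomes length mismatch")
    if len(outcomes) == 0:
        raise ValidationError("no subjects")
    df = pd.DataFrame({"group": list(groups), "relapse": [o.status == RELAPSE for o in outcomes]})
    level_order = list(pd.unique(df["group"]))
    if any((df["group"] == g).sum() == 0 for g in level_order):
        raise ValidationError("empty group")

    rows = []

    def _row(label, sub):
        n = len(sub)
        rel = int(sub["relapse"].sum())
        comp = n - rel
        rows.append(
            {
                "arm": label,
                "compliance_n": comp,
                "compliance_pct": _round_half_up(100.0 * comp / n),
                "relapse_n": rel,
                "relapse_pct": _round_half_up(100.0 * rel / n),
            }
        )

    _row("overall", df)
    for g in level_order:
        _row(str(g), df[df["group"] == g])
    table = pd.DataFrame(rows).set_index("arm")

    if len(level_order) >= 2:
        counts = [
            [int(r["compliance_n"]), int(r["relapse_n"])]
            for _, r in table.iloc[1:].iterrows()
        ]
        stat, dof, p = chi_square(counts)
        table.attrs["chi2"] = stat
        table.attrs["df"] = dof
        table.attrs["p"] = p
    return table


def pooled_t(a: GroupSummary, b: GroupSummary) -> tuple:
    """Two-sample t with pooled variance from group summaries.

    Returns ``(t, df)`` with ``df = n_a + n_b - 2``.  The pooled (equal
    variance) form is what reproduces the printed baseline statistics from
    printed summaries; Welch does not.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 <= 0:
        raise ValidationError("zero pooled variance")
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float(t), int(df)


def socrates_total(items: Sequence[int]) -> int:
    """Total SOCRATES motivation score: sum of 19 items scored 1-5."""
    items = list(items)
    if len(items) != 19:
        raise ValidationError(f"SOCRATES has 19 items, got {len(items)}")
    if any(not 1 <= int(x) <= 5 for x in items):
        raise ValidationError("SOCRATES items must lie in [1, 5]")
    return int(sum(int(x) for x in items))


class HadsScores(NamedTuple):
    anxiety: int
    depression: int
    total: int
    anxiety_positive: bool
    depression_positive: bool


def hads_scores(items: Sequence[int], reverse_mask: Sequence[int] = ()) -> HadsScores:
    """Score the 14-item HADS into anxiety/depression subscales and flags.

    ``reverse_mask`` lists 0-based indices of reverse-keyed items, mapped
    ``x -> 3 - x`` before summing.  A subscale score at or above 8 flags
    positive symptoms.
    """
    items = [int(x) for x in items]
    if len(items) != 14:
        raise ValidationError(f"HADS has 14 items, got {len(items)}")
    if any(not 0 <= x <= 3 for x in items):
        raise ValidationError("HADS items must lie in [0, 3]")
    rev = set(int(i) for i in reverse_mask)
    if any(not 0 <= i < 14 for i in rev):
        raise ValidationError("reverse_mask indices must lie in [0, 13]")
    scored = [3 - x if i in rev else x for i, x in enumerate(items)]
    anx = sum(scored[i] for i in HADS_ANXIETY_IDX)
    dep = sum(scored[i] for i in range(14) if i not in HADS_ANXIETY_IDX)
    return HadsScores(anx, dep, anx + dep, anx >= HADS_THRESHOLD, dep >= HADS_THRESHOLD)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("need an n x k matrix with k >= 2")
    n, k = X.shape
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValidationError("zero total-score variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def baseline_table(cohort_frame: pd.DataFrame) -> pd.DataFrame:
    """Prevalence-style baseline comparison of the two arms.

    For each categorical covariate: per-arm percentages and the Pearson
    chi-square across levels; for each continuous one: mean(SD) per arm and
    the pooled t.  One row per level (categorical) or variable (continuous).
    """
    arms = list(pd.unique(cohort_frame["group"]))
    if len(arms) != 2:
        raise ValidationError("baseline table expects exactly two arms")
    a, b = arms
    fa = cohort_frame[cohort_frame["group"] == a]
    fb = cohort_frame[cohort_frame["group"] == b]

    categorical = [
        "marital", "household", "education", "econ", "employment",
        "first_detox", "drug_type", "prior_arrest", "physical",
    ]
    continuous = ["age", "age_first_use", "hads_total", "socrates_total"]

    rows = []
    for var in continuous:
        if var not in cohort_frame.columns:
            continue
        sa = GroupSummary(fa[var].mean(), fa[var].std(ddof=1), len(fa))
        sb = GroupSummary(fb[var].mean(), fb[var].std(ddof=1), len(fb))
        t, dof = pooled_t(sa, sb)
        rows.append(
            {
                "variable": var, "level": "",
                "overall": f"{cohort_frame[var].mean():.2f}({cohort_frame[var].std(ddof=1):.3f})",
                a: f"{sa.mean:.2f}({sa.sd:.3f})", b: f"{sb.mean:.2f}({sb.sd:.3f})",
                "statistic": t, "kind": "t", "df": dof,
            }
        )
    for var in categorical:
        if var not in cohort_frame.columns:
            continue
        levels = list(pd.unique(cohort_frame[var]))
        counts = [[int((fx[var] == lv).sum()) for fx in (fa, fb)] for lv in levels]
        try:
            stat, dof, _ = chi_square(counts)
        except ValidationError:
            stat, dof = float("nan"), 0
        for lv in levels:
            rows.append(
                {
                    "variable": var, "level": str(lv),
                    "overall": f"{100.0 * (cohort_frame[var] == lv).mean():.1f}%",
                    a: f"{100.0 * (fa[var] == lv).mean():.1f}%",
                    b: f"{100.0 * (fb[var] == lv).mean():.1f}%",
                    "statistic": stat, "kind": "chi2", "df": dof,
                }
            )
    return pd.DataFrame(rows)
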