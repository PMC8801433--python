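"""Multiple imputation of per-subject survival times from the fitted posterior.

Each imputation reuses the sampler's latent event times at m retained
iterations chosen at equal spacing across the retained chain (the Gibbs
augmentation analogue of drawing the imputation model's parameters from
their posterior), so every imputed time automatically respects the
subject's censoring region: inside (L-1, R] for an observed relapse window,
beyond the censor day for a compliant subject.  The m draws are combined by
their arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelError
from .survival import PosteriorDraws


@dataclass(frozen=True)
class ImputationSet:
    """m imputed survival times for one subject and their mean."""

    subject_id: int
    draws: tuple
    combined: float

    @property
    def m(self) -> int:
        return len(self.draws)


def impute_times(
    draws: PosteriorDraws,
    outcomes=None,
    m: int = 10,
    seed: Optional[int] = None,
) -> list[ImputationSet]:
    """Impute each subject's survival time m times from the retained chain.

    Iterations are picked at equal spacing over the flattened retained
    draws (deterministic; ``seed`` is accepted for interface symmetry but
    selection involves no randomness).  ``outcomes`` may be passed to carry
    subject ids; otherwise subjects are numbered 1..n.
    """
    total = draws.n_chains * draws.n_kept
    if m < 1:
        raise ModelError("m must be >= 1")
    if m > total:
        raise ModelError(f"m={m} exceeds the {total} retained iterations")
    flat = draws.latent.reshape(total, draws.n_subjects)
    picks = np.floor(np.linspace(0, total - 1, num=m)).astype(int) if m > 1 else np.array([total // 2])

    if outcomes is not None:
        ids = [o.subject_id for o in outcomes]
        if len(ids) != draws.n_subjects:
            raise ModelError("outcomes and draws subject-count mismatch")
    else:
        ids = list(range(1, draws.n_subjects + 1))

    lo, hi = draws.region_lo, draws.region_hi
    sets = []
    for j, sid in enumerate(ids):
        vals = flat[picks, j]
        if not (np.all(vals > lo[j]) and np.all(vals <= hi[j])):
            raise ModelError(f"imputed time escaped the censoring region for subject {sid}")
        sets.append(ImputationSet(subject_id=int(sid), draws=tuple(float(v) for v in vals), combined=float(vals.mean())))
    return sets


def imputation_report(sets: Sequence[ImputationSet]) -> dict:
    """Descriptive summary of the combined survival times."""
    if not sets:
        raise ModelError("no imputation sets")
    combined = np.array([s.combined for s in sets])
    degenerate = combined.size < 3 or np.ptp(combined) == 0.0
    return {
        "n": int(combined.size),
        "min": float(combined.min()),
        "max": float(combined.max()),
        "mean": float(combined.mean()),
        "skewness": 0.0 if degenerate else float(stats.skew(combined)),
    }


def imputations_to_frame(sets: Sequence[ImputationSet]) -> pd.DataFrame:
    m = sets[0].m if sets else 0
    data = {"id": [s.subject_id for s in sets]}
    for j in range(m):
        data[f"draw_{j + 1}"] = [s.draws[j] for s in sets]
    data["combined"] = [s.combined for s in sets]
    return pd.DataFrame(data)
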