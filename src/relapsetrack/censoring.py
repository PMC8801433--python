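"""Follow-up schedule and censoring of true relapse times.

The study design revisits each subject at fixed days after release
(default 7, 30, 90, 180, 270, 360) plus a final assessment at study end.
A relapse is only ever located to the window between two consecutive
attended visits, so observed outcomes are interval censored; subjects with
no relapse by study end are right censored at ``study_end - release_day``.

Day-counting convention: the release day is day 0 and the first possible
relapse day is day 1.  Windows are stored with the *printed* integer bounds
(L = previous visit + 1, R = detection visit), e.g. a relapse found at the
180-day visit after a clean 90-day visit is recorded as "91 < <180".  The
continuous event-time region equivalent to that record, used for truncated
sampling and round-trip checks, is ``(L - 1, R]``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError

RELAPSE = "relapse"
COMPLIANT = "compliant"

DEFAULT_VISIT_DAYS = (7, 30, 90, 180, 270, 360)


@dataclass(frozen=True)
class FollowUpSchedule:
    """Ordered post-release visit days."""

    visit_days: tuple = DEFAULT_VISIT_DAYS

    def __post_init__(self):
        days = tuple(int(d) for d in self.visit_days)
        if not days or days[0] < 1:
            raise ConfigError("first visit day must be >= 1")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("visit days must be strictly increasing")
        object.__setattr__(self, "visit_days", days)

    def window_labels(self) -> list[str]:
        """Printed labels of the scheduled windows, plus the post-schedule one."""
        labels = []
        prev = 0
        for v in self.visit_days:
            lo = prev + 1
            labels.append(f"{lo} day{'s' if lo > 1 else ''} < <{v} days")
            prev = v
        labels.append(f">{prev} days")
        return labels


@dataclass(frozen=True)
class ObservedOutcome:
    """Observed relapse status of one subject.

    For relapse: event day lies in {L, ..., R} (continuous region (L-1, R]).
    For compliance: survival exceeds ``censor_day``.
    """

    subject_id: int
    status: str
    lower: Optional[int] = None
    upper: Optional[int] = None
    censor_day: Optional[int] = None

    def __post_init__(self):
        if self.status == RELAPSE:
            if self.lower is None or self.upper is None or not 1 <= self.lower <= self.upper:
                raise ValidationError(f"subject {self.subject_id}: bad relapse window ({self.lower}, {self.upper})")
        elif self.status == COMPLIANT:
            if self.censor_day is None or self.censor_day < 1:
                raise ValidationError(f"subject {self.subject_id}: bad censor day {self.censor_day}")
        else:
            raise ValidationError(f"subject {self.subject_id}: unknown status {self.status!r}")

    @property
    def region(self) -> tuple:
        """Continuous event-time region: (L-1, R] for relapse, (censor, inf) for compliant."""
        if self.status == RELAPSE:
            return (float(self.lower - 1), float(self.upper))
        return (float(self.censor_day), float("inf"))


def censor_observation(
    true_day: Optional[float],
    release_day: int,
    schedule: FollowUpSchedule,
    study_end_day: int,
) -> ObservedOutcome:
    """Map one subject's true relapse day to the observed record.

    ``true_day`` is days since release (None means no relapse ever).
    Relapse is detected at the first attended visit on or after the true
    day; the final study-end assessment counts as an attended visit, so a
    relapse after the last scheduled visit but before study end falls in
    the open window above that visit.
    """
    if release_day >= study_end_day:
        raise ValidationError(f"release day {release_day} not before study end {study_end_day}")
    censor = int(study_end_day - release_day)
    if true_day is not None and true_day <= 0:
        raise ValidationError(f"true relapse day must be positive, got {true_day}")

    if true_day is None or true_day > censor:
        return ObservedOutcome(subject_id=-1, status=COMPLIANT, censor_day=censor)

    attended = [v for v in schedule.visit_days if v <= censor]
    i = bisect.bisect_left(attended, true_day)
    prev = attended[i - 1] if i > 0 else 0
    detect = attended[i] if i < len(attended) else censor
    return ObservedOutcome(subject_id=-1, status=RELAPSE, lower=prev + 1, upper=detect)


def censor_cohort(cohort, true_days, schedule: FollowUpSchedule, study_end_day: int) -> list[ObservedOutcome]:
    """Apply :func:`censor_observation` across a cohort (keeps subject ids)."""
    outcomes = []
    for subject, t in zip(cohort, true_days):
        o = censor_observation(float(t) if t is not None else None, subject.release_day, schedule, study_end_day)
        outcomes.append(
            ObservedOutcome(
                subject_id=subject.id,
                status=o.status,
                lower=o.lower,
                upper=o.upper,
                censor_day=o.censor_day,
            )
        )
    return outcomes


def _round_half_up(x: float, ndigits: int = 1) -> float:
    import math

    f = 10**ndigits
    return math.floor(x * f + 0.5) / f


def tabulate_relapse_windows(
    outcomes: Sequence[ObservedOutcome],
    groups: Optional[Sequence[str]] = None,
    schedule: FollowUpSchedule = FollowUpSchedule(),
) -> pd.DataFrame:
    """Count relapses per schedule window, overall and per group.

    Windows are keyed by their lower printed bound; any relapse window whose
    lower bound exceeds the last scheduled visit is pooled into the
    post-schedule row.  Percentages (rounded half-up to 0.1) are of each
    column's relapsed subjects and sum to 100 +- 0.1.
    """
    lowers = [0] + [v for v in schedule.visit_days]
    starts = [lo + 1 for lo in lowers[:-1]]  # printed L of each scheduled window
    labels = schedule.window_labels()
    last_visit = schedule.visit_days[-1]

    def window_index(o: ObservedOutcome) -> int:
        if o.lower > last_visit:
            return len(labels) - 1
        if o.lower not in starts:
            raise ValidationError(
                f"subject {o.subject_id}: window lower bound {o.lower} does not match the schedule"
            )
        return starts.index(o.lower)

    cols = {"overall": [0] * len(labels)}
    group_of = {}
    if groups is not None:
        if len(groups) != len(outcomes):
            raise ValidationError("groups and outcomes length mismatch")
        group_of = dict(zip((o.subject_id for o in outcomes), groups))
        for g in pd.unique(pd.Series(list(groups))):
            cols[str(g)] = [0] * len(labels)

    for o in outcomes:
        if o.status != RELAPSE:
            continue
        idx = window_index(o)
        cols["overall"][idx] += 1
        if groups is not None:
            cols[str(group_of[o.subject_id])][idx] += 1

    table = pd.DataFrame(cols, index=labels)
    for c in list(table.columns):
        total = table[c].sum()
        table[f"{c}_pct"] = [
            _round_half_up(100.0 * v / total) if total else 0.0 for v in table[c]
        ]
    # Drop the post-schedule row when empty, matching the printed table shape.
    if table.loc[labels[-1], [c for c in cols]].sum() == 0:
        table = table.drop(index=labels[-1])
    return table


def outcomes_to_frame(outcomes: Sequence[ObservedOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [o.subject_id for o in outcomes],
            "status": [o.status for o in outcomes],
            "L": [o.lower if o.lower is not None else "" for o in outcomes],
            "R": [o.upper if o.upper is not None else "" for o in outcomes],
            "censor_day": [o.censor_day if o.censor_day is not None else "" for o in outcomes],
        }
    )


def frame_to_outcomes(frame: pd.DataFrame) -> list[ObservedOutcome]:
    out = []
    for _, r in frame.iterrows():
        status = str(r["status"])
        if status == RELAPSE:
            out.append(ObservedOutcome(int(r["id"]), RELAPSE, lower=int(r["L"]), upper=int(r["R"])))
        else:
            out.append(ObservedOutcome(int(r["id"]), COMPLIANT, censor_day=int(float(r["censor_day"]))))
    return out
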