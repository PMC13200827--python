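"""IHC scoring, WHO grade assignment and progression-free-survival comparison.

Grading of well-differentiated neuroendocrine tumors uses two proliferation
readouts: the mitotic count per 10 high-power fields and the Ki-67 labeling
index.  Each maps to a grade — G1 (<2 mitoses and Ki-67 < 3%), G2 (2-20
mitoses or Ki-67 3-20%), G3 (>20 mitoses or Ki-67 > 20%) — and on
discordance the higher grade wins.  IHC staining is scored semi-
quantitatively as intensity (0-3) times a positive-area score (1-4), with
any total > 0 counted as positive expression.

Survival comparison uses the Kaplan-Meier product-limit estimator and the
log-rank test (lifelines under the hood).  The two-group hazard ratio is
reported as the ratio of observed/expected event counts from the log-rank
table; no proportional-hazards model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Upper edges of the positive-area bins mapping percent positive cells to
#: a 1-4 proportion score (<=25 -> 1, <=50 -> 2, <=75 -> 3, else 4).
PROPORTION_BINS: tuple[float, float, float] = (25.0, 50.0, 75.0)


@dataclass(frozen=True)
class IhcScore:
    intensity: int
    proportion_percent: float
    proportion_score: int
    total: int

    @property
    def positive(self) -> bool:
        return self.total > 0


def proportion_score(percent: float, bins: Sequence[float] = PROPORTION_BINS) -> int:
    """Positive-area score 1-4 from the percentage of positive cells."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    for score, edge in enumerate(bins, start=1):
        if percent <= edge:
            return score
    return len(bins) + 1


def ihc_total(intensity: int, percent: float, bins: Sequence[float] = PROPORTION_BINS) -> IhcScore:
    """Total IHC score = staining intensity x positive-area score."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be 0-3, got {intensity}")
    p = proportion_score(percent, bins)
    return IhcScore(intensity=intensity, proportion_percent=percent, proportion_score=p, total=intensity * p)


def _grade_by_mitoses(mitoses: float) -> int:
    if mitoses < 0:
        raise ValueError(f"mitotic count must be non-negative, got {mitoses}")
    if mitoses < 2:
        return 1
    return 2 if mitoses <= 20 else 3


def _grade_by_ki67(ki67: float) -> int:
    if not 0.0 <= ki67 <= 100.0:
        raise ValueError(f"Ki-67 must be in [0, 100], got {ki67}")
    if ki67 < 3:
        return 1
    return 2 if ki67 <= 20 else 3


def who_grade(mitoses: float, ki67: float) -> str:
    """WHO grade from mitotic count (/10 HPF) and Ki-67 index (%).

    Each readout is graded separately and the higher grade is assigned, so
    e.g. 1 mitosis with Ki-67 25% is G3 despite the G1 mitotic count.
    """
    return f"G{max(_grade_by_mitoses(mitoses), _grade_by_ki67(ki67))}"


@dataclass(frozen=True)
class SurvivalRecord:
    """One follow-up record: time in months, event=1 for progression/death."""

    time: float
    event: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as (time, survival) steps.

    Returns one row per distinct event time with the survival probability
    just after that time; censored times only shrink later risk sets.
    """
    if not records:
        raise ValueError("need at least one record")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit([r.time for r in records], [r.event for r in records])
    sf = kmf.survival_function_
    event_times = sorted({r.time for r in records if r.event == 1})
    rows = [(t, float(sf.loc[t].iloc[0])) for t in event_times]
    return pd.DataFrame(rows, columns=["time", "survival"])


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, int, float]:
    """Log-rank comparison of the grouped records: (chi-square, df, p).

    Ties are handled with the standard hypergeometric variance at tied event
    times; df = number of groups - 1.
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not any(r.event == 1 for r in records):
        raise ValueError("log-rank test undefined with no events")
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(
        np.array([r.time for r in records]),
        np.array([r.group for r in records]),
        np.array([r.event for r in records]),
    )
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


def observed_expected(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Observed and log-rank-expected event counts per group.

    At each distinct event time the expected events for a group are
    ``d_t · n_gt / n_t`` (total deaths times the group's share of the risk
    set), summed over event times.
    """
    groups = sorted({r.group for r in records})
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    labels = np.array([r.group for r in records])
    observed = {g: int(events[labels == g].sum()) for g in groups}
    expected = {g: 0.0 for g in groups}
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        for g in groups:
            n_gt = int((at_risk & (labels == g)).sum())
            expected[g] += d_t * n_gt / n_t
    return pd.DataFrame(
        {"group": groups, "observed": [observed[g] for g in groups], "expected": [expected[g] for g in groups]}
    )


def hazard_ratio(records: Sequence[SurvivalRecord]) -> float:
    """Two-group hazard ratio as (O1/E1) / (O2/E2), groups in sorted order."""
    oe = observed_expected(records)
    if len(oe) != 2:
        raise ValueError("hazard ratio defined for exactly two groups")
    o1, e1 = oe.loc[0, "observed"], oe.loc[0, "expected"]
    o2, e2 = oe.loc[1, "observed"], oe.loc[1, "expected"]
    if o2 == 0 or e1 == 0:
        return float("inf") if o1 > 0 else float("nan")
    return float((o1 / e1) / (o2 / e2))
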