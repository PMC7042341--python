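"""Survival association of T-cell response levels: median split, Kaplan-Meier
curves and the Mantel-Cox log-rank test.

Patients are split into HIGH and LOW responders at the cohort median of a
response level (e.g. CD8 IFN-gamma net response after PD-1 blockade) and the
two overall-survival curves compared.  Estimation and testing are delegated
to lifelines; this module owns the grouping conventions and edge-case
behavior.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger("apofrag")

HIGH = "HIGH"
LOW = "LOW"


@dataclasses.dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    months: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.months <= 0:
            raise ValueError("months must be > 0")
        if self.group not in (HIGH, LOW):
            raise ValueError(f"group must be {HIGH} or {LOW}")


def median_split(values: Mapping[str, float]) -> dict[str, str]:
    """Assign HIGH to patients strictly above the cohort median, LOW otherwise.

    Ties at the median go LOW (strict exceedance); with an even cohort the
    median is the midpoint of the two central order statistics.  An all-equal
    cohort yields all LOW with a warning.
    """
    if len(values) < 2:
        raise ValueError("median split needs at least 2 patients")
    arr = np.asarray(list(values.values()), dtype=float)
    med = float(np.median(arr))
    groups = {pid: (HIGH if v > med else LOW) for pid, v in values.items()}
    if all(g == LOW for g in groups.values()):
        logger.warning("median_split: no value exceeds the median; all LOW")
    return groups


def km_curve(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate for one group.

    Returns (times, survival) step-function coordinates starting at
    (0, 1); censored times thin the risk set without producing drops.
    """
    if not records:
        raise ValueError("km_curve needs at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.months for r in records],
        event_observed=[r.event for r in records],
    )
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank(
    group_high: Sequence[SurvivalRecord],
    group_low: Sequence[SurvivalRecord],
) -> tuple[float, float]:
    """Mantel-Cox log-rank comparison of the two groups.

    Chi-square statistic (1 df) with two-sided p.  Zero hypergeometric
    variance (e.g. no events, or a single shared event time exhausting the
    risk set) yields the undefined-test sentinel (nan, nan).
    """
    if not group_high or not group_low:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in [*group_high, *group_low]):
        return math.nan, math.nan
    result = logrank_test(
        durations_A=[r.months for r in group_high],
        durations_B=[r.months for r in group_low],
        event_observed_A=[r.event for r in group_high],
        event_observed_B=[r.event for r in group_low],
    )
    stat = float(result.test_statistic)
    p = float(result.p_value)
    if not math.isfinite(stat):
        return math.nan, math.nan
    return stat, p


def survival_report(records: Sequence[SurvivalRecord]) -> dict:
    """Per-group KM coordinates plus the log-rank statistic, as a JSON-ready dict."""
    high = [r for r in records if r.group == HIGH]
    low = [r for r in records if r.group == LOW]
    stat, p = logrank(high, low)
    out: dict = {
        "n_high": len(high),
        "n_low": len(low),
        "chi_square": stat,
        "p_value": p,
        "curves": {},
    }
    for name, grp in ((HIGH, high), (LOW, low)):
        t, s = km_curve(grp)
        out["curves"][name] = {"months": t.tolist(), "survival": s.tolist()}
    return out
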