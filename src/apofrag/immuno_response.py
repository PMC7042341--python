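"""Cytokine-response statistics for pool-stimulated T-cell assays.

Flow-cytometry readouts arrive as percentages of a T-cell subset (CD4 or CD8)
producing IFN-gamma, TNF-alpha or both, with and without peptide-pool
stimulation, per patient and treatment stage (T0 before therapy, T1 after
chemotherapy, T2 after PD-1 blockade; HD = healthy donor, NAIVE = untreated
early-stage patient).  This module computes background-subtracted net
responses, responder calls, cohort magnitude (mean net response per pool),
responder fold changes between stages, PD-1-within-specific kinetics, and the
supporting two-sample and one-way ANOVA comparisons.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("apofrag")

TIMEPOINTS = ("T0", "T1", "T2", "HD", "NAIVE")
SUBSETS = ("CD4", "CD8")
CYTOKINES = ("IFNG", "TNFA", "DUAL")

#: sentinels for responder fold change edge cases
FC_INFINITE = math.inf
FC_UNDEFINED = math.nan


@dataclasses.dataclass(frozen=True)
class PoolResponse:
    patient_id: str
    timepoint: str
    subset: str
    cytokine: str
    pool: int
    pct_stim: float
    pct_ns: float
    pct_pd1_within_specific: float | None = None

    def __post_init__(self) -> None:
        for name in ("pct_stim", "pct_ns"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclasses.dataclass(frozen=True)
class ResponderCall:
    patient_id: str
    timepoint: str
    subset: str
    cytokine: str
    pool: int
    net: float
    responder: bool


def net_response(pct_stim: float, pct_ns: float) -> float:
    """Background-subtracted response, floored at zero percentage points."""
    for name, v in (("pct_stim", pct_stim), ("pct_ns", pct_ns)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return max(pct_stim - pct_ns, 0.0)


def call_responder(net: float, floor: float = 0.01) -> bool:
    """A measurement is a response when net >= floor (closed threshold)."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    return net >= floor


def call_table(responses: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Add net and responder columns to a response table."""
    out = responses.copy()
    out["net"] = np.maximum(out["pct_stim"] - out["pct_ns"], 0.0)
    out["responder"] = out["net"] >= floor
    return out


def magnitude(responses: pd.DataFrame) -> pd.DataFrame:
    """Cohort magnitude: mean net response across patients per
    (pool, subset, cytokine, timepoint); missing patients are excluded and the
    contributing count reported."""
    df = responses.copy()
    if "net" not in df.columns:
        df["net"] = np.maximum(df["pct_stim"] - df["pct_ns"], 0.0)
    grouped = (
        df.dropna(subset=["net"])
        .groupby(["pool", "subset", "cytokine", "timepoint"], sort=True)["net"]
        .agg(magnitude="mean", n="count")
        .reset_index()
    )
    empty = grouped[grouped["n"] == 0]
    if not empty.empty:
        logger.warning("magnitude: %d empty groups dropped", len(empty))
    return grouped[grouped["n"] > 0]


def responder_fold_change(pct_responders_t2: float, pct_responders_t1: float) -> float:
    """Ratio of responder percentages between two treatment stages
    (post-PD-1-blockade over post-chemotherapy).

    Edge cases return sentinels rather than raising: x/0 -> +inf, 0/0 -> NaN.
    """
    for v in (pct_responders_t2, pct_responders_t1):
        if not 0 <= v <= 100:
            raise ValueError(f"responder percentage {v} outside [0, 100]")
    if pct_responders_t1 == 0:
        return FC_UNDEFINED if pct_responders_t2 == 0 else FC_INFINITE
    return pct_responders_t2 / pct_responders_t1


def responder_fold_change_table(
    responses: pd.DataFrame,
    floor: float = 0.01,
    stage_after: str = "T2",
    stage_before: str = "T1",
) -> pd.DataFrame:
    """Per (pool, subset, cytokine): % of patients responding at each stage
    and the fold change between them."""
    calls = call_table(responses, floor)
    rows = []
    for (pool, subset, cytokine), grp in calls.groupby(["pool", "subset", "cytokine"]):
        pct = {}
        for stage in (stage_before, stage_after):
            sub = grp[grp["timepoint"] == stage]
            if sub.empty:
                pct[stage] = None
            else:
                by_patient = sub.groupby("patient_id")["responder"].any()
                pct[stage] = 100.0 * by_patient.mean()
        if pct[stage_before] is None or pct[stage_after] is None:
            continue
        rows.append(
            {
                "pool": pool,
                "subset": subset,
                "cytokine": cytokine,
                f"pct_responders_{stage_before}": pct[stage_before],
                f"pct_responders_{stage_after}": pct[stage_after],
                "fold_change": responder_fold_change(pct[stage_after], pct[stage_before]),
            }
        )
    return pd.DataFrame(rows)


def pd1_kinetics(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint mean PD-1% within specific cells, paired with the mean
    net specific response — the series behind the observation that PD-1 rises
    after chemotherapy and collapses under PD-1 blockade while the specific
    response keeps growing."""
    if "pct_pd1" not in responses.columns or responses["pct_pd1"].dropna().empty:
        logger.warning("pd1_kinetics: no PD-1 measurements present")
        return pd.DataFrame(columns=["timepoint", "mean_pd1", "mean_net", "n"])
    df = responses.dropna(subset=["pct_pd1"]).copy()
    if "net" not in df.columns:
        df["net"] = np.maximum(df["pct_stim"] - df["pct_ns"], 0.0)
    out = (
        df.groupby("timepoint", sort=True)
        .agg(mean_pd1=("pct_pd1", "mean"), mean_net=("net", "mean"), n=("pct_pd1", "count"))
        .reset_index()
    )
    return out


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t test (pooled variance by default, Welch by flag).

    Degenerate zero-variance inputs are resolved by convention: equal means
    give (0, 1); distinct means give a signed infinite statistic with p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def anova_oneway(*samples: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p; a thin supporting comparison."""
    f, p = stats.f_oneway(*[np.asarray(s, dtype=float) for s in samples])
    return float(f), float(p)
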