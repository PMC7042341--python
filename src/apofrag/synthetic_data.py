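"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without any instrument or patient data:
a random proteome in which a chosen fraction of proteins is cleaved after an
aspartate into a low-molecular-weight fragment (a minimal stand-in for
caspase activity during apoptosis), forward/reverse SILAC quant tables with
lognormal ratio noise and one-channel "singleton" detections, MS-evidence
peptides inside each fragment, and a patient cohort with stage-dependent
cytokine responses (T0 < T1 < T2), rise-then-fall PD-1 kinetics, and
exponential survival coupled to the CD8 IFN-gamma response level.

One global seed fans out into independent per-stage streams, so any stage can
be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from pyteomics import mass as pmass

from .formats_io import ProteinRecord, RunConfig, default_gel_boundaries
from .pool_matrix import PoolDesign
from .silac_quant import (
    DOWNREGULATED,
    FRAGMENTED,
    UNCHANGED,
    UPREGULATED,
    QuantEntry,
    assign_gel_section,
)

logger = logging.getLogger("apofrag")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WATER_AVG = pmass.calculate_mass(formula="H2O", average=True)

#: average residue masses (Da), monomer minus water
RESIDUE_AVG = {
    aa: pmass.calculate_mass(sequence=aa, average=True) - WATER_AVG
    for aa in AMINO_ACIDS
}

_STAGE_STREAMS = {
    "proteome": 1,
    "fragmentation": 2,
    "silac": 3,
    "cohort": 4,
    "evidence": 5,
}

MIN_FRAGMENT_RESIDUES = 25  # room for an evidence peptide plus flanks


class CohortConfig(BaseModel):
    """Patient-cohort generator settings.

    ``stage_means`` are the true mean net cytokine responses (% of subset) for
    pools containing an immunogenic tile at each treatment stage; the ordering
    T0 < T1 < T2 encodes the boost from chemotherapy and then PD-1 blockade.
    ``pd1_means`` rise after chemotherapy and fall back under blockade.
    Survival is exponential with the hazard divided by ``hazard_ratio`` for
    patients whose CD8 IFN-gamma net response at T2 is above the cohort
    median; ``hazard_baseline`` (events/month) sets the low-responder arm and
    ``censoring_rate`` is the censoring-to-baseline hazard ratio.
    """

    n_patients: int = 14
    stage_means: dict[str, float] = Field(
        default_factory=lambda: {"T0": 0.02, "T1": 0.15, "T2": 0.40}
    )
    pd1_means: dict[str, float] = Field(
        default_factory=lambda: {"T0": 20.0, "T1": 45.0, "T2": 18.0}
    )
    pd1_sd: float = 5.0
    response_noise_sigma: float = 0.35
    ns_mean: float = 0.02
    ns_sd: float = 0.005
    hazard_baseline: float = 1.0 / 30.0
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.2


class SimulationConfig(BaseModel):
    """Settings for the full synthetic study."""

    rng_seed: int = 0
    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (100, 900)
    fraction_fragmented: float = 0.08
    fraction_up: float = 0.3
    fraction_down: float = 0.5
    ratio_noise_sigma: float = 0.25
    singleton_probability: float = 0.3
    ratio_cap: float = 100.0
    cohort: CohortConfig = Field(default_factory=CohortConfig)


@dataclasses.dataclass(frozen=True)
class FragmentTruth:
    """Generative ground truth for one protein."""

    accession: str
    label: str
    fragment_start: int | None = None
    fragment_end: int | None = None
    fragment_mass_kda: float | None = None


def _stream(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, _STAGE_STREAMS[stage]])


def average_mass_kda(sequence: str) -> float:
    """Average molecular mass of a polypeptide (kDa): residues plus water."""
    return (sum(RESIDUE_AVG[aa] for aa in sequence) + WATER_AVG) / 1000.0


def generate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """Random proteome: uniform residue composition, lengths uniform in range."""
    rng = _stream(config, "proteome")
    lo, hi = config.protein_length_range
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        records.append(ProteinRecord(f"SYN{i + 1:04d}", f"syng{i + 1}", seq))
    return records


def simulate_fragmentation(
    proteins: list[ProteinRecord],
    config: SimulationConfig,
    boundaries: list[float] | None = None,
) -> dict[str, FragmentTruth]:
    """Draw each protein's true class; give FRAGMENTED proteins a cleavage.

    Cleavage falls C-terminal to a randomly chosen aspartate (uniform site if
    the protein has none); the fragment is the shorter side.  Sites are
    resampled until the fragment's gel section sits at least one below the
    intact protein's and the fragment can hold an evidence peptide.
    """
    rng = _stream(config, "fragmentation")
    bounds = boundaries or default_gel_boundaries()
    f_frag = config.fraction_fragmented
    f_up = config.fraction_up
    f_down = config.fraction_down
    truth: dict[str, FragmentTruth] = {}
    for prot in proteins:
        u = rng.random()
        if u < f_frag:
            label = FRAGMENTED
        elif u < f_frag + f_up:
            label = UPREGULATED
        elif u < f_frag + f_up + f_down:
            label = DOWNREGULATED
        else:
            label = UNCHANGED
        if label != FRAGMENTED:
            truth[prot.accession] = FragmentTruth(prot.accession, label)
            continue
        seq = prot.sequence
        length = len(seq)
        intact_section = assign_gel_section(average_mass_kda(seq), bounds)[0]
        d_sites = [i + 1 for i, aa in enumerate(seq) if aa == "D"]
        chosen = None
        for _ in range(200):
            if d_sites:
                site = int(rng.choice(d_sites))  # cleave after this residue
            else:
                site = int(rng.integers(1, length))
            left, right = (1, site), (site + 1, length)
            start, end = left if site <= length - site else right
            if end - start + 1 < MIN_FRAGMENT_RESIDUES:
                continue
            frag_mass = average_mass_kda(seq[start - 1 : end])
            if assign_gel_section(frag_mass, bounds)[0] <= intact_section - 1:
                chosen = (start, end, frag_mass)
                break
        if chosen is None:
            # No admissible aspartate site; fall back to a mid-sequence cut.
            site = length // 2
            start, end = 1, site
            chosen = (start, end, average_mass_kda(seq[:site]))
        truth[prot.accession] = FragmentTruth(
            prot.accession, FRAGMENTED, chosen[0], chosen[1], chosen[2]
        )
    return truth


def simulate_silac_tables(
    proteins: list[ProteinRecord],
    truth: dict[str, FragmentTruth],
    config: SimulationConfig,
    boundaries: list[float] | None = None,
) -> tuple[list[QuantEntry], list[QuantEntry]]:
    """Forward and reverse quant tables consistent with the ground truth.

    True apoptotic/live ratios are drawn per class (UP > 2, DOWN < 0.5,
    UNCHANGED = 1, FRAGMENTED >= 2 or a one-channel singleton) and multiplied
    by independent lognormal noise per orientation.  The apparent-weight range
    comes from the fragment's gel section for FRAGMENTED proteins and the
    intact protein's otherwise.
    """
    rng = _stream(config, "silac")
    bounds = boundaries or default_gel_boundaries()
    sigma = config.ratio_noise_sigma
    cap = config.ratio_cap
    tables: dict[str, list[QuantEntry]] = {"forward": [], "reverse": []}
    for prot in proteins:
        t = truth[prot.accession]
        intact_mass = average_mass_kda(prot.sequence)
        if t.label == FRAGMENTED:
            section, lo, hi = assign_gel_section(t.fragment_mass_kda, bounds)
        else:
            section, lo, hi = assign_gel_section(intact_mass, bounds)
        if t.label == UPREGULATED:
            true_ratio = float(np.exp(rng.uniform(np.log(2.2), np.log(20.0))))
        elif t.label == DOWNREGULATED:
            true_ratio = float(np.exp(rng.uniform(np.log(0.05), np.log(0.45))))
        elif t.label == UNCHANGED:
            true_ratio = 1.0
        else:
            true_ratio = float(np.exp(rng.uniform(np.log(2.0), np.log(30.0))))
        n_pep = 1 + int(rng.poisson(1.5))
        for orientation in ("forward", "reverse"):
            singleton = (
                t.label == FRAGMENTED
                and rng.random() < config.singleton_probability
            )
            if singleton:
                ratio, capped = cap, True
            else:
                noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
                ratio = true_ratio * noise
                capped = ratio >= cap
                ratio = min(ratio, cap)
            tables[orientation].append(
                QuantEntry(
                    accession=prot.accession,
                    gene=prot.gene,
                    n_unique_peptides=n_pep,
                    ratio_apoptotic_live=ratio,
                    capped=capped,
                    mwcal=intact_mass,
                    mwexp_lo=lo,
                    mwexp_hi=hi,
                    orientation=orientation,
                    gel_section=section,
                )
            )
    return tables["forward"], tables["reverse"]


def evidence_from_truth(
    truth: dict[str, FragmentTruth], config: SimulationConfig
) -> pd.DataFrame:
    """One MS-evidence peptide (8-15 residues) inside each true fragment."""
    rng = _stream(config, "evidence")
    rows = []
    for t in truth.values():
        if t.label != FRAGMENTED:
            continue
        flen = t.fragment_end - t.fragment_start + 1
        pep_len = int(rng.integers(8, min(16, flen + 1)))
        start = t.fragment_start + int(rng.integers(0, flen - pep_len + 1))
        rows.append(
            {"accession": t.accession, "start": start, "end": start + pep_len - 1}
        )
    return pd.DataFrame(rows, columns=["accession", "start", "end"])


def simulate_cohort(
    design: PoolDesign,
    positive_tiles: set[str],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Response and survival tables for a synthetic patient cohort.

    Each patient x timepoint x subset x cytokine x pool row carries a
    background (unstimulated) percentage near ``ns_mean`` and a stimulated
    percentage that adds a stage-dependent effect only for pools containing a
    truth-positive (immunogenic) tile.  PD-1-within-specific percentages
    follow the configured rise-then-fall means.  Survival couples to the CD8
    IFN-gamma net response at T2 through a median split of the true hazard.
    """
    rng = _stream(config, "cohort")
    cc = config.cohort
    positive_pools = sorted(
        {p for t in positive_tiles for p in design.assignment[t]}
    )
    patients = [f"PT{i + 1:02d}" for i in range(cc.n_patients)]
    rows = []
    for pid in patients:
        for tp, stage_mean in cc.stage_means.items():
            for subset in ("CD8", "CD4"):
                for cytokine in ("IFNG", "TNFA", "DUAL"):
                    for pool in range(1, design.n_pools + 1):
                        ns = max(0.0, rng.normal(cc.ns_mean, cc.ns_sd))
                        effect = 0.0
                        if pool in positive_pools:
                            effect = stage_mean * float(
                                np.exp(rng.normal(0.0, cc.response_noise_sigma))
                            )
                        stim = min(100.0, ns + effect)
                        pd1 = np.nan
                        if pool in positive_pools:
                            pd1 = float(
                                np.clip(rng.normal(cc.pd1_means[tp], cc.pd1_sd), 0, 100)
                            )
                        rows.append(
                            (pid, tp, subset, cytokine, pool, stim, ns, pd1)
                        )
    responses = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "subset", "cytokine", "pool",
            "pct_stim", "pct_ns", "pct_pd1",
        ],
    )
    # survival: hazard lowered for above-median CD8 IFN-gamma responders at T2
    t2 = responses.query(
        "timepoint == 'T2' and subset == 'CD8' and cytokine == 'IFNG'"
    ).copy()
    t2["net"] = np.maximum(t2["pct_stim"] - t2["pct_ns"], 0.0)
    level = t2.groupby("patient_id")["net"].mean()
    median = level.median()
    surv_rows = []
    for pid in patients:
        high = level[pid] > median
        hazard = cc.hazard_baseline / (cc.hazard_ratio if high else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = (
            rng.exponential(1.0 / (cc.censoring_rate * cc.hazard_baseline))
            if cc.censoring_rate > 0
            else np.inf
        )
        months = max(min(t_event, t_cens), 1e-3)
        surv_rows.append(
            {
                "patient_id": pid,
                "months": months,
                "event": bool(t_event <= t_cens),
                "value": level[pid],
            }
        )
    survival = pd.DataFrame(surv_rows)
    logger.info(
        "simulate_cohort: %d patients, %d positive pools", cc.n_patients,
        len(positive_pools),
    )
    return responses, survival


def simulate_survival_arms(
    n: int,
    hazard_ratio: float,
    rng: np.random.Generator,
    hazard_baseline: float = 1.0 / 30.0,
    censoring_rate: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two equal survival arms (HIGH with hazard/hazard_ratio) for power studies."""
    half = n // 2
    frames = []
    for group, hr in (("HIGH", hazard_ratio), ("LOW", 1.0)):
        t_event = rng.exponential(hr / hazard_baseline, size=half)
        if censoring_rate > 0:
            t_cens = rng.exponential(
                1.0 / (censoring_rate * hazard_baseline), size=half
            )
        else:
            t_cens = np.full(half, np.inf)
        months = np.maximum(np.minimum(t_event, t_cens), 1e-3)
        frames.append(
            pd.DataFrame(
                {"months": months, "event": t_event <= t_cens, "group": group}
            )
        )
    return frames[0], frames[1]
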