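"""SILAC quantitation core: isotope-pair matching, apoptotic/live ratios,
gel-section molecular-weight assignment and abundance/fragment classification.

The workflow this models compares apoptotic (cisplatin-treated) against live
tumor cells grown in heavy vs light SILAC media.  Peptides appear in spectra
as heavy/light peak pairs separated by the labeled-residue mass shift; the
channel ratio measures relative abundance between the two cell states.  A
protein identified in a gel section whose apparent molecular weight (MWexp)
lies below its sequence-derived weight (MWcal) is called a fragment —
here the caspase-cleavage products that act as non-mutated neoantigen
candidates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

from .formats_io import RunConfig

#: isotopic mass differences, Da
DELTA_13C = 1.003355
DELTA_15N = 0.997035

#: nominal heavy-light shifts by labeled residue content (Lys count, Arg count)
SHIFT_CLASSES: dict[str, tuple[int, int]] = {
    "K1": (1, 0),
    "R1": (0, 1),
    "K2": (2, 0),
    "K1R1": (1, 1),
    "R2": (0, 2),
}

FRAGMENTED = "FRAGMENTED"
UPREGULATED = "UPREGULATED"
DOWNREGULATED = "DOWNREGULATED"
UNCHANGED = "UNCHANGED"


@dataclasses.dataclass(frozen=True)
class Peak:
    """A centroided, singly-charged MALDI peak."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be > 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclasses.dataclass(frozen=True)
class SilacPair:
    light_mz: float
    heavy_mz: float
    shift_class: str
    light_intensity: float
    heavy_intensity: float

    def __post_init__(self) -> None:
        if self.heavy_mz <= self.light_mz:
            raise ValueError("heavy_mz must exceed light_mz")


@dataclasses.dataclass(frozen=True)
class QuantEntry:
    """One protein's SILAC quantitation row.

    ``ratio_apoptotic_live`` is always oriented apoptotic over live regardless
    of which channel was heavy; ``capped`` marks one-channel detections whose
    live partner was undetected.  Masses are kDa.
    """

    accession: str
    gene: str
    n_unique_peptides: int
    ratio_apoptotic_live: float
    capped: bool
    mwcal: float
    mwexp_lo: float
    mwexp_hi: float
    orientation: str
    gel_section: int | None = None

    def __post_init__(self) -> None:
        if self.ratio_apoptotic_live <= 0:
            raise ValueError(f"{self.accession}: ratio must be > 0")
        if not self.mwexp_lo < self.mwexp_hi:
            raise ValueError(f"{self.accession}: need mwexp_lo < mwexp_hi")
        if self.n_unique_peptides < 1:
            raise ValueError(f"{self.accession}: need >= 1 unique peptide")


@dataclasses.dataclass(frozen=True)
class AbundanceCall:
    accession: str
    label: str
    orientation: str
    rule: str = ""


def label_mass_shift(n_lys: int, n_arg: int) -> float:
    """Heavy-minus-light mass shift (Da) for a peptide with the given labeled
    residue counts (13C6-Lys: six 13C; 13C6-15N4-Arg: six 13C plus four 15N).

    Additive in the residue counts; printed shifts for the five tryptic
    classes round to 6.02, 10.01, 12.04, 16.03 and 20.02 Da.
    """
    if n_lys < 0 or n_arg < 0:
        raise ValueError("residue counts must be non-negative")
    if n_lys == 0 and n_arg == 0:
        raise ValueError("unlabeled peptide has no SILAC pair")
    lys_shift = 6 * DELTA_13C
    arg_shift = 6 * DELTA_13C + 4 * DELTA_15N
    return n_lys * lys_shift + n_arg * arg_shift


def nominal_shifts() -> dict[str, float]:
    """Exact shift (Da) for each of the five tryptic shift classes."""
    return {
        name: label_mass_shift(k, r) for name, (k, r) in SHIFT_CLASSES.items()
    }


def match_pairs(peaks: Sequence[Peak], tolerance: float) -> list[SilacPair]:
    """Pair peaks whose m/z difference matches a nominal SILAC shift.

    Greedy: candidate pairs are ranked by |difference - nominal| (ties broken
    by lower light m/z, then smaller shift) and accepted while neither peak is
    already used.  A heuristic, but verified against brute-force optimal
    matching on small lists.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    shifts = nominal_shifts()
    ordered = sorted(peaks, key=lambda p: p.mz)
    candidates: list[tuple[float, float, float, int, int, str]] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            diff = ordered[j].mz - ordered[i].mz
            best = None
            for name, nominal in shifts.items():
                err = abs(diff - nominal)
                if err <= tolerance and (best is None or err < best[0]):
                    best = (err, nominal, name)
            if best is not None:
                candidates.append(
                    (best[0], ordered[i].mz, best[1], i, j, best[2])
                )
    used: set[int] = set()
    pairs: list[SilacPair] = []
    for err, light_mz, _nom, i, j, name in sorted(candidates):
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(
            SilacPair(
                light_mz=ordered[i].mz,
                heavy_mz=ordered[j].mz,
                shift_class=name,
                light_intensity=ordered[i].intensity,
                heavy_intensity=ordered[j].intensity,
            )
        )
    pairs.sort(key=lambda p: p.light_mz)
    return pairs


def pair_ratio(
    heavy_intensity: float,
    light_intensity: float,
    orientation: str,
    cap: float = 100.0,
) -> tuple[float, bool]:
    """Apoptotic/live intensity ratio for one SILAC pair.

    In the forward orientation apoptotic cells are heavy-labeled, so the ratio
    is heavy/light; the reverse (label-swap) replicate inverts this.  A missing
    live-channel partner yields the cap with the capped flag set; finite
    ratios above the cap are truncated.
    """
    if heavy_intensity < 0 or light_intensity < 0:
        raise ValueError("intensities must be >= 0")
    if heavy_intensity == 0 and light_intensity == 0:
        raise ValueError("both channels empty: nothing to quantify")
    if orientation == "forward":
        apoptotic, live = heavy_intensity, light_intensity
    elif orientation == "reverse":
        apoptotic, live = light_intensity, heavy_intensity
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if live == 0:
        return cap, True
    ratio = apoptotic / live
    if ratio > cap:
        return cap, True
    return ratio, False


def assign_gel_section(
    mass_kda: float, boundaries: Sequence[float]
) -> tuple[int, float, float]:
    """Locate a mass in the gel-section ladder.

    Sections are half-open [lo, hi) kDa, numbered 1 (lowest mass) upward.
    Masses below the first breakpoint fall into the lowest band (they run off
    the gel bottom); masses at or above the last breakpoint are out of range.
    """
    if any(x >= y for x, y in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")
    if mass_kda >= boundaries[-1]:
        raise ValueError(
            f"mass {mass_kda:.3f} kDa above top boundary {boundaries[-1]:.3f}"
        )
    if mass_kda < boundaries[0]:
        return 1, boundaries[0], boundaries[1]
    for idx in range(len(boundaries) - 1):
        if boundaries[idx] <= mass_kda < boundaries[idx + 1]:
            return idx + 1, boundaries[idx], boundaries[idx + 1]
    raise AssertionError("unreachable")


def classify_protein(entry: QuantEntry, config: RunConfig | None = None) -> AbundanceCall:
    """Classify one quant entry as FRAGMENTED / UP / DOWN / UNCHANGED.

    The molecular-weight rule dominates: an entry whose entire apparent-weight
    range lies below MWcal, and which is enriched in the apoptotic channel
    (ratio > 1, or one-channel capped), is a fragment whatever its fold
    change.  Otherwise the symmetric 2-fold window applies.
    """
    cfg = config or RunConfig()
    ratio = entry.ratio_apoptotic_live
    apoptotic_enriched = entry.capped or ratio > 1.0
    if entry.mwexp_hi < entry.mwcal and apoptotic_enriched:
        label, rule = FRAGMENTED, "mwexp_hi < mwcal and apoptotic-enriched"
    elif ratio > cfg.ratio_up_threshold:
        label, rule = UPREGULATED, f"ratio > {cfg.ratio_up_threshold}"
    elif ratio < cfg.ratio_down_threshold:
        label, rule = DOWNREGULATED, f"ratio < {cfg.ratio_down_threshold}"
    else:
        label, rule = UNCHANGED, "ratio within no-change window"
    return AbundanceCall(
        accession=entry.accession,
        label=label,
        orientation=entry.orientation,
        rule=rule,
    )


def classify_table(
    entries: Iterable[QuantEntry], config: RunConfig | None = None
) -> list[AbundanceCall]:
    return [classify_protein(e, config) for e in entries]


def replicate_concordance(
    forward_calls: Sequence[AbundanceCall],
    reverse_calls: Sequence[AbundanceCall],
) -> set[str]:
    """Accessions called FRAGMENTED in both label orientations.

    Matching is by accession (gene names are not always transcribed
    consistently between replicates).
    """
    for calls, name in ((forward_calls, "forward"), (reverse_calls, "reverse")):
        accs = [c.accession for c in calls]
        if len(accs) != len(set(accs)):
            raise ValueError(f"duplicate accession in {name} calls")
    frag_f = {c.accession for c in forward_calls if c.label == FRAGMENTED}
    frag_r = {c.accession for c in reverse_calls if c.label == FRAGMENTED}
    return frag_f & frag_r
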