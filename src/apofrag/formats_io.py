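"""Readers, writers and run configuration for the pipeline's external formats.

All on-disk coordinates are 1-based inclusive; conversions happen only here.
Quant tables carry the calibrated molecular weight (MWcal) in daltons on disk
(as printed by proteomics software, possibly with thousands separators) and in
kilodaltons in memory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger("apofrag")

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: heavy/light nominal mass shifts (Da) for tryptic peptides by labeled
#: residue content: K = 13C6-Lys, R = 13C6-15N4-Arg.
QUANT_COLUMNS = [
    "accession",
    "gene",
    "peptides",
    "ratio",
    "mwcal_da",
    "mwexp_lo_kda",
    "mwexp_hi_kda",
]


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line/row."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its database accession.

    The sequence is stored uppercase over the 20-letter amino-acid alphabet.
    """

    accession: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def default_gel_boundaries() -> list[float]:
    """17 log-spaced breakpoints from 5 to 250 kDa delimiting 16 gel sections."""
    return [float(x) for x in np.geomspace(5.0, 250.0, 17)]


class RunConfig(BaseModel):
    """Thresholds and design parameters for a pipeline run.

    ``ratio_up_threshold`` / ``ratio_down_threshold`` are apoptotic/live
    fold-change cut-offs for calling a protein over- or under-abundant;
    ``ratio_cap`` is the value reported for one-channel detections (the live
    partner undetected).  The gel boundaries delimit the 16 SDS-PAGE sections
    (5-250 kDa) used to assign an apparent molecular-weight range.
    """

    ratio_up_threshold: float = 2.0
    ratio_down_threshold: float = 0.5
    ratio_cap: float = 100.0
    gel_section_boundaries: list[float] = Field(
        default_factory=default_gel_boundaries
    )
    flank_residues: int = 20
    tile_length: int = 20
    tile_overlap: int = 12
    n_pools: int = 12
    pair_match_tolerance: float = 0.05
    responder_floor: float = 0.01
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not (0 < self.ratio_down_threshold < 1 < self.ratio_up_threshold):
            raise ValueError(
                "need 0 < ratio_down_threshold < 1 < ratio_up_threshold"
            )
        if self.tile_overlap >= self.tile_length:
            raise ValueError("tile_overlap must be < tile_length")
        b = self.gel_section_boundaries
        if any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("gel_section_boundaries must be strictly increasing")
        if self.n_pools < 3:
            raise ValueError("n_pools must be >= 3")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a YAML file; keyword overrides win over file keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA; sequences are uppercased.

    The first whitespace-separated token of the header is the accession, the
    second (if any) the gene name.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        accession = parts[0]
        gene = parts[1] if len(parts) > 1 else ""
        seq = str(rec.seq).upper()
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        try:
            records.append(ProteinRecord(accession, gene, seq))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.accession} {rec.gene}".rstrip()
            fh.write(f"{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Quant tables


def _parse_number(raw: str, *, row: int, column: str) -> float:
    """Parse a decimal that may carry thousands separators ('51,854')."""
    text = str(raw).strip().replace(",", "")
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"row {row}: non-numeric value {raw!r} in column {column!r}"
        ) from None


def read_quant_table(path: str | Path, orientation: str, *, ratio_cap: float = 100.0):
    """Read a SILAC quant TSV into a list of QuantEntry.

    The on-disk MWcal is in daltons and converted to kDa; ratios exactly equal
    to the cap are flagged as one-channel (capped) detections.  ``orientation``
    records which channel (heavy or light) held the apoptotic cells.
    """
    from .silac_quant import QuantEntry  # avoid import cycle

    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        ratio = _parse_number(row.ratio, row=i, column="ratio")
        mwcal_kda = _parse_number(row.mwcal_da, row=i, column="mwcal_da") / 1000.0
        entries.append(
            QuantEntry(
                accession=str(row.accession),
                gene="" if pd.isna(row.gene) else str(row.gene),
                n_unique_peptides=int(_parse_number(row.peptides, row=i, column="peptides")),
                ratio_apoptotic_live=ratio,
                capped=ratio >= ratio_cap,
                mwcal=mwcal_kda,
                mwexp_lo=_parse_number(row.mwexp_lo_kda, row=i, column="mwexp_lo_kda"),
                mwexp_hi=_parse_number(row.mwexp_hi_kda, row=i, column="mwexp_hi_kda"),
                orientation=orientation,
            )
        )
    logger.info(
        "read_quant_table: %d %s-orientation entries from %s",
        len(entries), orientation, path,
    )
    return entries


def write_quant_table(entries: Sequence, path: str | Path) -> None:
    """Write QuantEntries to TSV (MWcal back in Da), sorted by accession."""
    rows = [
        {
            "accession": e.accession,
            "gene": e.gene,
            "peptides": e.n_unique_peptides,
            "ratio": e.ratio_apoptotic_live,
            "mwcal_da": e.mwcal * 1000.0,
            "mwexp_lo_kda": e.mwexp_lo,
            "mwexp_hi_kda": e.mwexp_hi,
        }
        for e in sorted(entries, key=lambda e: e.accession)
    ]
    pd.DataFrame(rows, columns=QUANT_COLUMNS).to_csv(path, sep="\t", index=False)


def packaged_quant_table(orientation: str):
    """The curated fragmented-protein quant table shipped with the package.

    Sixteen forward-orientation and eleven reverse-orientation entries from
    CDDP-treated NSCLC cells, transcribed as printed (thousands separators and
    all), serving as a fixture and regression anchor for the classifier.
    """
    name = {"forward": "nsclc_cddp_forward.tsv", "reverse": "nsclc_cddp_reverse.tsv"}[
        orientation
    ]
    path = Path(__file__).parent / "data" / name
    return read_quant_table(path, orientation)


# ---------------------------------------------------------------------------
# Peak lists, evidence, tiles, generic tables


def read_peak_list(path: str | Path):
    """Read a centroided peak list TSV (columns mz, intensity)."""
    from .silac_quant import Peak

    df = pd.read_csv(path, sep="\t")
    for col in ("mz", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [Peak(mz=float(r.mz), intensity=float(r.intensity)) for r in df.itertuples()]


def read_evidence_table(path: str | Path):
    """Read MS-evidence peptides (accession, start, end; 1-based inclusive)."""
    from .epitope_design import EvidencePeptide

    df = pd.read_csv(path, sep="\t")
    return [
        EvidencePeptide(accession=str(r.accession), start=int(r.start), end=int(r.end))
        for r in df.itertuples()
    ]


def write_tiles(tiles: Sequence, path: str | Path) -> None:
    """Write peptide tiles to TSV sorted by (accession, start)."""
    rows = [
        {
            "tile_id": t.tile_id,
            "accession": t.accession,
            "start": t.start,
            "end": t.end,
            "sequence": t.sequence,
        }
        for t in sorted(tiles, key=lambda t: (t.accession, t.start))
    ]
    pd.DataFrame(rows, columns=["tile_id", "accession", "start", "end", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_tiles(path: str | Path):
    from .epitope_design import PeptideTile

    df = pd.read_csv(path, sep="\t")
    return [
        PeptideTile(
            tile_id=str(r.tile_id),
            accession=str(r.accession),
            start=int(r.start),
            end=int(r.end),
            sequence=str(r.sequence),
        )
        for r in df.itertuples()
    ]


def write_calls(calls: Sequence, path: str | Path) -> None:
    """Classification report as JSON: per-accession label, ratio, MW fields."""
    payload = [
        {
            "accession": c.accession,
            "orientation": c.orientation,
            "label": c.label,
            "rule": c.rule,
        }
        for c in sorted(calls, key=lambda c: (c.orientation, c.accession))
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_pool_design(design, path: str | Path) -> None:
    """PoolDesign JSON: pool membership lists plus per-tile pool pairs."""
    pools: dict[int, list[str]] = {i: [] for i in range(1, design.n_pools + 1)}
    for tile_id, (a, b) in sorted(design.assignment.items()):
        pools[a].append(tile_id)
        pools[b].append(tile_id)
    payload = {
        "n_pools": design.n_pools,
        "pools": {str(k): sorted(v) for k, v in pools.items()},
        "pairs": {t: sorted(p) for t, p in sorted(design.assignment.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_pool_design(path: str | Path):
    from .pool_matrix import PoolDesign

    with open(path) as fh:
        payload = json.load(fh)
    assignment = {
        t: frozenset(int(i) for i in pair) for t, pair in payload["pairs"].items()
    }
    return PoolDesign(n_pools=int(payload["n_pools"]), assignment=assignment)


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Per-patient per-pool cytokine response TSV.

    Columns: patient_id, timepoint, subset, cytokine, pool, pct_stim, pct_ns
    and optionally pct_pd1 (percentage of PD-1+ cells within the specific
    subset).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "timepoint", "subset", "cytokine", "pool", "pct_stim", "pct_ns"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Survival TSV: patient_id, months, event and either group or value."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if "group" not in df.columns and "value" not in df.columns:
        raise FormatError(f"{path}: need a 'group' or 'value' column")
    return df
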