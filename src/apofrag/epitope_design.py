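"""Overlapping-peptide library design around MS-identified fragment evidence.

For each fragmented protein, a target region of ``flank`` residues on either
side of each MS-identified peptide is selected (clipped to the protein), and
regions are tiled into fixed-length peptides with a fixed overlap — the
standard design for synthesis panels meant to cover all HLA restrictions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from .formats_io import ProteinRecord, RunConfig
from .silac_quant import FRAGMENTED, AbundanceCall

MIN_EVIDENCE_LENGTH = 6  # shortest identifiable MS peptide


@dataclasses.dataclass(frozen=True)
class EvidencePeptide:
    """An MS-identified peptide located in its parent protein (1-based incl.)."""

    accession: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.accession}: invalid evidence coordinates")
        if self.end - self.start + 1 < MIN_EVIDENCE_LENGTH:
            raise ValueError(
                f"{self.accession}: evidence peptide shorter than "
                f"{MIN_EVIDENCE_LENGTH} residues"
            )


@dataclasses.dataclass(frozen=True)
class TargetRegion:
    accession: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class PeptideTile:
    tile_id: str
    accession: str
    start: int
    end: int
    sequence: str
    short: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1


def extract_regions(
    protein: ProteinRecord,
    evidence: Sequence[EvidencePeptide],
    flank: int = 20,
) -> list[TargetRegion]:
    """Expand each evidence peptide by ``flank`` residues each side, clip to
    the protein, and merge overlapping or adjacent intervals."""
    length = len(protein)
    intervals: list[tuple[int, int]] = []
    for ev in evidence:
        if ev.accession != protein.accession:
            raise ValueError(
                f"evidence {ev.accession} does not belong to {protein.accession}"
            )
        if ev.end > length:
            raise ValueError(
                f"{ev.accession}: evidence ({ev.start},{ev.end}) outside protein "
                f"of length {length}"
            )
        intervals.append((max(1, ev.start - flank), min(length, ev.end + flank)))
    intervals.sort()
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [TargetRegion(protein.accession, lo, hi) for lo, hi in merged]


def tile_region(
    region: TargetRegion,
    protein: ProteinRecord,
    length: int = 20,
    overlap: int = 12,
) -> list[PeptideTile]:
    """Tile a region into ``length``-mers overlapping by ``overlap`` residues.

    Tiles step by length - overlap from the region start; if the last stepped
    tile stops short of the region end, one extra tile is right-anchored to
    end exactly there (keeping every tile full-length).  Regions shorter than
    one tile yield a single flagged short tile.
    """
    if overlap >= length:
        raise ValueError("overlap must be < tile length")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    seq = protein.sequence

    def make(start: int, end: int, short: bool = False) -> PeptideTile:
        return PeptideTile(
            tile_id=f"{region.accession}_{start}",
            accession=region.accession,
            start=start,
            end=end,
            sequence=seq[start - 1 : end],
            short=short,
        )

    span = len(region)
    if span < length:
        return [make(region.start, region.end, short=True)]
    step = length - overlap
    tiles = []
    start = region.start
    while start + length - 1 <= region.end:
        tiles.append(make(start, start + length - 1))
        start += step
    if tiles[-1].end < region.end:
        tiles.append(make(region.end - length + 1, region.end))
    return tiles


def design_library(
    proteins: Iterable[ProteinRecord],
    calls: Sequence[AbundanceCall],
    evidence: Sequence[EvidencePeptide],
    config: RunConfig | None = None,
    accessions: Sequence[str] | None = None,
) -> list[PeptideTile]:
    """Tile every selected protein's merged target regions.

    By default all FRAGMENTED accessions are selected; an explicit accession
    list overrides.  Tile ids are deterministic (accession_start) and output
    is sorted by (accession, start).
    """
    cfg = config or RunConfig()
    by_acc: Mapping[str, ProteinRecord] = {p.accession: p for p in proteins}
    if accessions is None:
        accessions = sorted({c.accession for c in calls if c.label == FRAGMENTED})
    ev_by_acc: dict[str, list[EvidencePeptide]] = {}
    for ev in evidence:
        ev_by_acc.setdefault(ev.accession, []).append(ev)
    tiles: list[PeptideTile] = []
    for acc in accessions:
        if acc not in by_acc:
            raise ValueError(f"selected accession {acc} has no sequence")
        if acc not in ev_by_acc:
            raise ValueError(f"selected accession {acc} has no MS evidence")
        protein = by_acc[acc]
        for region in extract_regions(protein, ev_by_acc[acc], cfg.flank_residues):
            tiles.extend(
                tile_region(region, protein, cfg.tile_length, cfg.tile_overlap)
            )
    tiles.sort(key=lambda t: (t.accession, t.start))
    return tiles
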