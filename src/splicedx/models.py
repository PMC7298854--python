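"""Gene and transcript models.

Coordinates are 1-based closed throughout (GTF convention). Introns are the
gaps between consecutive exons; the junction key of an intron is
(chrom, first intronic base, last intronic base), matching the coordinate
convention of STAR's splice-junction output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated mRNA isoform.

    Parameters
    ----------
    exons : ordered 1-based closed intervals, sorted by genomic coordinate.
    cds : optional CDS intervals; a transcript with CDS is coding and its
        exonic positions outside the CDS are UTR.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            object.__setattr__(self, "cds", tuple(sorted(tuple(c) for c in self.cds)))
        if not exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        for (s, e) in exons:
            if s > e:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon start {s} > end {e}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons near {e1}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons: (first, last) intronic base."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def coding(self) -> bool:
        return self.cds is not None and len(self.cds) > 0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start: lowest coordinate on +, highest on -."""
        return self.span[1] if self.strand == "-" else self.span[0]


@dataclass
class GeneModel:
    """A gene with its set of annotated transcripts T_g."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def add(self, t: TranscriptModel) -> None:
        if t.gene_id != self.gene_id:
            raise ValidationError(
                f"transcript {t.transcript_id} gene_id {t.gene_id} != {self.gene_id}")
        self.transcripts[t.transcript_id] = t

    @property
    def span(self) -> tuple[int, int]:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        spans = [t.span for t in self.transcripts.values()]
        return min(s for s, _ in spans), max(e for _, e in spans)

    @property
    def coding(self) -> bool:
        return any(t.coding for t in self.transcripts.values())

    def junctions(self) -> set[tuple[str, int, int]]:
        """All annotated junction keys across transcripts."""
        out: set[tuple[str, int, int]] = set()
        for t in self.transcripts.values():
            for s, e in t.introns:
                out.add((self.chrom, s, e))
        return out


def build_genes(transcripts: Iterable[TranscriptModel]) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    for t in transcripts:
        g = genes.setdefault(t.gene_id, GeneModel(t.gene_id, t.chrom, t.strand))
        g.add(t)
    return genes
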