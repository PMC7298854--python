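"""Transcript-deleterious variant (TDV) classification.

Positions are classified into six classes by where they fall relative to a
gene model:

    a  canonical splice donor/acceptor — first or last 2 bp of an intron
    b  first or last base pair of an exon
    c  any other intronic position (annotated with its signed intronic
       offset; within 50 bp of the nearest exon it is capturable by
       standard exome capture)
    d  coding-exonic, excluding the terminal exon bases
    e  UTR (5' or 3')
    f  promoter/regulatory (default window 1000 bp upstream of the most
       5' transcription start)

A position intronic in one transcript and exonic in another takes the most
severe class, ordered a > b > c > d > e > f. Intronic offsets follow the
HGVS convention: positive counting into the intron from the donor side,
negative from the acceptor side; a class-c variant is assigned the side
with the smaller absolute offset (ties resolve to the donor side).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io import VariantRecord
from .models import GeneModel, TranscriptModel, ValidationError

log = logging.getLogger(__name__)

PROMOTER_WINDOW = 1000
WES_CAPTURE_FLANK = 50
MAX_ALLELE_FREQUENCY = 0.001

SEVERITY = ("a", "b", "c", "d", "e", "f")
TIER1 = ("a", "b")
TIER2 = ("c", "d", "e", "f")


class HgvsParseError(ValueError):
    def __init__(self, hgvs: str, position: int, message: str):
        self.hgvs, self.position = hgvs, position
        super().__init__(f"{hgvs!r} at char {position}: {message}")


@dataclass(frozen=True)
class TDVClassification:
    variant: Optional[VariantRecord]
    tdv_class: str  # a/b/c/d/e/f or noncoding_other
    intron_offset: Optional[int] = None
    wes_capturable: Optional[bool] = None

    def __post_init__(self):
        if self.tdv_class == "a" and self.intron_offset is not None:
            assert abs(self.intron_offset) in (1, 2)
        if self.tdv_class == "c":
            assert self.intron_offset is None or abs(self.intron_offset) >= 3


def _intron_offset(pos: int, intron: tuple[int, int], strand: str) -> int:
    """Signed HGVS-style offset of an intronic position, smaller side wins.

    Donor side (+) is the low-coordinate end on + strand and the
    high-coordinate end on - strand; ties go to the donor side.
    """
    start, end = intron
    low = pos - start + 1          # distance from low-coordinate intron end
    high = end - pos + 1           # distance from high-coordinate intron end
    if strand == "-":
        donor_off, acceptor_off = high, low
    else:
        donor_off, acceptor_off = low, high
    if donor_off <= acceptor_off:
        return donor_off
    return -acceptor_off


def _classify_in_transcript(pos: int, t: TranscriptModel,
                            promoter_window: int) -> Optional[tuple[str, Optional[int]]]:
    """(class, intron_offset) for one transcript, or None if outside."""
    for (s, e) in t.exons:
        if s <= pos <= e:
            if pos == s or pos == e:
                return "b", None
            if t.cds:
                in_cds = any(cs <= pos <= ce for cs, ce in t.cds)
                return ("d", None) if in_cds else ("e", None)
            return "d", None
    for intron in t.introns:
        if intron[0] <= pos <= intron[1]:
            off = _intron_offset(pos, intron, t.strand)
            return ("a", off) if abs(off) <= 2 else ("c", off)
    span = t.span
    if t.strand == "-":
        if span[1] < pos <= span[1] + promoter_window:
            return "f", None
    else:
        if span[0] - promoter_window <= pos < span[0]:
            return "f", None
    return None


def classify_variant(v: VariantRecord, gene: GeneModel,
                     promoter_window: int = PROMOTER_WINDOW) -> TDVClassification:
    """Classify a variant position against every transcript of ``gene``,
    returning the most severe class (a > b > c > d > e > f)."""
    best: Optional[tuple[str, Optional[int]]] = None
    for t in gene.transcripts.values():
        res = _classify_in_transcript(v.pos, t, promoter_window)
        if res is None:
            continue
        if best is None or SEVERITY.index(res[0]) < SEVERITY.index(best[0]):
            best = res
        elif res[0] == best[0] == "c" and res[1] is not None and best[1] is not None:
            if abs(res[1]) < abs(best[1]):
                best = res
    if best is None:
        log.warning("%s outside gene %s span (+%d bp promoter): noncoding_other",
                    v.key(), gene.gene_id, promoter_window)
        return TDVClassification(v, "noncoding_other")
    cls, off = best
    wes = (abs(off) <= WES_CAPTURE_FLANK) if cls == "c" and off is not None else None
    return TDVClassification(v, cls, intron_offset=off, wes_capturable=wes)


_HGVS_OFFSET = re.compile(r"(\d+)([+-]\d+)")
_HGVS_CORE = re.compile(r"(?:[A-Z]{2}_[\w.]+\s*:\s*)?c\.(\S+)")


def classify_hgvs(hgvs_c: str) -> TDVClassification:
    """Classify an intronic-offset HGVS coding string (classes a and c only).

    Accepts forms like ``c.1033+1G>A``, ``c.286+335A>G``, ``c.739-18G>A``
    and offset ranges (``c.100+3_100+6del``); the smallest absolute offset
    decides the class. Non-intronic HGVS (no offset) is refused — those
    need the genomic-coordinate path.
    """
    m = _HGVS_CORE.search(hgvs_c)
    if m is None:
        raise HgvsParseError(hgvs_c, 0, "not a c. HGVS string")
    body = m.group(1)
    offsets = [int(off) for _, off in _HGVS_OFFSET.findall(body)]
    if not offsets:
        if re.match(r"^[\d_*-]+[A-Za-z>]", body) or re.match(r"^\d", body):
            raise ValidationError(
                f"{hgvs_c!r}: no intronic offset; classify by genomic coordinate instead")
        raise HgvsParseError(hgvs_c, m.start(1), "cannot parse position")
    off = min(offsets, key=abs)
    if abs(off) in (1, 2):
        return TDVClassification(None, "a", intron_offset=off)
    return TDVClassification(None, "c", intron_offset=off,
                             wes_capturable=abs(off) <= WES_CAPTURE_FLANK)


def frequency_filter(variants: Sequence[VariantRecord],
                     max_af: float = MAX_ALLELE_FREQUENCY) -> list[VariantRecord]:
    """Keep variants with allele frequency strictly below ``max_af``.

    Variants without AF annotation pass but are flagged ``AF_unknown``.
    """
    if not (0 < max_af <= 1):
        raise ValidationError("max_af must be in (0, 1]")
    out = []
    for v in variants:
        if v.allele_frequency is None:
            out.append(v.with_flag("AF_unknown"))
        elif v.allele_frequency < max_af:
            out.append(v)
    return out


def prioritize_candidates(classified: Iterable[TDVClassification],
                          has_alternate_candidate: bool = False,
                          ) -> list[TDVClassification]:
    """Apply the class-precedence rule within one family.

    Classes a/b are always considered. Classes c/d/e/f are considered only
    when the family has no alternate candidate variant and no class-a/b
    TDV.
    """
    classified = list(classified)
    tier1 = [c for c in classified if c.tdv_class in TIER1]
    if tier1:
        return tier1
    if has_alternate_candidate:
        return []
    return [c for c in classified if c.tdv_class in TIER2]
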