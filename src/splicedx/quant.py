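"""Normal-transcript abundance quantification (ω and ρ).

For each coding gene g with transcript set T_g the adjusted abundance is

    ω_g = Σ_{t ∈ T_g} w_t x_t

where x_t is the CPM of transcript t and w_t ∈ [0, 1] is the rate at which
the annotated, normally spliced form of t is expressed given the observed
splice-junction evidence. Low ω flags low-abundance outliers and splicing
outliers that escaped nonsense-mediated decay; the normal fraction
ρ_g = ω_g / Σ x_t isolates the splicing component.

w_t is computed from local junction evidence. For each annotated intron j
of t, the support fraction is

    s_j = a_j / (a_j + c_j + r_j)

with a_j the uniquely mapped reads spanning exactly j, c_j the reads of any
other junction sharing j's donor or acceptor coordinate, and r_j nonsplit
reads assigned to j's intron (intron-retention evidence; zero when no
per-intron coverage is supplied). With no local evidence at all s_j = 1:
genes expressed below junction-detection depth are not splicing outliers by
construction (their low abundance is captured by the α score instead).
w_t aggregates s_j across introns with a minimum by default (one fully
aberrant junction zeroes the transcript); a product rule is available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .io import AbundanceTable, JunctionTable
from .models import GeneModel, TranscriptModel, ValidationError

log = logging.getLogger(__name__)

#: junctions with fewer uniquely mapped supporting reads are discarded
MIN_JUNCTION_SUPPORT = 5


def compute_cpm(est_counts: np.ndarray) -> np.ndarray:
    """Counts-per-million; all-zero input maps to all-zero output."""
    counts = np.asarray(est_counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative estimated counts")
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    return counts / total * 1e6


def filter_junctions(table: JunctionTable,
                     min_support: int = MIN_JUNCTION_SUPPORT) -> JunctionTable:
    """Drop junctions with < ``min_support`` unique reads.

    Intron-coverage rows are evidence of a different kind and pass through
    untouched.
    """
    if min_support < 0:
        raise ValidationError("min_support must be >= 0")
    kept = table.data[table.data["unique_reads"] >= min_support].reset_index(drop=True)
    return JunctionTable(table.sample_id, kept, table.coverage)


class JunctionIndex:
    """O(1) lookup of junction evidence by coordinate.

    Built from a *filtered* junction table; indexes exact junctions, total
    reads per donor and per acceptor coordinate, and nonsplit intron
    coverage.
    """

    def __init__(self, table: JunctionTable):
        self.exact: dict[tuple[str, int, int], int] = {}
        self.donor_total: dict[tuple[str, int], int] = {}
        self.acceptor_total: dict[tuple[str, int], int] = {}
        self.nonsplit: dict[tuple[str, int, int], int] = {}
        df = table.data
        for chrom, s, e, reads in zip(df["chrom"], df["intron_start"],
                                      df["intron_end"], df["unique_reads"]):
            key = (chrom, int(s), int(e))
            self.exact[key] = self.exact.get(key, 0) + int(reads)
            dk, ak = (chrom, int(s)), (chrom, int(e))
            self.donor_total[dk] = self.donor_total.get(dk, 0) + int(reads)
            self.acceptor_total[ak] = self.acceptor_total.get(ak, 0) + int(reads)
        if table.coverage is not None:
            for chrom, s, e, n in zip(table.coverage["chrom"],
                                      table.coverage["intron_start"],
                                      table.coverage["intron_end"],
                                      table.coverage["nonsplit_reads"]):
                self.nonsplit[(chrom, int(s), int(e))] = int(n)

    def support(self, chrom: str, start: int, end: int) -> float:
        """Annotated-support fraction s_j for intron (start, end)."""
        key = (chrom, start, end)
        a = self.exact.get(key, 0)
        c = (self.donor_total.get((chrom, start), 0)
             + self.acceptor_total.get((chrom, end), 0) - 2 * a)
        r = self.nonsplit.get(key, 0)
        denom = a + c + r
        if denom == 0:
            return 1.0
        return a / denom


def junction_support(intron: tuple[int, int], transcript: TranscriptModel,
                     table: JunctionTable) -> float:
    """s_j for one intron of ``transcript`` against a filtered table."""
    if tuple(intron) not in transcript.introns:
        raise ValidationError(
            f"{intron} is not an intron of {transcript.transcript_id}")
    return JunctionIndex(table).support(transcript.chrom, intron[0], intron[1])


def transcript_normal_rate(t: TranscriptModel, index: JunctionIndex,
                           combine: str = "min") -> float:
    """w_t: aggregate of s_j over the transcript's introns; 1 if intronless."""
    introns = t.introns
    if not introns:
        return 1.0
    supports = [index.support(t.chrom, s, e) for s, e in introns]
    if combine == "min":
        return float(min(supports))
    if combine == "product":
        return float(np.prod(supports))
    raise ValidationError(f"unknown combine rule {combine!r}")


def omega(gene: GeneModel, w: Mapping[str, float], x: Mapping[str, float]) -> float:
    """ω_g = Σ_{t∈T_g} w_t x_t; transcripts absent from x count as 0."""
    total = 0.0
    for tid in gene.transcripts:
        if tid not in x:
            log.warning("gene %s: transcript %s missing from abundance; x=0",
                        gene.gene_id, tid)
        total += w.get(tid, 1.0) * x.get(tid, 0.0)
    return total


def rho(omega_g: float, total_cpm: float) -> tuple[float, bool]:
    """ρ_g = ω_g / Σ x_t; (0, not_expressed=True) when the gene has no signal."""
    if total_cpm == 0:
        return 0.0, True
    return omega_g / total_cpm, False


@dataclass
class OmegaProfile:
    """Per-sample ω/ρ per gene plus the per-transcript w_t, x_t behind them."""

    sample_id: str
    genes: pd.DataFrame        # index gene_id: omega, rho, total_cpm, n_transcripts, not_expressed
    transcripts: pd.DataFrame  # transcript_id, gene_id, w, x
    combine: str = "min"

    def omega_series(self) -> pd.Series:
        return self.genes["omega"]

    def rho_series(self) -> pd.Series:
        return self.genes["rho"]


def compute_omega_profile(gene_models: Mapping[str, GeneModel],
                          abundance: AbundanceTable,
                          junctions: JunctionTable,
                          min_support: int = MIN_JUNCTION_SUPPORT,
                          combine: str = "min",
                          coding_only: bool = True) -> OmegaProfile:
    """Full ω/ρ profile for one sample."""
    filtered = filter_junctions(junctions, min_support)
    index = JunctionIndex(filtered)
    cpm = abundance.cpm_series().to_dict()
    gene_rows = []
    tx_rows = []
    for gid, gene in gene_models.items():
        if coding_only and not gene.coding:
            continue
        w: dict[str, float] = {}
        total_cpm = 0.0
        for tid, t in gene.transcripts.items():
            w[tid] = transcript_normal_rate(t, index, combine)
            total_cpm += cpm.get(tid, 0.0)
            tx_rows.append((tid, gid, w[tid], cpm.get(tid, 0.0)))
        om = omega(gene, w, cpm)
        rh, not_expr = rho(om, total_cpm)
        gene_rows.append((gid, om, rh, total_cpm, len(gene.transcripts), not_expr))
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "omega", "rho", "total_cpm", "n_transcripts",
                 "not_expressed"]).set_index("gene_id").sort_index()
    tx = pd.DataFrame(tx_rows, columns=["transcript_id", "gene_id", "w", "x"])
    return OmegaProfile(abundance.sample_id, genes, tx, combine)


def write_omega_profile(profile: OmegaProfile, path) -> None:
    out = profile.genes.reset_index()
    out["flags"] = np.where(out["not_expressed"], "not_expressed", "")
    out[["gene_id", "omega", "rho", "n_transcripts", "flags"]].to_csv(
        path, sep="\t", index=False)
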