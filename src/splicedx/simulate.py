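"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure of a bulk RNA-seq
diagnostic cohort: per-gene lognormal expression shared by controls and
patients, Dirichlet isoform shares, Poisson-sampled junction read support
proportional to isoform CPM, and patient samples carrying one injected
transcript-level aberration — exon skipping (reads diverted to a novel
unannotated junction), transcript-abundance loss (NMD-like count
reduction), or intron retention (nonsplit intronic reads). ROH intervals
covering the causal gene emulate autozygosity mapping.

All randomness flows through one seeded generator; identical seeds give
byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import (AbundanceTable, JunctionTable, ROHSet, SampleMeta,
                 merge_intervals)
from .models import GeneModel, TranscriptModel, ValidationError, build_genes
from .quant import compute_cpm


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Expression is lognormal across genes (``log_mean``/``log_sd`` on the
    natural-log scale, CPM-like units) with mild per-sample lognormal
    noise; junction depth follows ``reads_per_cpm``.
    """

    seed: int
    n_genes: int = 500
    transcripts_per_gene: tuple[int, int] = (1, 4)
    exons_per_transcript: tuple[int, int] = (1, 8)
    n_controls: int = 30
    n_patients: int = 7
    tissue: str = "blood_lcl"
    log_mean: float = 5.0
    log_sd: float = 1.0
    sample_log_sd: float = 0.1
    reads_per_cpm: float = 0.2
    chrom: str = "1"
    chrom_length: int = 240_000_000

    def __post_init__(self):
        for name in ("n_genes", "n_controls", "n_patients"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


@dataclass(frozen=True)
class AberrationSpec:
    """Ground-truth handle: which gene is aberrant, how, and in whom."""

    gene_id: str
    kind: str  # exon_skip | low_abundance | intron_retention
    severity: float
    carrier_sample_id: str

    def __post_init__(self):
        if self.kind not in ("exon_skip", "low_abundance", "intron_retention"):
            raise ValidationError(f"unknown aberration kind {self.kind!r}")
        if self.severity <= 1:
            raise ValidationError("severity must be > 1")


# ---------------------------------------------------------------------------
# gene models

def generate_gene_models(config: SimulationConfig) -> dict[str, GeneModel]:
    """Non-overlapping genes on one chromosome, 1-4 transcripts each."""
    rng = np.random.default_rng([config.seed, 1])
    transcripts: list[TranscriptModel] = []
    cursor = 10_000
    lo_t, hi_t = config.transcripts_per_gene
    lo_e, hi_e = config.exons_per_transcript
    for gi in range(config.n_genes):
        gid = f"G{gi:05d}"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = rng.integers(80, 301, n_exons)
        intron_lens = rng.integers(200, 2001, max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))
            pos = exons[-1][1] + 1
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _trim_cds(exons)
        chains: list[tuple[tuple[int, int], ...]] = [tuple(exons)]
        n_tx = int(rng.integers(lo_t, hi_t + 1))
        attempts = 0
        while len(chains) < n_tx and attempts < 10:
            attempts += 1
            alt = _alternative_chain(exons, rng)
            if alt is not None and alt not in chains:
                chains.append(alt)
        for ti, chain in enumerate(chains):
            transcripts.append(TranscriptModel(
                transcript_id=f"{gid}.T{ti + 1}", gene_id=gid,
                chrom=config.chrom, strand=strand, exons=chain,
                cds=_trim_cds(list(chain))))
        cursor = exons[-1][1] + int(rng.integers(5_000, 20_001))
        if cursor > config.chrom_length:
            raise ValidationError(
                f"infeasible packing: {config.n_genes} genes exceed "
                f"chromosome length {config.chrom_length}")
    return build_genes(transcripts)


def _trim_cds(exons: list[tuple[int, int]]) -> Optional[tuple[tuple[int, int], ...]]:
    """CDS = exon chain with 10 bp UTR trimmed off each end when possible."""
    total = sum(e - s + 1 for s, e in exons)
    if total <= 30:
        return tuple(exons)
    cds = [list(e) for e in exons]
    cds[0][0] = min(cds[0][0] + 10, cds[0][1])
    cds[-1][1] = max(cds[-1][1] - 10, cds[-1][0])
    return tuple((s, e) for s, e in cds)


def _alternative_chain(exons: list[tuple[int, int]],
                       rng: np.random.Generator) -> Optional[tuple[tuple[int, int], ...]]:
    if len(exons) >= 3:
        k = int(rng.integers(1, len(exons) - 1))  # internal exon
        return tuple(e for i, e in enumerate(exons) if i != k)
    if len(exons) == 2:
        return (tuple(exons[0]),)
    return None


def write_gtf(genes: dict[str, GeneModel], path, source: str = "splicedx_sim") -> None:
    """Deterministic GTF serialization (byte-identical under a fixed seed)."""
    lines = []
    for gid in sorted(genes):
        g = genes[gid]
        gs, ge = g.span
        lines.append("\t".join([
            g.chrom, source, "gene", str(gs), str(ge), ".", g.strand, ".",
            f'gene_id "{gid}";']))
        for tid in sorted(g.transcripts):
            t = g.transcripts[tid]
            ts, te = t.span
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            lines.append("\t".join([
                g.chrom, source, "transcript", str(ts), str(te), ".",
                t.strand, ".", attrs]))
            for s, e in t.exons:
                lines.append("\t".join([
                    g.chrom, source, "exon", str(s), str(e), ".",
                    t.strand, ".", attrs]))
            for s, e in (t.cds or ()):
                lines.append("\t".join([
                    g.chrom, source, "CDS", str(s), str(e), ".",
                    t.strand, "0", attrs]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression and samples

def gene_expression_means(genes: dict[str, GeneModel],
                          config: SimulationConfig) -> pd.DataFrame:
    """Cohort-level per-transcript expected expression (CPM-like units).

    Gene means are lognormal. Isoform shares are Dirichlet with a dominant
    first (full-length) isoform — concentration (8, 1, 1, ...), giving the
    canonical isoform ~80% of the gene on average, as is typical of
    expressed genes. Drawn once per seed so controls and patients share
    the same expression landscape.
    """
    rng = np.random.default_rng([config.seed, 2])
    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        mean = float(rng.lognormal(config.log_mean, config.log_sd))
        tids = sorted(g.transcripts)
        conc = np.ones(len(tids))
        conc[0] = 8.0
        shares = rng.dirichlet(conc)
        for tid, share in zip(tids, shares):
            rows.append((tid, gid, mean * float(share)))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "mean_expr"])


def simulate_sample(genes: dict[str, GeneModel], means: pd.DataFrame,
                    config: SimulationConfig, rng: np.random.Generator,
                    sample_id: str) -> tuple[AbundanceTable, JunctionTable]:
    """One sample: noisy counts per transcript + Poisson junction reads."""
    noise = rng.lognormal(0.0, config.sample_log_sd, len(means))
    est = means["mean_expr"].to_numpy() * noise * 2.0  # arbitrary library scale
    ab = pd.DataFrame({
        "transcript_id": means["transcript_id"],
        "est_count": est,
    })
    ab["cpm"] = compute_cpm(est)
    abundance = AbundanceTable(sample_id, ab)
    cpm = dict(zip(ab["transcript_id"], ab["cpm"]))
    # junction support: Poisson around reads_per_cpm × (sum of CPM of
    # transcripts carrying that junction)
    jxn_cpm: dict[tuple[str, int, int, str], float] = {}
    for gid in sorted(genes):
        g = genes[gid]
        for tid in sorted(g.transcripts):
            t = g.transcripts[tid]
            for s, e in t.introns:
                key = (g.chrom, s, e, t.strand)
                jxn_cpm[key] = jxn_cpm.get(key, 0.0) + cpm.get(tid, 0.0)
    keys = sorted(jxn_cpm)
    lam = np.array([config.reads_per_cpm * jxn_cpm[k] for k in keys])
    reads = rng.poisson(lam)
    jdf = pd.DataFrame({
        "chrom": [k[0] for k in keys],
        "intron_start": [k[1] for k in keys],
        "intron_end": [k[2] for k in keys],
        "strand": [k[3] for k in keys],
        "unique_reads": reads.astype(int),
        "annotated": True,
    })
    jdf = jdf[jdf["unique_reads"] > 0].reset_index(drop=True)
    return abundance, JunctionTable(sample_id, jdf)


# ---------------------------------------------------------------------------
# aberration injection

def inject_aberration(abundance: AbundanceTable, junctions: JunctionTable,
                      genes: dict[str, GeneModel], spec: AberrationSpec,
                      ) -> tuple[AbundanceTable, JunctionTable, dict]:
    """Apply one aberration to a patient's tables; returns a truth record."""
    if spec.gene_id not in genes:
        raise ValidationError(f"aberration gene {spec.gene_id} not in models")
    gene = genes[spec.gene_id]
    if spec.kind == "low_abundance":
        return _inject_low_abundance(abundance, junctions, gene, spec)
    if spec.kind == "exon_skip":
        return _inject_exon_skip(abundance, junctions, gene, spec)
    return _inject_intron_retention(abundance, junctions, gene, spec)


def _truth(spec: AberrationSpec, driver: str, detail: dict) -> dict:
    return {"gene_id": spec.gene_id, "kind": spec.kind,
            "severity": spec.severity,
            "carrier_sample_id": spec.carrier_sample_id,
            "expected_driver": driver, **detail}


def _inject_low_abundance(abundance, junctions, gene, spec):
    tids = set(gene.transcripts)
    ab = abundance.data.copy()
    mask = ab["transcript_id"].isin(tids)
    ab.loc[mask, "est_count"] /= spec.severity
    ab["cpm"] = compute_cpm(ab["est_count"].to_numpy())
    jdf = junctions.data.copy()
    jkeys = gene.junctions()
    jmask = [(c, s, e) in jkeys for c, s, e in
             zip(jdf["chrom"], jdf["intron_start"], jdf["intron_end"])]
    jdf.loc[jmask, "unique_reads"] = np.round(
        jdf.loc[jmask, "unique_reads"] / spec.severity).astype(int)
    return (AbundanceTable(abundance.sample_id, ab),
            JunctionTable(junctions.sample_id, jdf, junctions.coverage),
            _truth(spec, "alpha", {}))


def skippable_exons(gene: GeneModel) -> list[tuple[str, int]]:
    """(transcript_id, internal exon index) pairs whose skip junction is
    NOT an annotated junction of the gene (i.e. a genuinely novel event)."""
    annotated = gene.junctions()
    out = []
    for tid in sorted(gene.transcripts):
        t = gene.transcripts[tid]
        for k in range(1, len(t.exons) - 1):
            skip = (gene.chrom, t.exons[k - 1][1] + 1, t.exons[k + 1][0] - 1)
            if skip not in annotated:
                out.append((tid, k))
    return out


def disruptive_skips(gene: GeneModel) -> list[tuple[str, int]]:
    """Skippable exons whose flanking introns touch *every* isoform of the
    gene — a homozygous splice defect there disrupts the whole gene."""
    out = []
    for tid, k in skippable_exons(gene):
        t = gene.transcripts[tid]
        j1 = (t.exons[k - 1][1] + 1, t.exons[k][0] - 1)
        j2 = (t.exons[k][1] + 1, t.exons[k + 1][0] - 1)
        if all(j1 in o.introns or j2 in o.introns
               for o in gene.transcripts.values()):
            out.append((tid, k))
    return out


def _inject_exon_skip(abundance, junctions, gene, spec):
    options = disruptive_skips(gene) or skippable_exons(gene)
    if not options:
        raise ValidationError(
            f"gene {gene.gene_id}: no skippable exon with a novel junction "
            "(intronless or all skip junctions annotated)")
    tid, k = options[0]
    t = gene.transcripts[tid]
    j1 = (gene.chrom, t.exons[k - 1][1] + 1, t.exons[k][0] - 1)
    j2 = (gene.chrom, t.exons[k][1] + 1, t.exons[k + 1][0] - 1)
    novel = (gene.chrom, j1[1], j2[2])
    jdf = junctions.data.copy()
    moved_total = 0
    for jk in (j1, j2):
        sel = ((jdf["chrom"] == jk[0]) & (jdf["intron_start"] == jk[1])
               & (jdf["intron_end"] == jk[2]))
        reads = int(jdf.loc[sel, "unique_reads"].sum())
        keep = int(round(reads / spec.severity))
        moved_total += reads - keep
        jdf.loc[sel, "unique_reads"] = keep
    novel_row = pd.DataFrame([{
        "chrom": novel[0], "intron_start": novel[1], "intron_end": novel[2],
        "strand": t.strand, "unique_reads": moved_total, "annotated": False}])
    jdf = pd.concat([jdf, novel_row], ignore_index=True)
    return (abundance,
            JunctionTable(junctions.sample_id, jdf, junctions.coverage),
            _truth(spec, "beta", {"skipped_exon": t.exons[k],
                                  "novel_junction": novel}))


def shared_introns(gene: GeneModel) -> list[tuple[int, int]]:
    """Introns present in every isoform of the gene, sorted by coordinate."""
    sets = [set(t.introns) for t in gene.transcripts.values()]
    return sorted(set.intersection(*sets)) if sets else []


def _inject_intron_retention(abundance, junctions, gene, spec):
    shared = shared_introns(gene)
    introns = [(None, iv) for iv in shared] or [
        (tid, iv) for tid in sorted(gene.transcripts)
        for iv in gene.transcripts[tid].introns]
    if not introns:
        raise ValidationError(f"gene {gene.gene_id} is intronless: cannot retain an intron")
    _, (s, e) = introns[0]
    jdf = junctions.data
    sel = ((jdf["chrom"] == gene.chrom) & (jdf["intron_start"] == s)
           & (jdf["intron_end"] == e))
    a = int(jdf.loc[sel, "unique_reads"].sum())
    nonsplit = int(round((spec.severity - 1) * a))
    cov_row = pd.DataFrame([{
        "chrom": gene.chrom, "intron_start": s, "intron_end": e,
        "nonsplit_reads": nonsplit}])
    cov = junctions.coverage
    cov = pd.concat([cov, cov_row], ignore_index=True) if cov is not None else cov_row
    return (abundance,
            JunctionTable(junctions.sample_id, jdf.copy(), cov),
            _truth(spec, "beta", {"retained_intron": (s, e)}))


# ---------------------------------------------------------------------------
# ROH

def generate_roh(genes: dict[str, GeneModel], causal_gene_id: str,
                 n_decoy_intervals: int = 3, margin: int = 2000,
                 seed: int = 0) -> ROHSet:
    """One interval covering the causal gene plus intergenic decoys."""
    if causal_gene_id not in genes:
        raise ValidationError(f"causal gene {causal_gene_id} not in models")
    rng = np.random.default_rng([seed, 3])
    spans = sorted((genes[g].span, genes[g].chrom, g) for g in genes)
    causal = genes[causal_gene_id]
    cs, ce = causal.span
    intervals = [(causal.chrom, max(cs - 1 - margin, 0), ce + margin)]
    # decoy intervals live in gaps between consecutive genes, away from any span
    gaps = []
    for ((_, e1), chrom, g1), (((s2, _), _, g2)) in zip(spans, spans[1:]):
        gap = (e1 + margin + 1, s2 - margin - 1)
        if gap[1] - gap[0] > 2000 and causal_gene_id not in (g1, g2):
            gaps.append((chrom, gap))
    if gaps and n_decoy_intervals > 0:
        picks = rng.choice(len(gaps), size=min(n_decoy_intervals, len(gaps)),
                           replace=False)
        for i in sorted(picks):
            chrom, (lo, hi) = gaps[i]
            width = int(rng.integers(1000, max(hi - lo, 1001)))
            start = int(rng.integers(lo, max(hi - width, lo) + 1))
            intervals.append((chrom, start, start + width))
    return ROHSet(merge_intervals(intervals))


# ---------------------------------------------------------------------------
# whole cohorts

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genes: dict[str, GeneModel]
    samples: list[SampleMeta]
    abundances: dict[str, AbundanceTable]
    junctions: dict[str, JunctionTable]
    truths: list[dict] = field(default_factory=list)
    roh: Optional[ROHSet] = None

    @property
    def patients(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.role == "patient"]

    @property
    def controls(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.role == "control"]


def pick_causal_gene(genes: dict[str, GeneModel], kind: str,
                     rng: np.random.Generator,
                     means: Optional[pd.DataFrame] = None,
                     min_cpm: float = 50.0,
                     min_dominant_share: float = 0.75) -> str:
    """A gene compatible with the requested aberration.

    When expression means are given, the gene must be expressed well enough
    for its junctions to clear the support filter, and for splicing
    aberrations it must have a clean dominant-isoform baseline
    (``min_dominant_share``) so the control ρ sits near 1 — the regime in
    which a splicing defect of the stated severity is detectable at all.
    """
    ok = []
    expr = share = None
    if means is not None:
        expr = means.groupby("gene_id")["mean_expr"].sum()
        share = means.groupby("gene_id")["mean_expr"].max() / expr.replace(0, np.nan)
    for gid in sorted(genes):
        g = genes[gid]
        if expr is not None and expr.get(gid, 0.0) < min_cpm:
            continue
        if (share is not None and kind in ("exon_skip", "intron_retention")
                and not share.get(gid, 0.0) >= min_dominant_share):
            continue
        if kind == "exon_skip" and not disruptive_skips(g):
            continue
        if kind == "intron_retention" and not shared_introns(g):
            continue
        ok.append(gid)
    if not ok:
        raise ValidationError(f"no gene compatible with aberration kind {kind!r}")
    return ok[int(rng.integers(0, len(ok)))]


def simulate_cohort(config: SimulationConfig,
                    aberration_kind: Optional[str] = "exon_skip",
                    severity: float = 5.0,
                    with_roh: bool = True,
                    n_decoy_intervals: int = 3) -> SimulatedCohort:
    """Controls + patients, with one aberration injected into patient 1."""
    genes = generate_gene_models(config)
    means = gene_expression_means(genes, config)
    rng = np.random.default_rng([config.seed, 4])
    samples, abundances, junctions = [], {}, {}
    for i in range(config.n_controls):
        sid = f"C{i + 1:03d}"
        rin = float(np.round(8.0 + 2.0 * rng.random(), 1))
        samples.append(SampleMeta(sid, config.tissue, rin, "control"))
        abundances[sid], junctions[sid] = simulate_sample(
            genes, means, config, rng, sid)
    for i in range(config.n_patients):
        sid = f"P{i + 1:03d}"
        rin = float(np.round(6.0 + 4.0 * rng.random(), 1))
        samples.append(SampleMeta(sid, config.tissue, rin, "patient"))
        abundances[sid], junctions[sid] = simulate_sample(
            genes, means, config, rng, sid)
    truths: list[dict] = []
    roh = None
    if aberration_kind is not None and config.n_patients >= 1:
        carrier = "P001"
        causal = pick_causal_gene(genes, aberration_kind, rng, means)
        spec = AberrationSpec(causal, aberration_kind, severity, carrier)
        abundances[carrier], junctions[carrier], truth = inject_aberration(
            abundances[carrier], junctions[carrier], genes, spec)
        truths.append(truth)
        if with_roh:
            roh = generate_roh(genes, causal, n_decoy_intervals,
                               seed=config.seed)
    return SimulatedCohort(config, genes, samples, abundances, junctions,
                           truths, roh)
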