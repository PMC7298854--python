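"""Readers and writers for the pipeline's external formats.

All coordinate conversions are centralized here:

* splice-junction tables — 1-based closed intronic coordinates (STAR
  ``SJ.out.tab`` convention), both on disk and in memory;
* GTF gene models — 1-based closed;
* ROH BED — 0-based half-open on disk and in the :class:`ROHSet`.

Chromosome names are normalized by stripping a leading ``"chr"`` by default
(the analysis mixes annotation sources that disagree on the prefix).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .models import GeneModel, TranscriptModel, ValidationError, build_genes

log = logging.getLogger(__name__)

TISSUES = ("blood_lcl", "blood_paxgene", "fibroblast", "renal_epithelial")
ROLES = ("patient", "control")

#: chromosomes retained by default (autosomes + X)
DEFAULT_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X",)


class FormatError(ValueError):
    """Raised when a file does not match its expected dialect."""


def normalize_chrom(chrom: str, strip_chr: bool = True) -> str:
    if strip_chr and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# sample sheet

@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    rin: float
    role: str

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValidationError(f"{self.sample_id}: unknown tissue {self.tissue!r}")
        if self.role not in ROLES:
            raise ValidationError(f"{self.sample_id}: unknown role {self.role!r}")
        if not (1.0 <= self.rin <= 10.0):
            raise ValidationError(f"{self.sample_id}: RIN {self.rin} outside [1, 10]")


def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "rin", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in sheet: {dups}")
    return [
        SampleMeta(r.sample_id, r.tissue, float(r.rin), r.role)
        for r in df.itertuples(index=False)
    ]


def write_sample_sheet(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.tissue, s.rin, s.role) for s in samples],
        columns=["sample_id", "tissue", "rin", "role"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcript abundance

@dataclass
class AbundanceTable:
    """Per-sample transcript abundance: estimated counts and CPM (x_t)."""

    sample_id: str
    data: pd.DataFrame  # columns: transcript_id, est_count, cpm

    def __post_init__(self):
        if self.data["transcript_id"].duplicated().any():
            dups = self.data.loc[
                self.data["transcript_id"].duplicated(), "transcript_id"
            ].tolist()
            raise ValidationError(
                f"{self.sample_id}: duplicate transcript_id: {dups[:5]}")
        if (self.data["est_count"] < 0).any():
            raise ValidationError(f"{self.sample_id}: negative est_count")

    def cpm_series(self) -> pd.Series:
        return self.data.set_index("transcript_id")["cpm"]


_COUNT_ALIASES = ("est_counts", "est_count", "estimated_counts", "counts")
_TID_ALIASES = ("target_id", "transcript_id")


def read_abundance(path, sample_id: str) -> AbundanceTable:
    """Read a Kallisto-style abundance TSV and recompute CPM from counts."""
    from .quant import compute_cpm

    df = pd.read_csv(path, sep="\t")
    tid_col = next((c for c in _TID_ALIASES if c in df.columns), None)
    cnt_col = next((c for c in _COUNT_ALIASES if c in df.columns), None)
    if tid_col is None:
        raise FormatError(f"{path}: no transcript id column (expected one of {_TID_ALIASES})")
    if cnt_col is None:
        raise FormatError(f"{path}: no count column (expected one of {_COUNT_ALIASES})")
    counts = pd.to_numeric(df[cnt_col], errors="coerce")
    if counts.isna().any():
        bad = (counts.isna().to_numpy().nonzero()[0] + 2).tolist()  # +2: header + 1-based
        raise ValidationError(f"{path}: unparseable counts on line(s) {bad[:10]}")
    out = pd.DataFrame({
        "transcript_id": df[tid_col].astype(str),
        "est_count": counts.astype(float),
    })
    out["cpm"] = compute_cpm(out["est_count"].to_numpy())
    return AbundanceTable(sample_id, out)


def write_abundance(table: AbundanceTable, path) -> None:
    table.data[["transcript_id", "est_count"]].rename(
        columns={"est_count": "est_counts"}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# splice junctions

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_STRAND_TO_CODE = {".": 0, "+": 1, "-": 2}

_NATIVE_COLS = ["chrom", "intron_start", "intron_end", "strand",
                "unique_reads", "annotated"]


@dataclass
class JunctionTable:
    """Per-sample splice junctions (1-based closed intronic coordinates).

    ``coverage`` optionally holds per-intron nonsplit read counts used as
    intron-retention evidence.
    """

    sample_id: str
    data: pd.DataFrame  # columns: _NATIVE_COLS
    coverage: Optional[pd.DataFrame] = None  # chrom, intron_start, intron_end, nonsplit_reads

    def __post_init__(self):
        if (self.data["intron_start"] > self.data["intron_end"]).any():
            raise ValidationError(f"{self.sample_id}: intron_start > intron_end")
        if (self.data["unique_reads"] < 0).any():
            raise ValidationError(f"{self.sample_id}: negative unique_reads")


def read_junctions(path, sample_id: str, coverage_path=None,
                   strip_chr: bool = True) -> JunctionTable:
    """Read a junction table in STAR ``SJ.out.tab`` or the native dialect.

    STAR rows carry 9 columns; strand codes 0/1/2 map to ./+/-; only
    uniquely-mapped read counts are retained as support (multimappers are
    ignored). The native dialect carries the six in-memory columns and a
    header.
    """
    try:
        probe = pd.read_csv(path, sep="\t", header=None, nrows=1)
    except pd.errors.EmptyDataError:
        data = pd.DataFrame(columns=_NATIVE_COLS)
        return JunctionTable(sample_id, _coerce_junctions(data))
    ncol = probe.shape[1]
    if ncol == 9:
        df = pd.read_csv(path, sep="\t", header=None, names=[
            "chrom", "intron_start", "intron_end", "strand_code", "motif",
            "annotated", "unique_reads", "multi_reads", "overhang"])
        data = pd.DataFrame({
            "chrom": df["chrom"].astype(str).map(lambda c: normalize_chrom(c, strip_chr)),
            "intron_start": df["intron_start"],
            "intron_end": df["intron_end"],
            "strand": df["strand_code"].map(_STRAND_CODE),
            "unique_reads": df["unique_reads"],
            "annotated": df["annotated"].astype(bool),
        })
    elif ncol == 6:
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != _NATIVE_COLS:
            raise FormatError(
                f"{path}: 6 columns but header {list(df.columns)} does not match "
                f"native junction dialect {_NATIVE_COLS}")
        df["chrom"] = df["chrom"].astype(str).map(lambda c: normalize_chrom(c, strip_chr))
        data = df
    else:
        raise FormatError(
            f"{path}: {ncol} columns; expected 9 (STAR SJ.out.tab) or 6 (native dialect)")
    coverage = None
    if coverage_path is not None:
        cov = pd.read_csv(coverage_path, sep="\t")
        need = ["chrom", "intron_start", "intron_end", "nonsplit_reads"]
        if list(cov.columns) != need:
            raise FormatError(f"{coverage_path}: expected columns {need}")
        cov["chrom"] = cov["chrom"].astype(str).map(lambda c: normalize_chrom(c, strip_chr))
        coverage = cov
    return JunctionTable(sample_id, _coerce_junctions(data), coverage)


def _coerce_junctions(data: pd.DataFrame) -> pd.DataFrame:
    data = data.copy()
    data["chrom"] = data["chrom"].astype(str)
    for c in ("intron_start", "intron_end", "unique_reads"):
        data[c] = data[c].astype(int) if len(data) else data[c]
    data["annotated"] = data["annotated"].astype(bool) if len(data) else data["annotated"]
    return data.reset_index(drop=True)


def write_junctions(table: JunctionTable, path, coverage_path=None) -> None:
    table.data[_NATIVE_COLS].to_csv(path, sep="\t", index=False)
    if coverage_path is not None and table.coverage is not None:
        table.coverage.to_csv(coverage_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models (GTF)

def read_gene_models(path, strip_chr: bool = True,
                     chroms: Optional[Sequence[str]] = DEFAULT_CHROMS,
                     ) -> dict[str, GeneModel]:
    """Parse a GTF into :class:`GeneModel` objects.

    Only features on ``chroms`` (after name normalization) are retained;
    pass ``chroms=None`` to keep everything. Exons are grouped per
    transcript; introns are derived as inter-exon gaps.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique")
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    known_tids: set[str] = set()
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        known_tids.add(tid)
    for f in db.features_of_type(("exon", "CDS")):
        try:
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValidationError(
                f"{path}: {f.featuretype} at {f.seqid}:{f.start} lacks {exc} attribute")
        if known_tids and tid not in known_tids:
            raise ValidationError(
                f"{path}: {f.featuretype} references unknown transcript {tid!r}")
        chrom = normalize_chrom(f.seqid, strip_chr)
        if chroms is not None and chrom not in chroms:
            continue
        meta[tid] = (gid, chrom, f.strand or ".")
        target = exons if f.featuretype == "exon" else cds
        target.setdefault(tid, []).append((f.start, f.end))
    transcripts = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        transcripts.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            exons=tuple(sorted(ex)),
            cds=tuple(sorted(cds[tid])) if tid in cds else None))
    return build_genes(transcripts)


# ---------------------------------------------------------------------------
# ROH (autozygome) intervals

@dataclass(frozen=True)
class ROHSet:
    """Runs of homozygosity as merged, 0-based half-open intervals."""

    intervals: tuple[tuple[str, int, int], ...] = ()

    def __len__(self):
        return len(self.intervals)

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """1-bp overlap test against a 0-based half-open query."""
        for c, s, e in self.intervals:
            if c == chrom and start0 < e and s < end0:
                return True
        return False

    def contains(self, chrom: str, start0: int, end0: int) -> bool:
        return any(c == chrom and s <= start0 and end0 <= e
                   for c, s, e in self.intervals)


def merge_intervals(rows: Sequence[tuple[str, int, int]]) -> tuple[tuple[str, int, int], ...]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(rows):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return tuple(out)


def read_roh_bed(path, strip_chr: bool = True) -> ROHSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
    except pd.errors.EmptyDataError:
        return ROHSet()
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValidationError(
            f"{path}: BED start >= end at {bad.chrom}:{bad.start}-{bad.end}")
    rows = [(normalize_chrom(str(c), strip_chr), int(s), int(e))
            for c, s, e in df.itertuples(index=False)]
    return ROHSet(merge_intervals(rows))


def write_roh_bed(roh: ROHSet, path) -> None:
    pd.DataFrame(list(roh.intervals), columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# variants

_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: Optional[str] = None
    hgvs_c: Optional[str] = None
    allele_frequency: Optional[float] = None
    zygosity: str = "hom"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele:
                raise ValidationError(f"{self.key()}: empty {name}")
            if not (set(allele) <= _BASES or allele.startswith("<")):
                raise ValidationError(f"{self.key()}: bad {name} allele {allele!r}")
        if self.allele_frequency is not None and not (0 <= self.allele_frequency <= 1):
            raise ValidationError(f"{self.key()}: AF {self.allele_frequency} outside [0,1]")
        if self.zygosity not in ("hom", "het", "hemi"):
            raise ValidationError(f"{self.key()}: zygosity {self.zygosity!r}")

    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def with_flag(self, flag: str) -> "VariantRecord":
        return VariantRecord(self.chrom, self.pos, self.ref, self.alt,
                             self.gene_id, self.hgvs_c, self.allele_frequency,
                             self.zygosity, self.flags + (flag,))


def read_variants(path, strip_chr: bool = True) -> list[VariantRecord]:
    """Read variants from VCF (via cyvcf2) or a TSV with VariantRecord columns."""
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return _read_vcf(path, strip_chr)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "ref", "alt"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: variant TSV missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        af = getattr(r, "allele_frequency", None)
        af = None if af is None or pd.isna(af) else float(af)
        hgvs = getattr(r, "hgvs_c", None)
        hgvs = None if hgvs is None or pd.isna(hgvs) else str(hgvs)
        gene = getattr(r, "gene_id", None)
        gene = None if gene is None or pd.isna(gene) else str(gene)
        out.append(VariantRecord(
            chrom=normalize_chrom(str(r.chrom), strip_chr), pos=int(r.pos),
            ref=str(r.ref), alt=str(r.alt), gene_id=gene, hgvs_c=hgvs,
            allele_frequency=af, zygosity=getattr(r, "zygosity", "hom")))
    return out


def _read_vcf(path: str, strip_chr: bool) -> list[VariantRecord]:
    from cyvcf2 import VCF

    out = []
    vcf = VCF(path)
    has_samples = len(vcf.samples) > 0
    for v in vcf:
        af = v.INFO.get("AF")
        gene = v.INFO.get("GENE")
        hgvs = v.INFO.get("HGVSC")
        zyg = "hom"
        if has_samples:
            gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            zyg = {0: "het", 1: "het", 3: "hom"}.get(int(gt[0]), "hom")
        for alt in v.ALT:
            out.append(VariantRecord(
                chrom=normalize_chrom(v.CHROM, strip_chr), pos=v.POS,
                ref=v.REF, alt=alt, gene_id=gene, hgvs_c=hgvs,
                allele_frequency=float(af) if af is not None else None,
                zygosity=zyg))
    return out


# ---------------------------------------------------------------------------
# candidate tables

CANDIDATE_COLUMNS = ["gene_id", "alpha", "beta", "rank_alpha", "rank_beta",
                     "selected", "in_autozygome"]


def write_candidates(candidates: pd.DataFrame, path) -> None:
    missing = set(CANDIDATE_COLUMNS) - set(candidates.columns)
    if missing:
        raise ValidationError(f"candidate table missing columns {sorted(missing)}")
    candidates[CANDIDATE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_candidates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != CANDIDATE_COLUMNS:
        raise FormatError(f"{path}: expected columns {CANDIDATE_COLUMNS}")
    for c in ("selected", "in_autozygome"):
        df[c] = df[c].astype(bool)
    return df
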