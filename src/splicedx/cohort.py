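"""Cohort-level tallies: TDV fractions, class breakdowns, expression-by-RNA-
source tallies, and in-silico tool concordance against RT-PCR truth.

Percentages are rounded half-up at the requested number of decimals;
class-breakdown shares below 1% are reported at two decimals, truncated,
so sub-percent classes are never overstated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import ValidationError

EXPRESSION_SOURCES = ("blood", "fibroblast", "renal")
EXPRESSION_STATES = ("expressed", "poorly_expressed", "not_expressed", "untested")


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, decimals: int = 0) -> float:
    f = 10 ** decimals
    return math.floor(x * f) / f


@dataclass(frozen=True)
class CohortRecord:
    """One family/variant row of the cohort bookkeeping table."""

    family_id: str
    solved: bool
    variant_key: Optional[str] = None
    tdv: bool = False
    tdv_class: Optional[str] = None
    mapped_single_locus: bool = False
    protein_truncating: bool = False
    expression_status: Mapping[str, str] = field(default_factory=dict)
    insilico_calls: Mapping[str, str] = field(default_factory=dict)
    rtpcr_aberrant: str = "untested"

    def __post_init__(self):
        if self.tdv != (self.tdv_class is not None):
            raise ValidationError(
                f"{self.family_id}: tdv_class present iff tdv is true")
        if not self.solved and self.variant_key is not None:
            raise ValidationError(f"{self.family_id}: unsolved family with variant")
        for src, st in self.expression_status.items():
            if st not in EXPRESSION_STATES:
                raise ValidationError(f"{self.family_id}: bad expression state {st!r}")
        if self.rtpcr_aberrant not in ("aberrant", "normal", "untested"):
            raise ValidationError(f"{self.family_id}: bad rtpcr state")


Predicate = Callable[[CohortRecord], bool]


def tally_fraction(records: Sequence[CohortRecord],
                   numerator: Predicate, denominator: Predicate,
                   decimals: int = 0) -> float:
    """100 × |num ∧ denom| / |denom|, rounded half-up."""
    denom = [r for r in records if denominator(r)]
    if not denom:
        raise ValidationError("tally_fraction: zero denominator")
    num = sum(1 for r in denom if numerator(r))
    return round_half_up(100.0 * num / len(denom), decimals)


def class_breakdown(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Counts and percentages per TDV class.

    Shares ≥ 1% are rounded half-up at one decimal; shares < 1% are
    reported at two decimals, truncated.
    """
    tdvs = [r for r in records if r.tdv]
    for r in tdvs:
        if r.tdv_class is None:
            raise ValidationError(f"{r.family_id}: TDV without class")
    total = len(tdvs)
    if total == 0:
        raise ValidationError("class_breakdown: no TDV records")
    counts = pd.Series([r.tdv_class for r in tdvs]).value_counts().sort_index()
    rows = []
    for cls, n in counts.items():
        share = 100.0 * n / total
        pct = round_half_up(share, 1) if share >= 1 else truncate(share, 2)
        rows.append((cls, int(n), pct))
    df = pd.DataFrame(rows, columns=["tdv_class", "count", "percent"])
    assert df["count"].sum() == total
    return df


def expression_tally(gene_status: pd.DataFrame,
                     include_poorly: bool = True,
                     decimals: int = 1) -> dict:
    """Per-RNA-source expression fractions over tested genes.

    ``gene_status`` is genes × sources with values from
    :data:`EXPRESSION_STATES`. A gene counts as expressed in a source when
    its status is ``expressed`` (or ``poorly_expressed`` when
    ``include_poorly``). Both the inclusive and the strict tallies are
    useful; call twice to get both. Also reported: the fraction of genes
    expressed in every tested source and the fraction expressed in none
    (``not_expressed`` everywhere it was tested).
    """
    n = len(gene_status)
    if n == 0:
        raise ValidationError("expression_tally: no genes")
    good = {"expressed", "poorly_expressed"} if include_poorly else {"expressed"}
    out: dict = {"n_genes": n, "include_poorly": include_poorly, "per_source": {}}
    expressed = gene_status.isin(good)
    tested = gene_status != "untested"
    for src in gene_status.columns:
        out["per_source"][src] = round_half_up(
            100.0 * expressed[src].sum() / n, decimals)
    all_src = (expressed | ~tested).all(axis=1) & tested.any(axis=1)
    none_src = (gene_status.isin({"not_expressed"}) | ~tested).all(axis=1) & tested.any(axis=1)
    out["all_sources"] = round_half_up(100.0 * all_src.sum() / n, decimals)
    out["no_source"] = round_half_up(100.0 * none_src.sum() / n, decimals)
    return out


def insilico_concordance(records: Sequence[CohortRecord],
                         decimals: int = 0) -> dict:
    """Per-tool sensitivity on RT-PCR-confirmed aberrant variants.

    Sensitivity = fraction of tested aberrant records a tool calls
    deleterious. Also reports the fraction of aberrant records missed by
    at least one tool that tested them.
    """
    aberrant = [r for r in records if r.rtpcr_aberrant == "aberrant"]
    if not aberrant:
        raise ValidationError("insilico_concordance: no RT-PCR aberrant records")
    tools = sorted({t for r in aberrant for t in r.insilico_calls})
    sens = {}
    for tool in tools:
        tested = [r for r in aberrant
                  if r.insilico_calls.get(tool, "untested") != "untested"]
        if not tested:
            raise ValidationError(f"insilico_concordance: tool {tool} never tested")
        hit = sum(1 for r in tested if r.insilico_calls[tool] == "deleterious")
        sens[tool] = round_half_up(100.0 * hit / len(tested), decimals)
    missed = sum(
        1 for r in aberrant
        if any(c == "non_deleterious" for c in r.insilico_calls.values()))
    return {
        "sensitivity": sens,
        "any_tool_missed": round_half_up(100.0 * missed / len(aberrant), decimals),
        "n_aberrant": len(aberrant),
    }


def read_cohort_tsv(path) -> list[CohortRecord]:
    """Read the cohort bookkeeping TSV (one row per family/variant)."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str})
    records = []
    for r in df.itertuples(index=False):
        expr = {src: getattr(r, f"expr_{src}", "untested")
                for src in EXPRESSION_SOURCES
                if hasattr(r, f"expr_{src}")}
        tools = {c[8:]: getattr(r, c) for c in df.columns if c.startswith("insilico_")}
        cls = getattr(r, "tdv_class", None)
        cls = None if cls is None or pd.isna(cls) else str(cls)
        vk = getattr(r, "variant_key", None)
        vk = None if vk is None or pd.isna(vk) else str(vk)
        records.append(CohortRecord(
            family_id=str(r.family_id), solved=bool(r.solved), variant_key=vk,
            tdv=bool(getattr(r, "tdv", False)), tdv_class=cls,
            mapped_single_locus=bool(getattr(r, "mapped_single_locus", False)),
            protein_truncating=bool(getattr(r, "protein_truncating", False)),
            expression_status=expr, insilico_calls=tools,
            rtpcr_aberrant=str(getattr(r, "rtpcr_aberrant", "untested"))))
    return records
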