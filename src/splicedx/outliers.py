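"""α/β outlier scoring, candidate selection, and autozygome filtering.

For patient i and gene g, with ω_g(k) and ρ_g(k) the control second-
percentile baselines:

    α_g(i) = ω_g(k) / (ω_g(i) + ε)        β_g(i) = ρ_g(k) / (ρ_g(i) + ε)

with ε = 0.001 guarding division by zero. High α flags low-abundance or
splicing outliers; high β isolates splicing. Gene g is a causative
candidate for patient i when

    1. α_g(i) ≥ 3.0 or β_g(i) ≥ 3.0, and
    2. i is the strict extreme of α_g among same-tissue patients.

Criterion 2 suppresses genes aberrant across all patients (systematic
artifacts); the default direction requires α_g(i) > α_g(j) for every other
patient j (``cross_patient="strict_max"``). The inverted direction is
available as ``"printed"``, and ``"none"`` disables the criterion. Ties are
rejected for all tied patients.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ROHSet
from .models import GeneModel, ValidationError

log = logging.getLogger(__name__)

EPSILON = 0.001
ALPHA_THRESHOLD = 3.0
BETA_THRESHOLD = 3.0


def alpha_score(omega_patient, omega_k, epsilon: float = EPSILON):
    """α = ω_k / (ω_patient + ε); vectorized."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    return np.asarray(omega_k, dtype=float) / (np.asarray(omega_patient, dtype=float) + epsilon)


def beta_score(rho_patient, rho_k, epsilon: float = EPSILON):
    """β = ρ_k / (ρ_patient + ε); vectorized."""
    return alpha_score(rho_patient, rho_k, epsilon)


def score_table(patient_genes: pd.DataFrame, baseline: pd.DataFrame,
                epsilon: float = EPSILON) -> pd.DataFrame:
    """Per-gene α/β for one patient.

    ``patient_genes`` needs columns omega, rho (index gene_id);
    ``baseline`` needs omega_k, rho_k. Genes missing on either side are
    scored with value 0 on that side (absent gene = no expression).
    """
    idx = patient_genes.index.union(baseline.index)
    om = patient_genes["omega"].reindex(idx, fill_value=0.0)
    rh = patient_genes["rho"].reindex(idx, fill_value=0.0)
    om_k = baseline["omega_k"].reindex(idx, fill_value=0.0)
    rh_k = baseline["rho_k"].reindex(idx, fill_value=0.0)
    return pd.DataFrame({
        "alpha": alpha_score(om.to_numpy(), om_k.to_numpy(), epsilon),
        "beta": beta_score(rh.to_numpy(), rh_k.to_numpy(), epsilon),
    }, index=idx).sort_index()


def _ranked(df: pd.DataFrame) -> pd.DataFrame:
    """Attach rank_alpha / rank_beta (1 = largest; ties broken on gene_id)."""
    out = df.copy()
    out = out.reset_index().rename(columns={"index": "gene_id"})
    for col, rank_col in (("alpha", "rank_alpha"), ("beta", "rank_beta")):
        order = out.sort_values([col, "gene_id"], ascending=[False, True]).index
        ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
        out[rank_col] = ranks.reindex(out.index).astype(int)
    return out


def select_candidates(scores: Mapping[str, pd.DataFrame],
                      tissues: Optional[Mapping[str, str]] = None,
                      alpha_thresh: float = ALPHA_THRESHOLD,
                      beta_thresh: float = BETA_THRESHOLD,
                      cross_patient: str = "strict_max",
                      ) -> dict[str, pd.DataFrame]:
    """Apply the two selection criteria to same-tissue patient score tables.

    ``scores`` maps sample_id -> DataFrame(index gene_id: alpha, beta) over
    a shared gene universe. Returns per patient a candidate table with
    columns gene_id, alpha, beta, rank_alpha, rank_beta, selected,
    in_autozygome (ranks within that patient's candidate set, 1 = largest;
    in_autozygome starts undetermined/False until the ROH filter runs).
    """
    if tissues is not None and len(set(tissues.values())) > 1:
        raise ValidationError(
            f"patients of mixed tissues in one call: {sorted(set(tissues.values()))}")
    sample_ids = list(scores)
    universes = [tuple(scores[s].index) for s in sample_ids]
    if len(set(universes)) > 1:
        raise ValidationError("patients must share one gene universe")
    if cross_patient not in ("strict_max", "printed", "none"):
        raise ValidationError(f"unknown cross_patient mode {cross_patient!r}")
    alpha_mat = pd.DataFrame({s: scores[s]["alpha"] for s in sample_ids})
    out: dict[str, pd.DataFrame] = {}
    for s in sample_ids:
        df = scores[s]
        crit1 = (df["alpha"] >= alpha_thresh) | (df["beta"] >= beta_thresh)
        others = alpha_mat.drop(columns=s)
        if cross_patient == "none" or others.shape[1] == 0:
            crit2 = pd.Series(True, index=df.index)
        elif cross_patient == "strict_max":
            crit2 = df["alpha"] > others.max(axis=1)
        else:  # "printed": α_g(i) < α_g(j) for all other j, verbatim
            crit2 = df["alpha"] < others.min(axis=1)
        cand = df[crit1 & crit2]
        cand = _ranked(cand[["alpha", "beta"]])
        cand = cand.rename(columns={cand.columns[0]: "gene_id"})
        cand["selected"] = True
        cand["in_autozygome"] = False
        # report order: max(alpha, beta) descending, gene_id breaking ties
        cand["_key"] = np.maximum(cand["alpha"], cand["beta"])
        cand = (cand.sort_values(["_key", "gene_id"], ascending=[False, True])
                .drop(columns="_key").reset_index(drop=True))
        out[s] = cand[["gene_id", "alpha", "beta", "rank_alpha", "rank_beta",
                       "selected", "in_autozygome"]]
        log.info("patient %s: %d genes pass criterion 1, %d after criterion 2",
                 s, int(crit1.sum()), len(cand))
    return out


def _roh_tree(roh: ROHSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in roh.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def autozygome_filter(candidates: pd.DataFrame,
                      roh: Optional[ROHSet],
                      gene_models: Mapping[str, GeneModel],
                      mode: str = "overlap",
                      subset: bool = True,
                      empty_roh: str = "pass_through") -> pd.DataFrame:
    """Flag candidates whose gene span intersects the autozygome.

    ``mode="overlap"`` requires ≥ 1 bp overlap with any ROH interval;
    ``mode="containment"`` requires the gene span to lie inside one
    interval. With ``subset=True`` only in-autozygome candidates are
    returned. A missing/empty ROH set passes everything through with a
    warning (no mapping data — the filter does not apply).
    """
    cand = candidates.copy()
    if roh is None or len(roh) == 0:
        if empty_roh != "pass_through":
            raise ValidationError("empty ROH set and pass-through disabled")
        log.warning("no ROH intervals: autozygome filter skipped (pass-through)")
        return cand
    trees = _roh_tree(roh)
    flags = []
    for gid in cand["gene_id"]:
        g = gene_models.get(gid)
        if g is None:
            flags.append(False)
            continue
        start1, end1 = g.span
        start0, end0 = start1 - 1, end1  # to 0-based half-open
        tree = trees.get(g.chrom)
        if tree is None:
            flags.append(False)
        elif mode == "overlap":
            flags.append(bool(tree.overlap(start0, end0)))
        elif mode == "containment":
            flags.append(any(iv.begin <= start0 and end0 <= iv.end
                             for iv in tree.overlap(start0, end0)))
        else:
            raise ValidationError(f"unknown autozygome mode {mode!r}")
    cand["in_autozygome"] = pd.Series(flags, dtype=bool, index=cand.index)
    if subset:
        n0 = len(cand)
        cand = cand[cand["in_autozygome"]].reset_index(drop=True)
        log.info("autozygome filter: %d -> %d candidates", n0, len(cand))
    return cand
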