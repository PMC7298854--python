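"""Control baselines: RIN-based sample QC, second-percentile per-gene
baselines, and matched-control-tissue selection.

Patient samples with RIN < 6.0 and control samples with RIN < 8.0 are
excluded. Per gene, the baseline ω_g(k) and ρ_g(k) are the q-th percentile
(default q = 2, linear interpolation between closest ranks) of the control
cohort's values; a gene absent from a control contributes ω = 0 there. The
matched control tissue is the candidate set whose per-gene median ω vector
correlates best (Spearman by default) with the patient profile.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMeta
from .models import ValidationError
from .quant import OmegaProfile

log = logging.getLogger(__name__)

PATIENT_MIN_RIN = 6.0
CONTROL_MIN_RIN = 8.0
BASELINE_PERCENTILE = 2.0


def qc_filter_samples(samples: Sequence[SampleMeta],
                      patient_min_rin: float = PATIENT_MIN_RIN,
                      control_min_rin: float = CONTROL_MIN_RIN,
                      ) -> tuple[list[SampleMeta], list[SampleMeta], list[tuple[SampleMeta, str]]]:
    """Partition samples into retained patients, retained controls, and
    exclusions with reasons. Thresholds are strict (<)."""
    patients, controls, excluded = [], [], []
    for s in samples:
        if s.role == "patient":
            if s.rin < patient_min_rin:
                excluded.append((s, f"patient RIN {s.rin} < {patient_min_rin}"))
            else:
                patients.append(s)
        else:
            if s.rin < control_min_rin:
                excluded.append((s, f"control RIN {s.rin} < {control_min_rin}"))
            else:
                controls.append(s)
    for s, reason in excluded:
        log.info("QC excluded %s: %s", s.sample_id, reason)
    return patients, controls, excluded


def _stack_profiles(profiles: Sequence[OmegaProfile], column: str) -> pd.DataFrame:
    """Genes × samples matrix of one per-gene column; missing genes -> 0."""
    series = {p.sample_id: p.genes[column] for p in profiles}
    mat = pd.DataFrame(series)
    missing = mat.isna()
    if missing.to_numpy().any():
        n = int(missing.to_numpy().sum())
        log.warning("%d gene/control cells absent; treated as 0", n)
        mat = mat.fillna(0.0)
    return mat


@dataclass
class BaselineProfile:
    """Per-gene control baseline ω_g(k), ρ_g(k) for one tissue."""

    control_set_id: str
    tissue: str
    data: pd.DataFrame  # index gene_id: omega_k, rho_k
    n_controls: int
    q: float = BASELINE_PERCENTILE
    method: str = "linear"

    def __post_init__(self):
        if self.n_controls < 2:
            raise ValidationError("baseline requires >= 2 control samples")


def percentile(values: np.ndarray, q: float, method: str = "linear") -> float:
    """q-th percentile; ``linear`` interpolates between closest ranks,
    ``nearest-rank`` takes the nearest order statistic."""
    if method == "linear":
        return float(np.percentile(values, q, method="linear"))
    if method == "nearest-rank":
        return float(np.percentile(values, q, method="nearest"))
    raise ValidationError(f"unknown percentile method {method!r}")


def baseline_percentile(profiles: Sequence[OmegaProfile],
                        q: float = BASELINE_PERCENTILE,
                        method: str = "linear",
                        tissue: str = "unknown",
                        control_set_id: str = "controls",
                        metas: Optional[Sequence[SampleMeta]] = None,
                        ) -> BaselineProfile:
    """Per-gene q-th percentile of control ω and ρ."""
    if len(profiles) < 2:
        raise ValidationError("need >= 2 control profiles for a baseline")
    if metas is not None:
        tissues = {m.tissue for m in metas}
        if len(tissues) > 1:
            raise ValidationError(f"mixed control tissues in one baseline: {sorted(tissues)}")
        tissue = tissues.pop()
    omega_mat = _stack_profiles(profiles, "omega")
    rho_mat = _stack_profiles(profiles, "rho")
    data = pd.DataFrame({
        "omega_k": np.percentile(omega_mat.to_numpy(), q, axis=1,
                                 method="linear" if method == "linear" else "nearest"),
        "rho_k": np.percentile(rho_mat.to_numpy(), q, axis=1,
                               method="linear" if method == "linear" else "nearest"),
    }, index=omega_mat.index)
    return BaselineProfile(control_set_id, tissue, data.sort_index(),
                           n_controls=len(profiles), q=q, method=method)


@dataclass
class ControlSet:
    """A tissue-homogeneous control cohort and its per-gene median ω."""

    control_set_id: str
    tissue: str
    profiles: list[OmegaProfile]

    def median_omega(self) -> pd.Series:
        return _stack_profiles(self.profiles, "omega").median(axis=1)

    def baseline(self, q: float = BASELINE_PERCENTILE, method: str = "linear") -> BaselineProfile:
        return baseline_percentile(self.profiles, q=q, method=method,
                                   tissue=self.tissue,
                                   control_set_id=self.control_set_id)


def select_control_tissue(patient: OmegaProfile,
                          control_sets: Sequence[ControlSet],
                          metric: str = "spearman",
                          min_shared_genes: int = 10,
                          ) -> tuple[str, pd.DataFrame]:
    """Pick the control set maximizing correlation with the patient profile.

    Returns the winning ``control_set_id`` and a report of all correlations.
    """
    if not control_sets:
        raise ValidationError("no candidate control sets")
    patient_omega = patient.genes["omega"]
    rows = []
    for cs in control_sets:
        med = cs.median_omega()
        shared = patient_omega.index.intersection(med.index)
        if len(shared) < min_shared_genes:
            raise ValidationError(
                f"control set {cs.control_set_id}: only {len(shared)} shared genes "
                f"(need >= {min_shared_genes})")
        a = patient_omega.loc[shared].to_numpy()
        b = med.loc[shared].to_numpy()
        if metric == "spearman":
            r = stats.spearmanr(a, b).statistic
        elif metric == "pearson_log1p":
            r = stats.pearsonr(np.log1p(a), np.log1p(b)).statistic
        else:
            raise ValidationError(f"unknown correlation metric {metric!r}")
        rows.append((cs.control_set_id, cs.tissue, float(r), len(shared)))
    report = pd.DataFrame(rows, columns=["control_set_id", "tissue",
                                         "correlation", "n_shared_genes"])
    best = report.sort_values(["correlation", "control_set_id"],
                              ascending=[False, True]).iloc[0]
    return str(best.control_set_id), report
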