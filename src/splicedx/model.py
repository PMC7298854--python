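"""Model/Results surface for transcript-level outlier diagnostics.

:class:`TranscriptOutlierModel` is built from patient and control ω
profiles; ``fit()`` estimates the per-gene control baseline and returns a
:class:`TranscriptOutlierResults` carrying the α/β score tables, the
selected candidate genes per patient, and a ``summary()`` report. The
autozygome (ROH) filter is applied on the results object.

Example
-------
>>> model = TranscriptOutlierModel(patient_profiles, control_profiles,
...                                tissue="blood_lcl")
>>> res = model.fit()
>>> print(res.summary())
>>> final = res.apply_autozygome(roh, gene_models)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import baseline as _baseline
from . import outliers as _outliers
from .io import ROHSet, SampleMeta
from .models import GeneModel, ValidationError
from .quant import OmegaProfile


class TranscriptOutlierModel:
    """Outlier model for one tissue: patients scored against a control cohort.

    Parameters
    ----------
    patient_profiles, control_profiles
        Per-sample :class:`~splicedx.quant.OmegaProfile` objects.
    tissue
        Tissue label; all samples are assumed homogeneous for this tissue
        (criterion 2 compares only same-tissue patients).
    q, percentile_method
        Control baseline percentile (default: second percentile, linear
        interpolation).
    epsilon
        Division guard in the α/β ratios.
    """

    def __init__(self, patient_profiles: Sequence[OmegaProfile],
                 control_profiles: Sequence[OmegaProfile],
                 tissue: str = "unknown",
                 q: float = _baseline.BASELINE_PERCENTILE,
                 percentile_method: str = "linear",
                 epsilon: float = _outliers.EPSILON,
                 control_metas: Optional[Sequence[SampleMeta]] = None):
        if not patient_profiles:
            raise ValidationError("no patient samples after QC")
        self.patient_profiles = list(patient_profiles)
        self.control_profiles = list(control_profiles)
        self.tissue = tissue
        self.q = q
        self.percentile_method = percentile_method
        self.epsilon = epsilon
        self.control_metas = control_metas

    @classmethod
    def from_samples(cls, profiles: Mapping[str, OmegaProfile],
                     samples: Sequence[SampleMeta], tissue: str,
                     patient_min_rin: float = _baseline.PATIENT_MIN_RIN,
                     control_min_rin: float = _baseline.CONTROL_MIN_RIN,
                     **kwargs) -> "TranscriptOutlierModel":
        """Build from a sample sheet, applying RIN QC and tissue selection."""
        same_tissue = [s for s in samples if s.tissue == tissue]
        patients, controls, _ = _baseline.qc_filter_samples(
            same_tissue, patient_min_rin, control_min_rin)
        return cls([profiles[s.sample_id] for s in patients],
                   [profiles[s.sample_id] for s in controls],
                   tissue=tissue, control_metas=controls, **kwargs)

    def fit(self, alpha_thresh: float = _outliers.ALPHA_THRESHOLD,
            beta_thresh: float = _outliers.BETA_THRESHOLD,
            cross_patient: str = "strict_max") -> "TranscriptOutlierResults":
        """Estimate the baseline, score every patient, select candidates."""
        bl = _baseline.baseline_percentile(
            self.control_profiles, q=self.q, method=self.percentile_method,
            tissue=self.tissue, metas=self.control_metas)
        scores = {
            p.sample_id: _outliers.score_table(p.genes, bl.data, self.epsilon)
            for p in self.patient_profiles
        }
        candidates = _outliers.select_candidates(
            scores, alpha_thresh=alpha_thresh, beta_thresh=beta_thresh,
            cross_patient=cross_patient)
        params = {
            "tissue": self.tissue, "q": self.q,
            "percentile_method": self.percentile_method,
            "epsilon": self.epsilon, "alpha_thresh": alpha_thresh,
            "beta_thresh": beta_thresh, "cross_patient": cross_patient,
            "n_controls": len(self.control_profiles),
            "n_patients": len(self.patient_profiles),
        }
        return TranscriptOutlierResults(self, bl, scores, candidates, params)


@dataclass
class TranscriptOutlierResults:
    """Fitted baseline, α/β scores and candidates for one patient cohort."""

    model: TranscriptOutlierModel
    baseline: _baseline.BaselineProfile
    scores: dict[str, pd.DataFrame]
    candidates: dict[str, pd.DataFrame]
    params: dict = field(default_factory=dict)

    def score_frame(self) -> pd.DataFrame:
        """Long-form α/β table (sample_id, gene_id, alpha, beta)."""
        frames = []
        for sid, df in self.scores.items():
            f = df.reset_index(names="gene_id")
            f.insert(0, "sample_id", sid)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def candidate_table(self, sample_id: Optional[str] = None) -> pd.DataFrame:
        if sample_id is not None:
            return self.candidates[sample_id]
        frames = []
        for sid, df in self.candidates.items():
            f = df.copy()
            f.insert(0, "sample_id", sid)
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def apply_autozygome(self, roh: Optional[ROHSet],
                         gene_models: Mapping[str, GeneModel],
                         mode: str = "overlap", subset: bool = True,
                         ) -> "TranscriptOutlierResults":
        """Return a copy with candidates restricted to the autozygome."""
        filtered = {
            sid: _outliers.autozygome_filter(df, roh, gene_models,
                                             mode=mode, subset=subset)
            for sid, df in self.candidates.items()
        }
        params = dict(self.params, autozygome_mode=mode,
                      autozygome_applied=roh is not None and len(roh) > 0)
        return TranscriptOutlierResults(self.model, self.baseline,
                                        self.scores, filtered, params)

    def summary(self) -> str:
        lines = ["Transcript outlier analysis"]
        lines.append("=" * 60)
        for k in ("tissue", "n_patients", "n_controls", "q", "epsilon",
                  "alpha_thresh", "beta_thresh", "cross_patient"):
            lines.append(f"{k:>18}: {self.params.get(k)}")
        lines.append("-" * 60)
        lines.append(f"{'patient':>18}  candidates  top gene (alpha, beta)")
        for sid, df in self.candidates.items():
            if len(df):
                top = df.iloc[0]
                desc = f"{top.gene_id} ({top.alpha:.2f}, {top.beta:.2f})"
            else:
                desc = "-"
            lines.append(f"{sid:>18}  {len(df):>10d}  {desc}")
        return "\n".join(lines)
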