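"""End-to-end orchestration: quantify -> baseline -> score -> select ->
autozygome filter -> report.

`RunConfig` aggregates every decision-bearing threshold; all of them are
echoed into the output metadata so a report is self-describing. Stage
counts (genes, junctions filtered, candidates before/after criterion 2 and
before/after the ROH filter) are logged one line per stage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as fio
from .baseline import (BASELINE_PERCENTILE, CONTROL_MIN_RIN, PATIENT_MIN_RIN,
                       qc_filter_samples)
from .model import TranscriptOutlierModel
from .models import ValidationError
from .outliers import ALPHA_THRESHOLD, BETA_THRESHOLD, EPSILON
from .quant import MIN_JUNCTION_SUPPORT, compute_omega_profile

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "gtf", "samples", "abundance_dir", "junction_dir", "coverage_dir",
    "roh", "variants", "out_dir", "alpha_thresh", "beta_thresh", "epsilon",
    "min_junction_support", "percentile_q", "percentile_method",
    "patient_min_rin", "control_min_rin", "max_af", "promoter_window",
    "cross_patient", "combine", "tissue", "seed", "strip_chr",
}


@dataclass
class RunConfig:
    gtf: str
    samples: str
    abundance_dir: str
    junction_dir: str
    out_dir: str
    coverage_dir: Optional[str] = None
    roh: Optional[str] = None
    variants: Optional[str] = None
    tissue: Optional[str] = None
    alpha_thresh: float = ALPHA_THRESHOLD
    beta_thresh: float = BETA_THRESHOLD
    epsilon: float = EPSILON
    min_junction_support: int = MIN_JUNCTION_SUPPORT
    percentile_q: float = BASELINE_PERCENTILE
    percentile_method: str = "linear"
    patient_min_rin: float = PATIENT_MIN_RIN
    control_min_rin: float = CONTROL_MIN_RIN
    max_af: float = 0.001
    promoter_window: int = 1000
    cross_patient: str = "strict_max"
    combine: str = "min"
    strip_chr: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if not (self.epsilon > 0):
            raise ValidationError("epsilon must be > 0")
        if self.alpha_thresh < 0 or self.beta_thresh < 0:
            raise ValidationError("thresholds must be >= 0")
        if not (0 <= self.percentile_q <= 100):
            raise ValidationError("percentile_q must be in [0, 100]")
        if self.min_junction_support < 0:
            raise ValidationError("min_junction_support must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_outlier_pipeline(config: RunConfig) -> dict:
    """Run the full candidate-gene pipeline; returns a result manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = fio.read_gene_models(config.gtf, strip_chr=config.strip_chr)
    log.info("stage=gene_models n=%d", len(genes))
    samples = fio.read_sample_sheet(config.samples)
    if config.tissue is not None:
        samples = [s for s in samples if s.tissue == config.tissue]
    patients, controls, excluded = qc_filter_samples(
        samples, config.patient_min_rin, config.control_min_rin)
    log.info("stage=qc patients=%d controls=%d excluded=%d",
             len(patients), len(controls), len(excluded))
    if not patients:
        raise ValidationError("no patient samples after QC")
    if len(controls) < 2:
        raise ValidationError("need >= 2 control samples after QC")

    profiles = {}
    for s in patients + controls:
        ab = fio.read_abundance(
            Path(config.abundance_dir) / f"{s.sample_id}.tsv", s.sample_id)
        cov = None
        if config.coverage_dir is not None:
            cpath = Path(config.coverage_dir) / f"{s.sample_id}.tsv"
            cov = cpath if cpath.exists() else None
        jx = fio.read_junctions(
            Path(config.junction_dir) / f"{s.sample_id}.tsv", s.sample_id,
            coverage_path=cov, strip_chr=config.strip_chr)
        n_before = len(jx.data)
        profiles[s.sample_id] = compute_omega_profile(
            genes, ab, jx, min_support=config.min_junction_support,
            combine=config.combine)
        log.info("stage=quant sample=%s junctions_in=%d", s.sample_id, n_before)

    tissue = config.tissue or patients[0].tissue
    model = TranscriptOutlierModel(
        [profiles[s.sample_id] for s in patients],
        [profiles[s.sample_id] for s in controls],
        tissue=tissue, q=config.percentile_q,
        percentile_method=config.percentile_method, epsilon=config.epsilon)
    results = model.fit(alpha_thresh=config.alpha_thresh,
                        beta_thresh=config.beta_thresh,
                        cross_patient=config.cross_patient)
    pre_roh = {sid: len(df) for sid, df in results.candidates.items()}
    log.info("stage=candidates pre_roh=%s", pre_roh)

    roh = fio.read_roh_bed(config.roh, config.strip_chr) if config.roh else None
    if config.roh is None:
        log.warning("no ROH file: autozygome filtering skipped")
        final = results
    else:
        final = results.apply_autozygome(roh, genes)
    post_roh = {sid: len(df) for sid, df in final.candidates.items()}
    log.info("stage=autozygome post_roh=%s", post_roh)

    for sid, df in final.candidates.items():
        fio.write_candidates(df, out_dir / f"candidates_{sid}.tsv")
    metadata = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "fit": final.params,
        "stage_counts": {"candidates_pre_roh": pre_roh,
                         "candidates_post_roh": post_roh},
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(final.summary() + "\n")
    return {"results": final, "metadata": metadata,
            "candidates": final.candidates}
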