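import numpy as np
import pandas as pd
import pytest

from splicedx.io import AbundanceTable, JunctionTable
from splicedx.models import GeneModel, TranscriptModel, build_genes
from splicedx.quant import compute_cpm


@pytest.fixture
def toy_transcript():
    """Two-exon plus-strand transcript: exons 100-200 and 301-400."""
    return TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="1", strand="+",
        exons=((100, 200), (301, 400)))


@pytest.fixture
def toy_gene(toy_transcript):
    return build_genes([toy_transcript])["G1"]


@pytest.fixture
def three_exon_gene():
    """Plus-strand gene with exons 100-200, 301-400, 501-600 and a CDS
    leaving 10 bp UTR at each end."""
    t = TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="1", strand="+",
        exons=((100, 200), (301, 400), (501, 600)),
        cds=((110, 200), (301, 400), (501, 590)))
    return build_genes([t])["G1"]


def make_junction_table(rows, sample_id="S1", coverage=None):
    """rows: (chrom, start, end, strand, unique_reads, annotated)."""
    df = pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end",
                                     "strand", "unique_reads", "annotated"])
    cov = None
    if coverage is not None:
        cov = pd.DataFrame(coverage, columns=["chrom", "intron_start",
                                              "intron_end", "nonsplit_reads"])
    return JunctionTable(sample_id, df, cov)


def make_abundance(counts: dict, sample_id="S1"):
    df = pd.DataFrame({"transcript_id": list(counts),
                       "est_count": [float(v) for v in counts.values()]})
    df["cpm"] = compute_cpm(df["est_count"].to_numpy())
    return AbundanceTable(sample_id, df)


@pytest.fixture
def small_cohort():
    """Small seeded cohort with one injected exon-skip aberration."""
    from splicedx.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(seed=11, n_genes=60, n_controls=8, n_patients=3)
    return simulate_cohort(cfg, aberration_kind="exon_skip", severity=5.0)


@pytest.fixture
def cohort_profiles(small_cohort):
    from splicedx.quant import compute_omega_profile

    return {
        sid: compute_omega_profile(small_cohort.genes,
                                   small_cohort.abundances[sid],
                                   small_cohort.junctions[sid])
        for sid in small_cohort.abundances
    }
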