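import numpy as np
import pandas as pd
import pytest

from splicedx.models import ValidationError
from splicedx.quant import compute_omega_profile
from splicedx.simulate import (AberrationSpec, SimulationConfig,
                               generate_gene_models, generate_roh,
                               gene_expression_means, inject_aberration,
                               pick_causal_gene, simulate_cohort, write_gtf)


@pytest.fixture(scope="module")
def cfg():
    return SimulationConfig(seed=5, n_genes=40, n_controls=5, n_patients=2)


@pytest.fixture(scope="module")
def genes(cfg):
    return generate_gene_models(cfg)


class TestGeneModels:
    def test_gene_count_conserved(self, cfg, genes):
        assert len(genes) == cfg.n_genes

    def test_deterministic_gtf(self, cfg, genes, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(genes, p1)
        write_gtf(generate_gene_models(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gtf_reads_back_identically(self, genes, tmp_path):
        from splicedx.io import read_gene_models

        p = tmp_path / "sim.gtf"
        write_gtf(genes, p)
        back = read_gene_models(p)
        assert set(back) == set(genes)
        gid = sorted(genes)[0]
        assert {t.exons for t in back[gid].transcripts.values()} == \
               {t.exons for t in genes[gid].transcripts.values()}

    def test_single_transcript_config(self):
        cfg = SimulationConfig(seed=1, n_genes=10, transcripts_per_gene=(1, 1))
        genes = generate_gene_models(cfg)
        assert all(len(g.transcripts) == 1 for g in genes.values())

    def test_nonoverlapping_spans(self, genes):
        spans = sorted(g.span for g in genes.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(seed=1, n_genes=100, chrom_length=10_000)
        with pytest.raises(ValidationError, match="packing"):
            generate_gene_models(cfg)


class TestCohortSimulation:
    def test_same_seed_identical_different_seed_not(self, cfg):
        a = simulate_cohort(cfg, aberration_kind=None)
        b = simulate_cohort(cfg, aberration_kind=None)
        sid = a.samples[0].sample_id
        pd.testing.assert_frame_equal(a.abundances[sid].data,
                                      b.abundances[sid].data)
        c = simulate_cohort(SimulationConfig(seed=6, n_genes=40, n_controls=5,
                                             n_patients=2),
                            aberration_kind=None)
        assert not a.abundances[sid].data["est_count"].equals(
            c.abundances[sid].data["est_count"])

    def test_control_omega_close_to_total(self, cfg):
        """Controls carry only annotated junctions, so ω tracks Σx up to
        annotated-isoform competition."""
        cohort = simulate_cohort(cfg, aberration_kind=None)
        sid = cohort.controls[0].sample_id
        prof = compute_omega_profile(cohort.genes, cohort.abundances[sid],
                                     cohort.junctions[sid])
        assert (prof.genes["omega"] <= prof.genes["total_cpm"] + 1e-9).all()
        single = prof.genes[prof.genes["n_transcripts"] == 1]
        expressed = single[~single["not_expressed"]]
        assert np.allclose(expressed["omega"], expressed["total_cpm"])

    def test_mean_expression_matches_configured_lognormal(self):
        cfg = SimulationConfig(seed=9, n_genes=400, n_controls=2, n_patients=1)
        genes = generate_gene_models(cfg)
        means = gene_expression_means(genes, cfg)
        log_gene_means = np.log(means.groupby("gene_id")["mean_expr"].sum())
        se = cfg.log_sd / np.sqrt(cfg.n_genes)
        assert abs(log_gene_means.mean() - cfg.log_mean) < 3 * se * 2

    def test_control_rins_pass_qc(self, cfg):
        cohort = simulate_cohort(cfg, aberration_kind=None)
        assert all(s.rin >= 8.0 for s in cohort.controls)
        assert all(s.rin >= 6.0 for s in cohort.patients)


class TestInjection:
    def test_low_abundance_divides_counts(self, cfg):
        cohort = simulate_cohort(cfg, aberration_kind=None)
        sid = cohort.patients[0].sample_id
        genes = cohort.genes
        rng = np.random.default_rng(0)
        gid = pick_causal_gene(genes, "low_abundance", rng)
        spec = AberrationSpec(gid, "low_abundance", 10.0, sid)
        ab0 = cohort.abundances[sid]
        ab1, _, truth = inject_aberration(ab0, cohort.junctions[sid], genes, spec)
        tids = set(genes[gid].transcripts)
        before = ab0.data[ab0.data["transcript_id"].isin(tids)]["est_count"].sum()
        after = ab1.data[ab1.data["transcript_id"].isin(tids)]["est_count"].sum()
        assert after == pytest.approx(before / 10)
        assert truth["expected_driver"] == "alpha"

    def test_exon_skip_reduces_rho_by_severity(self, cfg):
        cohort = simulate_cohort(cfg, aberration_kind="exon_skip", severity=5.0)
        truth = cohort.truths[0]
        sid = truth["carrier_sample_id"]
        prof = compute_omega_profile(cohort.genes, cohort.abundances[sid],
                                     cohort.junctions[sid])
        control = compute_omega_profile(cohort.genes,
                                        cohort.abundances["C001"],
                                        cohort.junctions["C001"])
        gid = truth["gene_id"]
        assert prof.genes.loc[gid, "rho"] <= control.genes.loc[gid, "rho"] / 3

    def test_intron_retention_adds_nonsplit_evidence(self, cfg):
        cohort = simulate_cohort(cfg, aberration_kind="intron_retention",
                                 severity=5.0)
        truth = cohort.truths[0]
        sid = truth["carrier_sample_id"]
        jt = cohort.junctions[sid]
        assert jt.coverage is not None and len(jt.coverage) == 1
        prof = compute_omega_profile(cohort.genes, cohort.abundances[sid], jt)
        assert prof.genes.loc[truth["gene_id"], "rho"] < 0.35

    def test_severity_at_most_one_rejected(self):
        with pytest.raises(ValidationError, match="severity"):
            AberrationSpec("G1", "exon_skip", 1.0, "P1")

    def test_exon_skip_on_intronless_gene_rejected(self):
        cfg = SimulationConfig(seed=2, n_genes=5, exons_per_transcript=(1, 1),
                               n_controls=2, n_patients=1)
        cohort = simulate_cohort(cfg, aberration_kind=None)
        sid = cohort.samples[0].sample_id
        spec = AberrationSpec(sorted(cohort.genes)[0], "exon_skip", 5.0, sid)
        with pytest.raises(ValidationError, match="skippable|intronless"):
            inject_aberration(cohort.abundances[sid], cohort.junctions[sid],
                              cohort.genes, spec)


class TestRoh:
    def test_causal_gene_always_covered(self, genes):
        for seed in range(10):
            gid = sorted(genes)[seed % len(genes)]
            roh = generate_roh(genes, gid, n_decoy_intervals=3, seed=seed)
            s, e = genes[gid].span
            assert roh.contains(genes[gid].chrom, s - 1, e)

    def test_zero_decoys_single_interval(self, genes):
        gid = sorted(genes)[0]
        roh = generate_roh(genes, gid, n_decoy_intervals=0, seed=1)
        assert len(roh) == 1

    def test_decoys_avoid_other_genes(self, genes):
        gid = sorted(genes)[3]
        roh = generate_roh(genes, gid, n_decoy_intervals=5, seed=2)
        covered = [g for g, m in genes.items()
                   if roh.overlaps(m.chrom, m.span[0] - 1, m.span[1])]
        assert covered == [gid]
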