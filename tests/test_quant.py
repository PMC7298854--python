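import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicedx.models import TranscriptModel, ValidationError, build_genes
from splicedx.quant import (JunctionIndex, compute_cpm, compute_omega_profile,
                            filter_junctions, junction_support, omega, rho,
                            transcript_normal_rate)

from conftest import make_abundance, make_junction_table


class TestCpm:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 1, 2), (250000, 250000, 500000)),
        ((0, 0), (0, 0)),
        ((3, 7), (300000, 700000)),
    ])
    def test_definition(self, counts, expected):
        assert np.allclose(compute_cpm(np.array(counts, float)), expected)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            compute_cpm(np.array([-1.0, 2.0]))

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_sums_to_million(self, counts):
        cpm = compute_cpm(np.array(counts))
        if sum(counts) > 0:
            assert np.isclose(cpm.sum(), 1e6, rtol=1e-6)
        else:
            assert cpm.sum() == 0


class TestFilterJunctions:
    def test_below_threshold_removed_boundary_retained(self):
        t = make_junction_table([("1", 201, 300, "+", 4, True),
                                 ("1", 500, 600, "+", 5, True)])
        kept = filter_junctions(t, 5)
        assert list(kept.data["unique_reads"]) == [5]

    def test_zero_threshold_is_identity(self):
        t = make_junction_table([("1", 201, 300, "+", 1, True)])
        assert len(filter_junctions(t, 0).data) == 1

    def test_coverage_rows_untouched(self):
        t = make_junction_table([("1", 201, 300, "+", 1, True)],
                                coverage=[("1", 201, 300, 99)])
        kept = filter_junctions(t, 5)
        assert len(kept.data) == 0
        assert kept.coverage.iloc[0].nonsplit_reads == 99


class TestJunctionSupport:
    def test_competing_donor_reads(self, toy_transcript):
        # a=95 matching, c=5 sharing the donor coordinate
        t = make_junction_table([("1", 201, 300, "+", 95, True),
                                 ("1", 201, 350, "+", 5, False)])
        s = junction_support((201, 300), toy_transcript, t)
        assert s == pytest.approx(0.95)

    def test_no_evidence_gives_one(self, toy_transcript):
        t = make_junction_table([])
        assert junction_support((201, 300), toy_transcript, t) == 1.0

    def test_all_aberrant_gives_zero(self, toy_transcript):
        t = make_junction_table([("1", 150, 300, "+", 10, False)])
        assert junction_support((201, 300), toy_transcript, t) == 0.0

    def test_nonsplit_reads_count_against(self, toy_transcript):
        t = make_junction_table([("1", 201, 300, "+", 80, True)],
                                coverage=[("1", 201, 300, 20)])
        assert junction_support((201, 300), toy_transcript, t) == pytest.approx(0.8)

    def test_not_an_intron_is_contract_violation(self, toy_transcript):
        t = make_junction_table([])
        with pytest.raises(ValidationError, match="not an intron"):
            junction_support((100, 200), toy_transcript, t)


class TestNormalRate:
    def test_min_rule(self):
        t = TranscriptModel("T", "G", "1", "+",
                            exons=((1, 10), (21, 30), (41, 50)))
        jt = make_junction_table([("1", 11, 20, "+", 100, True),
                                  ("1", 31, 40, "+", 95, True),
                                  ("1", 31, 60, "+", 5, False)])
        idx = JunctionIndex(jt)
        assert transcript_normal_rate(t, idx) == pytest.approx(0.95)

    def test_intronless_is_one(self):
        t = TranscriptModel("T", "G", "1", "+", exons=((1, 10),))
        assert transcript_normal_rate(t, JunctionIndex(make_junction_table([]))) == 1.0

    def test_zero_support_zeroes_transcript(self):
        t = TranscriptModel("T", "G", "1", "+", exons=((1, 10), (21, 30)))
        jt = make_junction_table([("1", 11, 25, "+", 10, False)])
        assert transcript_normal_rate(t, JunctionIndex(jt)) == 0.0

    def test_product_rule_multiplies(self):
        t = TranscriptModel("T", "G", "1", "+",
                            exons=((1, 10), (21, 30), (41, 50)))
        jt = make_junction_table([("1", 11, 20, "+", 90, True),
                                  ("1", 11, 25, "+", 10, False),
                                  ("1", 31, 40, "+", 80, True),
                                  ("1", 31, 45, "+", 20, False)])
        idx = JunctionIndex(jt)
        assert transcript_normal_rate(t, idx, "product") == pytest.approx(0.9 * 0.8)
        assert transcript_normal_rate(t, idx, "min") == pytest.approx(0.8)


class TestOmegaRho:
    def test_direct_formula(self, toy_gene):
        assert omega(toy_gene, {"T1": 0.5}, {"T1": 50.0}) == pytest.approx(25.0)

    def test_rho_division_and_flags(self):
        assert rho(125.0, 150.0) == (pytest.approx(125 / 150), False)
        assert rho(0.0, 0.0) == (0.0, True)

    def test_missing_transcript_counts_zero(self, toy_gene):
        assert omega(toy_gene, {"T1": 1.0}, {}) == 0.0


def _brute_force_omega(gene, cpm, junction_rows, coverage_rows, min_support=5):
    """Independent recomputation: enumerate each intron's read partition
    directly from the raw row lists."""
    rows = [r for r in junction_rows if r[4] >= min_support]
    total = 0.0
    for t in gene.transcripts.values():
        supports = []
        for (s, e) in t.introns:
            a = sum(r[4] for r in rows
                    if (r[0], r[1], r[2]) == (t.chrom, s, e))
            c = sum(r[4] for r in rows
                    if (r[0], r[1], r[2]) != (t.chrom, s, e)
                    and r[0] == t.chrom and (r[1] == s or r[2] == e))
            r_ns = sum(cv[3] for cv in coverage_rows
                       if (cv[0], cv[1], cv[2]) == (t.chrom, s, e))
            denom = a + c + r_ns
            supports.append(1.0 if denom == 0 else a / denom)
        w = min(supports) if supports else 1.0
        total += w * cpm.get(t.transcript_id, 0.0)
    return total


class TestOracleEquivalence:
    def test_omega_matches_brute_force_enumeration(self):
        """Pipeline ω equals an independent per-junction enumeration on
        small multi-isoform genes with competing and nonsplit evidence."""
        t1 = TranscriptModel("T1", "G", "1", "+",
                             exons=((1, 10), (21, 30), (41, 50)))
        t2 = TranscriptModel("T2", "G", "1", "+", exons=((1, 10), (41, 50)))
        t3 = TranscriptModel("T3", "G", "1", "+", exons=((1, 10), (21, 30)))
        gene = build_genes([t1, t2, t3])["G"]
        rng = np.random.default_rng(0)
        for _ in range(50):
            rows = []
            for (s, e) in {(11, 20), (31, 40), (11, 40), (11, 35), (25, 40)}:
                reads = int(rng.integers(0, 60))
                if reads:
                    rows.append(("1", s, e, "+", reads, True))
            coverage = []
            if rng.random() < 0.5:
                coverage.append(("1", 11, 20, int(rng.integers(0, 30))))
            counts = {tid: float(rng.integers(0, 100)) for tid in ("T1", "T2", "T3")}
            ab = make_abundance(counts)
            jt = make_junction_table(rows, coverage=coverage or None)
            prof = compute_omega_profile({"G": gene}, ab, jt, coding_only=False)
            cpm = ab.cpm_series().to_dict()
            expected = _brute_force_omega(gene, cpm, rows, coverage)
            assert prof.genes.loc["G", "omega"] == pytest.approx(expected)


class TestConservation:
    def test_omega_bounded_by_total_cpm(self, small_cohort, cohort_profiles):
        for prof in cohort_profiles.values():
            g = prof.genes
            assert (g["omega"] >= -1e-9).all()
            assert (g["omega"] <= g["total_cpm"] * (1 + 1e-9) + 1e-9).all()
            assert ((g["rho"] >= 0) & (g["rho"] <= 1 + 1e-12)).all()

    def test_rho_one_when_only_annotated_matching_support(self):
        """Single-isoform cohort: every junction's evidence matches the
        annotated junction, so ρ = 1 on expressed genes."""
        from splicedx.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(seed=3, n_genes=30, n_controls=2, n_patients=1,
                               transcripts_per_gene=(1, 1))
        cohort = simulate_cohort(cfg, aberration_kind=None)
        sid = cohort.samples[0].sample_id
        prof = compute_omega_profile(cohort.genes, cohort.abundances[sid],
                                     cohort.junctions[sid])
        expressed = prof.genes[~prof.genes["not_expressed"]]
        assert np.allclose(expressed["rho"], 1.0)

    def test_monotone_in_matching_reads(self, toy_gene):
        """Increasing a_j (c, r held) never decreases ω."""
        last = -1.0
        for a in (0, 5, 10, 40, 80):
            rows = [("1", 201, 350, "+", 10, False)]
            if a:
                rows.append(("1", 201, 300, "+", a, True))
            prof = compute_omega_profile(
                {"G1": toy_gene}, make_abundance({"T1": 100}),
                make_junction_table(rows), coding_only=False)
            om = prof.genes.loc["G1", "omega"]
            assert om >= last - 1e-12
            last = om
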