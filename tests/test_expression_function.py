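"""FPKM arithmetic, Pearson correlation, multiple-testing corrections
against step-up enumeration oracles, hypergeometric enrichment against a
full draw-enumeration oracle, co-expression edge recovery, and the
read-containment counting rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lncseeker.expression_function import (
    assign_reads_to_genes,
    bh_fdr,
    bonferroni,
    build_coexpression,
    compute_fpkm,
    go_enrichment,
    hypergeom_upper_tail,
    pearson_r_p,
    predict_function,
)
from lncseeker.models import GenomeInterval


class TestFpkm:
    def test_unit_definition(self):
        assert compute_fpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_fragments(self):
        assert compute_fpkm(0, 1000, 10**6) == 0.0

    def test_direct_arithmetic(self):
        assert compute_fpkm(5, 500, 2 * 10**6) == pytest.approx(5.0)

    def test_zero_length_or_total_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            compute_fpkm(1, 1000, 0)


class TestPearson:
    def test_identical_vectors(self):
        r, _p, und = pearson_r_p([1, 2, 3, 4], [1, 2, 3, 4])
        assert not und and r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2.5; cov 4; sds sqrt(5) each -> r = 4/5
        r, p, _ = pearson_r_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        # two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = 2
        from scipy import stats
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, df=2), rel=1e-6)

    def test_perfect_anticorrelation(self):
        r, _p, _ = pearson_r_p([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        res = pearson_r_p([1, 1, 1], [1, 2, 3])
        assert res.undefined and res.r is None and res.p is None

    def test_affine_invariance_sign(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        for a in (2.5, -0.3):
            r, _p, _ = pearson_r_p(x, a * x + 1.0)
            assert r == pytest.approx(math.copysign(1.0, a))
        assert abs(pearson_r_p(x, rng.normal(size=10)).r) <= 1.0


def _oracle_bh(p):
    """Step-up enumeration: q(i) = min_{j>=i} p(j)*m/j, input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(1.0, running)
    return q


class TestCorrections:
    def test_worked_bh_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_bonferroni_caps_at_one(self):
        assert bonferroni([0.3, 0.01, 0.2, 0.4])[0] == 1.0
        assert bonferroni([0.01, 0.3, 0.2, 0.4])[0] == pytest.approx(0.04)

    def test_bh_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 40))).tolist()
            assert np.allclose(bh_fdr(p), _oracle_bh(p))

    def test_bh_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        perm = rng.permutation(25)
        assert np.allclose(bh_fdr(p[perm]), q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bonferroni([-0.1])


def _oracle_upper_tail(k, K, n, N):
    """Enumerate all C(N, n) draws from a labelled population."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestHypergeom:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 4, 3, 10) == pytest.approx(1.0)

    def test_enumerated_example(self):
        # k=2, K=4, n=3, N=10: 40/120
        assert hypergeom_upper_tail(2, 4, 3, 10) == \
            pytest.approx(_oracle_upper_tail(2, 4, 3, 10)) == \
            pytest.approx(1 / 3)

    def test_forced_outcome(self):
        assert hypergeom_upper_tail(3, 10, 3, 10) == pytest.approx(1.0)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 3, 10)

    def test_full_enumeration_sweep_small_populations(self):
        """Agreement with draw enumeration for every parameter combination
        with N <= 12."""
        for N in range(1, 13):
            for n in range(0, N + 1):
                for K in range(0, N + 1):
                    # enumerate once per (N, K, n); check every k
                    population = [1] * K + [0] * (N - K)
                    counts = [0] * (n + 2)
                    total = 0
                    for draw in itertools.combinations(range(N), n):
                        total += 1
                        counts[sum(population[i] for i in draw)] += 1
                    for k in range(0, n + 1):
                        expected = sum(counts[k:]) / total
                        assert hypergeom_upper_tail(k, K, n, N) == \
                            pytest.approx(expected, abs=1e-12)


class TestCoexpression:
    def _matrix(self, seed=4, n_samples=10):
        rng = np.random.default_rng(seed)
        target = rng.lognormal(2, 1, n_samples)
        rows = {"lnc1": target}
        for i in range(5):  # planted partners
            rows[f"pc{i}"] = 1.5 * target + rng.normal(0, 0.01, n_samples)
        for i in range(10):  # background
            rows[f"bg{i}"] = rng.lognormal(2, 1, n_samples)
        return pd.DataFrame(rows).T

    def test_planted_block_recovered(self):
        m = self._matrix()
        coding = [r for r in m.index if r != "lnc1"]
        edges = build_coexpression(["lnc1"], coding, m)
        partners = {e.coding_id for e in edges}
        assert {f"pc{i}" for i in range(5)} <= partners
        # per-pair direct computation agrees on r and p
        for e in edges:
            r, p, _ = pearson_r_p(m.loc[e.lnc_id], m.loc[e.coding_id])
            assert e.r == pytest.approx(r, abs=1e-9)
            assert e.p == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_impossible_r_threshold_empty(self):
        m = self._matrix()
        assert build_coexpression(["lnc1"], ["pc0"], m,
                                  r_threshold=1.01) == []

    def test_single_pair_q_equals_p(self):
        m = self._matrix()
        (edge,) = build_coexpression(["lnc1"], ["pc0"], m, q_threshold=1.1,
                                     r_threshold=0.0)
        assert edge.q == pytest.approx(edge.p)

    def test_constant_row_skipped_with_warning(self, caplog):
        import logging
        m = self._matrix()
        m.loc["flat"] = 3.0
        with caplog.at_level(logging.WARNING,
                             logger="lncseeker.expression_function"):
            edges = build_coexpression(["lnc1"], ["pc0", "flat"], m,
                                       q_threshold=1.1, r_threshold=0.0)
        assert {e.coding_id for e in edges} == {"pc0"}
        assert any("flat" in rec.message for rec in caplog.records)


class TestEnrichment:
    def test_planted_term_ranks_first(self):
        # 10 of 12 partners share T; background frequency 20/200
        population = [f"g{i}" for i in range(200)]
        ann = {}
        for i, g in enumerate(population):
            ann[g] = {"GO:other%d" % (i % 7)}
            if i < 20:
                ann[g].add("GO:T")
        partners = population[:10] + population[150:152]
        rows = go_enrichment(partners, ann, population)
        assert rows[0].go_term == "GO:T"
        assert rows[0].k == 10 and rows[0].K == 20
        assert rows[0].p == pytest.approx(
            hypergeom_upper_tail(10, 20, 12, 200))

    def test_universal_term_not_significant(self):
        population = [f"g{i}" for i in range(20)]
        ann = {g: {"GO:ALL"} for g in population}
        rows = go_enrichment(population[:5], ann, population)
        assert rows[0].p == pytest.approx(1.0)

    def test_partner_set_equal_population_all_p_one(self):
        population = [f"g{i}" for i in range(10)]
        ann = {g: {"GO:A"} if int(g[1:]) % 2 else {"GO:B"}
               for g in population}
        for row in go_enrichment(population, ann, population):
            assert row.p == pytest.approx(1.0)

    def test_empty_partner_set_empty_result(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING,
                             logger="lncseeker.expression_function"):
            assert go_enrichment([], {"g": {"GO:A"}}, ["g"]) == []

    def test_partners_must_be_subset_of_population(self):
        with pytest.raises(ValueError):
            go_enrichment(["x"], {"x": {"GO:A"}}, ["g"])


def _iv(start, end, strand="+", chrom="chr1"):
    return GenomeInterval(chrom, start, end, strand)


class TestReadAssignment:
    GENES = [(_iv(50, 200), "gA"), (_iv(100, 400), "gB"),
             (_iv(50, 200, "-"), "gC")]

    def test_contained_read_counts(self):
        counts = assign_reads_to_genes([_iv(100, 120)], self.GENES)
        assert counts["gA"] == 1

    def test_overhanging_read_not_counted(self):
        counts = assign_reads_to_genes([_iv(190, 210)], self.GENES)
        assert counts["gA"] == 0 and counts["gB"] == 1

    def test_opposite_strand_not_counted(self):
        counts = assign_reads_to_genes([_iv(100, 120, "-")], self.GENES)
        assert counts["gA"] == 0 and counts["gC"] == 1

    def test_multi_containment_counts_once_per_gene(self):
        counts = assign_reads_to_genes([_iv(120, 150)], self.GENES)
        assert counts["gA"] == 1 and counts["gB"] == 1

    def test_matches_brute_force_assigner(self):
        rng = np.random.default_rng(8)
        genes = [(_iv(int(s), int(s) + int(rng.integers(50, 300)),
                      "+" if rng.random() < 0.5 else "-"), f"g{i}")
                 for i, s in enumerate(rng.integers(0, 5000, size=40))]
        reads = [_iv(int(s), int(s) + int(rng.integers(20, 120)),
                     "+" if rng.random() < 0.5 else "-")
                 for s in rng.integers(0, 5200, size=300)]
        counts = assign_reads_to_genes(reads, genes)
        for giv, gid in genes:
            expected = sum(
                1 for r in reads
                if r.strand == giv.strand and r.chrom == giv.chrom
                and giv.start <= r.start and r.end <= giv.end)
            assert counts[gid] == expected


def test_end_to_end_function_prediction_on_fixture(bundle):
    edges, enrichment = predict_function(
        bundle.target_lnc, bundle.expression,
        bundle.coding_expression_ids, bundle.go_annotation)
    assert {e.coding_id for e in edges} >= set(bundle.partner_ids[:4])
    assert enrichment[0].go_term == bundle.spec.planted_go_term
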