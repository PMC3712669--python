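"""The architecture-matched permutation machinery."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import pathperm as pp
from pathperm.permutation import (
    GenomeFeaturePool,
    PoolExhaustedError,
    count_significant,
    empirical_p,
    investigate,
    permutation_test,
    sample_matched_null,
)
from pathperm.types import FeatureSet, LdBlock, PathwayArchitecture, SnpRecord


def _feature_fixture(n_simple=123, n_complex=122, sig_simple=15, sig_complex=24,
                     block_size=3, alpha=0.05):
    """Feature set + p-values with exact significant-feature counts."""
    simple = tuple(f"s{i}" for i in range(n_simple))
    complex_feats = tuple(
        tuple(f"c{i}_{j}" for j in range(block_size)) for i in range(n_complex)
    )
    pvals = {}
    for i, s in enumerate(simple):
        pvals[s] = alpha / 2 if i < sig_simple else (1 + alpha) / 2
    for i, members in enumerate(complex_feats):
        for j, m in enumerate(members):
            sig = i < sig_complex and j == 0
            pvals[m] = alpha / 2 if sig else (1 + alpha) / 2
    return FeatureSet("pathway", simple, complex_feats), pvals


class TestCounting:
    def test_paper_style_count(self):
        fs, pvals = _feature_fixture()
        assert count_significant(fs, pvals, alpha=0.05) == 39

    def test_all_null_pvalues(self):
        fs, _ = _feature_fixture()
        pvals = {s: 1.0 for s in fs.snps}
        assert count_significant(fs, pvals) == 0

    def test_alpha_sweep_monotone(self):
        rng = np.random.default_rng(4)
        fs, _ = _feature_fixture(n_simple=30, n_complex=20)
        pvals = {s: float(rng.random()) for s in fs.snps}
        counts = [count_significant(fs, pvals, alpha=a)
                  for a in np.linspace(0.01, 0.10, 10)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_missing_pvalues_use_available_members(self):
        fs = FeatureSet("g", ("a",), (("b", "c"),))
        # complex feature scored from its one known member; the simple
        # feature with no p-value is dropped
        assert count_significant(fs, {"b": 0.01}) == 1
        assert count_significant(fs, {"c": 0.9}) == 0


class TestEmpiricalP:
    def test_six_in_thousand_is_exactly_0006(self):
        nulls = np.r_[np.full(6, 40), np.full(994, 10)]
        assert empirical_p(39, nulls) == 0.006

    def test_ties_not_counted_as_exceedance(self):
        nulls = np.r_[np.full(10, 39), np.full(990, 5)]
        assert empirical_p(39, nulls) == 0.0

    def test_corrected_estimator(self):
        nulls = np.r_[np.full(6, 40), np.full(994, 10)]
        assert empirical_p(39, nulls, estimator="corrected") == pytest.approx(7 / 1001)


def _pool(n_simple=5, complex_sizes=(3, 3, 3, 3, 3)):
    simple = tuple(f"ps{i}" for i in range(n_simple))
    complex_feats = tuple(
        tuple(f"pc{i}_{j}" for j in range(k)) for i, k in enumerate(complex_sizes)
    )
    return GenomeFeaturePool(simple=simple, complex=complex_feats)


class TestNullSampling:
    def test_forced_draw_when_pool_exactly_matches(self):
        pool = _pool(n_simple=2, complex_sizes=(3,))
        arch = PathwayArchitecture(n_simple=2, complex_sizes=(3,))
        rng = np.random.default_rng(0)
        for _ in range(10):
            draw = sample_matched_null(arch, pool, rng)
            assert sorted(draw.simple) == sorted(pool.simple)
            assert draw.complex == pool.complex

    def test_architecture_matched_exactly_without_fallback(self):
        pool = _pool(n_simple=10, complex_sizes=(2, 2, 3, 3, 4, 4, 4))
        arch = PathwayArchitecture(n_simple=4, complex_sizes=(2, 3, 4, 4))
        rng = np.random.default_rng(1)
        for _ in range(50):
            draw = sample_matched_null(arch, pool, rng)
            assert draw.architecture == arch

    def test_sampling_without_replacement_within_draw(self):
        pool = _pool(n_simple=3, complex_sizes=(3, 3))
        arch = PathwayArchitecture(n_simple=3, complex_sizes=(3, 3))
        rng = np.random.default_rng(2)
        draw = sample_matched_null(arch, pool, rng)
        assert len(set(draw.simple)) == 3
        assert len(set(draw.complex)) == 2

    def test_size_fallback_and_strict_mode(self):
        pool = _pool(n_simple=3, complex_sizes=(6, 6))
        arch = PathwayArchitecture(n_simple=1, complex_sizes=(7,))
        rng = np.random.default_rng(3)
        draw = sample_matched_null(arch, pool, rng)
        assert len(draw.complex[0]) == 6  # nearest available size
        with pytest.raises(PoolExhaustedError, match="size 7"):
            sample_matched_null(arch, pool, rng, strict=True)

    def test_pool_exhausted_error_names_size(self):
        pool = _pool(n_simple=3, complex_sizes=(2,))
        arch = PathwayArchitecture(n_simple=1, complex_sizes=(9,))
        with pytest.raises(PoolExhaustedError, match="size 9"):
            sample_matched_null(arch, pool, np.random.default_rng(4), strict=False)

    def test_draw_frequencies_uniform_on_tiny_pool(self):
        """Exhaustive enumeration oracle: architecture (2 simple, {3})
        over a 10-feature pool has C(5,2) x 5 = 50 equally likely draws;
        a chi-square goodness-of-fit over 50,000 draws must not reject."""
        pool = _pool(n_simple=5, complex_sizes=(3, 3, 3, 3, 3))
        arch = PathwayArchitecture(n_simple=2, complex_sizes=(3,))
        expected_draws = [
            (frozenset(c), frozenset(pool.complex[k]))
            for c in itertools.combinations(pool.simple, 2)
            for k in range(5)
        ]
        assert len(expected_draws) == 50
        rng = np.random.default_rng(5)
        counts = Counter()
        n_draws = 50_000
        for _ in range(n_draws):
            d = sample_matched_null(arch, pool, rng)
            counts[(frozenset(d.simple), frozenset(d.complex[0]))] += 1
        assert set(counts) <= set(expected_draws)
        observed = np.array([counts.get(k, 0) for k in expected_draws])
        stat, p = stats.chisquare(observed)
        assert p > 0.01


class TestPermutationTest:
    def test_identical_seed_reproduces_null_counts(self):
        fs, pvals = _feature_fixture(n_simple=5, n_complex=4, sig_simple=2,
                                     sig_complex=1)
        pool = _pool(n_simple=30, complex_sizes=tuple([3] * 20))
        rng = np.random.default_rng(8)
        for s in pool.simple:
            pvals[s] = float(rng.random())
        for c in pool.complex:
            for m in c:
                pvals[m] = float(rng.random())
        a = permutation_test(fs, pvals, pool, n_perm=200, seed=77)
        b = permutation_test(fs, pvals, pool, n_perm=200, seed=77)
        assert a.null_counts == b.null_counts
        assert a.p_value == b.p_value

    def test_zero_observed_under_hot_pool(self):
        """Observed count 0 against a pool where every feature is
        significant: every null draw exceeds it, p = 1."""
        fs = FeatureSet("cold", ("a", "b"), ())
        pool = _pool(n_simple=20, complex_sizes=())
        pvals = {"a": 1.0, "b": 1.0}
        pvals.update({s: 0.001 for s in pool.simple})
        res = permutation_test(fs, pvals, pool, n_perm=100, seed=1)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_n_perm_validation(self):
        fs, pvals = _feature_fixture(n_simple=2, n_complex=0)
        pool = _pool()
        with pytest.raises(ValueError):
            permutation_test(fs, pvals, pool, n_perm=0)

    def test_untestable_empty_feature_set(self):
        fs = FeatureSet("empty", (), ())
        res = permutation_test(fs, {}, _pool(), n_perm=50, seed=0)
        assert not res.testable


class TestInvestigate:
    def _setup(self):
        g1, p1 = _feature_fixture(n_simple=3, n_complex=2, sig_simple=1,
                                  sig_complex=1)
        g1 = FeatureSet("GENE1", g1.simple, g1.complex)
        g2 = FeatureSet("GENE2", ("x1", "x2"), ())
        pvals = dict(p1)
        pvals.update({"x1": 1.0, "x2": 1.0})
        pool = _pool(n_simple=40, complex_sizes=tuple([3] * 15))
        rng = np.random.default_rng(10)
        for s in pool.simple:
            pvals[s] = float(rng.random())
        for c in pool.complex:
            for m in c:
                pvals[m] = float(rng.random())
        return {"GENE1": g1, "GENE2": g2}, pvals, pool

    def test_per_gene_determinism(self):
        genes, pvals, pool = self._setup()
        r1, t1 = investigate(genes, pvals, pool, n_perm=100, seed=9)
        r2, t2 = investigate(genes, pvals, pool, n_perm=100, seed=9)
        for g in genes:
            assert r1[g].null_counts == r2[g].null_counts
        assert t1.equals(t2)

    def test_all_null_gene_has_high_p(self):
        genes, pvals, pool = self._setup()
        res, _ = investigate(genes, pvals, pool, n_perm=200, seed=9)
        g2 = res["GENE2"]
        assert g2.observed == 0
        # p equals the fraction of null draws with any significant feature
        frac = np.mean([c > 0 for c in g2.null_counts])
        assert g2.p_value == pytest.approx(frac)

    def test_snp_table_groups_by_gene(self):
        genes, pvals, pool = self._setup()
        _, table = investigate(genes, pvals, pool, n_perm=50, seed=9)
        assert set(table["GENE"]) == {"GENE1", "GENE2"}
        sub = table[table["GENE"] == "GENE2"]
        assert sorted(sub["SNP"]) == ["x1", "x2"]

    def test_zero_feature_gene_untestable(self):
        genes, pvals, pool = self._setup()
        genes["EMPTY"] = FeatureSet("EMPTY", (), ())
        res, _ = investigate(genes, pvals, pool, n_perm=50, seed=9)
        assert not res["EMPTY"].testable


class TestPoolBuild:
    def test_pathway_features_excluded(self):
        snps = [SnpRecord(f"s{i}", "1", 100 * (i + 1), "A", "G", 0.3)
                for i in range(8)]
        blocks = [LdBlock("1", ("s0", "s1"), 100, 200),
                  LdBlock("1", ("s2", "s3"), 300, 400)]
        pool = GenomeFeaturePool.build(snps, blocks, exclude_snps={"s0", "s4"})
        assert "s4" not in pool.simple
        assert ("s0", "s1") not in pool.complex  # block touching exclusion dropped
        assert ("s2", "s3") in pool.complex

    def test_x_exclusion(self):
        snps = [SnpRecord("a", "1", 100, "A", "G", 0.3),
                SnpRecord("b", "X", 100, "A", "G", 0.3),
                SnpRecord("c", "X", 200, "A", "G", 0.3)]
        blocks = [LdBlock("X", ("b", "c"), 100, 200)]
        pool = GenomeFeaturePool.build(snps, blocks, include_x=False)
        assert pool.simple == ("a",)
        assert pool.complex == ()
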