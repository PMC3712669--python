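"""Generator checks: LD structure, genotype support, disease model."""

import numpy as np
import pytest
from scipy import stats

import pathperm as pp
from pathperm.ld import pairwise_r2, panel_blocks


def _block_r2_values(panel):
    """Realized pairwise r^2 within every ground-truth block."""
    vals = []
    ids = {s.id: i for i, s in enumerate(panel.snps)}
    for b in panel.blocks_truth:
        idx = [ids[s] for s in b.snps]
        r2 = np.corrcoef(panel.haplotypes[:, idx].T) ** 2
        iu = np.triu_indices(len(idx), k=1)
        vals.extend(r2[iu])
    return np.array(vals)


class TestReferencePanel:
    def test_flip_rate_hits_target_r2(self):
        """Mean realized within-block r^2 lands within 0.1 of the target,
        measured by direct correlation of the generated haplotypes."""
        cfg = pp.PanelConfig(
            n_haplotypes=1000, n_chromosomes=4, blocks_per_chromosome=10,
            block_size_range=(3, 5), singleton_fraction=0.2,
            within_block_r2=0.8, include_x=False, seed=5,
        )
        panel = pp.generate_reference_panel(cfg)
        assert abs(_block_r2_values(panel).mean() - 0.8) < 0.1

    def test_all_singletons_yield_no_blocks(self):
        cfg = pp.PanelConfig(
            n_haplotypes=500, n_chromosomes=2, blocks_per_chromosome=20,
            singleton_fraction=1.0, include_x=False, seed=6,
        )
        panel = pp.generate_reference_panel(cfg)
        assert panel.blocks_truth == []
        assert panel_blocks(panel, threshold=0.8) == []

    def test_perfect_ld_block_columns_identical(self):
        cfg = pp.PanelConfig(
            n_haplotypes=200, n_chromosomes=1, blocks_per_chromosome=1,
            block_size_range=(3, 3), singleton_fraction=0.0,
            within_block_r2=1.0, include_x=False, seed=7,
        )
        panel = pp.generate_reference_panel(cfg)
        h = panel.haplotypes
        assert h.shape[1] == 3
        assert np.array_equal(h[:, 0], h[:, 1])
        assert np.array_equal(h[:, 0], h[:, 2])

    def test_genotype_support_and_frequencies(self, small_panel):
        rng = np.random.default_rng(0)
        geno = small_panel.draw_genotypes(400, rng)
        assert set(np.unique(geno)) <= {0, 1, 2}
        freq = geno.mean(axis=0) / 2.0
        lo, hi = small_panel.config.maf_range
        assert (freq >= lo - 0.06).all() and (freq <= hi + 0.06).all()

    def test_identical_seeds_reproduce(self):
        cfg = pp.PanelConfig(n_haplotypes=300, n_chromosomes=3,
                             blocks_per_chromosome=5, seed=11)
        a = pp.generate_reference_panel(cfg)
        b = pp.generate_reference_panel(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.snps == b.snps
        assert a.blocks_truth == b.blocks_truth

    def test_block_finder_recovers_ground_truth(self):
        """Jaccard overlap >= 0.9 between recovered and true blocks at
        high within-block r^2 and ample haplotypes."""
        cfg = pp.PanelConfig(
            n_haplotypes=600, n_chromosomes=4, blocks_per_chromosome=8,
            within_block_r2=0.95, include_x=False, seed=13,
        )
        panel = pp.generate_reference_panel(cfg)
        found = panel_blocks(panel, threshold=0.8)
        truth = {frozenset(b.snps) for b in panel.blocks_truth}
        est = {frozenset(b.snps) for b in found}
        jaccard = len(truth & est) / len(truth | est)
        assert jaccard >= 0.9

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            pp.PanelConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            pp.PanelConfig(maf_range=(0.1, 0.6))
        with pytest.raises(ValueError):
            pp.PanelConfig(block_size_range=(1, 4))
        with pytest.raises(ValueError):
            pp.PanelConfig(singleton_fraction=1.2)


class TestCohorts:
    def test_exact_case_control_counts(self, small_panel):
        cfg = pp.CohortConfig(n_cases=123, n_controls=77, seed=21)
        study = pp.generate_cohort(small_panel, cfg)
        assert study.n_cases == 123
        assert study.n_controls == 77

    def test_unknown_causal_snp_rejected(self, small_panel):
        cfg = pp.CohortConfig(causal=(pp.CausalEffect("nope", 0.4),), seed=1)
        with pytest.raises(ValueError, match="nope"):
            pp.generate_cohort(small_panel, cfg)

    def test_infeasible_quota_fails_with_message(self, small_panel):
        cfg = pp.CohortConfig(n_cases=50, n_controls=50,
                              baseline_logit=-40.0, seed=2)
        with pytest.raises(RuntimeError, match="infeasible"):
            pp.generate_cohort(small_panel, cfg)

    def test_male_x_genotypes_hemizygous(self, small_panel):
        study = pp.generate_cohort(
            small_panel, pp.CohortConfig(n_cases=100, n_controls=100, seed=23)
        )
        xcols = np.array([s.chrom == "X" for s in study.snps])
        males = study.sex == "male"
        assert xcols.any() and males.any()
        x_geno = study.genotypes[np.ix_(np.where(males)[0], np.where(xcols)[0])]
        assert set(np.unique(x_geno)) <= {0, 2}

    def test_null_pvalues_uniform(self):
        """With all effects zero, per-SNP p-values are uniform: KS against
        U(0,1) passes at the 1% level and ~5% fall below 0.05."""
        cfg = pp.PanelConfig(
            n_haplotypes=400, n_chromosomes=1, blocks_per_chromosome=100,
            block_size_range=(2, 8), singleton_fraction=1.0,
            include_x=False, seed=31,
        )
        panel = pp.generate_reference_panel(cfg)
        study = pp.generate_cohort(
            panel, pp.CohortConfig(n_cases=300, n_controls=300, seed=32)
        )
        res = pp.trend_scan(study.genotypes, study.status)
        pvals = res["P"].dropna().to_numpy()
        assert len(pvals) >= 450
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert abs((pvals < 0.05).mean() - 0.05) < 0.03

    def test_effect_recovery_within_three_se(self):
        """A simulated log OR of ln(1.5) is recovered by the logistic fit
        within three standard errors at n = 2,000/2,000."""
        cfg = pp.PanelConfig(
            n_haplotypes=500, n_chromosomes=1, blocks_per_chromosome=4,
            singleton_fraction=1.0, include_x=False, seed=41,
        )
        panel = pp.generate_reference_panel(cfg)
        target = float(np.log(1.5))
        snp = panel.snps[2].id
        study = pp.generate_cohort(
            panel,
            pp.CohortConfig(
                n_cases=2000, n_controls=2000,
                causal=(pp.CausalEffect(snp, target),), seed=42,
            ),
        )
        j = panel.index_of([snp])[0]
        res = pp.logistic_association(
            study.genotypes[:, j], study.status, study.covariate_frame()
        )
        assert res.ok
        assert abs(res.beta - target) < 3 * res.se


class TestAnnotations:
    def test_default_pathway_shape(self, small_panel):
        ann, pathway = pp.generate_annotations(
            small_panel,
            pathway_spec=pp.PathwaySpec(n_genes=23, n_x_genes=2,
                                        snps_per_gene=(2, 4)),
            seed=50,
        )
        assert len(pathway.genes) == 23
        by_symbol = {g.symbol: g for g in ann}
        x_genes = [g for g in pathway.genes if by_symbol[g].chrom == "X"]
        assert len(x_genes) == 2
        assert set(x_genes) == {"ARSD", "STS"}  # canonical X-linked members
        # every pathway gene window holds at least one genotyped SNP
        for g in pathway.genes:
            mapped = pp.map_snps_to_gene(small_panel.snps, by_symbol[g],
                                         flank=pathway.flank)
            assert mapped

    def test_seeded_annotations_reproduce(self, small_panel):
        spec = pp.PathwaySpec(n_genes=5, n_x_genes=1, snps_per_gene=(3, 6))
        a1, p1 = pp.generate_annotations(small_panel, pathway_spec=spec, seed=8)
        a2, p2 = pp.generate_annotations(small_panel, pathway_spec=spec, seed=8)
        assert a1 == a2 and p1 == p2
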