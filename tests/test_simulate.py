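"""Simulator: haplotype pools, gene dropping, liability-threshold phenotypes."""
import numpy as np
import pytest
from scipy import stats

from hrhm.simulate import (
    SimConfig,
    HaplotypePool,
    simulate_haplotype_pool,
    gene_drop,
    simulate_phenotype,
    simulate_dataset,
    ibd_sharing,
)
from hrhm.grm import compute_grm
from hrhm.panel import qc_filter


def test_seed_determinism():
    cfg = SimConfig(n_families=5, n_unrelated=20, n_blocks=3, snps_per_block=5,
                    hg2_region=0.1, hg2_polygenic=0.1, prevalence=0.3, seed=42)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert np.array_equal(a[0].panel.dosages, b[0].panel.dosages)
    assert a[1].equals(b[1])
    assert a[2].var_region == b[2].var_region


class TestHaplotypePool:
    def test_frequencies_sum_to_one_and_polymorphic(self):
        cfg = SimConfig(n_unrelated=10, n_blocks=5, snps_per_block=7, seed=1)
        pool = simulate_haplotype_pool(cfg)
        for b in range(5):
            assert abs(pool.frequencies[b].sum() - 1.0) < 1e-12
            p = pool.snp_freqs(b)
            assert ((p > 0) & (p < 1)).all()

    def test_two_haplotypes_one_snp_frequency(self):
        pool = HaplotypePool(
            [np.array([[0], [1]], dtype=np.uint8)], [np.array([0.5, 0.5])]
        )
        pool.validate()
        assert pool.snp_freqs(0)[0] == 0.5

    def test_monomorphic_pool_rejected(self):
        pool = HaplotypePool(
            [np.array([[1, 0], [1, 0]], dtype=np.uint8)], [np.array([0.5, 0.5])]
        )
        with pytest.raises(ValueError, match="monomorphic block"):
            pool.validate()

    def test_sampled_r2_matches_pool_r2(self):
        """Empirical LD on sampled haplotypes equals exhaustive pool computation."""
        cfg = SimConfig(n_unrelated=10, n_blocks=1, snps_per_block=9,
                        haplotypes_per_block_pool=8, seed=7)
        pool = simulate_haplotype_pool(cfg)
        h, f = pool.haplotypes[0], pool.frequencies[0]
        rng = np.random.default_rng(7)
        sample = h[rng.choice(len(f), size=10_000, p=f)].astype(float)

        def r2(x_freqs, hmat):
            p = x_freqs @ hmat
            cov = (x_freqs[:, None] * hmat).T @ hmat - np.outer(p, p)
            denom = np.sqrt(np.outer(p * (1 - p), p * (1 - p)))
            return (cov / denom) ** 2

        exact = r2(f, h.astype(float))
        emp = np.corrcoef(sample.T) ** 2
        iu = np.triu_indices(9, 1)
        assert np.abs(exact[iu] - emp[iu]).max() < 0.02


class TestGeneDrop:
    def test_homozygous_parents_give_homozygous_offspring(self):
        cfg = SimConfig(n_families=30, family_size=5, n_unrelated=0, n_blocks=2,
                        snps_per_block=4, haplotypes_per_block_pool=2, seed=3)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        idx = gdr.hap_pool_idx
        for fam in range(cfg.n_families):
            base = fam * cfg.family_size
            for b in range(2):
                if (idx[base, b] == idx[base, b, 0]).all() and (
                    idx[base + 1, b] == idx[base, b, 0]
                ).all():
                    # both parents homozygous for the same pool haplotype
                    for child in range(base + 2, base + cfg.family_size):
                        assert (idx[child, b] == idx[base, b, 0]).all()

    def test_full_sib_sharing_mean_and_sd(self):
        """Mean IBD sharing ~0.5 across blocks; per-block variance matches 1/8."""
        cfg = SimConfig(n_families=1, family_size=4, n_unrelated=0, n_blocks=2000,
                        snps_per_block=1, haplotypes_per_block_pool=2, seed=5)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        share = ibd_sharing(gdr, 2, 3)  # the two sibs
        B = len(share)
        assert abs(share.mean() - 0.5) < 4 * np.sqrt(0.125 / B)
        assert abs(share.var() - 0.125) < 0.02

    def test_unrelated_grm_off_diagonal_near_zero(self):
        cfg = SimConfig(n_unrelated=150, n_blocks=60, snps_per_block=10, seed=8)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        panel = qc_filter(gdr.panel, maf_min=0.01, missing_max=1.0)
        grm = compute_grm(panel)
        off = grm.matrix[np.triu_indices(grm.n, 1)]
        se = off.std() / np.sqrt(len(off))
        # sample-frequency centering forces a structural -1/(n-1) offset
        assert abs(off.mean()) < 1 / (grm.n - 1) + 3 * se
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.05


class TestPhenotype:
    def test_null_trait_independent_of_genotype(self):
        """With no genetic variance, case status is independent of the causal block."""
        cfg = SimConfig(n_unrelated=300, n_blocks=4, snps_per_block=5, hg2_region=0.0,
                        hg2_polygenic=0.0, prevalence=0.4, seed=10)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(30):
            covars, _, _ = simulate_phenotype(gdr, cfg, rng)
            y = covars["pheno"].to_numpy()
            x = gdr.panel.dosages[:, gdr.block_members[0][0]]
            table = np.zeros((2, 3))
            for yy, xx in zip(y, x.astype(int)):
                table[yy, xx] += 1
            table = table[:, table.sum(0) > 0]
            pvals.append(stats.chi2_contingency(table)[1])
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.2

    def test_balanced_prevalence(self):
        cfg = SimConfig(n_unrelated=2000, n_blocks=2, snps_per_block=4, prevalence=0.5,
                        seed=11)
        _, covars, truth, _ = simulate_dataset(cfg)
        se = np.sqrt(0.25 / 2000)
        assert abs(truth.realized_prevalence - 0.5) <= 3 * se

    def test_realized_prevalence_matches_k(self):
        cfg = SimConfig(n_unrelated=3000, n_blocks=3, snps_per_block=4, prevalence=0.13,
                        hg2_polygenic=0.3, seed=12)
        _, covars, truth, _ = simulate_dataset(cfg)
        se = np.sqrt(0.13 * 0.87 / 3000)
        assert abs(truth.realized_prevalence - 0.13) <= 3 * se

    def test_ascertainment_hits_target_fraction(self):
        cfg = SimConfig(n_unrelated=4000, n_blocks=2, snps_per_block=4, prevalence=0.1,
                        ascertainment=0.5, seed=13)
        _, covars, truth, keep = simulate_dataset(cfg)
        assert abs(covars["pheno"].mean() - 0.5) < 0.02
        assert len(keep) < 4000

    def test_unreachable_ascertainment_errors(self):
        cfg = SimConfig(n_unrelated=50, n_blocks=2, snps_per_block=4, prevalence=0.01,
                        ascertainment=0.9, seed=14)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        with pytest.raises(ValueError, match="unreachable"):
            # realized cases will be ~0 at K=0.01, n=50
            simulate_phenotype(gdr, cfg, np.random.default_rng(0))

    def test_liability_regression_slope_one(self):
        """Regressing the liability on the true genetic value recovers slope 1."""
        cfg = SimConfig(n_unrelated=3000, n_blocks=10, snps_per_block=8, hg2_region=0.2,
                        hg2_polygenic=0.3, phenotype_scale="liability", seed=15)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        rng = np.random.default_rng(15)
        covars, truth, _ = simulate_phenotype(gdr, cfg, rng)
        from hrhm.grm import standardized_dosages

        freqs = gdr.panel.allele_freqs()
        causal = gdr.block_members[0]
        causal = causal[(freqs[causal] > 0) & (freqs[causal] < 1)]
        g = standardized_dosages(gdr.panel, causal) @ np.asarray(truth.snp_effects)
        y = covars["pheno"].to_numpy(float)
        slope = np.cov(y, g)[0, 1] / np.var(g)
        assert abs(slope - 1.0) < 3 * np.sqrt((1 - 0.2) / (0.2 * 3000)) + 0.05

    def test_invalid_variance_budget_rejected(self):
        with pytest.raises(ValueError, match="< 1"):
            SimConfig(hg2_region=0.6, hg2_polygenic=0.5).validate()
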