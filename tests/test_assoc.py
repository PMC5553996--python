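"""Mixed-model association, EM phasing, haplotype tests, Bonferroni."""
import numpy as np
import pytest
from scipy import stats

from hrhm.assoc import (
    MixedModelAssoc,
    mlma,
    mlma_block,
    bonferroni,
    phase_block_em,
    haplotype_assoc,
)
from hrhm.grm import split_region, threshold_kin
from hrhm.reml import REMLResult

from conftest import make_panel

# the seven common-haplotype p-values printed for the hit block (inputs)
TABLE2_P = [2.47e-6, 5.77e-5, 6.10e-2, 1.24e-1, 4.60e-1, 5.05e-1, 5.59e-1]


def _null_fit(sigma2, n_comp=2):
    s = np.asarray(sigma2, dtype=float)
    return REMLResult(
        sigma2=s, se_sigma2=np.zeros_like(s), cov_sigma2=np.zeros((len(s), len(s))),
        beta=np.zeros(1), se_beta=np.zeros(1), loglik=0.0, converged=True, n_iter=0,
        names=[f"V{i}" for i in range(len(s))],
    )


class TestMlma:
    def test_zero_variance_components_equal_ols(self):
        """With V proportional to I the GLS estimate collapses to OLS."""
        rng = np.random.default_rng(0)
        n = 50
        x = rng.binomial(2, 0.3, n).astype(float)
        X = np.ones((n, 1))
        y = 0.4 * x + rng.standard_normal(n)
        import statsmodels.api as sm

        ols = sm.OLS(y, np.column_stack([X, x])).fit()
        K = np.zeros((n, n))
        rec = mlma(y, X, x, [K], null_fit=_null_fit([0.0, float(ols.mse_resid)]))
        assert abs(rec.beta - ols.params[1]) < 1e-10
        assert abs(rec.se_beta - ols.bse[1]) < 1e-10
        # point estimate is V-scale invariant
        rec2 = mlma(y, X, x, [K], null_fit=_null_fit([0.0, 1.0]))
        assert abs(rec2.beta - ols.params[1]) < 1e-10

    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(1)
        n = 20
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        x = rng.binomial(2, 0.4, n).astype(float)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        s = [0.7, 0.5]
        rec = mlma(y, X, x, [K], null_fit=_null_fit(s))
        V = s[0] * K + s[1] * np.eye(n)
        Vi = np.linalg.inv(V)
        Amat = np.column_stack([X, x])
        cov = np.linalg.inv(Amat.T @ Vi @ Amat)
        coef = cov @ (Amat.T @ Vi @ y)
        assert abs(rec.beta - coef[-1]) < 1e-10
        assert abs(rec.se_beta - np.sqrt(cov[-1, -1])) < 1e-10

    def test_monomorphic_dosage_rejected(self):
        n = 10
        with pytest.raises(ValueError, match="monomorphic"):
            mlma(np.zeros(n), np.ones((n, 1)), np.full(n, 2.0), [np.zeros((n, n))],
                 null_fit=_null_fit([0.0, 1.0]))

    def test_indefinite_v_reports_smallest_eigenvalue(self):
        n = 6
        K = -np.eye(n) * 10
        with pytest.raises(ValueError, match="smallest eigenvalue"):
            MixedModelAssoc(np.zeros(n), np.ones((n, 1)), [K], null_fit=_null_fit([1.0, 0.1]))

    def test_significant_snps_tag_one_haplotype_in_high_ld(self):
        """When one block haplotype is causal, the associated SNPs are in mutual LD."""
        from hrhm.simulate import SimConfig, simulate_haplotype_pool, gene_drop

        cfg = SimConfig(n_unrelated=800, n_blocks=3, snps_per_block=9,
                        haplotypes_per_block_pool=2, seed=77)
        gdr = gene_drop(cfg, simulate_haplotype_pool(cfg))
        rng = np.random.default_rng(77)
        copies = (gdr.hap_pool_idx[:, 0, :] == 0).sum(axis=1).astype(float)
        y = (0.6 * (copies - copies.mean()) + rng.standard_normal(len(copies)) > 0.5)
        y = y.astype(float)
        X = np.ones((len(y), 1))
        members = gdr.block_members[0]
        freqs = gdr.panel.allele_freqs()
        members = members[(freqs[members] > 0) & (freqs[members] < 1)]
        K0 = np.zeros((len(y), len(y)))
        df = mlma_block(y, X, gdr.panel, members, [K0],
                        null_fit=_null_fit([0.0, float(np.var(y))]))
        sig = df[df["p_adj"] < 0.05]["target"].tolist()
        assert len(sig) >= 2
        cols = [gdr.panel.snps.index[gdr.panel.snps["id"] == t][0] for t in sig]
        r2 = np.corrcoef(gdr.panel.dosages[:, cols].T) ** 2
        iu = np.triu_indices(len(cols), 1)
        assert np.median(r2[iu]) > 0.8

    def test_within_family_permutation_null_uniform(self, family_sim, family_panel_qc):
        """Permuting phenotypes within families keeps MLMA p-values uniform.

        Families are permuted internally and the unrelated singletons among
        themselves, preserving the relatedness structure the mixed model
        absorbs.
        """
        _, gdr, covars, _ = family_sim
        panel, blockset = family_panel_qc
        y = covars["pheno"].to_numpy(float)
        X = np.ones((len(y), 1))
        _, cgrm = split_region(panel, blockset, "B1")
        kin = threshold_kin(cgrm)
        engine = MixedModelAssoc(y, X, [cgrm, kin])
        x = panel.dosages[:, blockset.members_of("B1")[0]]
        fids = panel.samples["fid"].to_numpy()
        groups = [np.flatnonzero(fids == f) for f in np.unique(fids)]
        singles = np.concatenate([g for g in groups if len(g) == 1])
        families = [g for g in groups if len(g) > 1]
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(400):
            perm = np.arange(len(y))
            perm[singles] = rng.permutation(singles)
            for idx in families:
                perm[idx] = rng.permutation(idx)
            pvals.append(engine.test(x, phenotype=y[perm]).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestBonferroni:
    def test_printed_worked_examples(self):
        assert f"{bonferroni(2.47e-6, 7):.3g}" == "1.73e-05"
        assert f"{bonferroni(5.77e-5, 7):.3g}" == "0.000404"

    def test_cap_at_one(self):
        assert bonferroni(0.5, 7) == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 3)

    def test_exactly_two_significant_haplotypes(self):
        adj = bonferroni(TABLE2_P, 7)
        assert int((adj < 0.05).sum()) == 2


class TestPhaseEm:
    def test_homozygous_individual_single_diplotype(self, family_panel_qc):
        panel, blockset = family_panel_qc
        members = blockset.members_of("B0")[:4]
        table = phase_block_em(panel, members)
        G = panel.dosages[:, members]
        hom = np.flatnonzero((G != 1).all(axis=1))
        assert hom.size > 0
        for i in hom[:10]:
            assert table.dosages[i].max() == pytest.approx(2.0)

    def test_two_snp_em_matches_independent_implementation(self):
        """Fixed-point equality with a from-scratch two-locus EM."""
        rng = np.random.default_rng(13)
        n = 300
        h = rng.random(2 * n) < 0.6
        b = np.where(rng.random(2 * n) < 0.8, h, rng.random(2 * n) < 0.5)
        ga = (h[::2].astype(float) + h[1::2])
        gb = (b[::2].astype(float) + b[1::2])
        panel = make_panel(np.column_stack([ga, gb]))
        table = phase_block_em(panel, [0, 1], tol=1e-12)

        # independent EM over the four two-locus haplotypes
        f = np.full(4, 0.25)  # order: 11, 10, 01, 00
        counts = np.zeros((3, 3))
        np.add.at(counts, (ga.astype(int), gb.astype(int)), 1)
        for _ in range(10_000):
            dh = counts[1, 1]
            w11 = f[0] * f[3]
            w10 = f[1] * f[2]
            frac = w11 / (w11 + w10)
            c = np.zeros(4)
            c[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + dh * frac
            c[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + dh * (1 - frac)
            c[2] = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + dh * (1 - frac)
            c[3] = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1] + dh * frac
            f_new = c / (2 * n)
            if np.abs(f_new - f).max() < 1e-14:
                break
            f = f_new
        want = {"AA": f[0], "AG": f[1], "GA": f[2], "GG": f[3]}
        got = dict(zip(table.haplotypes, table.frequencies))
        for hap, freq in want.items():
            if freq > 1e-9:
                assert abs(got.get(hap, 0.0) - freq) < 1e-8

    def test_recovers_simulator_truth_frequencies(self):
        from hrhm.simulate import SimConfig, simulate_haplotype_pool, gene_drop

        cfg = SimConfig(n_unrelated=2000, n_blocks=1, snps_per_block=9,
                        haplotypes_per_block_pool=6, seed=17)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        table = phase_block_em(gdr.panel, gdr.block_members[0], tol=1e-8)
        idx = gdr.hap_pool_idx[:, 0, :].ravel()
        truth_freq = np.bincount(idx, minlength=6) / len(idx)
        a1 = gdr.panel.snps["a1"].to_numpy()
        a2 = gdr.panel.snps["a2"].to_numpy()
        truth_strings = {
            "".join(a1[j] if h[j] else a2[j] for j in range(9)): tf
            for h, tf in zip(pool.haplotypes[0], truth_freq)
        }
        est = dict(zip(table.haplotypes, table.frequencies))
        for hap, tf in truth_strings.items():
            assert abs(est.get(hap, 0.0) - tf) < 0.01

    def test_block_too_large_rejected(self, family_panel_qc):
        panel, _ = family_panel_qc
        with pytest.raises(ValueError, match="partition-ligation"):
            phase_block_em(panel, np.arange(min(30, panel.n_snps)), max_snps=25)


class TestHaplotypeAssoc:
    def test_frequency_filter_and_mass_conservation(self, family_sim, family_panel_qc):
        _, gdr, covars, _ = family_sim
        panel, blockset = family_panel_qc
        y = covars["pheno"].to_numpy(float)
        X = np.ones((len(y), 1))
        _, cgrm = split_region(panel, blockset, "B0")
        table = phase_block_em(panel, blockset.members_of("B0"))
        assert np.abs(table.dosages.sum(axis=1) - 2.0).max() < 1e-8
        df = haplotype_assoc(y, X, table, [cgrm], freq_min=0.01)
        assert (df["freq"] >= 0.01).all()
        np.testing.assert_allclose(df["p_adj"], np.minimum(1, len(df) * df["p"]))
        np.testing.assert_allclose(df["odds_ratio"], np.exp(df["logor"]), rtol=5e-4)

    def test_complementary_haplotypes_opposite_effects(self):
        """A causal haplotype and its complement show opposite-signed betas."""
        from hrhm.simulate import SimConfig, simulate_haplotype_pool, gene_drop

        cfg = SimConfig(n_unrelated=1500, n_blocks=2, snps_per_block=6,
                        haplotypes_per_block_pool=2, seed=19)
        pool = simulate_haplotype_pool(cfg)
        gdr = gene_drop(cfg, pool)
        rng = np.random.default_rng(19)
        # risk liability carried by copies of pool haplotype 0 of block 0
        copies = (gdr.hap_pool_idx[:, 0, :] == 0).sum(axis=1).astype(float)
        y = (0.5 * (copies - copies.mean()) + rng.standard_normal(len(copies)) > 0.3)
        y = y.astype(float)
        X = np.ones((len(y), 1))
        table = phase_block_em(gdr.panel, gdr.block_members[0])
        cgrm_mat = np.zeros((len(y), len(y)))
        df = haplotype_assoc(y, X, table, [cgrm_mat], null_fit=_null_fit([0.0, float(np.var(y))]))
        assert len(df) == 2
        betas = df.sort_values("freq")["beta"].to_numpy()
        assert betas[0] * betas[1] < 0

    def test_no_common_haplotype_errors(self, family_sim, family_panel_qc):
        _, gdr, covars, _ = family_sim
        panel, blockset = family_panel_qc
        y = covars["pheno"].to_numpy(float)
        table = phase_block_em(panel, blockset.members_of("B0"))
        with pytest.raises(ValueError, match="frequency"):
            haplotype_assoc(y, np.ones((len(y), 1)), table, [np.zeros((len(y),) * 2)],
                            freq_min=0.99, null_fit=_null_fit([0.0, 1.0]))
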