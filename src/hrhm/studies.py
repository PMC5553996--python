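"""Repeatable simulation studies: LRT calibration, recovery, liability round-trip.

Each study fixes a small number of gene-dropped genotype panels and redraws
phenotypes, so the expensive eigendecomposition of the background GRM is paid
once per panel while the Monte-Carlo replication runs through the fast
rotated REML kernel. Study sizes are chosen to keep a full run on one CPU in
the low minutes; docs/methods.md records the designs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimConfig, simulate_haplotype_pool, gene_drop, simulate_phenotype
from .grm import standardized_dosages
from .reml import _LowRankModel, _reml_driver, lrt_region
from .effects import observed_to_liability


@dataclass
class _RotatedPanel:
    """One gene-dropped panel with the background GRM eigendecomposed."""

    gdr: object
    lam_bg: np.ndarray  # eigenvalues of the complement (or whole) GRM
    Q: np.ndarray
    U_region: np.ndarray | None  # rotated low-rank factor of the regional GRM


def _prepare_panel(config: SimConfig, region_block: int | None) -> _RotatedPanel:
    pool = simulate_haplotype_pool(config)
    gdr = gene_drop(config, pool)
    panel = gdr.panel
    freqs = panel.allele_freqs()
    poly = (freqs > 0) & (freqs < 1)
    if region_block is not None:
        causal = gdr.block_members[region_block]
        bg_idx = np.setdiff1d(np.flatnonzero(poly), causal)
        region_idx = causal[poly[causal]]
    else:
        bg_idx = np.flatnonzero(poly)
        region_idx = None
    Zc = standardized_dosages(panel, bg_idx)
    Kc = (Zc @ Zc.T) / Zc.shape[1]
    lam, Q = np.linalg.eigh(Kc)
    lam = np.clip(lam, 0.0, None)
    U = None
    if region_idx is not None and region_idx.size:
        F = standardized_dosages(panel, region_idx) / np.sqrt(region_idx.size)
        U = Q.T @ F
    return _RotatedPanel(gdr, lam, Q, U)


def _fit_rotated(yt, Xt, lam, U, with_region: bool, vp: float, tol=1e-8, max_iter=100):
    comps = [(lam, 0.0)]
    if with_region:
        comps.append((None, 1.0))
    model = _LowRankModel(yt, Xt, comps, U=U if with_region else None)
    init = np.full(len(comps) + 1, vp / (len(comps) + 1))
    return _reml_driver(model, init, max_iter=max_iter, tol=tol)


def lrt_null_calibration(
    n_panels: int = 10,
    reps_per_panel: int = 100,
    seed: int = 0,
    n_families: int = 100,
    family_size: int = 4,
    n_unrelated: int = 100,
    n_blocks: int = 40,
    snps_per_block: int = 12,
    hg2_polygenic: float = 0.25,
    prevalence: float = 0.13,
) -> np.ndarray:
    """Two-GRM boundary-LRT p-values for null blocks in a family sample.

    The tested block carries no genetic effect (hg2_region = 0) while a
    polygenic background and the family structure are present, so the
    p-values probe the 50:50 boundary-mixture null.
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for ip in range(n_panels):
        cfg = SimConfig(
            n_families=n_families, family_size=family_size, n_unrelated=n_unrelated,
            n_blocks=n_blocks, snps_per_block=snps_per_block, causal_block_index=0,
            hg2_region=0.0, hg2_polygenic=hg2_polygenic, prevalence=prevalence,
            exact_scale=False, seed=int(rng.integers(2**31 - 1)),
        )
        rp = _prepare_panel(cfg, region_block=0)
        n = rp.gdr.panel.n_individuals
        Xt = rp.Q.T @ np.ones((n, 1))
        for _ in range(reps_per_panel):
            covars, _, _ = simulate_phenotype(rp.gdr, cfg, rng)
            y = covars["pheno"].to_numpy(float)
            yt = rp.Q.T @ y
            vp = float(np.var(y))
            full = _fit_rotated(yt, Xt, rp.lam_bg, rp.U_region, True, vp)
            null = _fit_rotated(yt, Xt, rp.lam_bg, rp.U_region, False, vp)
            _, p = lrt_region(full.loglik, null.loglik)
            pvals.append(p)
    return np.asarray(pvals)


def regional_recovery(
    n_panels: int = 4,
    reps_per_panel: int = 50,
    seed: int = 0,
    n_unrelated: int = 2000,
    n_blocks: int = 50,
    snps_per_block: int = 10,
    var_region: float = 0.05,
    var_polygenic: float = 0.20,
) -> np.ndarray:
    """Two-GRM REML estimates of a known regional variance on the analysis scale.

    The phenotype is Gaussian with the genetic components drawn from the
    exact mixed-model law (per-SNP effects N(0, sigma^2/m)), so the true
    regional variance equals ``var_region`` on the scale being analysed.
    """
    rng = np.random.default_rng(seed)
    estimates = []
    for ip in range(n_panels):
        cfg = SimConfig(
            n_families=0, n_unrelated=n_unrelated, n_blocks=n_blocks,
            snps_per_block=snps_per_block, causal_block_index=0,
            hg2_region=var_region, hg2_polygenic=var_polygenic,
            phenotype_scale="liability", exact_scale=False,
            seed=int(rng.integers(2**31 - 1)),
        )
        rp = _prepare_panel(cfg, region_block=0)
        n = rp.gdr.panel.n_individuals
        Xt = rp.Q.T @ np.ones((n, 1))
        for _ in range(reps_per_panel):
            covars, _, _ = simulate_phenotype(rp.gdr, cfg, rng)
            y = covars["pheno"].to_numpy(float)
            yt = rp.Q.T @ y
            fit = _fit_rotated(yt, Xt, rp.lam_bg, rp.U_region, True, float(np.var(y)))
            estimates.append(fit.sigma2[1])  # regional component
    return np.asarray(estimates)


def liability_roundtrip(
    n_panels: int = 4,
    reps_per_panel: int = 25,
    seed: int = 0,
    n_unrelated: int = 2000,
    n_blocks: int = 50,
    snps_per_block: int = 10,
    h2_liab: float = 0.30,
    prevalence: float = 0.134,
) -> np.ndarray:
    """Estimate a liability-scale polygenic h2 from a thresholded binary trait.

    Whole-genome REML on the 0/1 phenotype gives an observed-scale fraction
    that is mapped back to the liability scale with the threshold-model
    factor at the generating prevalence; returns the per-replicate
    liability-scale estimates.
    """
    rng = np.random.default_rng(seed)
    out = []
    for ip in range(n_panels):
        cfg = SimConfig(
            n_families=0, n_unrelated=n_unrelated, n_blocks=n_blocks,
            snps_per_block=snps_per_block, hg2_region=0.0, hg2_polygenic=h2_liab,
            prevalence=prevalence, exact_scale=False,
            seed=int(rng.integers(2**31 - 1)),
        )
        rp = _prepare_panel(cfg, region_block=None)
        n = rp.gdr.panel.n_individuals
        Xt = rp.Q.T @ np.ones((n, 1))
        for _ in range(reps_per_panel):
            covars, _, _ = simulate_phenotype(rp.gdr, cfg, rng)
            y = covars["pheno"].to_numpy(float)
            yt = rp.Q.T @ y
            fit = _fit_rotated(yt, Xt, rp.lam_bg, None, False, float(np.var(y)))
            h2_obs = float(fit.sigma2[0] / fit.sigma2.sum())
            P = float(y.mean())
            out.append(observed_to_liability(h2_obs, prevalence, P))
    return np.asarray(out)
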