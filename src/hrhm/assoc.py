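"""Localized association tests inside a significant block.

Single-SNP and haplotype-dosage tests follow the mixed-linear-model
association (MLMA) convention: variance components are estimated once under
the null model (no SNP term) with the complement GRM and its
kinship-thresholded version as random effects, then every SNP or haplotype is
tested as a fixed effect by generalized least squares with that covariance
held fixed. Haplotypes are phased within the block by an EM algorithm over
the diplotypes consistent with each unphased genotype.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .grm import GRM
from .reml import fit_reml, REMLResult
from .effects import linear_to_logit


@dataclass
class AssocRecord:
    """One SNP or haplotype test on the linear (observed) scale plus logit transform."""

    target: str
    a1: str
    a2: str
    freq: float
    beta: float
    se_beta: float
    logor: float
    se_logor: float
    odds_ratio: float
    p: float
    p_adj: float | None = None


def bonferroni(p_values, m: int):
    """Bonferroni adjustment min(1, m * p); m is the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out) if np.isscalar(p_values) or out.ndim == 0 else out


class MixedModelAssoc:
    """GLS association engine with variance components fixed at null REML estimates."""

    def __init__(self, y, X, grms, null_fit: REMLResult | None = None, max_iter=100, tol=1e-8):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != len(self.y):
            self.X = self.X.T
        if null_fit is None:
            null_fit = fit_reml(self.y, self.X, grms, max_iter=max_iter, tol=tol)
        self.null_fit = null_fit
        n = len(self.y)
        V = null_fit.sigma2[-1] * np.eye(n)
        mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float) for g in grms]
        for s, K in zip(null_fit.sigma2[:-1], mats):
            V += s * K
        try:
            self._cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:
            smallest = float(np.linalg.eigvalsh(V)[0])
            raise ValueError(
                f"covariance V is not positive definite (smallest eigenvalue {smallest:.3e})"
            ) from exc
        self.case_fraction = float(self.y.mean())

    def test(self, dosage, target: str = "snp", a1: str = "", a2: str = "",
             phenotype=None) -> AssocRecord:
        """Wald test of one dosage column as a fixed effect.

        ``phenotype`` substitutes an alternative response (e.g. a permuted
        one) while keeping the covariance fixed — the basis of within-family
        permutation calibration checks.
        """
        y = self.y if phenotype is None else np.asarray(phenotype, dtype=float)
        x = np.asarray(dosage, dtype=float).copy()
        finite = ~np.isnan(x)
        if np.nanstd(x) == 0:
            raise ValueError(f"monomorphic dosage for {target}")
        if not finite.all():
            x[~finite] = x[finite].mean()
        A = np.column_stack([self.X, x])
        VA = linalg.cho_solve(self._cf, A)
        AtVA = A.T @ VA
        cov = np.linalg.inv(AtVA)
        coef = cov @ (A.T @ linalg.cho_solve(self._cf, y))
        beta = float(coef[-1])
        se = float(np.sqrt(cov[-1, -1]))
        z = beta / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        logor, se_logor = linear_to_logit(beta, se, self.case_fraction)
        return AssocRecord(
            target=target,
            a1=a1,
            a2=a2,
            freq=float(np.mean(x) / 2.0),
            beta=beta,
            se_beta=se,
            logor=logor,
            se_logor=se_logor,
            odds_ratio=float(np.exp(logor)),
            p=p,
        )


def mlma(y, X, dosage, grms, null_fit=None, target="snp", a1="", a2="") -> AssocRecord:
    """Single mixed-model association test (convenience wrapper)."""
    return MixedModelAssoc(y, X, grms, null_fit=null_fit).test(dosage, target, a1, a2)


def mlma_block(y, X, panel, snp_indices, grms, null_fit=None) -> pd.DataFrame:
    """MLMA for every SNP in a block, Bonferroni-adjusted over the block."""
    engine = MixedModelAssoc(y, X, grms, null_fit=null_fit)
    snp_indices = np.asarray(snp_indices, dtype=int)
    recs = []
    for j in snp_indices:
        meta = panel.snps.iloc[j]
        recs.append(
            engine.test(panel.dosages[:, j], target=meta["id"], a1=meta["a1"], a2=meta["a2"])
        )
    m = len(recs)
    for r in recs:
        r.p_adj = bonferroni(r.p, m)
    return records_to_frame(recs)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# EM haplotype phasing


@dataclass
class HaplotypeTable:
    """Block haplotypes (A1/A2 letter strings), frequencies, expected dosages."""

    haplotypes: list[str]
    alleles01: np.ndarray  # (H, m) A1 indicator rows
    frequencies: np.ndarray
    dosages: np.ndarray  # (n, H) posterior expected copy counts
    n_iter: int

    def validate(self) -> None:
        if abs(self.frequencies.sum() - 1.0) > 1e-8:
            raise ValueError("haplotype frequencies do not sum to 1")
        if np.abs(self.dosages.sum(axis=1) - 2.0).max() > 1e-8:
            raise ValueError("per-individual dosages do not sum to 2")


def _compatible_pairs(row: np.ndarray, hap_ids: dict) -> list[tuple[int, int]]:
    """All unordered haplotype pairs consistent with one unphased genotype row."""
    het = np.flatnonzero(row == 1)
    base = (row // 2).astype(np.uint8)  # 2 -> 1, 0 -> 0 at homozygous sites
    if len(het) > 22:
        raise ValueError("too many heterozygous sites to enumerate diplotypes")

    def hid(hap: np.ndarray) -> int:
        key = hap.tobytes()
        if key not in hap_ids:
            hap_ids[key] = len(hap_ids)
        return hap_ids[key]

    if len(het) == 0:
        h = hid(base)
        return [(h, h)]
    pairs = []
    # fix the phase of the first het site to avoid double counting
    for mask in range(2 ** (len(het) - 1)):
        a, b = base.copy(), base.copy()
        a[het[0]] = 1
        for k, site in enumerate(het[1:]):
            if (mask >> k) & 1:
                a[site] = 1
            else:
                b[site] = 1
        pairs.append((hid(a), hid(b)))
    return pairs


def phase_block_em(
    panel, snp_indices, tol: float = 1e-6, max_iter: int = 5000, max_snps: int = 25
) -> HaplotypeTable:
    """EM haplotype frequency estimation and posterior dosages within a block.

    Genotypes must be complete hard calls; blocks larger than ``max_snps``
    SNPs are rejected (a partition-ligation extension is not implemented).
    """
    snp_indices = np.asarray(snp_indices, dtype=int)
    m = len(snp_indices)
    if m > max_snps:
        raise ValueError(
            f"block has {m} SNPs > {max_snps}: use partition-ligation phasing (not implemented)"
        )
    G = panel.dosages[:, snp_indices]
    if np.isnan(G).any():
        raise ValueError("EM phasing requires complete hard-call genotypes")
    G = G.astype(np.int8)
    n = G.shape[0]
    uniq, inverse, counts = np.unique(G, axis=0, return_inverse=True, return_counts=True)
    hap_ids: dict = {}
    pair_sets = [np.array(_compatible_pairs(row, hap_ids), dtype=int) for row in uniq]
    H = len(hap_ids)
    alleles01 = np.zeros((H, m), dtype=np.uint8)
    for key, idx in hap_ids.items():
        alleles01[idx] = np.frombuffer(key, dtype=np.uint8)

    f = np.full(H, 1.0 / H)
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(H)
        for pairs, cnt in zip(pair_sets, counts):
            a, b = pairs[:, 0], pairs[:, 1]
            w = f[a] * f[b] * np.where(a == b, 1.0, 2.0)
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(w), 1.0 / len(w))
            else:
                w = w / tot
            np.add.at(expected, a, cnt * w)
            np.add.at(expected, b, cnt * w)
        f_new = expected / (2.0 * n)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break

    dos_u = np.zeros((len(uniq), H))
    for i, pairs in enumerate(pair_sets):
        a, b = pairs[:, 0], pairs[:, 1]
        w = f[a] * f[b] * np.where(a == b, 1.0, 2.0)
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(len(w), 1.0 / len(w))
        np.add.at(dos_u[i], a, w)
        np.add.at(dos_u[i], b, w)
    dosages = dos_u[inverse]

    a1 = panel.snps["a1"].to_numpy()[snp_indices]
    a2 = panel.snps["a2"].to_numpy()[snp_indices]
    strings = ["".join(a1[j] if h[j] else a2[j] for j in range(m)) for h in alleles01]
    order = np.argsort(f)[::-1]
    table = HaplotypeTable(
        haplotypes=[strings[i] for i in order],
        alleles01=alleles01[order],
        frequencies=f[order],
        dosages=dosages[:, order],
        n_iter=it,
    )
    table.validate()
    return table


def haplotype_assoc(
    y, X, haplotable: HaplotypeTable, grms, freq_min: float = 0.01, null_fit=None
) -> pd.DataFrame:
    """MLMA-style test of each common haplotype's expected dosage.

    Only haplotypes with estimated frequency >= ``freq_min`` are tested;
    Bonferroni adjustment is over the number of haplotypes actually tested.
    """
    tested = np.flatnonzero(haplotable.frequencies >= freq_min)
    if tested.size == 0:
        raise ValueError(f"no haplotype reaches frequency {freq_min}")
    engine = MixedModelAssoc(y, X, grms, null_fit=null_fit)
    recs = []
    for i in tested:
        recs.append(engine.test(haplotable.dosages[:, i], target=haplotable.haplotypes[i]))
        recs[-1].freq = float(haplotable.frequencies[i])
    m = len(recs)
    for r in recs:
        r.p_adj = bonferroni(r.p, m)
    return records_to_frame(recs)
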