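"""Genomic relationship matrices: whole-genome, regional, complement, kinship.

The estimator is the standard per-SNP standardized cross-product

    A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with allele frequencies p_i computed once on the full analysis sample so that
the regional/complement decomposition satisfies the exact additivity identity
(m_r * rGRM + m_c * cGRM) / (m_r + m_c) = whole-genome GRM.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel

ROLES = ("whole", "rGRM", "cGRM", "cGRM_kin")


@dataclass
class GRM:
    """Symmetric relationship matrix with ids and a role tag."""

    matrix: np.ndarray
    ids: list[str]
    role: str = "whole"
    n_snps: int = 0
    factor: np.ndarray | None = field(default=None, repr=False)
    """Optional low-rank factor Z with matrix == Z @ Z.T (Z has m columns)."""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix must be square")
        if len(self.ids) != n:
            raise ValueError("id list does not match matrix dimension")
        if self.role not in ROLES:
            raise ValueError(f"unknown GRM role {self.role!r}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM matrix is not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def id_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in self.ids:
            parts = str(i).split("\t")
            out.append((parts[0], parts[-1]) if len(parts) > 1 else (str(i), str(i)))
        return out


def standardized_dosages(panel: GenotypePanel, snp_indices=None) -> np.ndarray:
    """(x - 2p) / sqrt(2p(1-p)) with full-panel frequencies, missing -> 0 (mean impute).

    Raises on monomorphic SNPs, naming the first offender.
    """
    if snp_indices is None:
        snp_indices = np.arange(panel.n_snps)
    snp_indices = np.asarray(snp_indices, dtype=int)
    if snp_indices.size == 0:
        raise ValueError("empty SNP subset")
    p = panel.allele_freqs()[snp_indices]
    mono = (p <= 0) | (p >= 1) | np.isnan(p)
    if mono.any():
        bad = panel.snps["id"].iloc[snp_indices[np.flatnonzero(mono)[0]]]
        raise ValueError(f"monomorphic SNP in subset: {bad}")
    x = panel.dosages[:, snp_indices]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    return np.nan_to_num(z, nan=0.0)


def compute_grm(panel: GenotypePanel, snp_indices=None, role: str = "whole") -> GRM:
    """GRM over all panel individuals from the given SNP subset (default: all)."""
    if snp_indices is None:
        snp_indices = np.arange(panel.n_snps)
    snp_indices = np.asarray(snp_indices, dtype=int)
    z = standardized_dosages(panel, snp_indices)
    m = z.shape[1]
    factor = z / np.sqrt(m)
    return GRM(factor @ factor.T, panel.iids, role=role, n_snps=m, factor=factor)


def split_region(panel: GenotypePanel, blockset, block_id) -> tuple[GRM, GRM]:
    """Regional GRM from the block's SNPs and complement GRM from all others."""
    members = blockset.members_of(block_id)
    comp = np.setdiff1d(np.arange(panel.n_snps), members)
    if comp.size == 0:
        raise ValueError(f"block {block_id} owns every SNP: complement GRM is empty")
    rgrm = compute_grm(panel, members, role="rGRM")
    cgrm = compute_grm(panel, comp, role="cGRM")
    return rgrm, cgrm


def threshold_kin(grm: GRM, cutoff: float = 0.05) -> GRM:
    """Zero off-diagonal entries <= cutoff; keeps the diagonal untouched.

    The result represents close-pedigree relatedness only (role cGRM_kin).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    mat = grm.matrix.copy()
    diag = np.diag(mat).copy()
    mat[mat <= cutoff] = 0.0
    np.fill_diagonal(mat, diag)
    return GRM(mat, list(grm.ids), role="cGRM_kin", n_snps=grm.n_snps)


def grm_pca(grm: GRM, k: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenvalues and eigenvectors (principal components) of a GRM.

    Eigenvectors are sorted by descending eigenvalue; each is signed so its
    largest-magnitude loading is positive.
    """
    if not np.isfinite(grm.matrix).all():
        raise ValueError("GRM contains non-finite entries")
    n = grm.n
    if not 0 < k <= n:
        raise ValueError("k must be in (0, n]")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs
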