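"""Genotype panel container and SNP-level quality control."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "sex"]


@dataclass
class GenotypePanel:
    """Individuals x SNPs additive dosage matrix with SNP/sample metadata.

    Dosages count copies of allele A1 (the PLINK A1 convention), taking
    values 0, 1 or 2; missing genotypes are stored as NaN. The stored matrix
    is never imputed: mean imputation to 2p happens only where a downstream
    statistic requires it (GRM construction, association testing).
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    _freqs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x SNPs) array")
        n, m = self.dosages.shape
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if len(self.samples) != n:
            raise ValueError(f"sample table has {len(self.samples)} rows, dosage matrix {n}")
        if len(self.snps) != m:
            raise ValueError(f"SNP table has {len(self.snps)} rows, dosage matrix {m}")
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP table missing columns {missing}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages[~ok].ravel()[0]
            raise ValueError(f"dosage values must be 0/1/2 or missing (found {bad!r})")
        if self.samples["iid"].duplicated().any():
            raise ValueError("individual ids are not unique")
        if self.snps["id"].duplicated().any():
            raise ValueError("SNP ids are not unique")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP positions decrease within chromosome {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def iids(self) -> list[str]:
        return self.samples["iid"].tolist()

    def allele_freqs(self) -> np.ndarray:
        """A1 allele frequency per SNP, ignoring missing genotypes (cached)."""
        if self._freqs is None:
            with np.errstate(invalid="ignore"):
                self._freqs = np.nanmean(self.dosages, axis=0) / 2.0
        return self._freqs

    def missing_rates(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            self.dosages[:, indices].copy(),
            self.snps.iloc[indices].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_individuals(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            self.dosages[indices].copy(),
            self.snps.copy(),
            self.samples.iloc[indices].reset_index(drop=True),
        )


def qc_filter(
    panel: GenotypePanel, maf_min: float = 0.01, missing_max: float = 0.02
) -> GenotypePanel:
    """Remove SNPs failing minor-allele-frequency or missingness thresholds.

    Parameters mirror the usual pre-analysis QC: ``maf_min`` is the minimum
    minor allele frequency (0 keeps monomorphic SNPs), ``missing_max`` the
    maximum per-SNP missing genotype rate.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    p = panel.allele_freqs()
    maf = np.minimum(p, 1 - p)
    # NaN frequency means every genotype missing: always remove at any threshold
    keep = (~np.isnan(maf)) & (maf >= maf_min) & (panel.missing_rates() <= missing_max)
    if maf_min > 0:
        keep &= maf > 0
    n_removed = int((~keep).sum())
    logger.info(
        "qc_filter: removed %d of %d SNPs (maf_min=%g, missing_max=%g)",
        n_removed, panel.n_snps, maf_min, missing_max,
    )
    if not keep.any():
        raise ValueError("qc_filter removed every SNP")
    if n_removed == 0:
        return panel
    return panel.subset_snps(np.flatnonzero(keep))
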