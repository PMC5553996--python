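"""Readers/writers for PLINK1 binary genotypes, GCTA binary GRMs and TSV tables.

The PLINK1 .bed codec follows the SNP-major 2-bit layout: magic bytes
0x6c 0x1b 0x01, then for each SNP ceil(n/4) bytes, four genotypes per byte
packed least-significant-bits first with codes 00 = homozygous A1 (dosage 2),
01 = missing, 10 = heterozygous, 11 = homozygous A2 (dosage 0). The GCTA GRM
format stores the lower triangle (diagonal included, row-major) as
little-endian float32 in .grm.bin, ids as a two-column text file, and the
per-pair SNP counts in .grm.N.bin.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .grm import GRM

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage (NaN = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0, 1.0: 2, 0.0: 3}  # missing handled separately


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK1 .bed/.bim/.fam (SNP-major, padding bits zero)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = pd.DataFrame(
        {
            "chrom": panel.snps["chrom"],
            "id": panel.snps["id"],
            "cm": 0,
            "pos": panel.snps["pos"],
            "a1": panel.snps["a1"],
            "a2": panel.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.samples["fid"],
            "iid": panel.samples["iid"],
            "father": panel.samples.get("father", pd.Series(["0"] * len(panel.samples))),
            "mother": panel.samples.get("mother", pd.Series(["0"] * len(panel.samples))),
            "sex": panel.samples["sex"],
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = panel.n_individuals, panel.n_snps
    codes = np.empty((m, n), dtype=np.uint8)
    dosages_t = panel.dosages.T
    missing = np.isnan(dosages_t)
    codes[missing] = 1
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[~missing & (dosages_t == dos)] = code
    n_pad = 4 * math.ceil(n / 4)
    padded = np.zeros((m, n_pad), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([1, 4, 16, 64], dtype=np.uint8)
    packed = (padded.reshape(m, -1, 4) * shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read PLINK1 .bed/.bim/.fam into a :class:`GenotypePanel`."""
    prefix = Path(prefix)
    fam_path, bim_path, bed_path = (prefix.with_suffix(s) for s in (".fam", ".bim", ".bed"))
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    if fam.empty:
        raise ValueError(f"empty .fam file: {fam_path}")
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    if bim.empty:
        raise ValueError(f"empty .bim file: {bim_path}")
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != PLINK_MAGIC:
        raise ValueError(f"{bed_path}: not SNP-major bed (magic bytes {raw[:3].hex()})")
    bytes_per_snp = math.ceil(n / 4)
    expected = 3 + m * bytes_per_snp
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: expected {expected} bytes for {n} individuals x {m} SNPs, "
            f"got {len(raw)} (truncated at byte offset {len(raw)})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    codes = (data[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()
    snps = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam[["fid", "iid", "sex", "father", "mother"]].copy()
    return GenotypePanel(dosages, snps, samples)


def decode_bed_byte(byte: int, n_individuals: int = 4) -> np.ndarray:
    """Decode one SNP-major .bed byte into up to four A1 dosages."""
    codes = (byte >> np.array([0, 2, 4, 6])) & 3
    return _CODE_TO_DOSAGE[codes][:n_individuals]


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """Write a GRM in GCTA binary format (.grm.bin/.grm.N.bin/.grm.id)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(grm.ids)
    tril = np.tril_indices(n)
    vals = grm.matrix[tril].astype("<f4")
    Path(f"{prefix}.grm.bin").write_bytes(vals.tobytes())
    nsnp = np.full(vals.shape, float(grm.n_snps), dtype="<f4")
    Path(f"{prefix}.grm.N.bin").write_bytes(nsnp.tobytes())
    ids = pd.DataFrame({"fid": [i[0] for i in grm.id_pairs()], "iid": [i[1] for i in grm.id_pairs()]})
    ids.to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str | Path, role: str = "whole") -> GRM:
    """Read a GCTA binary GRM; errors if the triangle size disagrees with .grm.id."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str)
    n = len(ids)
    n_vals = n * (n + 1) // 2
    raw = Path(f"{prefix}.grm.bin").read_bytes()
    vals = np.frombuffer(raw, dtype="<f4")
    if len(vals) != n_vals:
        raise ValueError(
            f"{prefix}.grm.bin holds {len(vals)} float32 values but {n} ids need {n_vals}"
        )
    mat = np.zeros((n, n))
    tril = np.tril_indices(n)
    mat[tril] = vals
    mat = mat + mat.T - np.diag(np.diag(mat))
    n_snps = 0
    npath = Path(f"{prefix}.grm.N.bin")
    if npath.exists():
        nvals = np.frombuffer(npath.read_bytes(), dtype="<f4")
        if len(nvals):
            n_snps = int(round(float(nvals[0])))
    iid_list = (ids["fid"] + "\t" + ids["iid"]).tolist()
    return GRM(matrix=mat, ids=iid_list, role=role, n_snps=n_snps)


# ---------------------------------------------------------------------------
# phenotype / covariate tables


def make_covariates(
    iid, pheno, age, sex, pcs: np.ndarray | None = None
) -> pd.DataFrame:
    """Assemble a phenotype/covariate table with the age^2 column derived."""
    df = pd.DataFrame({"iid": iid, "pheno": pheno, "age": age, "sex": sex})
    df["age2"] = df["age"] ** 2
    if pcs is not None:
        pcs = np.asarray(pcs)
        for k in range(pcs.shape[1]):
            df[f"pc{k + 1}"] = pcs[:, k]
    return df[["iid", "pheno", "age", "age2", "sex"] + [c for c in df.columns if c.startswith("pc")]]


def validate_covariates(df: pd.DataFrame, panel: GenotypePanel | None = None) -> None:
    if "age" in df.columns and "age2" in df.columns:
        # tolerance of a few ulp: text round trips perturb the last bit
        if not np.allclose(df["age2"].to_numpy(), (df["age"] ** 2).to_numpy(),
                           rtol=1e-12, atol=0.0):
            raise ValueError("age2 column does not equal age squared")
    if panel is not None:
        unknown = set(df["iid"]) - set(panel.iids)
        if unknown:
            raise ValueError(f"covariate rows for unknown individuals: {sorted(unknown)[:5]}")


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path, panel: GenotypePanel | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"iid": str}, comment="#")
    if "iid" not in df.columns or "pheno" not in df.columns:
        raise ValueError(f"{path}: covariate table needs 'iid' and 'pheno' columns")
    validate_covariates(df, panel)
    return df
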