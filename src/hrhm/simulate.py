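"""Family-structured genotype and liability-threshold phenotype simulation.

The generator emulates a family-plus-population cohort genotyped on SNPs that
fall into haplotype blocks separated by recombination hotspots: within a block
LD is carried entirely by a small pool of ancestral haplotypes, between blocks
recombination is free, and nuclear families (two founders plus full sibs)
share whole block haplotypes by descent. A binary trait is produced by
thresholding a standard-normal liability composed of a regional genetic
effect confined to one designated causal block, a polygenic background spread
over all other blocks, optional age/sex covariate effects, and Gaussian noise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel
from .grm import standardized_dosages

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters for one simulated cohort.

    Variance fractions are on the liability scale; ``prevalence`` is the
    population risk K and ``ascertainment`` either ``"population"`` (keep the
    realized case/control mix) or a target sample case proportion P reached by
    subsampling. ``phenotype_scale="liability"`` returns the continuous
    liability itself, which is convenient for checks whose truth must be exact
    on the analysis scale.
    """

    n_families: int = 0
    family_size: int = 4  # two founders + (family_size - 2) full sibs
    n_unrelated: int = 100
    n_blocks: int = 10
    snps_per_block: int | Sequence[int] = 10
    haplotypes_per_block_pool: int = 8
    causal_block_index: int = 0
    hg2_region: float = 0.0
    hg2_polygenic: float = 0.0
    prevalence: float = 0.5
    ascertainment: float | str = "population"
    beta_age: float = 0.0
    beta_sex: float = 0.0
    phenotype_scale: str = "binary"
    exact_scale: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0:
            raise ValueError("negative sample counts")
        if self.n_families > 0 and self.family_size < 3:
            raise ValueError("family_size must be >= 3 (two founders plus a child)")
        if self.n_families * self.family_size + self.n_unrelated < 2:
            raise ValueError("need at least two individuals")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.haplotypes_per_block_pool < 2:
            raise ValueError("haplotype pool needs >= 2 haplotypes")
        if min(self.snps_in_block(b) for b in range(self.n_blocks)) < 1:
            raise ValueError("each block needs >= 1 SNP")
        if not 0 <= self.hg2_region < 1 or not 0 <= self.hg2_polygenic < 1:
            raise ValueError("variance fractions must be in [0, 1)")
        if self.hg2_region + self.hg2_polygenic >= 1:
            raise ValueError("hg2_region + hg2_polygenic must be < 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence K must be in (0, 1)")
        if self.ascertainment != "population" and not 0 < float(self.ascertainment) < 1:
            raise ValueError("ascertainment P must be in (0, 1) or 'population'")
        if not 0 <= self.causal_block_index < self.n_blocks:
            raise ValueError("causal_block_index out of range")
        if self.phenotype_scale not in ("binary", "liability"):
            raise ValueError("phenotype_scale must be 'binary' or 'liability'")
        resid = 1 - self.hg2_region - self.hg2_polygenic - self.beta_age**2 - self.beta_sex**2
        if resid <= 0:
            raise ValueError("genetic plus covariate variance leaves no residual variance")

    def snps_in_block(self, b: int) -> int:
        if isinstance(self.snps_per_block, (int, np.integer)):
            return int(self.snps_per_block)
        return int(self.snps_per_block[b])

    @property
    def n_individuals(self) -> int:
        return self.n_families * self.family_size + self.n_unrelated


@dataclass
class HaplotypePool:
    """Per-block ancestral haplotypes (rows of 0/1 A1 indicators) and frequencies."""

    haplotypes: list[np.ndarray]
    frequencies: list[np.ndarray]

    def validate(self) -> None:
        for b, (h, f) in enumerate(zip(self.haplotypes, self.frequencies)):
            if len(h) < 2:
                raise ValueError(f"block {b}: pool needs >= 2 haplotypes")
            if abs(f.sum() - 1.0) > 1e-12:
                raise ValueError(f"block {b}: frequencies do not sum to 1")
            if (h == h[0]).all():
                raise ValueError(f"monomorphic block {b}")
            p = f @ h
            if ((p <= 0) | (p >= 1)).any():
                raise ValueError(f"block {b}: pooled allele frequency outside (0, 1)")

    def snp_freqs(self, b: int) -> np.ndarray:
        return self.frequencies[b] @ self.haplotypes[b]


@dataclass
class TruthRecord:
    causal_block: str
    snp_effects: list[float]
    var_region: float
    var_polygenic: float
    realized_prevalence: float
    prevalence: float
    threshold: float
    sample_case_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class GeneDropResult:
    panel: GenotypePanel
    pedigree: pd.DataFrame
    hap_pool_idx: np.ndarray  # (n, n_blocks, 2) pool index of each haplotype copy
    hap_labels: np.ndarray  # (n, n_blocks, 2) founder-haplotype labels (IBD bookkeeping)
    block_table: pd.DataFrame  # chrom, start, end, block_id
    block_members: list[np.ndarray]


def simulate_haplotype_pool(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePool:
    """Draw a pool of distinct block haplotypes with Dirichlet frequencies.

    Within-block LD is total along a haplotype; every SNP's pooled allele
    frequency is guaranteed polymorphic by redrawing degenerate pools.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    haps, freqs = [], []
    H = config.haplotypes_per_block_pool
    for b in range(config.n_blocks):
        m = config.snps_in_block(b)
        if H > 2**m:
            raise ValueError(
                f"block {b}: cannot draw {H} distinct haplotypes over {m} SNP(s)"
            )
        for _ in range(1000):
            p = rng.uniform(0.1, 0.9, size=m)
            h = (rng.random((H, m)) < p).astype(np.uint8)
            f = rng.dirichlet(np.ones(H))
            f = np.clip(f, 1e-6, None)
            f /= f.sum()
            pooled = f @ h
            distinct = len({tuple(row) for row in h}) == H
            if distinct and ((pooled > 0) & (pooled < 1)).all():
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError(f"could not draw a polymorphic pool for block {b}")
        haps.append(h)
        freqs.append(f)
    pool = HaplotypePool(haps, freqs)
    pool.validate()
    return pool


def gene_drop(
    config: SimConfig, pool: HaplotypePool, rng: np.random.Generator | None = None
) -> GeneDropResult:
    """Drop block haplotypes through nuclear families plus unrelated founders.

    Founders draw two haplotypes per block independently from the pool;
    each offspring inherits one intact block haplotype per parent, chosen
    independently across blocks (free recombination at block boundaries only).
    """
    config.validate()
    pool.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    B = config.n_blocks
    n = config.n_individuals
    fam_n = config.n_families * config.family_size

    fids, iids, fathers, mothers, sexes = [], [], [], [], []
    founder_rows, child_specs = [], []  # child_specs: (row, father_row, mother_row)
    for fam in range(config.n_families):
        base = fam * config.family_size
        fid = f"F{fam}"
        for k in range(config.family_size):
            row = base + k
            fids.append(fid)
            iids.append(f"{fid}_{k}")
            if k < 2:
                founder_rows.append(row)
                fathers.append("0")
                mothers.append("0")
                sexes.append(1 if k == 0 else 2)
            else:
                child_specs.append((row, base, base + 1))
                fathers.append(f"{fid}_0")
                mothers.append(f"{fid}_1")
                sexes.append(int(rng.integers(1, 3)))
    for u in range(config.n_unrelated):
        row = fam_n + u
        founder_rows.append(row)
        fids.append(f"U{u}")
        iids.append(f"U{u}_0")
        fathers.append("0")
        mothers.append("0")
        sexes.append(int(rng.integers(1, 3)))

    founder_rows = np.asarray(founder_rows)
    n_founders = len(founder_rows)
    hap_pool_idx = np.zeros((n, B, 2), dtype=np.int16)
    hap_labels = np.zeros((n, B, 2), dtype=np.int32)
    founder_labels = np.arange(2 * n_founders).reshape(n_founders, 2)

    m_total = sum(config.snps_in_block(b) for b in range(B))
    dosages = np.empty((n, m_total))
    col = 0
    block_rows, block_members = [], []
    for b in range(B):
        m = config.snps_in_block(b)
        h, f = pool.haplotypes[b], pool.frequencies[b]
        draw = rng.choice(len(f), size=(n_founders, 2), p=f)
        hap_pool_idx[founder_rows, b] = draw
        hap_labels[founder_rows, b] = founder_labels
        for row, fa, mo in child_specs:
            pick_f = rng.integers(2)
            pick_m = rng.integers(2)
            hap_pool_idx[row, b, 0] = hap_pool_idx[fa, b, pick_f]
            hap_pool_idx[row, b, 1] = hap_pool_idx[mo, b, pick_m]
            hap_labels[row, b, 0] = hap_labels[fa, b, pick_f]
            hap_labels[row, b, 1] = hap_labels[mo, b, pick_m]
        dosages[:, col : col + m] = h[hap_pool_idx[:, b, 0]] + h[hap_pool_idx[:, b, 1]]
        start = b * 100_000 + 1_000
        positions = start + 100 * np.arange(m)
        block_rows.append(
            {"chrom": 1, "start": int(start - 500), "end": int(positions[-1] + 500), "block_id": f"B{b}"}
        )
        block_members.append(np.arange(col, col + m))
        col += m

    alleles = np.stack(
        [_BASES[rng.integers(0, 4, size=m_total)], _BASES[rng.integers(0, 4, size=m_total)]]
    )
    same = alleles[0] == alleles[1]
    alleles[1, same] = np.array(
        [_BASES[(list(_BASES).index(a) + 1) % 4] for a in alleles[0, same]]
    )
    snps = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m_total)],
            "chrom": 1,
            "pos": np.concatenate(
                [b * 100_000 + 1_000 + 100 * np.arange(config.snps_in_block(b)) for b in range(B)]
            ),
            "a1": alleles[0],
            "a2": alleles[1],
        }
    )
    samples = pd.DataFrame(
        {"fid": fids, "iid": iids, "sex": sexes, "father": fathers, "mother": mothers}
    )
    panel = GenotypePanel(dosages, snps, samples)
    pedigree = samples[["fid", "iid", "father", "mother"]].copy()
    return GeneDropResult(
        panel, pedigree, hap_pool_idx, hap_labels, pd.DataFrame(block_rows), block_members
    )


def ibd_sharing(gdr: GeneDropResult, i: int, j: int) -> np.ndarray:
    """Per-block proportion of alleles shared identical-by-descent between two rows."""
    a = gdr.hap_labels[i]
    b = gdr.hap_labels[j]
    share = np.zeros(a.shape[0])
    for perm in ((0, 1), (1, 0)):
        s = (a[:, 0] == b[:, perm[0]]).astype(int) + (a[:, 1] == b[:, perm[1]]).astype(int)
        share = np.maximum(share, s)
    return share / 2.0


def simulate_phenotype(
    gdr: GeneDropResult, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, TruthRecord, np.ndarray]:
    """Liability-threshold phenotype on top of a gene-dropped panel.

    Returns the phenotype/covariate table (iid, pheno, age, age2, sex), the
    truth record, and the row indices of the panel retained after any
    case/control ascertainment subsampling.

    With ``exact_scale`` the genetic components are rescaled so their sample
    variances equal the configured fractions exactly; otherwise per-SNP
    effects are drawn with model variance hg2/m, which makes the phenotype
    law exactly the Gaussian mixed model implied by the GRMs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    panel = gdr.panel
    n = panel.n_individuals
    causal = gdr.block_members[config.causal_block_index]
    others = np.setdiff1d(np.arange(panel.n_snps), causal)

    freqs = panel.allele_freqs()

    def genetic_component(snp_idx: np.ndarray, hg2: float) -> tuple[np.ndarray, np.ndarray, float]:
        if hg2 == 0 or snp_idx.size == 0:
            return np.zeros(n), np.zeros(snp_idx.size), 0.0
        # SNPs monomorphic in this finite sample carry no variance; skip them
        snp_idx = snp_idx[(freqs[snp_idx] > 0) & (freqs[snp_idx] < 1)]
        if snp_idx.size == 0:
            raise ValueError("no polymorphic SNPs available for a genetic component")
        z = standardized_dosages(panel, snp_idx)
        m = z.shape[1]
        if config.exact_scale:
            u = rng.standard_normal(m)
            g = z @ u
            sd = g.std()
            if sd == 0:
                raise ValueError("degenerate genetic component (zero variance)")
            scale = np.sqrt(hg2) / sd
            g, u = g * scale, u * scale
        else:
            u = rng.normal(0.0, np.sqrt(hg2 / m), size=m)
            g = z @ u
        return g, u, float(g.var())

    g_r, u_r, var_r = genetic_component(causal, config.hg2_region)
    g_p, _, var_p = genetic_component(others, config.hg2_polygenic)

    age = rng.uniform(18, 65, size=n)
    sex01 = panel.samples["sex"].to_numpy() - 1
    age_std = (age - age.mean()) / age.std()
    sex_std = (sex01 - sex01.mean()) / (sex01.std() if sex01.std() > 0 else 1.0)
    var_e = 1 - config.hg2_region - config.hg2_polygenic - config.beta_age**2 - config.beta_sex**2
    liability = (
        g_r + g_p + config.beta_age * age_std + config.beta_sex * sex_std
        + rng.normal(0.0, np.sqrt(var_e), size=n)
    )

    K = config.prevalence
    threshold = float(stats.norm.isf(K))
    if config.phenotype_scale == "liability":
        pheno = liability
        realized_prev = float("nan")
        keep = np.arange(n)
    else:
        y = (liability > threshold).astype(int)
        realized_prev = float(y.mean())
        keep = np.arange(n)
        if config.ascertainment != "population":
            P = float(config.ascertainment)
            cases = np.flatnonzero(y == 1)
            controls = np.flatnonzero(y == 0)
            if len(cases) == 0 or len(controls) == 0:
                raise ValueError(
                    f"requested case fraction {P} unreachable: realized "
                    f"{len(cases)} cases / {len(controls)} controls"
                )
            frac = len(cases) / n
            if P >= frac:
                n_ctrl = int(round(len(cases) * (1 - P) / P))
                if n_ctrl < 1:
                    raise ValueError(f"requested case fraction {P} unreachable")
                keep_ctrl = rng.choice(controls, size=min(n_ctrl, len(controls)), replace=False)
                keep = np.sort(np.concatenate([cases, keep_ctrl]))
            else:
                n_case = int(round(len(controls) * P / (1 - P)))
                if n_case < 1:
                    raise ValueError(f"requested case fraction {P} unreachable")
                keep_case = rng.choice(cases, size=min(n_case, len(cases)), replace=False)
                keep = np.sort(np.concatenate([keep_case, controls]))
        pheno = y

    pheno_kept = np.asarray(pheno)[keep]
    covars = pd.DataFrame(
        {
            "iid": panel.samples["iid"].to_numpy()[keep],
            "pheno": pheno_kept,
            "age": age[keep],
            "sex": sex01[keep],
        }
    )
    covars["age2"] = covars["age"] ** 2
    covars = covars[["iid", "pheno", "age", "age2", "sex"]]
    if config.phenotype_scale == "binary":
        case_frac = float(pheno_kept.mean())
    else:
        case_frac = float("nan")
    truth = TruthRecord(
        causal_block=f"B{config.causal_block_index}",
        snp_effects=[float(v) for v in u_r],
        var_region=var_r,
        var_polygenic=var_p,
        realized_prevalence=realized_prev,
        prevalence=K,
        threshold=threshold,
        sample_case_fraction=case_frac,
    )
    return covars, truth, keep


def simulate_dataset(config: SimConfig, rng: np.random.Generator | None = None):
    """Pool -> gene drop -> phenotype in one call; returns (gdr, covars, truth, keep)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pool = simulate_haplotype_pool(config, rng)
    gdr = gene_drop(config, pool, rng)
    covars, truth, keep = simulate_phenotype(gdr, config, rng)
    return gdr, covars, truth, keep


def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate a cohort and write PLINK + block TSV + covariate TSV + truth JSON."""
    from . import io as gio
    from .blocks import write_blocks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gdr, covars, truth, keep = simulate_dataset(config)
    panel = gdr.panel.subset_individuals(keep) if len(keep) < gdr.panel.n_individuals else gdr.panel
    gio.write_plink(panel, outdir / "geno")
    write_blocks(gdr.block_table, outdir / "blocks.tsv")
    gio.write_covariates(covars, outdir / "covariates.tsv")
    truth.to_json(outdir / "truth.json")
    return {
        "plink_prefix": str(outdir / "geno"),
        "blocks": str(outdir / "blocks.tsv"),
        "covariates": str(outdir / "covariates.tsv"),
        "truth": str(outdir / "truth.json"),
        "n_individuals": panel.n_individuals,
        "n_snps": panel.n_snps,
    }
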