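"""Haplotype-block definitions: loading, SNP assignment, LD-based construction.

Block coordinates are 1-based and inclusive at both ends (``chr20:100-200``
contains a SNP at position 200). BED-style 0-based half-open input is accepted
via ``coords="bed"``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger(__name__)

BLOCK_COLUMNS = ["chrom", "start", "end", "block_id"]


@dataclass
class BlockSet:
    """Ordered, non-overlapping genomic intervals each owning >= 1 SNP index."""

    table: pd.DataFrame  # chrom, start, end, block_id
    members: list[np.ndarray]

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if len(self.table) != len(self.members):
            raise ValueError("table and member lists disagree in length")
        for i, m in enumerate(self.members):
            if len(m) == 0:
                raise ValueError(f"block {self.table['block_id'].iloc[i]} has no member SNPs")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping blocks on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def block_ids(self) -> list:
        return self.table["block_id"].tolist()

    def members_of(self, block_id) -> np.ndarray:
        idx = self.table.index[self.table["block_id"] == block_id]
        if len(idx) == 0:
            raise KeyError(f"unknown block {block_id!r}; available: {self.block_ids[:10]}...")
        return self.members[idx[0]]


def assign_snps(table: pd.DataFrame, panel: GenotypePanel, policy: str = "singleton") -> BlockSet:
    """Assign panel SNPs to block intervals by position (inclusive ends).

    SNPs falling in no interval become singleton blocks (``policy="singleton"``)
    or are dropped (``policy="drop"``). Intervals owning no SNP are dropped with
    a warning.
    """
    if policy not in ("singleton", "drop"):
        raise ValueError("policy must be 'singleton' or 'drop'")
    chroms = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    assigned = np.full(panel.n_snps, -1, dtype=int)
    rows, members = [], []
    for i, rec in table.iterrows():
        in_block = np.flatnonzero(
            (chroms == rec["chrom"]) & (pos >= rec["start"]) & (pos <= rec["end"])
        )
        if in_block.size == 0:
            warnings.warn(f"block {rec['block_id']} contains no genotyped SNP; dropped")
            continue
        assigned[in_block] = len(rows)
        rows.append(rec)
        members.append(in_block)
    if policy == "singleton":
        for j in np.flatnonzero(assigned < 0):
            rows.append(
                pd.Series(
                    {
                        "chrom": chroms[j],
                        "start": pos[j],
                        "end": pos[j],
                        "block_id": f"singleton_{panel.snps['id'].iloc[j]}",
                    }
                )
            )
            members.append(np.array([j]))
    out = pd.DataFrame(rows).reset_index(drop=True)[BLOCK_COLUMNS]
    order = np.lexsort((out["start"].to_numpy(), out["chrom"].astype(str).to_numpy()))
    return BlockSet(out.iloc[order], [members[i] for i in order])


def load_blocks(
    path: str | Path,
    panel: GenotypePanel,
    policy: str = "singleton",
    coords: str = "inclusive",
) -> BlockSet:
    """Load a block TSV (chrom, start, end[, block_id]) and assign panel SNPs."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"chrom", "start", "end"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: block file needs columns {sorted(needed)}")
    if "block_id" not in df.columns:
        df["block_id"] = [f"B{i}" for i in range(len(df))]
    if coords == "bed":
        df["start"] = df["start"] + 1  # half-open 0-based -> inclusive 1-based
    elif coords != "inclusive":
        raise ValueError("coords must be 'inclusive' or 'bed'")
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{path}: overlapping blocks on chromosome {chrom}")
    return assign_snps(df, panel, policy=policy)


def write_blocks(blockset: BlockSet | pd.DataFrame, path: str | Path) -> None:
    table = blockset.table if isinstance(blockset, BlockSet) else blockset
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[BLOCK_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD-based block construction (D' confidence-interval method)


def _two_locus_haplotype_freqs(ga: np.ndarray, gb: np.ndarray, tol: float = 1e-10):
    """EM haplotype frequency estimate for two biallelic loci from hard calls."""
    ok = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    n = len(ga)
    counts = np.zeros((3, 3))
    np.add.at(counts, (ga, gb), 1)
    pa, pb = ga.mean() / 2, gb.mean() / 2
    # haplotype order: (1,1), (1,0), (0,1), (0,0) in A1 counts
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    for _ in range(1000):
        # only the double heterozygote class is phase-ambiguous
        dh = counts[1, 1]
        w11 = f[0] * f[3]
        w10 = f[1] * f[2]
        frac = w11 / (w11 + w10) if (w11 + w10) > 0 else 0.5
        c = np.zeros(4)
        c[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + dh * frac
        c[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + dh * (1 - frac)
        c[2] = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + dh * (1 - frac)
        c[3] = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1] + dh * frac
        f_new = c / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f, counts, n


def dprime_ci(
    ga: np.ndarray, gb: np.ndarray, grid: int = 101, lo_q: float = 0.05, hi_q: float = 0.95
) -> tuple[float, float, float]:
    """|D'| point estimate and likelihood-based confidence interval.

    The likelihood of the nine two-locus genotype classes is profiled over
    |D'| in [0, 1] with allele frequencies fixed at their sample estimates;
    the normalized likelihood is treated as a density on |D'| and the
    (lo_q, hi_q) quantiles reported, Haploview-style.
    """
    f, counts, n = _two_locus_haplotype_freqs(ga, gb)
    if n < 10:
        raise ValueError("too few complete genotype pairs for a D' confidence interval")
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    if min(pa, 1 - pa, pb, 1 - pb) <= 0:
        raise ValueError("monomorphic locus: D' undefined")
    d_mle = f[0] - pa * pb
    if d_mle >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        raise ValueError("degenerate allele frequencies: D' undefined")
    dprimes = np.linspace(0.0, 1.0, grid)
    logls = np.empty(grid)
    sign = 1.0 if d_mle >= 0 else -1.0
    for i, dp in enumerate(dprimes):
        d = sign * dp * dmax
        h = np.array(
            [pa * pb + d, pa * (1 - pb) - d, (1 - pa) * pb - d, (1 - pa) * (1 - pb) + d]
        )
        h = np.clip(h, 1e-12, None)
        # genotype class probabilities under random union of haplotypes
        pmat = np.zeros((3, 3))
        pairs = [(0, 0), (0, 1), (0, 2), (0, 3), (1, 1), (1, 2), (1, 3), (2, 2), (2, 3), (3, 3)]
        a_dose = np.array([1, 1, 0, 0])
        b_dose = np.array([1, 0, 1, 0])
        for x, y in pairs:
            prob = h[x] * h[y] * (1 if x == y else 2)
            pmat[a_dose[x] + a_dose[y], b_dose[x] + b_dose[y]] += prob
        logls[i] = (counts * np.log(np.clip(pmat, 1e-300, None))).sum()
    like = np.exp(logls - logls.max())
    cdf = np.cumsum(like)
    cdf /= cdf[-1]
    lo = float(dprimes[np.searchsorted(cdf, lo_q)])
    hi = float(dprimes[min(np.searchsorted(cdf, hi_q), grid - 1)])
    return float(abs(d_mle) / dmax), lo, hi


def build_ld_blocks(
    panel: GenotypePanel,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_frac: float = 0.05,
    min_n: int = 40,
) -> BlockSet:
    """Partition each chromosome into LD blocks by the D' confidence-interval rule.

    Adjacent SNPs are greedily merged while at least ``1 - recomb_frac`` of the
    informative pairs inside the candidate block are in strong LD (CI lower
    bound >= ci_low and upper bound >= ci_high); pairs whose CI upper bound
    falls below 0.9 count as evidence of historical recombination. SNPs that
    join no block become singleton blocks, so the result is a partition.
    """
    if panel.n_individuals < min_n:
        raise ValueError(f"need >= {min_n} individuals for D' confidence intervals")
    chroms = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    rows, members = [], []

    def classify(i: int, j: int) -> str:
        try:
            _, lo, hi = dprime_ci(panel.dosages[:, i], panel.dosages[:, j])
        except ValueError:
            return "uninformative"
        if lo >= ci_low and hi >= ci_high:
            return "strong"
        if hi < 0.9:
            return "recomb"
        return "uninformative"

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            end = start
            strong, recomb = 0, 0
            while end + 1 < len(idx):
                cand = end + 1
                s_new, r_new = strong, recomb
                for k in range(start, cand):
                    cls = classify(idx[k], idx[cand])
                    if cls == "strong":
                        s_new += 1
                    elif cls == "recomb":
                        r_new += 1
                informative = s_new + r_new
                if informative == 0 or s_new / informative < 1 - recomb_frac:
                    break
                strong, recomb = s_new, r_new
                end = cand
            sel = idx[start : end + 1]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[sel[0]]),
                    "end": int(pos[sel[-1]]),
                    "block_id": f"LD{len(rows)}",
                }
            )
            members.append(sel)
            start = end + 1
    return BlockSet(pd.DataFrame(rows), members)
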