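"""Scale transformations and inverse-variance meta-analysis.

A binary trait analysed with a linear mixed model yields effects and variance
fractions on the observed 0/1 scale. A first-order Taylor expansion of the
logistic link maps a linear-scale allele effect beta to a log odds ratio
beta / (P (1 - P)) with P the sample case proportion; the liability-threshold
model maps an observed-scale heritability to the liability scale with the
ascertainment-corrected factor K^2 (1 - K)^2 / (z^2 P (1 - P)), where K is
the population prevalence, t = Phi^{-1}(1 - K) the liability threshold and
z = phi(t) the normal density at the threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ScaleParams:
    """Prevalence K, sample case proportion P, threshold t and density z = phi(t)."""

    K: float
    P: float
    t: float
    z: float

    @classmethod
    def from_prevalence(cls, K: float, P: float | None = None) -> "ScaleParams":
        if not 0 < K < 1:
            raise ValueError("prevalence K must be in (0, 1)")
        P = K if P is None else P
        if not 0 < P < 1:
            raise ValueError("case proportion P must be in (0, 1)")
        t = float(stats.norm.isf(K))
        return cls(K=K, P=P, t=t, z=float(stats.norm.pdf(t)))


def linear_to_logit(beta: float, se_beta: float, P: float) -> tuple[float, float]:
    """First-order Taylor map of a linear-scale effect to the logit scale.

    logOR = beta / (P (1 - P)); the SE scales identically, so the Wald z and
    p-value are unchanged by the transformation.
    """
    if not 0 < P < 1:
        raise ValueError("case proportion P must be in (0, 1)")
    scale = 1.0 / (P * (1.0 - P))
    return float(beta * scale), float(se_beta * scale)


def liability_multiplier(K: float, P: float | None = None) -> float:
    """Factor mapping observed-scale h2 to liability-scale h2."""
    sp = ScaleParams.from_prevalence(K, P)
    return (sp.K**2 * (1 - sp.K) ** 2) / (sp.z**2 * sp.P * (1 - sp.P))


def observed_to_liability(h2_obs: float, K: float, P: float | None = None) -> float:
    """Ascertainment-corrected threshold-model conversion of a heritability.

    With a population sample (P = K) the factor reduces to K (1 - K) / z^2.
    A result above 1 triggers a warning (likely misspecified K).
    """
    if h2_obs < 0:
        raise ValueError("h2_obs must be >= 0")
    h2_liab = h2_obs * liability_multiplier(K, P)
    if h2_liab > 1:
        warnings.warn(
            f"liability-scale heritability {h2_liab:.3f} exceeds 1; prevalence K may be misspecified"
        )
    return float(h2_liab)


def liability_to_observed(h2_liab: float, K: float, P: float | None = None) -> float:
    """Inverse of :func:`observed_to_liability`."""
    if h2_liab < 0:
        raise ValueError("h2_liab must be >= 0")
    return float(h2_liab / liability_multiplier(K, P))


# ---------------------------------------------------------------------------
# inverse-variance meta-analysis


@dataclass
class MetaResult:
    """Per-study effects (TE, seTE, weights) and the pooled estimate."""

    te: np.ndarray
    se_te: np.ndarray
    weights: np.ndarray
    te_pooled: float
    se_pooled: float
    z: float
    p: float
    q: float
    df: int
    tau2: float
    method: str


def _validate_meta(te, se_te):
    te = np.atleast_1d(np.asarray(te, dtype=float))
    se = np.atleast_1d(np.asarray(se_te, dtype=float))
    if len(te) != len(se) or len(te) < 1:
        raise ValueError("need matching TE and seTE vectors with >= 1 study")
    if not np.isfinite(te).all() or not np.isfinite(se).all():
        raise ValueError("non-finite effect or SE")
    if (se <= 0).any():
        raise ValueError("every seTE must be > 0")
    return te, se


def meta_fixed(te, se_te) -> MetaResult:
    """Fixed-effect inverse-variance pooling: weights 1/seTE^2."""
    te, se = _validate_meta(te, se_te)
    w = 1.0 / se**2
    pooled = float(np.sum(w * te) / np.sum(w))
    se_pooled = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / se_pooled
    p = 2.0 * float(stats.norm.sf(abs(z)))
    q = float(np.sum(w * (te - pooled) ** 2))
    return MetaResult(te, se, w, pooled, se_pooled, float(z), p, q, len(te) - 1, 0.0, "fixed")


def meta_random(te, se_te) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w) from the
    fixed-effect weights; homogeneous studies (Q <= df) collapse to the
    fixed-effect result.
    """
    te, se = _validate_meta(te, se_te)
    fixed = meta_fixed(te, se)
    w = fixed.weights
    if len(te) == 1:
        return MetaResult(te, se, w, fixed.te_pooled, fixed.se_pooled, fixed.z, fixed.p,
                          fixed.q, 0, 0.0, "random")
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (fixed.q - fixed.df) / c) if c > 0 else 0.0
    wr = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wr * te) / np.sum(wr))
    se_pooled = float(np.sqrt(1.0 / np.sum(wr)))
    z = pooled / se_pooled
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MetaResult(te, se, wr, pooled, se_pooled, float(z), p, fixed.q, fixed.df, tau2, "random")
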