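"""Mixed-model core: AI-REML, boundary-mixture LRT, genome scan, GREML power.

A binary phenotype is analysed on the observed 0/1 scale with a linear mixed
model y = X b + sum_k g_k + e, g_k ~ N(0, sigma_k^2 K_k), e ~ N(0, sigma_e^2 I).
Restricted maximum likelihood is maximized by average-information updates with
an expectation-maximization first step and EM fallback; variance components
are constrained to the boundary at zero. Because the regional component is
tested on its boundary, the likelihood-ratio statistic is referred to a 50:50
mixture of a point mass at zero and chi-square with one degree of freedom.

Two independent computational kernels are provided. The dense kernel works
with explicit n x n covariance matrices. The rotated kernel first moves the
data into the eigenbasis of a dense background GRM, after which every model
matrix is diagonal plus a shared low-rank term U U^T and all REML quantities
follow from Woodbury identities in O(n m^2) per iteration; it makes repeated
fits (genome scans, simulation studies) cheap. The two kernels evaluate the
same restricted likelihood and agree to high precision.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .grm import GRM, standardized_dosages, compute_grm
from .blocks import BlockSet

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class NotPositiveDefiniteError(RuntimeError):
    """Raised internally when a trial V is not positive definite."""


@dataclass
class REMLResult:
    """REML estimates on the analysis (observed) scale.

    ``sigma2`` holds one variance per random component with the residual
    last; ``cov_sigma2`` is the inverse average-information matrix from which
    the component SEs and variance-fraction SEs (delta method) derive.
    """

    sigma2: np.ndarray
    se_sigma2: np.ndarray
    cov_sigma2: np.ndarray
    beta: np.ndarray
    se_beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list[str]

    @property
    def sigma2_e(self) -> float:
        return float(self.sigma2[-1])

    @property
    def var_total(self) -> float:
        return float(self.sigma2.sum())

    def fraction(self, i: int = 0) -> tuple[float, float]:
        """Variance fraction sigma2_i / sigma2_total and its delta-method SE."""
        s = self.sigma2
        tot = s.sum()
        h = float(s[i] / tot)
        grad = np.full(len(s), -s[i] / tot**2)
        grad[i] += 1.0 / tot
        var = float(grad @ self.cov_sigma2 @ grad)
        return h, float(np.sqrt(max(var, 0.0)))


@dataclass
class _Pieces:
    loglik: float
    beta: np.ndarray
    xtvx_inv: np.ndarray
    grad: np.ndarray
    ai: np.ndarray
    tr_pk: np.ndarray
    qf: np.ndarray


class _LowRankModel:
    """Rotated kernel: V = sum_i s_i (diag(d_i) + g_i U U^T) + s_e I.

    ``comps`` is a list of (d_i, g_i) with d_i a length-n vector or None and
    g_i a scalar multiplying the shared low-rank factor U (n x m). y and X
    must already be expressed in the basis that makes the components diagonal
    (identity rotation is fine when every dense part really is diagonal).
    """

    def __init__(self, y, X, comps, U=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.comps = [(None if d is None else np.asarray(d, dtype=float), float(g)) for d, g in comps]
        self.comps.append((np.ones(len(self.y)), 0.0))  # residual
        self.U = None if U is None else np.asarray(U, dtype=float)
        self.n, self.p = self.X.shape
        self.n_comp = len(self.comps)

    def pieces(self, s: np.ndarray) -> _Pieces:
        n, p = self.n, self.p
        y, X, U = self.y, self.X, self.U
        d = np.zeros(n)
        g = 0.0
        for si, (di, gi) in zip(s, self.comps):
            if di is not None:
                d = d + si * di
            g += si * gi
        if d.min() <= 0:
            raise NotPositiveDefiniteError("diagonal part of V not positive")
        use_lr = U is not None and U.shape[1] > 0 and abs(g) > 1e-14
        if use_lr:
            W = U / d[:, None]
            S = U.T @ W
            m = S.shape[0]
            sign, ld_corr = np.linalg.slogdet(np.eye(m) + g * S)
            if sign <= 0:
                raise NotPositiveDefiniteError("V not positive definite (low-rank term)")
            M = np.eye(m) / g + S
            M_lu = linalg.lu_factor(M)

            def solv(Z):
                Zd = Z / d[:, None]
                return Zd - W @ linalg.lu_solve(M_lu, U.T @ Zd)

            logdet_v = float(np.sum(np.log(d)) + ld_corr)
        else:

            def solv(Z):
                return Z / d[:, None]

            W = None
            M_lu = None
            logdet_v = float(np.sum(np.log(d)))

        VX = solv(X)
        Vy = solv(y[:, None])[:, 0]
        XtVX = X.T @ VX
        try:
            cf = linalg.cho_factor(XtVX)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular fixed-effect design X") from exc
        XtVy = X.T @ Vy
        beta = linalg.cho_solve(cf, XtVy)
        Py = Vy - VX @ beta
        yPy = float(y @ Vy - XtVy @ beta)
        logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (logdet_v + logdet_xtvx + yPy + (n - p) * _LOG2PI)
        xtvx_inv = linalg.cho_solve(cf, np.eye(p))

        if U is not None and U.shape[1] > 0:
            VU = solv(U)
            UtVU = U.T @ VU
            UtPy = U.T @ Py
            UtVX = U.T @ VX
        tr_pk = np.empty(self.n_comp)
        qf = np.empty(self.n_comp)
        wmat = np.empty((n, self.n_comp))
        for i, (di, gi) in enumerate(self.comps):
            tr_v = 0.0
            xkx = np.zeros((p, p))
            w = np.zeros(n)
            if di is not None:
                tr_v += float(np.sum(di / d))
                if use_lr:
                    A = (W * di[:, None]).T @ W
                    tr_v -= float(np.trace(linalg.lu_solve(M_lu, A)))
                xkx += VX.T @ (di[:, None] * VX)
                w += di * Py
            if gi != 0.0:
                tr_v += gi * float(np.trace(UtVU))
                xkx += gi * (UtVX.T @ UtVX)
                w += gi * (U @ UtPy)
            tr_pk[i] = tr_v - float(np.trace(xtvx_inv @ xkx))
            qf[i] = float(Py @ w)
            wmat[:, i] = w
        grad = -0.5 * (tr_pk - qf)
        SW = solv(wmat)
        XtSW = X.T @ SW
        PW = SW - VX @ linalg.cho_solve(cf, XtSW)
        ai = 0.5 * (wmat.T @ PW)
        ai = 0.5 * (ai + ai.T)
        return _Pieces(ll, beta, xtvx_inv, grad, ai, tr_pk, qf)


class _DenseModel:
    """Dense kernel: V = sum_i s_i K_i + s_e I with explicit matrices."""

    def __init__(self, y, X, Ks):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.Ks = [np.asarray(K, dtype=float) for K in Ks]
        self.n, self.p = self.X.shape
        self.n_comp = len(self.Ks) + 1

    def pieces(self, s: np.ndarray) -> _Pieces:
        n, p = self.n, self.p
        y, X = self.y, self.X
        V = s[-1] * np.eye(n)
        for si, K in zip(s[:-1], self.Ks):
            V += si * K
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(str(exc)) from exc
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vinv = linalg.cho_solve(cf, np.eye(n))
        VX = Vinv @ X
        XtVX = X.T @ VX
        cfx = linalg.cho_factor(XtVX)
        xtvx_inv = linalg.cho_solve(cfx, np.eye(p))
        P = Vinv - VX @ (xtvx_inv @ VX.T)
        Py = P @ y
        yPy = float(y @ Py)
        logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        ll = -0.5 * (logdet_v + logdet_xtvx + yPy + (n - p) * _LOG2PI)
        beta = xtvx_inv @ (X.T @ (Vinv @ y))

        mats = self.Ks + [np.eye(n)]
        tr_pk = np.empty(self.n_comp)
        qf = np.empty(self.n_comp)
        wmat = np.empty((n, self.n_comp))
        for i, K in enumerate(mats):
            tr_pk[i] = float(np.sum(P * K))
            w = K @ Py
            wmat[:, i] = w
            qf[i] = float(Py @ w)
        grad = -0.5 * (tr_pk - qf)
        PW = P @ wmat
        ai = 0.5 * (wmat.T @ PW)
        ai = 0.5 * (ai + ai.T)
        return _Pieces(ll, beta, xtvx_inv, grad, ai, tr_pk, qf)


def _em_step(s: np.ndarray, pieces: _Pieces, n: int) -> np.ndarray:
    out = s + s**2 * (pieces.qf - pieces.tr_pk) / n
    return np.clip(out, 0.0, None)


def _reml_driver(model, init, max_iter=100, tol=1e-8, names=None) -> REMLResult:
    s = np.asarray(init, dtype=float).copy()
    nc = model.n_comp
    if len(s) != nc:
        raise ValueError("bad initial values")
    floor_e = max(1e-12, 1e-8 * float(s.sum()))
    # a thresholded kinship matrix need not be PSD, so the naive starting
    # point can give an indefinite V; shift variance onto the residual until
    # the initial V is positive definite
    total = float(s.sum())
    for _ in range(60):
        try:
            pieces = model.pieces(s)
            break
        except NotPositiveDefiniteError:
            s[:-1] *= 0.5
            s[-1] = total - float(s[:-1].sum())
    else:
        raise NotPositiveDefiniteError("could not find a positive-definite starting V")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it == 1:
            s_try = _em_step(s, pieces, model.n)
            s_try[-1] = max(s_try[-1], floor_e)
            try:
                cand = model.pieces(s_try)
            except NotPositiveDefiniteError:
                cand = None
            if cand is None or cand.loglik < pieces.loglik - 1e-6:
                s_try, cand = s, pieces
            s_new, pieces_new = s_try, cand
        else:
            active = np.array(
                [not (s[i] <= 0.0 and pieces.grad[i] < 0.0) for i in range(nc)], dtype=bool
            )
            active[-1] = True
            delta = np.zeros(nc)
            ai_a = pieces.ai[np.ix_(active, active)]
            try:
                delta[active] = np.linalg.solve(ai_a, pieces.grad[active])
            except np.linalg.LinAlgError:
                delta[active] = pieces.grad[active] / max(np.abs(np.diag(ai_a)).max(), 1.0)
            t = 1.0
            accepted = False
            while t > 1e-9:
                s_try = np.clip(s + t * delta, 0.0, None)
                s_try[~active] = s[~active]
                s_try[-1] = max(s_try[-1], floor_e)
                try:
                    cand = model.pieces(s_try)
                except (NotPositiveDefiniteError, np.linalg.LinAlgError):
                    t /= 2.0
                    continue
                if cand.loglik >= pieces.loglik - 1e-10:
                    s_new, pieces_new, accepted = s_try, cand, True
                    break
                t /= 2.0
            if not accepted:
                s_try = _em_step(s, pieces, model.n)
                s_try[-1] = max(s_try[-1], floor_e)
                try:
                    pieces_new = model.pieces(s_try)
                    s_new = s_try
                except NotPositiveDefiniteError:
                    s_new, pieces_new = s, pieces
        dll = pieces_new.loglik - pieces.loglik
        s, pieces = s_new, pieces_new
        if abs(dll) < tol:
            converged = True
            break
    cov = np.linalg.pinv(pieces.ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se_beta = np.sqrt(np.clip(np.diag(pieces.xtvx_inv), 0.0, None))
    if names is None:
        names = [f"V{i}" for i in range(nc - 1)] + ["Ve"]
    if not converged:
        logger.warning("REML did not converge in %d iterations (|dlogL|=%.3g)", max_iter, abs(dll))
    return REMLResult(
        sigma2=s,
        se_sigma2=se,
        cov_sigma2=cov,
        beta=pieces.beta,
        se_beta=se_beta,
        loglik=float(pieces.loglik),
        converged=converged,
        n_iter=it,
        names=list(names),
    )


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design X")


def _ols_result(y: np.ndarray, X: np.ndarray) -> REMLResult:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s_e = rss / (n - p)
    xtx = X.T @ X
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    ll = -0.5 * (
        (n - p) * np.log(s_e) + logdet_xtx + (n - p) + (n - p) * _LOG2PI
    )
    var_se = 2.0 * s_e**2 / (n - p)
    xtx_inv = np.linalg.inv(xtx)
    return REMLResult(
        sigma2=np.array([s_e]),
        se_sigma2=np.array([np.sqrt(var_se)]),
        cov_sigma2=np.array([[var_se]]),
        beta=beta,
        se_beta=np.sqrt(np.clip(np.diag(xtx_inv) * s_e, 0.0, None)),
        loglik=float(ll),
        converged=True,
        n_iter=0,
        names=["Ve"],
    )


def fit_reml(
    y,
    X,
    grms,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    init=None,
    names=None,
) -> REMLResult:
    """REML fit of a linear mixed model with the given GRMs as random effects.

    ``y`` is analysed on the scale given (a 0/1 case indicator yields
    observed-scale components); ``X`` must include the intercept. Components
    that hit zero are held on the boundary. Non-convergence flags the result
    instead of raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    _check_design(X)
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float) for g in grms]
    q = len(mats)
    if q == 0:
        return _ols_result(y, X)
    vp = float(np.var(y))
    if init is None:
        init = np.full(q + 1, vp / (q + 1))
    if names is None:
        names = [
            (g.role if isinstance(g, GRM) else f"V{i}") for i, g in enumerate(grms)
        ] + ["Ve"]
    if q == 1:
        lam, Q = np.linalg.eigh(mats[0])
        lam = np.clip(lam, 0.0, None)
        model = _LowRankModel(Q.T @ y, Q.T @ X, [(lam, 0.0)])
    else:
        model = _DenseModel(y, X, mats)
    return _reml_driver(model, init, max_iter=max_iter, tol=tol, names=names)


def restricted_loglik(y, X, grms, sigma2) -> float:
    """Restricted log-likelihood at fixed variance components (dense kernel)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float) for g in grms]
    model = _DenseModel(y, X, mats)
    return model.pieces(np.asarray(sigma2, dtype=float)).loglik


def lrt_region(logl_full: float, logl_null: float) -> tuple[float, float]:
    """Boundary-mixture likelihood-ratio test for one variance component.

    LRT = 2 (logL_full - logL_null) clipped at zero; under the null the
    statistic is a 50:50 mixture of a point mass at 0 and chi2(1), so
    p = 0.5 * Pr(chi2_1 >= LRT), giving p = 0.5 at LRT = 0.
    """
    lrt = max(0.0, 2.0 * (logl_full - logl_null))
    p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5
    return lrt, p


def preadjust(y, X, grm: GRM, *, max_iter: int = 100, tol: float = 1e-8):
    """Residualize the phenotype on fixed effects and the genome-wide BLUP.

    One genome-wide REML fit gives b-hat and the BLUP u-hat of the aggregate
    genetic effect; the returned y* = y - X b-hat - u-hat (equal to
    sigma_e^2 V^{-1} (y - X b-hat)) is then scanned with a single-rGRM model
    per block. With zero estimated genetic variance y* reduces to the OLS
    residuals.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    _check_design(X)
    lam, Q = np.linalg.eigh(grm.matrix)
    lam = np.clip(lam, 0.0, None)
    yt, Xt = Q.T @ y, Q.T @ X
    model = _LowRankModel(yt, Xt, [(lam, 0.0)])
    vp = float(np.var(y))
    res = _reml_driver(model, np.full(2, vp / 2), max_iter=max_iter, tol=tol, names=[grm.role, "Ve"])
    d = res.sigma2[0] * lam + res.sigma2[-1]
    rt = yt - Xt @ res.beta
    ystar = Q @ (res.sigma2[-1] * rt / d)
    return ystar, res


@dataclass
class ScanResult:
    records: pd.DataFrame
    threshold: float
    alpha: float
    mode: str


def bonferroni_threshold(n_blocks: int, alpha: float = 0.05) -> float:
    """Genome-wide LRT significance threshold alpha / n_blocks."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return alpha / n_blocks


def _design_from_covars(covars: pd.DataFrame | None, panel) -> tuple[np.ndarray, np.ndarray]:
    if covars is None:
        raise ValueError("a phenotype/covariate table is required")
    df = covars.set_index("iid").reindex(panel.iids)
    if df["pheno"].isna().any():
        missing = [i for i in panel.iids if i not in covars["iid"].values]
        raise ValueError(f"phenotype missing for individuals {missing[:5]}")
    y = df["pheno"].to_numpy(dtype=float)
    cols = [c for c in df.columns if c != "pheno"]
    X = np.column_stack([np.ones(len(y))] + [df[c].to_numpy(dtype=float) for c in cols])
    return y, X


def scan_genome(
    panel,
    blockset: BlockSet,
    covars: pd.DataFrame,
    mode: str = "preadjusted",
    alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ScanResult:
    """Per-block regional heritability scan with the boundary-mixture LRT.

    ``mode="preadjusted"``: one genome-wide REML fit residualizes covariates
    and the aggregate genetic effect, then each block is tested with a
    single-rGRM model on y* (fast, conservative). ``mode="two_grm"``: each
    block is tested with the rGRM + complement-cGRM model against the
    cGRM-only null (the unbiased estimator used to re-test hits).
    """
    if mode not in ("preadjusted", "two_grm"):
        raise ValueError("mode must be 'preadjusted' or 'two_grm'")
    if len(blockset) < 2:
        raise ValueError("need at least two blocks to scan")
    y, X = _design_from_covars(covars, panel)
    whole = compute_grm(panel)
    m_all = whole.n_snps
    rows = []

    if mode == "preadjusted":
        ystar, bg_fit = preadjust(y, X, whole, max_iter=max_iter, tol=tol)
        X1 = np.ones((len(ystar), 1))
        null = _ols_result(ystar, X1)
        vp = float(np.var(ystar))
        for bid, members in zip(blockset.block_ids, blockset.members):
            rec = blockset.table[blockset.table["block_id"] == bid].iloc[0]
            try:
                F = standardized_dosages(panel, members) / np.sqrt(len(members))
                model = _LowRankModel(ystar, X1, [(None, 1.0)], U=F)
                fit = _reml_driver(
                    model, np.full(2, vp / 2), max_iter=max_iter, tol=tol, names=["rGRM", "Ve"]
                )
                lrt, p = lrt_region(fit.loglik, null.loglik)
                hg2, se = fit.fraction(0)
                rows.append(
                    dict(block_id=bid, chrom=rec["chrom"], start=rec["start"], end=rec["end"],
                         n_snps=len(members), hg2=hg2, se=se, lrt=lrt, p=p,
                         converged=fit.converged)
                )
            except (ValueError, np.linalg.LinAlgError, NotPositiveDefiniteError) as exc:
                logger.warning("block %s failed: %s", bid, exc)
                rows.append(
                    dict(block_id=bid, chrom=rec["chrom"], start=rec["start"], end=rec["end"],
                         n_snps=len(members), hg2=np.nan, se=np.nan, lrt=np.nan, p=np.nan,
                         converged=False)
                )
    else:
        lam, Q = np.linalg.eigh(whole.matrix)
        lam = np.clip(lam, 0.0, None)
        yt, Xt = Q.T @ y, Q.T @ X
        vp = float(np.var(y))
        for bid, members in zip(blockset.block_ids, blockset.members):
            rec = blockset.table[blockset.table["block_id"] == bid].iloc[0]
            m_r = len(members)
            m_c = m_all - m_r
            try:
                if m_c == 0:
                    raise ValueError("block owns every SNP; complement empty")
                F = standardized_dosages(panel, members) / np.sqrt(m_r)
                Ut = Q.T @ F
                c_comp = ((m_all / m_c) * lam, -m_r / m_c)  # complement GRM
                full_model = _LowRankModel(yt, Xt, [c_comp, (None, 1.0)], U=Ut)
                null_model = _LowRankModel(yt, Xt, [c_comp], U=Ut)
                fit = _reml_driver(
                    full_model, np.full(3, vp / 3), max_iter=max_iter, tol=tol,
                    names=["cGRM", "rGRM", "Ve"],
                )
                nfit = _reml_driver(
                    null_model, np.full(2, vp / 2), max_iter=max_iter, tol=tol,
                    names=["cGRM", "Ve"],
                )
                lrt, p = lrt_region(fit.loglik, nfit.loglik)
                hg2, se = fit.fraction(1)
                rows.append(
                    dict(block_id=bid, chrom=rec["chrom"], start=rec["start"], end=rec["end"],
                         n_snps=m_r, hg2=hg2, se=se, lrt=lrt, p=p,
                         converged=fit.converged and nfit.converged)
                )
            except (ValueError, np.linalg.LinAlgError, NotPositiveDefiniteError) as exc:
                logger.warning("block %s failed: %s", bid, exc)
                rows.append(
                    dict(block_id=bid, chrom=rec["chrom"], start=rec["start"], end=rec["end"],
                         n_snps=m_r, hg2=np.nan, se=np.nan, lrt=np.nan, p=np.nan,
                         converged=False)
                )

    records = pd.DataFrame(rows)
    threshold = bonferroni_threshold(len(blockset), alpha)
    return ScanResult(records=records, threshold=threshold, alpha=alpha, mode=mode)


def fit_two_grm_block(panel, blockset: BlockSet, block_id, covars, **kw):
    """Two-GRM refit of a single block: returns (REMLResult, lrt, p, hg2, se)."""
    from .grm import split_region

    y, X = _design_from_covars(covars, panel)
    rgrm, cgrm = split_region(panel, blockset, block_id)
    full = fit_reml(y, X, [cgrm, rgrm], names=["cGRM", "rGRM", "Ve"], **kw)
    null = fit_reml(y, X, [cgrm], names=["cGRM", "Ve"], **kw)
    lrt, p = lrt_region(full.loglik, null.loglik)
    hg2, se = full.fraction(1)
    return full, lrt, p, hg2, se


def power_greml(n: int, var_offdiag: float = 2e-5, h2: float = 0.0, alpha: float = 0.05) -> float:
    """GREML power: SE(h2-hat) ~ sqrt(2 / (n^2 v)), chi-square test at alpha.

    ``var_offdiag`` is the variance of the GRM off-diagonal entries (about
    2e-5 for conventionally unrelated samples). Power is the probability that
    a noncentral chi2(1) with ncp (h2/SE)^2 exceeds the central critical
    value at alpha.
    """
    if var_offdiag <= 0:
        raise ValueError("var_offdiag must be > 0")
    se = np.sqrt(2.0 / (n**2 * var_offdiag))
    ncp = (h2 / se) ** 2
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(alpha)
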