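"""Bivariate GREML: genetic correlation from individual-level data.

Builds a genetic relationship matrix (GRM) from MAF-filtered standardized
dosages, prunes related individuals at a relatedness threshold, and fits
the two-trait linear mixed model

    y = X beta + g + e,   cov(g) = G0 (x) A,   cov(e) = E0 (x) I,

by average-information (AI) REML with damped fallback steps and boundary
clamping, yielding the genetic variances Vg1, Vg2, the genetic covariance
Cg and hence r_g = Cg / sqrt(Vg1 Vg2), with standard errors from the
inverse AI matrix (delta method for r_g).  Traits may be observed on
different, partially overlapping sample subsets; the residual covariance Ce
only couples the two observations of the same individual.

When both traits are measured on the identical sample set the model is
solved in the eigenbasis of the GRM, where the covariance factorises into
independent 2 x 2 blocks per eigenvalue: one eigendecomposition replaces
all large linear algebra and each REML iteration costs O(n).

A Haseman-Elston cross-product regression with block-jackknife standard
errors is provided as a method-of-moments oracle for the REML fit.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "GRM",
    "VarianceComponents",
    "RemlConvergenceError",
    "compute_grm",
    "prune_relatedness",
    "bivariate_reml",
    "he_regression",
]

_PARAM_NAMES = ("vg1", "cg", "vg2", "ve1", "ce", "ve2")


@dataclasses.dataclass
class GRM:
    """Genetic relationship matrix over a sample set."""

    ids: list[str]
    matrix: np.ndarray
    n_snps: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape inconsistent with id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")

    def subset(self, ids: Sequence[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return GRM(list(ids), self.matrix[np.ix_(idx, idx)], self.n_snps)


@dataclasses.dataclass
class VarianceComponents:
    """Bivariate variance-component estimates and their uncertainties."""

    vg1: float
    vg2: float
    cg: float
    ve1: float
    ve2: float
    ce: float
    r_g: float
    se: dict  # keys: vg1, cg, vg2, ve1, ce, ve2, r_g
    loglik: float
    n_iter: int
    converged: bool
    method: str = "ai-reml"
    r_e: float = float("nan")

    @property
    def r_g_pvalue(self) -> float:
        """Wald p-value for r_g = 0 against the normal reference."""
        se = self.se.get("r_g", float("nan"))
        if not np.isfinite(se) or se <= 0:
            return float("nan")
        return float(2.0 * sps.norm.sf(abs(self.r_g) / se))


class RemlConvergenceError(RuntimeError):
    """REML failed to converge; carries the last iterate and gradient norm."""

    def __init__(self, message, theta, grad_norm, loglik):
        super().__init__(message)
        self.theta = theta
        self.grad_norm = grad_norm
        self.loglik = loglik


# ---------------------------------------------------------------------------
# GRM construction and pruning
# ---------------------------------------------------------------------------

def compute_grm(panel: GenotypePanel, maf_min: float = 0.01) -> GRM:
    """GRM from standardized dosages: A = (1/m) Xs Xs' with
    Xs_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)), p_j the sample EAF.
    SNPs with minor allele frequency <= maf_min are excluded.
    """
    if panel.n_snps == 0 or panel.n_samples == 0:
        raise ValueError("empty genotype panel")
    p = panel.dosages.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    m = int(keep.sum())
    if m == 0:
        raise ValueError(f"no SNP passes the MAF > {maf_min} filter")
    x = panel.dosages[:, keep]
    pk = p[keep]
    xs = (x - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    a = (xs @ xs.T) / m
    return GRM(list(panel.sample_ids), a, m)


def prune_relatedness(grm: GRM, threshold: float = 0.025) -> list[str]:
    """Greedy relatedness pruning: while any off-diagonal relationship is
    >= threshold, drop the individual in the most such pairs (ties broken by
    dropping the lexicographically later id).  The retained set has all
    pairwise relationships below the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(grm.ids)
    adj = np.abs(grm.matrix) >= threshold
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    ids = np.asarray(grm.ids, dtype=object)
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        dmax = deg.max()
        if dmax == 0:
            break
        cand = np.flatnonzero(deg == dmax)
        drop = cand[np.argmax(ids[cand].astype(str))]
        active[drop] = False
    return [s for s, a in zip(grm.ids, active) if a]


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------

def _clamp(theta: np.ndarray, floor_g: float, floor_e: float,
           rho_max: float = 0.9999) -> np.ndarray:
    t = theta.copy()
    t[0] = max(t[0], floor_g)
    t[2] = max(t[2], floor_g)
    t[3] = max(t[3], floor_e)
    t[5] = max(t[5], floor_e)
    cmax = rho_max * np.sqrt(t[0] * t[2])
    t[1] = np.clip(t[1], -cmax, cmax)
    emax = rho_max * np.sqrt(t[3] * t[5])
    t[4] = np.clip(t[4], -emax, emax)
    return t


class _EigenBivariateREML:
    """Full-overlap solver in the GRM eigenbasis (O(n) per iteration)."""

    def __init__(self, a: np.ndarray, y: np.ndarray, w: np.ndarray):
        lam, u = np.linalg.eigh(a)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = u.T @ y          # (n, 2)
        self.wt = u.T @ w          # (n, q)
        self.n = a.shape[0]
        self.q = w.shape[1]
        self.n_records = 2 * self.n
        e12 = np.array([[0.0, 1.0], [1.0, 0.0]])
        e11 = np.array([[1.0, 0.0], [0.0, 0.0]])
        e22 = np.array([[0.0, 0.0], [0.0, 1.0]])
        ones = np.ones(self.n)
        self.kernels = [(self.lam, e11), (self.lam, e12), (self.lam, e22),
                        (ones, e11), (ones, e12), (ones, e22)]

    def _vinv(self, theta):
        vg1, cg, vg2, ve1, ce, ve2 = theta
        v11 = self.lam * vg1 + ve1
        v12 = self.lam * cg + ce
        v22 = self.lam * vg2 + ve2
        det = v11 * v22 - v12 ** 2
        if np.any(det <= 0) or np.any(v11 <= 0) or np.any(v22 <= 0):
            return None
        vinv = np.empty((self.n, 2, 2))
        vinv[:, 0, 0] = v22 / det
        vinv[:, 1, 1] = v11 / det
        vinv[:, 0, 1] = vinv[:, 1, 0] = -v12 / det
        return vinv, float(np.log(det).sum())

    def _xtvx(self, wmat):
        """Assemble the 2q x 2q matrix sum_i X_i' M_i X_i from per-block 2x2
        weights ``wmat`` (n, 2, 2)."""
        q = self.q
        out = np.empty((2 * q, 2 * q))
        for a in range(2):
            for b in range(2):
                out[a * q:(a + 1) * q, b * q:(b + 1) * q] = \
                    self.wt.T @ (wmat[:, a, b, None] * self.wt)
        return out

    def _apply_p(self, vinv, bmat, vec):
        """P v for a per-block vector field vec (n, 2)."""
        t = np.einsum("nab,nb->na", vinv, vec)
        xtv = np.concatenate([self.wt.T @ t[:, a] for a in range(2)])
        corr = np.linalg.solve(bmat, xtv).reshape(2, self.q)
        xc = np.stack([self.wt @ corr[a] for a in range(2)], axis=1)
        return t - np.einsum("nab,nb->na", vinv, xc)

    def evaluate(self, theta):
        res = self._vinv(theta)
        if res is None:
            return None
        vinv, logdetv = res
        bmat = self._xtvx(vinv)
        sign, logdetb = np.linalg.slogdet(bmat)
        if sign <= 0:
            return None
        viy = np.einsum("nab,nb->na", vinv, self.yt)
        xtvy = np.concatenate([self.wt.T @ viy[:, a] for a in range(2)])
        beta = np.linalg.solve(bmat, xtvy).reshape(2, self.q)
        resid = self.yt - np.stack([self.wt @ beta[a] for a in range(2)], axis=1)
        py = np.einsum("nab,nb->na", vinv, resid)
        ypy = float((resid * py).sum())
        loglik = -0.5 * (logdetv + logdetb + ypy)

        u_list = []
        trpk = np.empty(6)
        for j, (f, mmat) in enumerate(self.kernels):
            u = f[:, None] * (py @ mmat.T)
            u_list.append(u)
            # tr(Vinv K): sum_n f_n tr(Vinv_n M)
            term1 = float((f * np.einsum("nab,ba->n", vinv, mmat)).sum())
            nmat = np.einsum("nab,bc,ncd->nad", vinv, mmat, vinv) * f[:, None, None]
            cmat = self._xtvx(nmat)
            term2 = float(np.trace(np.linalg.solve(bmat, cmat)))
            trpk[j] = term1 - term2
        pu = [self._apply_p(vinv, bmat, u) for u in u_list]
        score = np.array([-0.5 * (trpk[j] - float((u_list[j] * py).sum()))
                          for j in range(6)])
        ai = 0.5 * np.array([[float((u_list[i] * pu[j]).sum()) for j in range(6)]
                             for i in range(6)])
        return loglik, score, ai


class _DenseBivariateREML:
    """General missing-pattern solver with explicit stacked covariance."""

    def __init__(self, a: np.ndarray, y1, y2, idx1, idx2, w: np.ndarray):
        n1, n2 = len(idx1), len(idx2)
        self.nt = n1 + n2
        self.n_records = self.nt
        kv = []
        z = np.zeros((self.nt, self.nt))
        kg1 = z.copy(); kg1[:n1, :n1] = a[np.ix_(idx1, idx1)]
        kg2 = z.copy(); kg2[n1:, n1:] = a[np.ix_(idx2, idx2)]
        kcg = z.copy()
        cross = a[np.ix_(idx1, idx2)]
        kcg[:n1, n1:] = cross; kcg[n1:, :n1] = cross.T
        ke1 = z.copy(); ke1[:n1, :n1] = np.eye(n1)
        ke2 = z.copy(); ke2[n1:, n1:] = np.eye(n2)
        kce = z.copy()
        same = (np.asarray(idx1)[:, None] == np.asarray(idx2)[None, :]).astype(float)
        kce[:n1, n1:] = same; kce[n1:, :n1] = same.T
        self.kernels = [kg1, kcg, kg2, ke1, kce, ke2]
        self.y = np.concatenate([y1, y2])
        q = w.shape[1]
        self.x = np.zeros((self.nt, 2 * q))
        self.x[:n1, :q] = w[idx1]
        self.x[n1:, q:] = w[idx2]

    def evaluate(self, theta):
        v = sum(t * k for t, k in zip(theta, self.kernels))
        try:
            cf = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return None
        logdetv = 2.0 * float(np.log(np.diag(cf)).sum())
        vinv = np.linalg.inv(v)
        xtvx = self.x.T @ vinv @ self.x
        sign, logdetb = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return None
        vix = vinv @ self.x
        p = vinv - vix @ np.linalg.solve(xtvx, vix.T)
        py = p @ self.y
        ypy = float(self.y @ py)
        loglik = -0.5 * (logdetv + logdetb + ypy)
        u = np.column_stack([k @ py for k in self.kernels])
        pu = p @ u
        score = np.array([-0.5 * (float((p * k).sum()) - float(u[:, j] @ py))
                          for j, k in enumerate(self.kernels)])
        ai = 0.5 * (u.T @ pu)
        return loglik, score, ai


def bivariate_reml(grm: GRM, phenotypes: PhenotypeTable,
                   covariates: Sequence[str] = (),
                   max_iter: int = 100, tol: float = 1e-6,
                   min_per_trait: int = 50) -> VarianceComponents:
    """Fit the bivariate GREML model and return variance components.

    ``phenotypes`` must carry exactly two traits; each needs at least
    ``min_per_trait`` non-missing observations among the GRM samples.
    Fixed effects are a per-trait intercept plus the named covariate
    columns.  AI steps that leave the parameter space or decrease the
    restricted likelihood are damped (step-halving), so the reported
    likelihood is non-decreasing; variance components are clamped at zero
    (boundary allowed) and covariances at |rho| <= 0.9999.
    """
    if len(phenotypes.traits) != 2:
        raise ValueError("bivariate_reml needs exactly two traits")
    t1, t2 = phenotypes.traits
    frame = phenotypes.frame
    in_phen = [i for i, s in enumerate(grm.ids) if s in frame.index]
    ids = [grm.ids[i] for i in in_phen]
    sub = frame.loc[ids]
    y1_all = sub[t1].to_numpy(dtype=float)
    y2_all = sub[t2].to_numpy(dtype=float)
    w = np.column_stack([np.ones(len(ids))] +
                        [sub[c].to_numpy(dtype=float) for c in covariates])
    if np.linalg.matrix_rank(w) < w.shape[1]:
        raise ValueError("singular fixed-effect design")
    cov_ok = np.isfinite(w).all(axis=1)
    obs1 = np.isfinite(y1_all) & cov_ok
    obs2 = np.isfinite(y2_all) & cov_ok
    if obs1.sum() < min_per_trait or obs2.sum() < min_per_trait:
        raise ValueError(
            f"need >= {min_per_trait} non-missing individuals per trait "
            f"(got {int(obs1.sum())}, {int(obs2.sum())})")
    a = grm.matrix[np.ix_(in_phen, in_phen)]

    # starting values: half the residual variance / covariance
    def _resid(y, mask):
        wm = w[mask]
        yv = y[mask]
        beta, *_ = np.linalg.lstsq(wm, yv, rcond=None)
        return yv - wm @ beta

    r1, r2 = _resid(y1_all, obs1), _resid(y2_all, obs2)
    vp1, vp2 = float(np.var(r1)), float(np.var(r2))
    both = obs1 & obs2
    if both.sum() > 2:
        rb1 = _resid(y1_all, both)
        rb2 = _resid(y2_all, both)
        c12 = float(np.cov(rb1, rb2)[0, 1])
    else:
        c12 = 0.0
    theta = np.array([vp1 / 2, c12 / 2, vp2 / 2, vp1 / 2, c12 / 2, vp2 / 2])
    floor_g = 1e-8 * max(vp1, vp2)
    floor_e = 1e-8 * max(vp1, vp2)
    theta = _clamp(theta, floor_g, floor_e)

    idx1 = np.flatnonzero(obs1)
    idx2 = np.flatnonzero(obs2)
    if len(idx1) == len(idx2) and np.array_equal(idx1, idx2):
        solver = _EigenBivariateREML(a[np.ix_(idx1, idx1)],
                                     np.column_stack([y1_all[idx1],
                                                      y2_all[idx1]]),
                                     w[idx1])
        method = "ai-reml (eigen)"
    else:
        solver = _DenseBivariateREML(a, y1_all[idx1], y2_all[idx2],
                                     idx1, idx2, w)
        method = "ai-reml (dense)"

    res = solver.evaluate(theta)
    if res is None:
        raise RemlConvergenceError("invalid starting point", theta,
                                   float("nan"), float("nan"))
    loglik, score, ai = res
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ridge = 1e-8 * max(1.0, float(np.abs(np.diag(ai)).max()))
        try:
            delta = np.linalg.solve(ai + ridge * np.eye(6), score)
        except np.linalg.LinAlgError:
            delta = score / max(1.0, float(np.linalg.norm(ai)))
        accepted = None
        for _ in range(30):  # damped fallback: halve until likelihood rises
            cand = _clamp(theta + delta, floor_g, floor_e)
            ev = solver.evaluate(cand)
            if ev is not None and ev[0] >= loglik - 1e-10:
                accepted = (cand, ev)
                break
            delta = delta / 2.0
        if accepted is None:
            converged = True  # no improving direction left: boundary optimum
            break
        new_theta, (new_ll, new_score, new_ai) = accepted
        rel = np.max(np.abs(new_theta - theta) /
                     np.maximum(np.abs(theta), 1e-3 * max(vp1, vp2)))
        theta, loglik, score, ai = new_theta, new_ll, new_score, new_ai
        if rel < tol:
            converged = True
            break
    grad_norm = float(np.linalg.norm(score))
    if not converged and it >= max_iter:
        raise RemlConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.3g})", theta, grad_norm, loglik)

    vg1, cg, vg2, ve1, ce, ve2 = theta
    r_g = float(cg / np.sqrt(vg1 * vg2)) if vg1 > 0 and vg2 > 0 else float("nan")
    r_e = float(ce / np.sqrt(ve1 * ve2)) if ve1 > 0 and ve2 > 0 else float("nan")
    se = {k: float("nan") for k in _PARAM_NAMES}
    se["r_g"] = float("nan")
    try:
        aiinv = np.linalg.inv(ai)
        d = np.diag(aiinv)
        if np.all(d > 0):
            for k, v in zip(_PARAM_NAMES, np.sqrt(d)):
                se[k] = float(v)
        if vg1 > 0 and vg2 > 0:
            grad = np.zeros(6)
            grad[0] = -r_g / (2 * vg1)
            grad[1] = 1.0 / np.sqrt(vg1 * vg2)
            grad[2] = -r_g / (2 * vg2)
            var_rg = float(grad @ aiinv @ grad)
            if var_rg > 0:
                se["r_g"] = float(np.sqrt(var_rg))
    except np.linalg.LinAlgError:
        pass
    return VarianceComponents(
        vg1=float(vg1), vg2=float(vg2), cg=float(cg),
        ve1=float(ve1), ve2=float(ve2), ce=float(ce),
        r_g=r_g, r_e=r_e, se=se, loglik=float(loglik),
        n_iter=it, converged=converged, method=method,
    )


# ---------------------------------------------------------------------------
# Haseman-Elston regression (method-of-moments oracle)
# ---------------------------------------------------------------------------

def _pair_slope(amat, prod, valid):
    """OLS slope (with intercept) of prod on amat over valid ordered pairs,
    together with per-quantity totals for jackknifing."""
    v = valid.astype(float)
    n = v.sum()
    sx = (amat * v).sum()
    sy = (prod * v).sum()
    sxx = (amat * amat * v).sum()
    sxy = (amat * prod * v).sum()
    return np.array([n, sx, sy, sxx, sxy])


def _slope_from_sums(s):
    n, sx, sy, sxx, sxy = s
    denom = sxx - sx * sx / n
    if denom <= 0:
        return float("nan")
    return float((sxy - sx * sy / n) / denom)


def _block_loo_sums(amat, prod, valid, blocks):
    """Totals and leave-one-block-out totals of the pair sums."""
    total = _pair_slope(amat, prod, valid)
    loo = []
    v = valid.astype(float)
    quantities = [v, amat * v, prod * v, amat * amat * v, amat * prod * v]
    for b in blocks:
        sub = np.zeros(5)
        for qi, qmat in enumerate(quantities):
            rows = qmat[b, :].sum()
            cols = qmat[:, b].sum()
            within = qmat[np.ix_(b, b)].sum()
            sub[qi] = rows + cols - within
        loo.append(total - sub)
    return total, loo


def he_regression(grm: GRM, phenotypes: PhenotypeTable,
                  n_blocks: int = 20) -> VarianceComponents:
    """Haseman-Elston cross-product regression on the GRM.

    Standardized within-trait products y_i y_j (i < j, both observed)
    regressed on A_ij estimate h2 per trait; between-trait products over
    distinct individuals estimate the standardized genetic covariance; r_g
    is their ratio.  Standard errors are block-jackknife over ``n_blocks``
    contiguous sample blocks.  Covariates are not adjusted here — this is a
    deliberately simple independent oracle for the REML fit.
    """
    if len(phenotypes.traits) != 2:
        raise ValueError("he_regression needs exactly two traits")
    t1, t2 = phenotypes.traits
    frame = phenotypes.frame
    in_phen = [i for i, s in enumerate(grm.ids) if s in frame.index]
    ids = [grm.ids[i] for i in in_phen]
    sub = frame.loc[ids]
    a = grm.matrix[np.ix_(in_phen, in_phen)]
    n = len(ids)

    ys = []
    masks = []
    for t in (t1, t2):
        y = sub[t].to_numpy(dtype=float)
        m = np.isfinite(y)
        ystd = np.zeros(n)
        ystd[m] = (y[m] - y[m].mean()) / y[m].std()
        ys.append(ystd)
        masks.append(m)
    y1, y2 = ys
    m1, m2 = masks
    offdiag = ~np.eye(n, dtype=bool)

    blocks = [np.arange(n)[i::n_blocks] for i in range(n_blocks)]

    def slopes_for(prod, valid):
        total, loo = _block_loo_sums(a, prod, valid, blocks)
        return _slope_from_sums(total), np.array([_slope_from_sums(s) for s in loo])

    h2_1, h2_1_loo = slopes_for(np.outer(y1, y1), np.outer(m1, m1) & offdiag)
    h2_2, h2_2_loo = slopes_for(np.outer(y2, y2), np.outer(m2, m2) & offdiag)
    cross_valid = np.outer(m1, m2) & offdiag
    if not cross_valid.any():
        raise ValueError("no overlapping cross-trait pairs; "
                         "cross-trait term unavailable")
    cg, cg_loo = slopes_for(np.outer(y1, y2), cross_valid)

    def _rg(h1, h2_, c):
        with np.errstate(invalid="ignore", divide="ignore"):
            return c / np.sqrt(h1 * h2_)

    r_g = float(_rg(h2_1, h2_2, cg))
    rg_loo = _rg(h2_1_loo, h2_2_loo, cg_loo)

    def jse(vals, est):
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        nb = len(vals)
        if nb < 2:
            return float("nan")
        return float(np.sqrt((nb - 1) / nb * ((vals - vals.mean()) ** 2).sum()))

    se = {
        "vg1": jse(h2_1_loo, h2_1), "vg2": jse(h2_2_loo, h2_2),
        "cg": jse(cg_loo, cg), "r_g": jse(rg_loo, r_g),
        "ve1": float("nan"), "ce": float("nan"), "ve2": float("nan"),
    }
    return VarianceComponents(
        vg1=float(h2_1), vg2=float(h2_2), cg=float(cg),
        ve1=float(1.0 - h2_1), ve2=float(1.0 - h2_2), ce=float("nan"),
        r_g=r_g, se=se, loglik=float("nan"), n_iter=0, converged=True,
        method="haseman-elston",
    )
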