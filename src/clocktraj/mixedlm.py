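"""Maximum-likelihood linear mixed models for small per-individual blocks.

Per-site trajectory models have at most a handful of observations per
individual (one per visit), so the marginal covariance factorises into
thousands of tiny per-individual blocks.  This fitter exploits that: groups
are padded into a (groups, m, m) batch, the profiled deviance is evaluated
with batched Cholesky factorisations, and the variance parameters are
optimised by quasi-Newton search on an unconstrained scale (log-SD for
each random effect and the residual, atanh for the intercept-slope
correlation), with deterministic restarts.  Fixed effects are profiled out
by generalised least squares at every step, so the search space is only
the 3-6 variance parameters.

Random-effect covariance structure: the first two random columns may share
a free correlation ("block" structure); all remaining columns are
independent.  Fitting with ``correlated=False`` gives the fully diagonal
structure, which also serves as the zero-correlation null for the
likelihood-ratio test of the intercept-slope correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMResult", "fit_lmm"]

_LOG_SD_FLOOR = -14.0  # ~1e-6 of the residual scale: an effectively-zero component
_START_FACTORS = (0.5, 1.0, 0.05)  # deterministic restart scales


@dataclass
class LMMResult:
    """ML fit of one linear mixed model."""

    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    names: list[str]
    sd_random: np.ndarray
    rho: float | None
    sd_resid: float
    loglik: float
    converged: bool
    singular: np.ndarray
    cov_beta: np.ndarray
    n_obs: int
    n_groups: int
    max_group_size: int

    def fixed(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) of a named fixed effect."""
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.pvalues[i])

    def contrast(self, weights: np.ndarray) -> tuple[float, float, float]:
        """Estimate, delta-method SE and Wald p of a fixed-effect contrast."""
        w = np.asarray(weights, dtype=float)
        est = float(w @ self.beta)
        se = float(np.sqrt(w @ self.cov_beta @ w))
        p = _wald_p(est, se)
        return est, se, p


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def _pack(y, X, Z, groups):
    """Pad observations into per-group blocks.

    Padded rows get zero design rows; the padded diagonal of each
    covariance block is later pinned to 1 so it contributes nothing to the
    log-determinant or the quadratic form.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    codes, counts = np.unique(groups, return_counts=True)
    gidx = np.searchsorted(codes, groups)
    order = np.argsort(gidx, kind="stable")
    g, m = len(codes), int(counts.max())
    # row position within group, in group-sorted order
    sorted_g = gidx[order]
    pos = np.concatenate([np.arange(c) for c in counts])
    Yp = np.zeros((g, m))
    Xp = np.zeros((g, m, X.shape[1]))
    Zp = np.zeros((g, m, Z.shape[1]))
    mask = np.zeros((g, m), bool)
    Yp[sorted_g, pos] = y[order]
    Xp[sorted_g, pos] = X[order]
    Zp[sorted_g, pos] = Z[order]
    mask[sorted_g, pos] = True
    return Yp, Xp, Zp, mask


def _sym_inv_logdet(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Batched inverse and total log-determinant of SPD blocks.

    Closed-form cofactor formulas for the 1x1/2x2/3x3 blocks the visit
    schedules produce (much cheaper than batched LAPACK at this size);
    larger blocks fall back to numpy.  Raises LinAlgError on a
    non-positive determinant.
    """
    m = V.shape[-1]
    if m == 1:
        det = V[:, 0, 0]
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("non-SPD block")
        return (1.0 / det)[:, None, None], float(np.log(det).sum())
    if m == 2:
        a, b, e = V[:, 0, 0], V[:, 0, 1], V[:, 1, 1]
        det = a * e - b * b
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("non-SPD block")
        inv = np.empty_like(V)
        inv[:, 0, 0] = e
        inv[:, 1, 1] = a
        inv[:, 0, 1] = inv[:, 1, 0] = -b
        inv /= det[:, None, None]
        return inv, float(np.log(det).sum())
    if m == 3:
        a, b, c = V[:, 0, 0], V[:, 0, 1], V[:, 0, 2]
        e, f, i = V[:, 1, 1], V[:, 1, 2], V[:, 2, 2]
        A = e * i - f * f
        B = c * f - b * i
        C = b * f - c * e
        det = a * A + b * B + c * C
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("non-SPD block")
        inv = np.empty_like(V)
        inv[:, 0, 0] = A
        inv[:, 0, 1] = inv[:, 1, 0] = B
        inv[:, 0, 2] = inv[:, 2, 0] = C
        inv[:, 1, 1] = a * i - c * c
        inv[:, 1, 2] = inv[:, 2, 1] = b * c - a * f
        inv[:, 2, 2] = a * e - b * b
        inv /= det[:, None, None]
        return inv, float(np.log(det).sum())
    sign, logdet = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("non-SPD block")
    return np.linalg.inv(V), float(logdet.sum())


class _Deviance:
    def __init__(self, y, X, Z, groups, correlated):
        self.Yp, self.Xp, self.Zp, self.mask = _pack(y, X, Z, groups)
        self.q = self.Zp.shape[2]
        self.p = self.Xp.shape[2]
        self.correlated = correlated and self.q >= 2
        self.n = int(self.mask.sum())
        self.n_theta = self.q + (1 if self.correlated else 0) + 1
        g, m = self.mask.shape
        self._eye = np.eye(m)
        self._pad = ~self.mask
        self._keep = self.mask[:, :, None] & self.mask[:, None, :]
        self._pad_idx = np.nonzero(self._pad)
        self._rhs = np.concatenate([self.Yp[:, :, None], self.Xp], axis=2)

    def build_G(self, theta):
        sds = np.exp(theta[: self.q])
        rho = np.tanh(theta[self.q]) if self.correlated else 0.0
        G = np.diag(sds**2)
        if self.correlated:
            G[0, 1] = G[1, 0] = rho * sds[0] * sds[1]
        return G, sds, rho

    def _profile(self, theta, want_grad: bool = False):
        G, sds, rho = self.build_G(theta)
        s2 = np.exp(2.0 * theta[-1])
        V = self.Zp @ G @ np.swapaxes(self.Zp, 1, 2) + s2 * self._eye
        # neutralise padded slots: zero their rows/columns, unit diagonal
        V = np.where(self._keep, V, 0.0)
        gi, mi = self._pad_idx
        V[gi, mi, mi] = 1.0
        Vinv, logdet = _sym_inv_logdet(V)
        W = Vinv @ self._rhs
        Wy, Wx = W[:, :, 0], W[:, :, 1:]
        A = np.einsum("gmp,gmq->pq", self.Xp, Wx)
        b = np.einsum("gmp,gm->p", self.Xp, Wy)
        yViy = float(np.einsum("gm,gm->", self.Yp, Wy))
        beta = np.linalg.solve(A, b)
        quad = yViy - float(beta @ b)
        nll = 0.5 * (self.n * np.log(2.0 * np.pi) + logdet + quad)
        if not want_grad:
            return nll, beta, A

        # analytic gradient of the profiled deviance: for each variance
        # parameter, d(nll) = 0.5 [tr(V^-1 dV) - u' dV u] with u = V^-1 r;
        # dV = Z dG Z' maps both terms onto the q x q summaries
        # M = sum_g Z' V^-1 Z and w_g = Z' u_g.
        u = Wy - np.einsum("gmp,p->gm", Wx, beta)
        M = np.einsum("gmq,gmn,gnr->qr", self.Zp, Vinv, self.Zp)
        w = np.einsum("gmq,gm->gq", self.Zp, u)
        Wq = np.einsum("gq,gr->qr", w, w)
        D = M - Wq
        grad = np.empty_like(theta)
        for k in range(self.q):
            dG = np.zeros((self.q, self.q))
            dG[k, k] = 2.0 * sds[k] ** 2
            if self.correlated and k in (0, 1):
                off = rho * sds[0] * sds[1]
                dG[0, 1] += off
                dG[1, 0] += off
            grad[k] = 0.5 * float(np.sum(D * dG))
        if self.correlated:
            dG = np.zeros((self.q, self.q))
            dG[0, 1] = dG[1, 0] = (1.0 - rho**2) * sds[0] * sds[1]
            grad[self.q] = 0.5 * float(np.sum(D * dG))
        tr_real = float(np.einsum("gii->", Vinv)) - len(self._pad_idx[0])
        grad[-1] = 0.5 * (2.0 * s2 * tr_real - 2.0 * s2 * float(np.sum(u * u)))
        return nll, beta, A, grad

    def nll(self, theta):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                val = self._profile(theta)[0]
        except np.linalg.LinAlgError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    def nll_grad(self, theta):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                nll, _, _, grad = self._profile(theta, want_grad=True)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
            return 1e12, np.zeros_like(theta)
        return nll, grad


def fit_lmm(
    y,
    X,
    Z,
    groups,
    x_names: list[str] | None = None,
    correlated: bool = True,
    maxiter: int = 300,
    gtol: float = 1e-7,
    theta0: np.ndarray | None = None,
) -> LMMResult:
    """Fit a linear mixed model by maximum likelihood.

    Parameters
    ----------
    y, X, Z, groups
        Response, fixed design (n, p), random design (n, q) and group
        labels, all row-aligned.  ``Z`` columns are random at the group
        (individual) level.
    correlated
        Whether random columns 0 and 1 share a free correlation.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.asarray(Z, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    names = x_names or [f"x{i}" for i in range(X.shape[1])]
    dev = _Deviance(y, X, Z, groups, correlated)

    # moment-based starting values from the OLS residual scale
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    dof = max(len(y) - X.shape[1], 1)
    s0 = max(float(np.sqrt(resid @ resid / dof)), 1e-10)
    zscale = np.maximum(np.sqrt(np.mean(Z**2, axis=0)), 1e-8)

    # box constraints keep every covariance block well conditioned for the
    # closed-form inverses: random-effect SDs may span [~1e-6, ~50x] of the
    # OLS residual scale, and the residual SD itself cannot collapse below
    # ~0.25% of that scale (which would let the random effects interpolate
    # the data through a numerically degenerate likelihood spike)
    ls0 = np.log(np.maximum(s0, 1e-10))
    bounds = [(ls0 + _LOG_SD_FLOOR, ls0 + 4.0)] * dev.q
    if dev.correlated:
        bounds.append((-6.0, 6.0))
    bounds.append((ls0 - 6.0, ls0 + 2.0))
    lo = ls0 + _LOG_SD_FLOOR

    blo = np.array([b[0] for b in bounds])
    bhi = np.array([b[1] for b in bounds])
    starts: list[np.ndarray] = []
    if theta0 is not None and len(theta0) == dev.n_theta:
        starts.append(np.clip(np.asarray(theta0, float), blo, bhi))
    for f in _START_FACTORS:
        th0 = np.empty(dev.n_theta)
        th0[: dev.q] = np.log(np.maximum(f * s0 / zscale, 1e-9))
        if dev.correlated:
            th0[dev.q] = 0.0
        th0[-1] = np.log(s0)
        starts.append(np.clip(th0, blo, bhi))

    best = None
    converged = False
    for th0 in starts:  # deterministic restarts until convergence
        res = optimize.minimize(
            dev.nll_grad, th0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            break
    converged = converged and np.isfinite(best.fun)

    nll, beta, A = dev._profile(best.x)
    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    pvals = np.array([_wald_p(b, s) for b, s in zip(beta, se)])
    sds = np.exp(best.x[: dev.q])
    rho = float(np.tanh(best.x[dev.q])) if dev.correlated else None
    sd_resid = float(np.exp(best.x[-1]))
    # a component whose variance contribution (on the scale of its design
    # column) is < 1% of the residual variance is effectively at the boundary
    singular = sds * zscale < 0.1 * sd_resid
    counts = np.unique(groups, return_counts=True)[1]
    return LMMResult(
        beta=beta,
        se=se,
        pvalues=pvals,
        names=list(names),
        sd_random=sds,
        rho=rho,
        sd_resid=sd_resid,
        loglik=-nll,
        converged=bool(converged),
        singular=singular,
        cov_beta=cov_beta,
        n_obs=len(y),
        n_groups=len(counts),
        max_group_size=int(counts.max()),
    )
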