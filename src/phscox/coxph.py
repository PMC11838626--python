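"""Cox partial likelihood, Breslow tie handling, and an L1 solver.

This is the numerical heart of the package. The model is the Cox
proportional-hazards model h(t|x) = h0(t) exp(x'b); the partial
likelihood cancels the baseline hazard and, with the Breslow
approximation for tied event times, is

    l(b) = sum over tie groups g [ sum_{i in g} eta_i
                                   - d_g * log sum_{k in R(t_g)} exp(eta_k) ]

with eta = X_pen b_pen + X_unpen b_unpen, d_g the number of events in
group g and R(t) = {k : y_k >= t} the risk set.

The penalized objective minimized by :func:`fit_penalized` is the
negative MEAN partial log-likelihood plus an L1 penalty on the variant
coefficients only,

    f(b) = -l(b)/n + lambda * ||b_pen||_1 ,

so lambda is comparable across sample sizes. Optimization is proximal
Newton: at the current solution a diagonal quadratic approximation
(IRLS working response) is formed and solved by cyclic coordinate
descent with soft-thresholding; adjustment covariates are never
penalized. A plain Newton-Raphson fitter with the full Hessian
(:func:`fit_cox_newton`) serves the low-dimensional fits where Wald
standard errors are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "CoxData",
    "CoxFit",
    "NewtonCoxFit",
    "make_cox_data",
    "partial_loglik",
    "gradient",
    "fit_penalized",
    "fit_cox_newton",
    "kkt_max_violation",
]

_ETA_CLIP = 500.0


@dataclass
class CoxData:
    """Survival outcomes plus design matrices with precomputed risk-set order.

    ``X_pen`` holds the penalized features (standardized variants) and
    ``X_unpen`` the unpenalized adjustment covariates. The sorted index
    structure (individuals ordered by time, unique-time groups, events
    per group) is built once so likelihood/gradient evaluations are
    O(n p) with no re-sorting.
    """

    y: np.ndarray
    status: np.ndarray
    X_pen: np.ndarray
    X_unpen: np.ndarray
    # derived, filled by make_cox_data
    order: np.ndarray = field(repr=False, default=None)
    status_sorted: np.ndarray = field(repr=False, default=None)
    uniq_inverse: np.ndarray = field(repr=False, default=None)
    uniq_first: np.ndarray = field(repr=False, default=None)
    d_uniq: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p_pen(self) -> int:
        return self.X_pen.shape[1]

    @property
    def p_unpen(self) -> int:
        return self.X_unpen.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


def make_cox_data(
    y: np.ndarray,
    status: np.ndarray,
    X_pen: np.ndarray | None = None,
    X_unpen: np.ndarray | None = None,
) -> CoxData:
    """Validate inputs and precompute the risk-set ordering structure."""
    y = np.asarray(y, dtype=np.float64).ravel()
    status = np.asarray(status, dtype=np.float64).ravel()
    n = y.shape[0]
    if status.shape[0] != n:
        raise ValueError("y and status lengths differ")
    if np.any(y <= 0):
        raise ValueError("all survival times must be > 0")
    if not np.all(np.isin(status, [0.0, 1.0])):
        raise ValueError("status must be 0/1")
    if status.sum() == 0:
        raise ValueError("no events in the data")
    X_pen = _as_design(X_pen, n)
    X_unpen = _as_design(X_unpen, n)
    order = np.argsort(y, kind="stable")
    y_sorted = y[order]
    status_sorted = status[order]
    uniq, first, inv = np.unique(y_sorted, return_index=True, return_inverse=True)
    d_uniq = np.bincount(inv, weights=status_sorted, minlength=uniq.size)
    return CoxData(
        y=y,
        status=status,
        X_pen=X_pen,
        X_unpen=X_unpen,
        order=order,
        status_sorted=status_sorted,
        uniq_inverse=inv,
        uniq_first=first,
        d_uniq=d_uniq,
    )


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.empty((n, 0))
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != n and X.shape[1] == n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("design matrix rows do not match y")
    return X


def _breslow(data: CoxData, eta: np.ndarray):
    """Log-likelihood (sum scale), score residuals u and IRLS weights h.

    u_i = status_i - w_i * H0(y_i) and h_i = w_i*A_i - w_i^2*B_i with
    H0 the Breslow cumulative hazard, A = sum d_g/r_g and
    B = sum d_g/r_g^2 over event times <= y_i; both returned in the
    original observation order.
    """
    if np.any(~np.isfinite(eta)):
        raise FloatingPointError(
            f"non-finite linear predictor (max |eta| = {np.nanmax(np.abs(eta))})"
        )
    if np.any(np.abs(eta) > _ETA_CLIP):
        warnings.warn("linear predictor clipped at +/-500 before exponentiation")
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    eta_s = eta[data.order]
    w = np.exp(eta_s)
    suffix = np.cumsum(w[::-1])[::-1]
    r_uniq = suffix[data.uniq_first]
    haz = data.d_uniq / r_uniq
    A = np.cumsum(haz)[data.uniq_inverse]
    B = np.cumsum(data.d_uniq / r_uniq**2)[data.uniq_inverse]
    u_s = data.status_sorted - w * A
    h_s = w * A - w * w * B
    ev = data.d_uniq > 0
    ll = float(np.sum(eta_s * data.status_sorted) - np.sum(data.d_uniq[ev] * np.log(r_uniq[ev])))
    u = np.empty_like(u_s)
    h = np.empty_like(h_s)
    u[data.order] = u_s
    h[data.order] = h_s
    return ll, u, h


def _eta(data: CoxData, beta_pen, beta_unpen) -> np.ndarray:
    eta = np.zeros(data.n)
    if data.p_pen:
        eta += data.X_pen @ beta_pen
    if data.p_unpen:
        eta += data.X_unpen @ beta_unpen
    return eta


def partial_loglik(data: CoxData, beta_pen=None, beta_unpen=None) -> float:
    """Breslow partial log-likelihood (sum over tie groups, not / n)."""
    beta_pen = _coef(beta_pen, data.p_pen)
    beta_unpen = _coef(beta_unpen, data.p_unpen)
    ll, _, _ = _breslow(data, _eta(data, beta_pen, beta_unpen))
    return ll


def gradient(data: CoxData, beta_pen=None, beta_unpen=None):
    """Gradient of the MEAN partial log-likelihood l(b)/n.

    Returns (g_pen, g_unpen); each entry is (X' u)/n with u the Breslow
    score residual, i.e. the exact analytic score in O(n) per feature.
    """
    beta_pen = _coef(beta_pen, data.p_pen)
    beta_unpen = _coef(beta_unpen, data.p_unpen)
    _, u, _ = _breslow(data, _eta(data, beta_pen, beta_unpen))
    g_pen = data.X_pen.T @ u / data.n if data.p_pen else np.empty(0)
    g_unpen = data.X_unpen.T @ u / data.n if data.p_unpen else np.empty(0)
    return g_pen, g_unpen


def _coef(beta, p: int) -> np.ndarray:
    if beta is None:
        return np.zeros(p)
    beta = np.asarray(beta, dtype=np.float64).ravel()
    if beta.shape[0] != p:
        raise ValueError(f"coefficient vector has length {beta.shape[0]}, expected {p}")
    return beta


# ----------------------------------------------------------------------
# penalized solver
# ----------------------------------------------------------------------
@dataclass
class CoxFit:
    """Solution of the penalized problem at one lambda."""

    beta_pen: np.ndarray
    beta_unpen: np.ndarray
    lam: float
    objective: float
    n_iter: int
    converged: bool

    @property
    def support(self) -> np.ndarray:
        """Indices of active (nonzero) penalized coefficients."""
        return np.flatnonzero(self.beta_pen)


@njit(cache=True)
def _cd_sweep(X, h, r, beta, lam, pf, xwx, n, only_active, active):
    """One cyclic coordinate-descent sweep on the weighted least squares
    surrogate (1/2n) sum h_i (z_i - x_i'b)^2 + lam * sum pf_j |b_j|.
    ``r`` is the working residual z - X b, updated in place. Returns the
    largest weighted squared coefficient change (glmnet convergence
    measure)."""
    max_d = 0.0
    p = X.shape[1]
    for j in range(p):
        if only_active and not active[j]:
            continue
        if xwx[j] <= 0.0:
            continue
        bj = beta[j]
        num = 0.0
        for i in range(n):
            num += h[i] * X[i, j] * r[i]
        num = num / n + xwx[j] * bj
        if pf[j] > 0.0:
            t = lam * pf[j]
            if num > t:
                bnew = (num - t) / xwx[j]
            elif num < -t:
                bnew = (num + t) / xwx[j]
            else:
                bnew = 0.0
        else:
            bnew = num / xwx[j]
        d = bnew - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            beta[j] = bnew
            change = d * d * xwx[j]
            if change > max_d:
                max_d = change
        active[j] = (beta[j] != 0.0) or (pf[j] == 0.0)
    return max_d


def _solve_wls(X, h, z, beta0, lam, pf, n, inner_tol, max_sweeps=1000):
    """Weighted lasso on the quadratic surrogate, active-set strategy."""
    beta = beta0.copy()
    xwx = (h @ (X * X)) / n
    r = z - X @ beta
    active = (beta != 0.0) | (pf == 0.0)
    # first full sweep to establish the active set
    _cd_sweep(X, h, r, beta, lam, pf, xwx, n, False, active)
    for _ in range(max_sweeps):
        d = _cd_sweep(X, h, r, beta, lam, pf, xwx, n, True, active)
        if d < inner_tol:
            d_full = _cd_sweep(X, h, r, beta, lam, pf, xwx, n, False, active)
            if d_full < inner_tol:
                break
    return beta


def fit_penalized(
    data: CoxData,
    lam: float,
    warm_start: CoxFit | None = None,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> CoxFit:
    """Lasso-penalized Cox fit at one penalty level.

    Proximal Newton: cyclic coordinate descent with soft-thresholding on
    the diagonal quadratic approximation of -l(b)/n, covariates
    unpenalized, stopping when the relative change of the penalized
    objective falls below ``tol``. The accepted step never increases the
    objective (step halving guards the quadratic approximation), so the
    objective is non-increasing across sweeps.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p, q = data.n, data.p_pen, data.p_unpen
    X = np.hstack([data.X_pen, data.X_unpen])
    # center columns: the partial likelihood is location-invariant, so the
    # coefficients and gradients are unchanged, but the diagonal IRLS
    # curvature along the (null) constant direction vanishes — without
    # this, uncentered covariates make the surrogate steps collapse
    X = np.asfortranarray(X - X.mean(axis=0))
    pf = np.concatenate([np.ones(p), np.zeros(q)])
    if warm_start is not None:
        beta = np.concatenate([
            _coef(warm_start.beta_pen, p),
            _coef(warm_start.beta_unpen, q),
        ])
    else:
        beta = np.zeros(p + q)

    eta = X @ beta
    ll, u, h = _breslow(data, eta)
    obj = -ll / n + lam * np.abs(beta[:p]).sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        hw = np.maximum(h, 1e-5)
        z = eta + u / hw
        # the surrogate must be solved to ~KKT-target^2 in the glmnet
        # weighted-squared-change measure, else the outer KKT refinement
        # can never be met
        beta_new = _solve_wls(X, hw, z, beta, lam, pf, n, inner_tol=(10.0 * tol) ** 2 * 0.1)
        # step halving: the quadratic model can overshoot
        step = beta_new - beta
        accepted = False
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * step
            ll_c, u_c, h_c = _breslow(data, X @ cand)
            obj_c = -ll_c / n + lam * np.abs(cand[:p]).sum()
            if obj_c <= obj + 1e-14:
                accepted = True
                break
            frac *= 0.5
        if not accepted:
            converged = True  # no descent direction left: at the optimum
            break
        rel = abs(obj - obj_c) / max(1.0, abs(obj))
        beta, obj, u, h = cand, obj_c, u_c, h_c
        eta = X @ beta
        if rel < tol:
            # objective has stalled; accept only once the subgradient
            # conditions hold to 10*tol as well
            if _kkt_violation_from_score(X, u, beta, lam, pf, n, p) <= 10.0 * tol:
                converged = True
                break
    if not converged:
        warnings.warn(f"fit_penalized did not converge in {max_iter} iterations")
    return CoxFit(
        beta_pen=beta[:p].copy(),
        beta_unpen=beta[p:].copy(),
        lam=float(lam),
        objective=float(obj),
        n_iter=it,
        converged=converged,
    )


def _kkt_violation_from_score(X, u, beta, lam, pf, n, p) -> float:
    """KKT violation given the current score residual (no extra pass)."""
    g = X.T @ u / n
    v = 0.0
    pen = slice(0, p)
    act = beta[pen] != 0
    gp = g[pen]
    if np.any(~act):
        v = max(v, float(np.max(np.abs(gp[~act])) - lam))
    if np.any(act):
        v = max(v, float(np.max(np.abs(gp[act] - lam * np.sign(beta[pen][act])))))
    if p < beta.shape[0]:
        v = max(v, float(np.max(np.abs(g[p:]))))
    return v


def kkt_max_violation(data: CoxData, fit: CoxFit) -> float:
    """Largest violation of the lasso optimality conditions.

    For the objective -l/n + lam*||b_pen||_1 the conditions are
    |g_j| <= lam for inactive penalized features, g_j = lam*sign(b_j)
    for active ones, and g_j = 0 for unpenalized covariates, where
    g is the gradient of the mean partial log-likelihood. Returns the
    largest absolute violation over all features.
    """
    g_pen, g_unpen = gradient(data, fit.beta_pen, fit.beta_unpen)
    v = 0.0
    if data.p_pen:
        act = fit.beta_pen != 0
        if np.any(~act):
            v = max(v, float(np.max(np.abs(g_pen[~act])) - fit.lam))
        if np.any(act):
            v = max(
                v,
                float(np.max(np.abs(g_pen[act] - fit.lam * np.sign(fit.beta_pen[act])))),
            )
    if data.p_unpen:
        v = max(v, float(np.max(np.abs(g_unpen))))
    return v


# ----------------------------------------------------------------------
# unpenalized Newton-Raphson (small p; Wald inference)
# ----------------------------------------------------------------------
@dataclass
class NewtonCoxFit:
    """Unpenalized Cox fit with the full observed information matrix."""

    beta: np.ndarray
    cov: np.ndarray  # inverse observed information (sum scale)
    loglik: float
    n_iter: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _hessian_sum(data: CoxData, X: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Observed information (negative Hessian of the SUM log-likelihood)."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    order = data.order
    w = np.exp(eta[order])
    Xs = X[order]
    p = X.shape[1]
    wx = w[:, None] * Xs
    s1 = np.cumsum(wx[::-1], axis=0)[::-1][data.uniq_first]  # (T, p)
    wxx = wx[:, :, None] * Xs[:, None, :]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1][data.uniq_first]  # (T, p, p)
    r = np.cumsum(w[::-1])[::-1][data.uniq_first]
    ev = data.d_uniq > 0
    d = data.d_uniq[ev]
    s1e, s2e, re = s1[ev], s2[ev], r[ev]
    H = np.einsum("g,gab->ab", d / re, s2e)
    H -= np.einsum("g,ga,gb->ab", d / re**2, s1e, s1e)
    return H


def fit_cox_newton(
    data: CoxData,
    use_penalized_features: bool = False,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> NewtonCoxFit:
    """Newton-Raphson Cox fit (Breslow ties) with step halving.

    Fits the unpenalized covariates by default; with
    ``use_penalized_features`` the penalized block is included too
    (useful only for small p). The covariance is the inverse observed
    information, giving Wald standard errors.
    """
    X = (
        np.hstack([data.X_pen, data.X_unpen])
        if use_penalized_features
        else data.X_unpen
    )
    p = X.shape[1]
    if p == 0:
        ll, _, _ = _breslow(data, np.zeros(data.n))
        return NewtonCoxFit(np.empty(0), np.empty((0, 0)), ll, 0, True)
    beta = np.zeros(p)
    ll, u, _ = _breslow(data, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = X.T @ u  # sum-scale score
        H = _hessian_sum(data, X, X @ beta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix in Cox Newton fit; "
                "inspect the predictor for degeneracy"
            ) from exc
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * step
            ll_c, u_c, _ = _breslow(data, X @ cand)
            if ll_c >= ll - 1e-12:
                break
            frac *= 0.5
        rel = abs(ll_c - ll) / max(1.0, abs(ll))
        beta, ll, u = cand, ll_c, u_c
        if rel < tol and float(np.max(np.abs(g))) / data.n < 1e-9:
            converged = True
            break
    if not converged and float(np.max(np.abs(X.T @ u))) / data.n < 1e-6:
        converged = True
    if not converged:
        warnings.warn("Cox Newton fit did not fully converge; inspect the score")
    H = _hessian_sum(data, X, X @ beta)
    cov = np.linalg.inv(H)
    return NewtonCoxFit(beta=beta, cov=cov, loglik=ll, n_iter=it, converged=converged)
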