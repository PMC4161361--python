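"""Weighted LASSO by coordinate descent, lambda paths and cross-validation.

The solver minimizes the glmnet-style objective

    (1 / 2n) * sum_i w_i (z_i - sum_j X_ij beta_j)^2
        + lambda * sum_j pf_j |beta_j|

where ``pf`` is a per-column penalty factor (0 marks unpenalized columns such
as the intercept, whose column need not be constant once rows are standardized
by the over-dispersion).  Weights are normalized to mean one so lambda is
comparable across sample sizes.  Regressor columns are deliberately *not*
standardized to unit variance: genotype indicators are already on a common
coding scale and coefficients must stay interpretable as genetic effects.

The inner coordinate sweeps are JIT-compiled; ``coordinate_descent(...,
debug=True)`` runs a plain-Python loop that asserts the objective never
increases between sweeps.

``fit_penalized_glm`` wraps the solver in the usual IRLS outer loop so a full
L1-penalized GLM path can be computed with warm starts, and
``cross_validate`` / ``bic_select`` choose the tuning parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .glmfam import GLMFamily

__all__ = [
    "WorkingData",
    "LassoSolution",
    "CVResult",
    "soft_threshold",
    "coordinate_descent",
    "lambda_path",
    "fit_penalized_glm",
    "cross_validate",
    "bic_select",
    "kkt_violation",
]


def soft_threshold(rho, lam):
    """sign(rho) * max(|rho| - lam, 0)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0)


@dataclass
class WorkingData:
    """Working response, design and weights for one quadratic subproblem."""

    z: np.ndarray
    X: np.ndarray
    w: np.ndarray
    penalty_factor: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.penalty_factor = np.asarray(self.penalty_factor, dtype=float)
        if not np.all(np.isfinite(self.z)) or not np.all(np.isfinite(self.X)):
            raise ValueError("working response and design must be finite")
        if np.any(self.w <= 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be positive and finite")

    def normalized_weights(self) -> np.ndarray:
        return self.w / self.w.mean()


@dataclass
class LassoSolution:
    coef: np.ndarray
    lam: float
    penalty_factor: np.ndarray
    objective: float
    n_sweeps: int
    converged: bool

    @property
    def intercept(self) -> float:
        free = np.flatnonzero(self.penalty_factor == 0)
        return float(self.coef[free[0]]) if free.size else 0.0

    @property
    def b(self) -> np.ndarray:
        """Penalized (genetic-effect) coefficients."""
        return self.coef[self.penalty_factor > 0]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.b))


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    sd_deviance: np.ndarray
    lambda_min: float
    seed: int
    fold_ids: np.ndarray = field(repr=False, default=None)


@njit(cache=True)
def _col_scales(XT, w):
    """Weighted column scales s_j = (1/n) sum_i w_i X_ij^2."""
    k, n = XT.shape
    s = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for i in range(n):
            acc += w[i] * XT[j, i] * XT[j, i]
        s[j] = acc / n
    return s


@njit(cache=True)
def _active_set(b, pf):
    out = np.empty(b.size, dtype=np.int64)
    m = 0
    for j in range(b.size):
        if b[j] != 0.0 or pf[j] == 0.0:
            out[m] = j
            m += 1
    return out[:m]


@njit(cache=True)
def _direct_active_solve(XT, z, w, lam, pf, b, r, act):
    """Active-set step: exact minimizer on the current support/signs, with
    zero-crossing elimination when a penalized coefficient would flip sign.

    Solves (1/n) X_A' W X_A beta = (1/n) X_A' W z - lam pf sign(b_A); if the
    solution flips a sign, moves to the first zero crossing, drops that
    coordinate and re-solves.  Greatly accelerates convergence when adjacent
    grid columns are nearly collinear.  Returns False (caller falls back to
    sweeps) only for oversized active sets.
    """
    m = act.size
    n = z.size
    if m == 0 or m >= n or m > 150:
        return False
    G = np.empty((m, m))
    xtz = np.empty(m)
    for a in range(m):
        ja = act[a]
        acc = 0.0
        for i in range(n):
            acc += w[i] * XT[ja, i] * z[i]
        xtz[a] = acc / n
        for c in range(a, m):
            jc = act[c]
            acc2 = 0.0
            for i in range(n):
                acc2 += w[i] * XT[ja, i] * XT[jc, i]
            G[a, c] = acc2 / n
            G[c, a] = G[a, c]
    trace = 0.0
    for a in range(m):
        trace += G[a, a]
    ridge = 1e-10 * max(trace / m, 1e-30)
    keep = np.ones(m, dtype=np.bool_)
    cur = np.empty(m)
    for a in range(m):
        cur[a] = b[act[a]]
    for _ in range(m):
        idx = np.flatnonzero(keep)
        mm = idx.size
        if mm == 0:
            break
        Gs = np.empty((mm, mm))
        rhs = np.empty(mm)
        for a in range(mm):
            ja = act[idx[a]]
            sgn = 0.0
            if pf[ja] > 0.0:
                sgn = 1.0 if cur[idx[a]] > 0 else -1.0
            rhs[a] = xtz[idx[a]] - lam * pf[ja] * sgn
            for c in range(mm):
                Gs[a, c] = G[idx[a], idx[c]]
            Gs[a, a] += ridge
        sol = np.linalg.solve(Gs, rhs)
        # largest feasible step before a penalized coefficient crosses zero
        gamma = 1.0
        cross = -1
        for a in range(mm):
            ja = act[idx[a]]
            if pf[ja] > 0.0 and sol[a] * cur[idx[a]] <= 0.0:
                denom = cur[idx[a]] - sol[a]
                g = cur[idx[a]] / denom if denom != 0.0 else 0.0
                if g < gamma:
                    gamma = g
                    cross = a
        if cross < 0:
            for a in range(mm):
                cur[idx[a]] = sol[a]
            break
        for a in range(mm):
            cur[idx[a]] = cur[idx[a]] + gamma * (sol[a] - cur[idx[a]])
        cur[idx[cross]] = 0.0
        keep[idx[cross]] = False
    for a in range(m):
        b[act[a]] = cur[a]
    for i in range(n):
        acc = z[i]
        for a in range(m):
            if cur[a] != 0.0:
                acc -= XT[act[a], i] * cur[a]
        r[i] = acc
    return True


@njit(cache=True)
def _cd_sweeps(XT, z, w, lam, pf, b, r, s, tol, max_sweeps):
    """Cyclic coordinate descent with active-set and exact-solve acceleration.

    ``XT`` is the k x n transposed design (rows contiguous per coordinate);
    ``r`` is the current residual z - X b (updated in place, as is ``b``);
    ``s`` holds the weighted column scales (1/n) sum_i w_i X_ij^2.
    Returns (n_sweeps, converged).
    """
    k, n = XT.shape
    all_idx = np.arange(k)
    sweeps = 0
    converged = False
    # attempt the exact active-set solve once per support configuration (its
    # tiny ridge bias would otherwise re-trigger it forever near the optimum)
    last_sig = np.int64(-1)
    while sweeps < max_sweeps:
        # full sweep over all coordinates: adds violators, checks optimality
        max_change = _one_sweep(XT, w, lam, pf, b, r, s, all_idx)
        sweeps += 1
        if max_change < tol:
            converged = True
            break
        act = _active_set(b, pf)
        sig = np.int64(act.size)
        for jj in range(act.size):
            sig = sig * np.int64(31) + np.int64(act[jj] + 1)
        if sig != last_sig:
            last_sig = sig
            if _direct_active_solve(XT, z, w, lam, pf, b, r, act):
                continue
        inner = 0
        while sweeps < max_sweeps and inner < 50:
            max_change = _one_sweep(XT, w, lam, pf, b, r, s, act)
            sweeps += 1
            inner += 1
            if max_change < tol:
                break
            if inner % 10 == 0:
                act2 = _active_set(b, pf)
                sig2 = np.int64(act2.size)
                for jj in range(act2.size):
                    sig2 = sig2 * np.int64(31) + np.int64(act2[jj] + 1)
                if sig2 != last_sig:
                    last_sig = sig2
                    if _direct_active_solve(XT, z, w, lam, pf, b, r, act2):
                        break
    return sweeps, converged


@njit(cache=True)
def _one_sweep(XT, w, lam, pf, b, r, s, index_set):
    n = r.size
    max_change = 0.0
    for jj in range(index_set.size):
        j = index_set[jj]
        sj = s[j]
        if sj <= 0.0:
            continue
        rho = 0.0
        for i in range(n):
            rho += w[i] * XT[j, i] * r[i]
        rho = rho / n + sj * b[j]
        thr = lam * pf[j]
        if thr > 0.0:
            if rho > thr:
                bnew = (rho - thr) / sj
            elif rho < -thr:
                bnew = (rho + thr) / sj
            else:
                bnew = 0.0
        else:
            bnew = rho / sj
        delta = bnew - b[j]
        if delta != 0.0:
            for i in range(n):
                r[i] -= XT[j, i] * delta
            b[j] = bnew
            ad = abs(delta)
            if ad > max_change:
                max_change = ad
    return max_change


def _objective(data: WorkingData, coef, lam, w_norm):
    resid = data.z - data.X @ coef
    pen = lam * float(data.penalty_factor @ np.abs(coef))
    return float(0.5 * np.mean(w_norm * resid**2) + pen)


def coordinate_descent(data: WorkingData, lam, tol=1e-7, max_sweeps=100_000,
                       warm_start=None, debug=False) -> LassoSolution:
    """Solve the weighted LASSO subproblem at a single lambda."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X, z = data.X, data.z
    w = data.normalized_weights()
    pf = data.penalty_factor
    n, k = X.shape
    XT = np.ascontiguousarray(X.T)
    b = np.zeros(k) if warm_start is None else np.array(warm_start, dtype=float)
    r = z - X @ b
    s = _col_scales(XT, w)
    if debug:
        sweeps, converged = _cd_debug(data, XT, lam, w, b, r, s, tol, max_sweeps)
    else:
        sweeps, converged = _cd_sweeps(XT, z, w, lam, pf, b, r, s, tol, max_sweeps)
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_sweeps} sweeps at lambda={lam:.4g}",
            RuntimeWarning,
        )
    return LassoSolution(
        coef=b, lam=float(lam), penalty_factor=pf,
        objective=_objective(data, b, lam, w), n_sweeps=int(sweeps),
        converged=bool(converged),
    )


def _cd_debug(data, XT, lam, w, b, r, s, tol, max_sweeps):
    """Pure-Python sweeps asserting a non-increasing objective."""
    pf = data.penalty_factor
    k = XT.shape[0]
    prev_obj = _objective(data, b, lam, w)
    for sweep in range(1, max_sweeps + 1):
        max_change = _one_sweep.py_func(XT, w, lam, pf, b, r, s, np.arange(k))
        obj = _objective(data, b, lam, w)
        assert obj <= prev_obj + 1e-10, "coordinate descent objective increased"
        prev_obj = obj
        if max_change < tol:
            return sweep, True
    return max_sweeps, False


def kkt_violation(data: WorkingData, coef, lam) -> float:
    """Largest violation of the LASSO stationarity conditions (0 if optimal)."""
    w = data.normalized_weights()
    n = data.z.size
    grad = -(data.X.T @ (w * (data.z - data.X @ coef))) / n
    pf = data.penalty_factor
    viol = np.zeros_like(grad)
    nz = coef != 0
    viol[nz] = np.abs(grad[nz] + lam * pf[nz] * np.sign(coef[nz]))
    viol[~nz] = np.maximum(np.abs(grad[~nz]) - lam * pf[~nz], 0.0)
    return float(np.max(viol)) if viol.size else 0.0


def lambda_path(data: WorkingData, n_lambda=25, lambda_min_ratio=0.05) -> np.ndarray:
    """Geometric grid from lambda_max (all penalized coefficients zero) down."""
    w = data.normalized_weights()
    n = data.z.size
    free = data.penalty_factor == 0
    coef0 = np.zeros(data.X.shape[1])
    if free.any():
        Xf = data.X[:, free]
        A = (Xf * w[:, None]).T @ Xf
        rhs = Xf.T @ (w * data.z)
        coef0[free] = np.linalg.lstsq(A, rhs, rcond=None)[0]
    resid = data.z - data.X @ coef0
    pen = data.penalty_factor > 0
    score = np.abs((data.X[:, pen] * w[:, None]).T @ resid) / n / data.penalty_factor[pen]
    if score.size == 0 or np.max(score) <= 0 or not np.isfinite(np.max(score)):
        warnings.warn("degenerate working data: flat lambda path", RuntimeWarning)
        return np.array([0.0])
    lam_max = float(np.max(score)) * 1.000001
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * lambda_min_ratio ** (np.arange(n_lambda) / (n_lambda - 1))


# -- penalized GLM ----------------------------------------------------------

def _init_eta(y, family: GLMFamily, trials=None):
    if family.family_name == "binomial":
        mu0 = np.clip(np.mean(y), 0.02, 0.98)
    elif family.family_name == "poisson":
        mu0 = max(np.mean(y), 0.1)
    else:
        mu0 = np.mean(y)
    return np.full(y.size, float(family.link(mu0)))


def irls_working(y, eta, family: GLMFamily, trials=None, psi=None):
    """IRLS working response and weight at the current linear predictor.

    ``psi`` is the per-individual over-dispersion: it enters the dispersion
    a_i(phi) = psi_i of the exponential family and therefore divides the
    weight, w_i = 1 / (psi_i V(mu_i) g'(mu_i)^2).
    """
    eta = family.clip_eta(np.asarray(eta, dtype=float))
    mu = family.inverse_link(eta)
    gp = family.link_deriv(mu)
    z = eta + (y - mu) * gp
    w = 1.0 / (family.variance(mu) * gp**2)
    if trials is not None:
        w = w * np.asarray(trials, dtype=float)
    if psi is not None:
        w = w / np.asarray(psi, dtype=float)
    w = np.clip(w, 1e-10, 1e10)
    return z, w


def fit_penalized_glm(y, X, family: GLMFamily, lambdas, penalty_factor, trials=None,
                      irls_tol=1e-6, max_irls=50, cd_tol=1e-7, max_sweeps=100_000,
                      coef0=None, dfmax=None, psi=None):
    """L1-penalized GLM along a descending lambda path with warm starts.

    Returns ``(coefs, deviances)`` with one coefficient vector per lambda.
    When ``dfmax`` is set the path stops once more than that many penalized
    coefficients are active (remaining entries repeat the truncation point).
    """
    y = np.asarray(y, dtype=float)
    X = np.ascontiguousarray(X, dtype=float)
    XT = np.ascontiguousarray(X.T)
    pf = np.asarray(penalty_factor, dtype=float)
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    k = X.shape[1]
    coefs = np.zeros((lambdas.size, k))
    deviances = np.zeros(lambdas.size)
    coef = np.zeros(k) if coef0 is None else np.array(coef0, dtype=float)
    for li, lam in enumerate(lambdas):
        eta = X @ coef if np.any(coef) else _init_eta(y, family, trials)
        for _ in range(max_irls):
            z, w = irls_working(y, eta, family, trials, psi=psi)
            w = w / w.mean()
            prev = coef.copy()
            r = z - X @ coef
            s = _col_scales(XT, w)
            _cd_sweeps(XT, z, w, lam, pf, coef, r, s, cd_tol, max_sweeps)
            change = float(np.max(np.abs(coef - prev))) if coef.size else 0.0
            eta = X @ coef
            if change < irls_tol:
                break
        coefs[li] = coef.copy()
        deviances[li] = family.deviance(y, family.inverse_link(eta), trials)
        if dfmax is not None and np.count_nonzero(coef[pf > 0]) > dfmax:
            coefs[li + 1 :] = coef
            deviances[li + 1 :] = deviances[li]
            break
    return coefs, deviances


def _fold_ids(n, folds, rng):
    ids = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    rng.shuffle(ids)
    return ids


def cross_validate(y, X, family: GLMFamily, penalty_factor, folds=5, seed=0,
                   lambdas=None, n_lambda=25, lambda_min_ratio=0.05, trials=None,
                   **fit_kwargs) -> CVResult:
    """K-fold CV of held-out deviance along a shared lambda path."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < folds:
        raise ValueError("need at least one observation per fold")
    rng = np.random.default_rng(seed)
    if lambdas is None:
        eta0 = _init_eta(y, family, trials)
        z, w = irls_working(y, eta0, family, trials)
        data = WorkingData(z=z, X=X, w=w, penalty_factor=penalty_factor)
        lambdas = lambda_path(data, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    ids = _fold_ids(n, folds, rng)
    if family.family_name == "binomial":
        if any(np.unique(y[ids == f]).size < 2 for f in range(folds)):
            ids = _fold_ids(n, folds, rng)  # re-draw once
            if any(np.unique(y[ids == f]).size < 2 for f in range(folds)):
                warnings.warn("a CV fold has a constant binomial response", RuntimeWarning)
    # path exploration can run at looser tolerances than the final solve
    fit_kwargs.setdefault("cd_tol", 2e-5)
    fit_kwargs.setdefault("irls_tol", 1e-4)
    fit_kwargs.setdefault("max_irls", 10)
    fit_kwargs.setdefault("dfmax", 40)
    dev = np.zeros((folds, lambdas.size))
    for f in range(folds):
        tr = ids != f
        te = ~tr
        coefs, _ = fit_penalized_glm(
            y[tr], X[tr], family, lambdas, penalty_factor,
            trials=None if trials is None else np.asarray(trials)[tr], **fit_kwargs,
        )
        for li in range(lambdas.size):
            mu = family.inverse_link(X[te] @ coefs[li])
            dev[f, li] = family.deviance(
                y[te], mu, None if trials is None else np.asarray(trials)[te]
            ) / max(te.sum(), 1)
    mean_dev = dev.mean(axis=0)
    sd_dev = dev.std(axis=0, ddof=1)
    lam_min = float(lambdas[int(np.argmin(mean_dev))])
    return CVResult(lambdas=lambdas, mean_deviance=mean_dev, sd_deviance=sd_dev,
                    lambda_min=lam_min, seed=seed, fold_ids=ids)


def bic_select(y, X, family: GLMFamily, penalty_factor, lambdas=None, n_lambda=25,
               lambda_min_ratio=0.05, trials=None, criterion="bic", **fit_kwargs):
    """Pick lambda by an information criterion along a single path.

    ``criterion`` is "bic" (deviance + df ln n) or "aic" (deviance + 2 df; the
    classical large-sample stand-in for leave-one-out CV, hence closest to the
    CV-minimum rule at a fraction of its cost).  Redundant selections the
    looser criterion lets through are removed downstream by the
    one-QTL-per-interval rule.  Returns ``(lambda, coefs_at_lambda)``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if lambdas is None:
        eta0 = _init_eta(y, family, trials)
        z, w = irls_working(y, eta0, family, trials)
        data = WorkingData(z=z, X=X, w=w, penalty_factor=penalty_factor)
        lambdas = lambda_path(data, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    fit_kwargs.setdefault("cd_tol", 2e-5)
    fit_kwargs.setdefault("irls_tol", 1e-4)
    fit_kwargs.setdefault("max_irls", 10)
    fit_kwargs.setdefault("dfmax", 40)
    coefs, deviances = fit_penalized_glm(y, X, family, lambdas, penalty_factor,
                                         trials=trials, **fit_kwargs)
    pf = np.asarray(penalty_factor) > 0
    df = np.count_nonzero(coefs[:, pf], axis=1)
    per_df = 2.0 if criterion == "aic" else np.log(n)
    ic = deviances + df * per_df
    best = int(np.argmin(ic))
    return float(lambdas[best]), coefs[best]
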