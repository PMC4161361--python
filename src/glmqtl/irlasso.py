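"""The iteratively reweighted LASSO for the over-saturated QTL GLM.

Replacing unknown QTL genotypes by their conditional expectations d_ij inflates
the residual variation heterogeneously across individuals: an individual whose
putative genotypes are uncertain (large conditional variances c_ij) carries
over-dispersion

    psi_i = 1 + sum_j b_j^2 c_ij  >= 1.

The fit alternates between (a) an L1-penalized GLM solved by IRLS plus
coordinate descent and (b) refreshing psi from the current non-zero effects;
the linear predictor (including the intercept column) is standardized by
1/sqrt(psi_i) so each inner solve works on homogeneous-dispersion data:

    1. start with all effects zero and psi = 1;
    2. shrink effects with the unweighted penalized fit (lambda by CV, BIC or
       fixed);
    3. update psi from the non-zero effects;
    4. shrink effects again on the psi-standardized design;
    5. alternate 3-4 until the coefficients stabilize.

The unweighted variant ("UWglmnet" mode) stops after step 2; it is nearly as
powerful for detection but underestimates effect sizes, which the downstream
post-selection refit corrects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .condprob import RegressorSet
from .glmfam import GLMFamily
from . import lassocore

__all__ = [
    "OverdispersionState",
    "IRLassoFit",
    "overdispersion",
    "standardized_design",
    "working_quantities",
    "fit",
]


@dataclass
class OverdispersionState:
    psi: np.ndarray

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        assert np.all(self.psi >= 1.0 - 1e-12), "over-dispersion must be >= 1"


@dataclass
class IRLassoFit:
    intercept: float
    b: np.ndarray
    psi: OverdispersionState
    lam: float
    outer_iterations: int
    converged: bool
    mode: str
    cv: object = field(repr=False, default=None)
    b_unweighted: np.ndarray | None = field(repr=False, default=None)

    @property
    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.b)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.b))


def overdispersion(b, regressors: RegressorSet) -> OverdispersionState:
    """psi_i = 1 + sum_j b_j^2 c_ij over all regressor columns."""
    b = np.asarray(b, dtype=float)
    C = regressors.cond_var_matrix()
    if b.size != C.shape[1]:
        raise ValueError("coefficient vector does not match regressor columns")
    return OverdispersionState(psi=1.0 + C @ b**2)


def standardized_design(regressors: RegressorSet, psi) -> np.ndarray:
    """Design matrix (intercept column first) with row i divided by sqrt(psi_i).

    With psi = 1 this is just [1 | D]; otherwise the intercept column becomes
    1/sqrt(psi_i) so the standardized linear predictor is
    (mu0 + sum_j d_ij b_j) / sqrt(psi_i).
    """
    psi = np.asarray(psi, dtype=float)
    assert np.all(psi >= 1.0 - 1e-12), "over-dispersion must be >= 1"
    D = regressors.design_matrix()
    inv_root = 1.0 / np.sqrt(psi)
    return np.hstack([inv_root[:, None], D * inv_root[:, None]])


def working_quantities(y, eta, family: GLMFamily, trials=None, psi=None):
    """IRLS working response z and weight w at the linear predictor.

    z_i = eta_i + (y_i - mu_i) g'(mu_i),  w_i = 1 / (psi_i V(mu_i) g'(mu_i)^2),
    with mu = g^{-1}(eta); binomial prior weights multiply w and the
    over-dispersion psi_i (the heterogeneous dispersion a_i(phi)) divides it.
    """
    return lassocore.irls_working(
        np.asarray(y, dtype=float), np.asarray(eta, dtype=float), family, trials,
        psi=psi,
    )


def _select_lambda(y, X, family, pf, cv, lam, folds, seed, n_lambda,
                   lambda_min_ratio, trials):
    """Choose lambda by the requested rule; returns (lambda, cv_result|None)."""
    if lam is not None:
        return float(lam), None
    if cv == "kfold":
        res = lassocore.cross_validate(
            y, X, family, pf, folds=folds, seed=seed, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, trials=trials,
        )
        return res.lambda_min, res
    if cv in ("bic", "aic"):
        lam_ic, _ = lassocore.bic_select(
            y, X, family, pf, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, trials=trials, criterion=cv,
        )
        return lam_ic, None
    raise ValueError("either a fixed lambda or cv in {'kfold', 'bic', 'aic'} is required")


def fit(y, regressors: RegressorSet, family: GLMFamily, *, mode="weighted",
        cv="kfold", lam=None, folds=5, seed=0, trials=None,
        outer_tol=1e-4, max_outer=25, reselect_lambda=False,
        n_lambda=25, lambda_min_ratio=0.05, irls_tol=1e-6, cd_tol=1e-7) -> IRLassoFit:
    """Run the iteratively reweighted (or unweighted) LASSO genome fit.

    lambda is chosen once at the unweighted step and reused while psi is
    iterated (set ``reselect_lambda=True`` to re-run selection each outer
    iteration, or pass ``lam`` to skip selection entirely).
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    y = np.asarray(y, dtype=float)
    family.y_support_check(y, trials)
    D = regressors.design_matrix()
    n, k = D.shape
    pf = np.concatenate([[0.0], np.ones(k)])

    # Step 1-2: unweighted penalized fit (psi = 1)
    X0 = standardized_design(regressors, np.ones(n))
    warm = None
    if lam is None and cv in ("bic", "aic"):
        # one path fit serves both the pipeline's information criterion and
        # the AIC (~ leave-one-out CV) lambda used for the unweighted record
        eta0 = lassocore._init_eta(y, family, trials)
        z0, w0 = lassocore.irls_working(y, eta0, family, trials)
        data0 = lassocore.WorkingData(z=z0, X=X0, w=w0, penalty_factor=pf)
        lams = lassocore.lambda_path(data0, n_lambda=n_lambda,
                                     lambda_min_ratio=lambda_min_ratio)
        coefs_p, devs_p = lassocore.fit_penalized_glm(
            y, X0, family, lams, pf, trials=trials,
            cd_tol=2e-5, irls_tol=1e-4, max_irls=10, dfmax=40,
        )
        df_p = np.count_nonzero(coefs_p[:, 1:], axis=1)
        per_df = 2.0 if cv == "aic" else np.log(n)
        i_main = int(np.argmin(devs_p + df_p * per_df))
        i_uw = int(np.argmin(devs_p + 2.0 * df_p))
        lam_sel, cv_res = float(lams[i_main]), None
        warm = coefs_p[i_main]
        coefs_uw, _ = lassocore.fit_penalized_glm(
            y, X0, family, [float(lams[i_uw])], pf, trials=trials,
            irls_tol=irls_tol, cd_tol=cd_tol, coef0=coefs_p[i_uw],
        )
        b_unweighted = coefs_uw[0][1:].copy()
    else:
        lam_sel, cv_res = _select_lambda(y, X0, family, pf, cv, lam, folds, seed,
                                         n_lambda, lambda_min_ratio, trials)
        b_unweighted = None
    coefs, _ = lassocore.fit_penalized_glm(y, X0, family, [lam_sel], pf, trials=trials,
                                           irls_tol=irls_tol, cd_tol=cd_tol, coef0=warm)
    coef = coefs[0]
    b = coef[1:]
    if b_unweighted is None:
        b_unweighted = b.copy()
    if mode == "unweighted":
        return IRLassoFit(
            intercept=float(coef[0]), b=b, psi=OverdispersionState(np.ones(n)),
            lam=lam_sel, outer_iterations=1, converged=True, mode=mode,
            cv=cv_res, b_unweighted=b_unweighted,
        )

    # Steps 3-5: alternate psi refresh and the weighted penalized fit on the
    # psi-standardized design (the L1 penalty bounds the coefficients, so the
    # alternation cannot run away)
    converged = False
    outer = 1
    best = (np.inf, coef, np.ones(n))
    seen = []
    for outer in range(2, max_outer + 1):
        psi = overdispersion(b, regressors).psi
        Xs = standardized_design(regressors, psi)
        if reselect_lambda and lam is None:
            lam_sel, cv_res = _select_lambda(y, Xs, family, pf, cv, None, folds,
                                             seed, n_lambda, lambda_min_ratio, trials)
        coefs, devs = lassocore.fit_penalized_glm(
            y, Xs, family, [lam_sel], pf, trials=trials,
            irls_tol=irls_tol, cd_tol=cd_tol, coef0=coef,
        )
        new_coef = coefs[0]
        obj = devs[0] + 2 * n * lam_sel * float(np.sum(np.abs(new_coef[1:])))
        if obj < best[0]:
            best = (obj, new_coef.copy(), psi.copy())
        change = float(np.max(np.abs(new_coef - coef)))
        coef = new_coef
        b = coef[1:]
        if change < outer_tol:
            converged = True
            break
        key = hash(np.round(coef, 8).tobytes())
        if key in seen:  # oscillation: return the best iterate seen
            warnings.warn("outer iteration is cycling; returning best iterate",
                          RuntimeWarning)
            coef, psi = best[1], best[2]
            b = coef[1:]
            break
        seen.append(key)
    psi = overdispersion(b, regressors).psi
    return IRLassoFit(
        intercept=float(coef[0]), b=b, psi=OverdispersionState(psi),
        lam=lam_sel, outer_iterations=outer, converged=converged, mode=mode,
        cv=cv_res, b_unweighted=b_unweighted,
    )
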