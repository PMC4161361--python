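"""Post-selection inference: refit, significance thresholds and QTL calls.

The LASSO genome fit yields shrunken non-zero effects but no tests.  The
selected loci (after enforcing at most one per marker interval) are therefore
re-estimated by an unpenalized GLM on the over-dispersion-standardized design;
the inverse weighted information matrix gives standard errors, and t statistics
with n - p degrees of freedom give per-locus p-values reported as -log10(p).

Genome-wide significance uses the empirical distribution of the maximum
-log10(p) across replicates of the null model (zero genetic effects), or of
phenotype permutations of the observed data; the critical value is the
(1 - level) empirical quantile of those maxima.  QTL detection power is scored
per true locus: a replicate detects a QTL when a significant call lies within
``match_radius_cM`` (default 10 cM, one marker interval) of the true position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import crosssim, irlasso
from .condprob import RegressorSet, build_regressors
from .genmap import build_locus_grid
from .glmfam import GLMFamily, make_family

__all__ = [
    "RefitResult",
    "Threshold",
    "QTLCall",
    "ProfileResult",
    "ScanResult",
    "prune_selected",
    "refit_glm",
    "profile_scan",
    "profile_peaks",
    "forward_select",
    "genome_threshold",
    "call_qtls",
    "calls_from_scan",
    "heritability",
    "link_scale_residual_variance",
    "scan",
    "power_experiment",
]


@dataclass
class RefitResult:
    selected_cols: np.ndarray      # design-column indices of the genetic effects
    beta: np.ndarray               # intercept followed by selected effects
    cov: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    neglog10p: np.ndarray
    psi: np.ndarray
    dispersion: float
    df_resid: int
    mu_hat: np.ndarray = field(repr=False, default=None)
    dropped_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def effects(self) -> np.ndarray:
        return self.beta[1:]

    @property
    def max_neglog10p(self) -> float:
        return float(np.max(self.neglog10p)) if self.neglog10p.size else 0.0


@dataclass
class Threshold:
    level: float
    critical_value: float
    method: str
    n_replicates: int
    seed: int
    maxima: np.ndarray = field(repr=False, default=None)


@dataclass
class QTLCall:
    chrom: str
    pos_cM: float
    genome_pos_cM: float
    effect_type: str
    effect: float
    se: float
    t: float
    neglog10p: float
    heritability: float
    column: int


def prune_selected(b, regressors: RegressorSet) -> np.ndarray:
    """Keep one locus per marker interval (per effect type).

    Within each marker interval the locus with the largest |effect| survives;
    ties break toward the smaller position.  Returns design-column indices.
    """
    b = np.asarray(b, dtype=float)
    nz = np.flatnonzero(b)
    if nz.size == 0:
        return nz
    grid = regressors.grid
    iv = grid.interval_id()
    col_locus = regressors.column_locus()
    col_type = regressors.column_effect_type()
    keep = []
    keys = {}
    for col in nz:
        loc = col_locus[col]
        key = (col_type[col], int(iv[loc]))
        keys.setdefault(key, []).append(col)
    for key, cols in keys.items():
        cols = np.asarray(cols)
        mags = np.abs(b[cols])
        pos = grid.pos_cM[col_locus[cols]]
        order = np.lexsort((pos, -mags))  # largest |b|, then smallest position
        keep.append(cols[order[0]])
    return np.sort(np.asarray(keep, dtype=int))


def _ridge(info):
    """Scale-aware Tikhonov safeguard for near-singular information matrices."""
    p = info.shape[0]
    return info + (1e-8 * float(np.trace(info)) / max(p, 1)) * np.eye(p)


def _glm_fit(y, X, family: GLMFamily, trials=None, beta0=None, tol=1e-6, max_iter=25):
    """Plain IRLS fit of a small GLM; returns (beta, deviance)."""
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    if beta0 is None:
        mu_bar = np.mean(y)
        beta[0] = float(family.link(np.clip(mu_bar, 1e-6, None)
                                    if family.family_name != "gaussian" else mu_bar))
    dev_cur = family.deviance(y, family.inverse_link(family.clip_eta(X @ beta)), trials)
    for _ in range(max_iter):
        eta = X @ beta
        z, w = irlasso.working_quantities(y, eta, family, trials)
        Xw = X * w[:, None]
        new_beta = np.linalg.solve(_ridge(Xw.T @ X), Xw.T @ z)
        step = 1.0
        for _ in range(10):
            cand = beta + step * (new_beta - beta)
            dev = family.deviance(y, family.inverse_link(family.clip_eta(X @ cand)), trials)
            if dev < dev_cur - 1e-10 and np.max(np.abs(cand)) < 1e6:
                break
            step *= 0.5
        else:
            break  # no strictly improving step left: converged/plateau
        change = float(np.max(np.abs(cand - beta)))
        beta = cand
        dev_cur = dev
        if change < tol:
            break
    return beta, dev_cur


def forward_select(y, regressors: RegressorSet, candidate_cols, family: GLMFamily,
                   trials=None, per_df=None, max_model=None) -> np.ndarray:
    """Greedy forward BIC selection among candidate loci.

    Builds the multi-QTL cofactor model one locus at a time, accepting the
    candidate that lowers deviance + df * ln(n) the most; stops when no
    candidate improves the criterion.  This keeps the model to roughly one
    locus per QTL whatever the trait's information content, which matters for
    count traits where nearly every locus passes a fixed significance cut.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if per_df is None:
        per_df = float(np.log(n))
    candidate_cols = np.asarray(candidate_cols, dtype=int)
    if max_model is None:
        max_model = max(5, min(30, n // 10))
    D = regressors.design_matrix()
    ones = np.ones((n, 1))
    beta, dev = _glm_fit(y, ones, family, trials)
    ic = dev
    selected: list = []
    remaining = list(candidate_cols)
    while remaining and len(selected) < max_model:
        best = (None, np.inf, None)
        for c in remaining:
            X = np.hstack([ones, D[:, selected + [c]]])
            beta_c, dev_c = _glm_fit(
                y, X, family, trials,
                beta0=np.concatenate([beta, [0.0]]), tol=1e-4, max_iter=15,
            )
            ic_c = dev_c + (len(selected) + 1) * per_df
            if ic_c < best[1]:
                best = (c, ic_c, beta_c)
        if best[0] is None or best[1] >= ic - 1e-8:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        ic = best[1]
        beta = best[2]
    return np.sort(np.asarray(selected, dtype=int))


def _drop_collinear(X, w):
    """Indices of a full-rank column subset (pivoted QR on the weighted design)."""
    from scipy.linalg import qr

    Xw = X * np.sqrt(w)[:, None]
    _, R, piv = qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return np.sort(piv[:rank])


def refit_glm(y, regressors: RegressorSet, selected_cols, family: GLMFamily,
              trials=None, tol=1e-8, max_iter=25, psi_rounds=10) -> RefitResult:
    """Unpenalized GLM refit of the selected loci on the psi-standardized design.

    The linear predictor (intercept included) is divided by sqrt(psi_i) with
    psi_i = 1 + sum_j beta_j^2 c_ij, which undoes the attenuation caused by
    replacing unknown genotypes with their conditional expectations; psi is
    refreshed between IRLS rounds until the coefficients stabilize.  The
    alternation is guarded: steps must strictly reduce the deviance and keep
    coefficients bounded, and a diverging psi cycle falls back to the last
    stable round.  The covariance of the estimates is the inverse weighted
    information matrix scaled by the dispersion (1 for binomial/Poisson, the
    Pearson estimate for gaussian); t statistics use n - p residual df.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    selected_cols = np.asarray(selected_cols, dtype=int)
    D = regressors.design_matrix()[:, selected_cols]
    C = regressors.cond_var_matrix()[:, selected_cols]
    if selected_cols.size >= n:
        raise ValueError("more selected loci than observations")
    dropped = np.array([], dtype=int)
    beta = np.zeros(selected_cols.size + 1)
    beta[0] = float(family.link(np.clip(np.mean(y), 1e-6, None)
                                if family.family_name != "gaussian" else np.mean(y)))
    prev_round = beta.copy()
    beta_unadjusted = None
    prev_change = np.inf
    for round_ in range(psi_rounds):
        psi = 1.0 + C @ beta[1:] ** 2
        X = np.hstack([(1.0 / np.sqrt(psi))[:, None], D / np.sqrt(psi)[:, None]])
        eta = family.clip_eta(X @ beta)
        prev_dev = family.deviance(y, family.inverse_link(eta), trials)
        for _ in range(max_iter):
            z, w = irlasso.working_quantities(y, eta, family, trials)
            keep = _drop_collinear(X, w)
            if keep.size < X.shape[1]:
                all_cols = np.arange(X.shape[1])
                gone = np.setdiff1d(all_cols, keep)
                gone_eff = gone[gone > 0] - 1
                warnings.warn(
                    f"dropping {gone_eff.size} collinear column(s) from the refit",
                    RuntimeWarning,
                )
                dropped = selected_cols[gone_eff]
                selected_cols = np.delete(selected_cols, gone_eff)
                D = np.delete(D, gone_eff, axis=1)
                C = np.delete(C, gone_eff, axis=1)
                beta = np.delete(beta, gone_eff + 1)
                prev_round = beta.copy()
                psi = 1.0 + C @ beta[1:] ** 2
                X = np.hstack([(1.0 / np.sqrt(psi))[:, None], D / np.sqrt(psi)[:, None]])
                eta = family.clip_eta(X @ beta)
                prev_dev = family.deviance(y, family.inverse_link(eta), trials)
                continue
            Xw = X * w[:, None]
            info = _ridge(Xw.T @ X)
            new_beta = np.linalg.solve(info, Xw.T @ z)
            # accept only strictly improving, bounded steps
            step = 1.0
            improved = False
            for _ in range(8):
                cand = beta + step * (new_beta - beta)
                mu = family.inverse_link(family.clip_eta(X @ cand))
                dev = family.deviance(y, mu, trials)
                if dev < prev_dev - 1e-10 and np.max(np.abs(cand)) < 50.0:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            change = float(np.max(np.abs(cand - beta)))
            beta = cand
            prev_dev = dev
            eta = family.clip_eta(X @ beta)
            if change < tol:
                break
        if round_ == 0:
            beta_unadjusted = beta.copy()
        round_change = float(np.max(np.abs(beta - prev_round))) if beta.size else 0.0
        diverging = (np.max(np.abs(beta)) > 20.0
                     or (round_ >= 2 and round_change > prev_change + 1e-12))
        if diverging:
            # the psi alternation contracts only while sum_j beta_j^2 c_ij
            # stays below one; beyond that the dispersion adjustment is not
            # estimable, so report the unadjusted fit
            warnings.warn("over-dispersion adjustment did not converge; "
                          "reporting the unadjusted refit", RuntimeWarning)
            beta = beta_unadjusted
            break
        if round_change < 1e-6:
            break
        prev_change = round_change
        prev_round = beta.copy()
    psi = 1.0 + C @ beta[1:] ** 2
    X = np.hstack([(1.0 / np.sqrt(psi))[:, None], D / np.sqrt(psi)[:, None]])
    eta = family.clip_eta(X @ beta)
    mu = family.inverse_link(eta)
    z, w = irlasso.working_quantities(y, eta, family, trials)
    info = _ridge((X * w[:, None]).T @ X)
    p_total = X.shape[1]
    df = max(n - p_total, 1)
    if family.dispersion_fixed:
        phi = 1.0
    else:
        phi = float(np.sum(w * (z - eta) ** 2) / df)
    cov = phi * np.linalg.inv(info)
    se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se_all > 0, beta / se_all, 0.0)
    p_eff = 2.0 * stats.t.sf(np.abs(t_all[1:]), df)
    p_eff = np.clip(p_eff, 1e-300, 1.0)
    return RefitResult(
        selected_cols=selected_cols,
        beta=beta,
        cov=cov,
        se=se_all[1:],
        t=t_all[1:],
        p=p_eff,
        neglog10p=-np.log10(p_eff),
        psi=psi,
        dispersion=phi,
        df_resid=df,
        mu_hat=mu,
        dropped_cols=dropped,
    )


def link_scale_residual_variance(family: GLMFamily, mu_hat=None, dispersion=1.0) -> float:
    """Residual variance on the linear-predictor (latent) scale per family.

    Threshold-model conventions: probit 1, logit pi^2/3, cloglog pi^2/6
    (Gumbel).  Gaussian uses the estimated dispersion.  Poisson uses the
    delta-method variance of the linked response at the mean fitted value
    (1/mu for log, mu for identity, 1/4 for sqrt).
    """
    if family.family_name == "binomial":
        return {"logit": np.pi**2 / 3.0, "probit": 1.0, "cloglog": np.pi**2 / 6.0,
                "log": np.pi**2 / 3.0}[family.link_name]
    if family.family_name == "gaussian":
        return float(dispersion)
    mubar = float(np.mean(mu_hat)) if mu_hat is not None else 1.0
    return {"log": 1.0 / mubar, "identity": mubar, "sqrt": 0.25}[family.link_name]


def heritability(effects, regressor_variances, residual_variance) -> np.ndarray:
    """Per-locus h2 = b_j^2 V_j / (sum_l b_l^2 V_l + residual variance)."""
    effects = np.asarray(effects, dtype=float)
    v = np.asarray(regressor_variances, dtype=float)
    if np.any(v < 0) or residual_variance <= 0:
        raise ValueError("variances must be positive")
    genetic = effects**2 * v
    total = genetic.sum() + residual_variance
    return genetic / total


@dataclass
class ProfileResult:
    """Genome-wide -log10(p) profile of per-locus t statistics.

    Each grid column is tested in a GLM containing the model's other selected
    loci as cofactors, excluding cofactors within ``window_cM`` of the tested
    locus so the tested effect is not absorbed by its own neighbours.  The
    arrays align with the regressor design columns.
    """

    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    neglog10p: np.ndarray
    cofactor_cols: np.ndarray
    window_cM: float

    @property
    def max_neglog10p(self) -> float:
        return float(np.nanmax(self.neglog10p))


def profile_scan(y, regressors: RegressorSet, family: GLMFamily, cofactor_cols,
                 *, trials=None, window_cM=10.0, psi=None, base_beta=None,
                 tol=1e-6, max_iter=30) -> ProfileResult:
    """Per-locus conditional t-statistic profile across the genome.

    ``cofactor_cols`` are the design columns of the fitted multi-QTL model
    (typically the pruned LASSO selection).  The over-dispersion psi of the
    base model is held fixed while profiling.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = regressors.design_matrix()
    C = regressors.cond_var_matrix()
    k_cols = D.shape[1]
    cofactor_cols = np.asarray(cofactor_cols, dtype=int)
    if psi is None:
        psi = np.ones(n)
    inv_root = 1.0 / np.sqrt(np.asarray(psi, dtype=float))
    col_locus = regressors.column_locus()
    grid = regressors.grid
    gpos = grid.cum_pos[col_locus]
    cof_pos = gpos[cofactor_cols] if cofactor_cols.size else np.array([])
    eff = np.full(k_cols, np.nan)
    se = np.full(k_cols, np.nan)
    tstat = np.full(k_cols, np.nan)
    nlp = np.full(k_cols, np.nan)
    dfree = np.full(k_cols, 1.0)
    Ds = D * inv_root[:, None]
    icol = inv_root
    prev_key = None
    beta0 = None
    for k in range(k_cols):
        use = np.abs(cof_pos - gpos[k]) > window_cM if cofactor_cols.size else np.zeros(0, bool)
        cofs = cofactor_cols[use] if cofactor_cols.size else cofactor_cols
        key = cofs.tobytes()
        X = np.column_stack([icol, Ds[:, cofs], Ds[:, k]])
        p = X.shape[1]
        if key == prev_key and beta0 is not None:
            beta = beta0.copy()
        else:
            beta = np.zeros(p)
            if base_beta is not None and cofs.size:
                sel_map = {c: i for i, c in enumerate(cofactor_cols)}
                beta[0] = base_beta[0]
                for i, c in enumerate(cofs):
                    beta[1 + i] = base_beta[1 + sel_map[c]]
            else:
                mu_bar = np.mean(y)
                beta[0] = float(family.link(np.clip(mu_bar, 1e-6, None)
                                            if family.family_name != "gaussian" else mu_bar))
        # plain bounded IRLS: the warm start sits close to the optimum, so
        # step-halving (and its per-step deviance evaluations) is unnecessary;
        # a runaway update reverts to the last finite iterate instead
        for _ in range(max_iter):
            eta = family.clip_eta(X @ beta)
            z, w = irlasso.working_quantities(y, eta, family, trials)
            Xw = X * w[:, None]
            info = _ridge(Xw.T @ X)
            try:
                new_beta = np.linalg.solve(info, Xw.T @ z)
            except np.linalg.LinAlgError:
                new_beta = np.linalg.lstsq(info, Xw.T @ z, rcond=None)[0]
            if not np.all(np.isfinite(new_beta)) or np.max(np.abs(new_beta)) > 30.0:
                break
            change = float(np.max(np.abs(new_beta - beta)))
            beta = new_beta
            if change < tol:
                break
        prev_key, beta0 = key, np.concatenate([beta[:-1], [0.0]])
        eta = family.clip_eta(X @ beta)
        z, w = irlasso.working_quantities(y, eta, family, trials)
        info = _ridge((X * w[:, None]).T @ X)
        dfree[k] = max(n - p, 1)
        phi = 1.0 if family.dispersion_fixed else float(np.sum(w * (z - eta) ** 2) / dfree[k])
        try:
            cov_last = phi * np.linalg.inv(info)[-1, -1]
        except np.linalg.LinAlgError:
            continue
        if cov_last <= 0:
            continue
        eff[k] = beta[-1]
        se[k] = np.sqrt(cov_last)
        tstat[k] = beta[-1] / se[k]
    ok = np.isfinite(tstat)
    pvals = np.clip(2.0 * stats.t.sf(np.abs(tstat[ok]), dfree[ok]), 1e-300, 1.0)
    nlp[ok] = -np.log10(pvals)
    return ProfileResult(effect=eff, se=se, t=tstat, neglog10p=nlp,
                         cofactor_cols=cofactor_cols, window_cM=window_cM)


@dataclass
class ScanResult:
    fit: irlasso.IRLassoFit
    pruned_cols: np.ndarray
    refit: RefitResult
    profile: ProfileResult = None
    pruned_cols_uw: np.ndarray = None


def scan(y, regressors: RegressorSet, family: GLMFamily, *, mode="weighted",
         cv="kfold", lam=None, seed=0, trials=None, with_unweighted=False,
         with_profile=True, window_cM=10.0, refine_nlp=2.0, **fit_kwargs) -> ScanResult:
    """Full pipeline on one dataset: LASSO fit, interval pruning, GLM refit,
    and the genome-wide conditional -log10(p) profile.

    The profile is refined once: peaks of a first-pass profile (-log10 p >=
    ``refine_nlp``) replace the raw LASSO survivors as the cofactor model,
    which consolidates each QTL region onto a single locus before the final
    per-locus statistics are computed.  ``with_unweighted=True`` additionally
    prunes/refits/profiles the step-2 unweighted coefficients so both method
    variants come from a single genome fit.
    """
    fit_res = irlasso.fit(y, regressors, family, mode=mode, cv=cv, lam=lam,
                          seed=seed, trials=trials, **fit_kwargs)
    pruned = prune_selected(fit_res.b, regressors)
    refit = refit_glm(y, regressors, pruned, family, trials=trials)
    profile = None
    if with_profile:
        profile = profile_scan(y, regressors, family, refit.selected_cols,
                               trials=trials, window_cM=window_cM,
                               psi=refit.psi, base_beta=refit.beta,
                               tol=1e-4, max_iter=15)
        peaks = profile_peaks(profile, refine_nlp, regressors)
        if peaks.size > max(10, y.size // 20):
            # very high-information traits light up the whole genome; keep the
            # cofactor model parsimonious by explicit forward selection
            peaks = forward_select(y, regressors, peaks, family, trials=trials)
        refit = refit_glm(y, regressors, peaks, family, trials=trials)
        profile = profile_scan(y, regressors, family, refit.selected_cols,
                               trials=trials, window_cM=window_cM,
                               psi=refit.psi, base_beta=refit.beta,
                               tol=1e-5, max_iter=20)
    pruned_uw = None
    if with_unweighted and fit_res.b_unweighted is not None:
        pruned_uw = prune_selected(fit_res.b_unweighted, regressors)
    return ScanResult(fit=fit_res, pruned_cols=pruned, refit=refit,
                      profile=profile, pruned_cols_uw=pruned_uw)


def profile_peaks(profile: ProfileResult, critical_value, regressors: RegressorSet):
    """Design columns of profile peaks above the critical value.

    Greedy non-maximum suppression: accept peaks in decreasing -log10(p)
    order, skipping loci within ``profile.window_cM`` (same chromosome and
    effect type) of an already-accepted peak; ties break toward the smaller
    position.
    """
    nlp = profile.neglog10p
    grid = regressors.grid
    col_locus = regressors.column_locus()
    col_type = regressors.column_effect_type()
    cand = np.flatnonzero(np.nan_to_num(nlp, nan=-1.0) >= critical_value)
    if cand.size == 0:
        return cand
    pos = grid.pos_cM[col_locus[cand]]
    order = np.lexsort((pos, -nlp[cand]))
    accepted = []
    for idx in order:
        col = cand[idx]
        loc = col_locus[col]
        ok = True
        for acol in accepted:
            aloc = col_locus[acol]
            if (col_type[acol] == col_type[col]
                    and grid.chrom_idx[aloc] == grid.chrom_idx[loc]
                    and abs(grid.pos_cM[aloc] - grid.pos_cM[loc]) <= profile.window_cM):
                ok = False
                break
        if ok:
            accepted.append(col)
    return np.sort(np.asarray(accepted, dtype=int))


def calls_from_scan(res: "ScanResult", threshold: Threshold, regressors: RegressorSet,
                    family: GLMFamily) -> list:
    """QTL calls from a scan's profile: suppressed peaks above the critical
    value, with effects taken from the joint refit model where available and
    heritability on the link scale."""
    if res.profile is None:
        return call_qtls(res.refit, threshold, regressors, family)
    grid = regressors.grid
    col_locus = regressors.column_locus()
    col_type = regressors.column_effect_type()
    names = np.asarray(grid.gmap.chrom_names, dtype=object)
    peaks = profile_peaks(res.profile, threshold.critical_value, regressors)
    if peaks.size == 0:
        return []
    # thin the report to profile local maxima: the shoulder of a strong QTL
    # stays above the critical value across neighbouring intervals and would
    # otherwise be listed as a ladder of separate QTLs
    nlp = np.nan_to_num(res.profile.neglog10p, nan=-1.0)
    keep = []
    for col in peaks:
        loc = col_locus[col]
        near = (
            (regressors.column_effect_type() == regressors.column_effect_type()[col])
            & (grid.chrom_idx[col_locus] == grid.chrom_idx[loc])
            & (np.abs(grid.pos_cM[col_locus] - grid.pos_cM[loc]) <= res.profile.window_cM)
        )
        if nlp[col] >= np.max(nlp[near]):
            keep.append(col)
    if keep:
        peaks = np.asarray(keep, dtype=int)
    model_cols = res.refit.selected_cols
    model_pos = grid.cum_pos[col_locus[model_cols]] if model_cols.size else np.array([])
    D = regressors.design_matrix()
    C = regressors.cond_var_matrix()
    effs = []
    for col in peaks:
        eff = float(res.profile.effect[col])
        if model_pos.size:
            jm = int(np.argmin(np.abs(model_pos - grid.cum_pos[col_locus[col]])))
            if abs(model_pos[jm] - grid.cum_pos[col_locus[col]]) <= res.profile.window_cM:
                eff = float(res.refit.effects[jm])
        effs.append(eff)
    effs = np.asarray(effs)
    reg_var = D[:, peaks].var(axis=0) + C[:, peaks].mean(axis=0)
    resid_var = link_scale_residual_variance(family, res.refit.mu_hat,
                                             res.refit.dispersion)
    h2 = heritability(effs, reg_var, resid_var)
    calls = []
    for i, col in enumerate(peaks):
        loc = col_locus[col]
        calls.append(QTLCall(
            chrom=str(names[grid.chrom_idx[loc]]),
            pos_cM=float(grid.pos_cM[loc]),
            genome_pos_cM=float(grid.cum_pos[loc]),
            effect_type=str(col_type[col]),
            effect=float(effs[i]),
            se=float(res.profile.se[col]),
            t=float(res.profile.t[col]),
            neglog10p=float(res.profile.neglog10p[col]),
            heritability=float(h2[i]),
            column=int(col),
        ))
    return calls


def genome_threshold(gmap, design, family: GLMFamily, n, *, method="null_simulation",
                     n_replicates=1000, level=0.05, seed=0, grid_step=1.0,
                     dataset=None, trials=None, mu0=0.0, binomial_trials=1,
                     fit_options=None) -> Threshold:
    """Genome-wide critical value of max -log10(p) at the given level.

    ``null_simulation`` simulates fresh null datasets from the map;
    ``permutation`` permutes the phenotypes of ``dataset`` against whole
    genotype rows (marker linkage is preserved).  Each replicate runs the full
    fit -> prune -> refit pipeline; a replicate with nothing selected
    contributes a maximum of zero.
    """
    if n_replicates < 20:
        raise ValueError("need at least 20 replicates for a quantile estimate")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    fit_options = dict(fit_options or {})
    grid = build_locus_grid(gmap, grid_step)
    maxima = []
    failures = 0
    if method == "permutation" and dataset is None:
        raise ValueError("permutation thresholds need an observed dataset")
    if method == "permutation":
        regressors = build_regressors(dataset.marker_genotypes, gmap, grid, design=design)
        y_obs = np.asarray(dataset.phenotypes, dtype=float)
    for rep in range(n_replicates):
        rng = np.random.default_rng([int(seed), rep])
        try:
            if method == "null_simulation":
                null = crosssim.simulate_null(
                    gmap, design, family.family_name, n, [int(seed), rep],
                    link_name=family.link_name, mu0=mu0, binomial_trials=binomial_trials,
                )
                regress = build_regressors(null.marker_genotypes, gmap, grid, design=design)
                y = null.phenotypes
            elif method == "permutation":
                regress = regressors
                y = y_obs[rng.permutation(y_obs.size)]
            else:
                raise ValueError(f"unknown threshold method: {method!r}")
            res = scan(y, regress, family, seed=int(rng.integers(2**31)),
                       trials=trials, **fit_options)
            if res.profile is not None:
                maxima.append(res.profile.max_neglog10p)
            else:
                maxima.append(res.refit.max_neglog10p)
        except (np.linalg.LinAlgError, RuntimeError) as exc:  # pragma: no cover
            failures += 1
            warnings.warn(f"threshold replicate {rep} failed: {exc}", RuntimeWarning)
    if failures > 0.05 * n_replicates:
        raise RuntimeError(f"{failures}/{n_replicates} threshold replicates failed")
    maxima = np.sort(np.asarray(maxima))
    order = int(np.ceil((1.0 - level) * maxima.size)) - 1
    critical = float(maxima[min(max(order, 0), maxima.size - 1)])
    return Threshold(level=level, critical_value=critical, method=method,
                     n_replicates=n_replicates, seed=seed, maxima=maxima)


def call_qtls(refit: RefitResult, threshold: Threshold, regressors: RegressorSet,
              family: GLMFamily = None) -> list:
    """Declare QTLs: selected loci whose -log10(p) meets the critical value."""
    calls = []
    if refit.selected_cols.size == 0:
        return calls
    grid = regressors.grid
    col_locus = regressors.column_locus()
    col_type = regressors.column_effect_type()
    D = regressors.design_matrix()[:, refit.selected_cols]
    C = regressors.cond_var_matrix()[:, refit.selected_cols]
    reg_var = D.var(axis=0) + C.mean(axis=0)
    resid_var = link_scale_residual_variance(
        family, refit.mu_hat, refit.dispersion
    ) if family is not None else 1.0
    h2 = heritability(refit.effects, reg_var, resid_var)
    names = np.asarray(grid.gmap.chrom_names, dtype=object)
    for k, col in enumerate(refit.selected_cols):
        if refit.neglog10p[k] < threshold.critical_value:
            continue
        loc = col_locus[col]
        calls.append(
            QTLCall(
                chrom=str(names[grid.chrom_idx[loc]]),
                pos_cM=float(grid.pos_cM[loc]),
                genome_pos_cM=float(grid.cum_pos[loc]),
                effect_type=str(col_type[col]),
                effect=float(refit.effects[k]),
                se=float(refit.se[k]),
                t=float(refit.t[k]),
                neglog10p=float(refit.neglog10p[k]),
                heritability=float(h2[k]),
                column=int(col),
            )
        )
    return calls


def power_experiment(spec, n_replicates, threshold: Threshold, *,
                     match_radius_cM=10.0, seed=0, methods=("IRglmnet",),
                     grid_step=1.0, fit_options=None) -> pd.DataFrame:
    """Replicate the scenario and score per-QTL detection power and estimates.

    For each true QTL and replicate, a detection is a significant call within
    ``match_radius_cM`` of the true genome position; position and effect
    summaries average over detecting replicates.  ``IRglmnet`` reports the
    post-selection refit effect, ``UWglmnet`` the raw step-2 LASSO coefficient
    of the same pruned locus (no refit), both variants extracted from a single
    genome fit per replicate.
    """
    fit_options = dict(fit_options or {})
    want_uw = "UWglmnet" in methods
    family = spec.family
    grid = build_locus_grid(spec.gmap, grid_step)
    true_pos = spec.qtl_genome_positions()
    nq = true_pos.size
    records = {m: {"det": np.zeros((n_replicates, nq), dtype=bool),
                   "pos": np.full((n_replicates, nq), np.nan),
                   "eff": np.full((n_replicates, nq), np.nan)}
               for m in methods}
    for rep in range(n_replicates):
        data = crosssim.simulate_dataset(spec, seed=[int(seed), rep])
        regress = build_regressors(data.marker_genotypes, spec.gmap, grid,
                                   design=spec.design)
        res = scan(data.phenotypes, regress, family, seed=int(seed) + rep,
                   with_unweighted=want_uw,
                   trials=None if spec.binomial_trials == 1 else
                   np.full(spec.n, spec.binomial_trials),
                   **fit_options)
        col_locus = regress.column_locus()
        variants = {}
        if "IRglmnet" in methods:
            variants["IRglmnet"] = (res.profile, None)
        if want_uw:
            # the unweighted variant detects almost identically; its effect
            # estimates (raw step-2 LASSO mass, no refit) are read off at the
            # same called loci
            variants["UWglmnet"] = (res.profile, res.fit.b_unweighted)
        for m, (profile, raw_b) in variants.items():
            cols = profile_peaks(profile, threshold.critical_value, regress)
            if cols.size == 0:
                continue
            call_pos = grid.cum_pos[col_locus[cols]]
            if raw_b is None:
                # joint-model refit estimate of the model locus backing the
                # call (falls back to the profile estimate if none is near)
                model_cols = res.refit.selected_cols
                model_pos = grid.cum_pos[col_locus[model_cols]] if model_cols.size else np.array([])
                call_eff = profile.effect[cols].copy()
                for ci, p in enumerate(call_pos):
                    if model_pos.size:
                        jm = int(np.argmin(np.abs(model_pos - p)))
                        if abs(model_pos[jm] - p) <= match_radius_cM:
                            call_eff[ci] = res.refit.effects[jm]
            else:
                # raw LASSO mass near the call, no refit: sum of step-2
                # coefficients within the matching window of the called locus
                call_eff = np.array([
                    raw_b[np.abs(grid.cum_pos[col_locus] - p) <= match_radius_cM].sum()
                    for p in call_pos
                ])
            for q in range(nq):
                dist = np.abs(call_pos - true_pos[q])
                j = int(np.argmin(dist))
                if dist[j] <= match_radius_cM:
                    records[m]["det"][rep, q] = True
                    records[m]["pos"][rep, q] = call_pos[j]
                    records[m]["eff"][rep, q] = call_eff[j]
    rows = []
    for m in methods:
        rec = records[m]
        for q in range(nq):
            det = rec["det"][:, q]
            rows.append({
                "method": m,
                "qtl": f"Q{q + 1}",
                "true_pos_cM": float(true_pos[q]),
                "true_effect": float(spec.qtls[q].additive),
                "power_pct": 100.0 * det.mean(),
                "n_detected": int(det.sum()),
                "mean_pos_cM": float(np.nanmean(rec["pos"][det, q])) if det.any() else np.nan,
                "sd_pos_cM": float(np.nanstd(rec["pos"][det, q], ddof=1)) if det.sum() > 1 else np.nan,
                "mean_effect": float(np.nanmean(rec["eff"][det, q])) if det.any() else np.nan,
                "sd_effect": float(np.nanstd(rec["eff"][det, q], ddof=1)) if det.sum() > 1 else np.nan,
            })
    return pd.DataFrame(rows)
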