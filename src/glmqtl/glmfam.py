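"""GLM family registry: links, variance functions, log-likelihoods.

Supported pairs are normal/identity; Poisson with log, identity or sqrt links;
and binomial with logit, cloglog, probit or log links.  Link and variance
arithmetic is delegated to statsmodels' family objects; this module adds the
mean-domain clipping needed to keep iteratively reweighted least squares (IRLS)
weights finite, exact per-observation log-likelihoods (through scipy), and unit
deviances for cross-validation.

Binomial responses are handled on the per-trial (proportion) scale: the mean
``mu`` is a probability, a phenotype with ``trials`` Bernoulli trials enters as
the success proportion with prior weight ``trials``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import statsmodels.genmod.families as sm_families
import statsmodels.genmod.families.links as sm_links

__all__ = ["GLMFamily", "make_family", "SUPPORTED_PAIRS"]

# clipping keeps V(mu) and g'(mu) finite at extreme linear predictors
_EPS_BINOM = 1e-10
_EPS_POISSON = 1e-10
_MAX_POISSON = 1e12

_LINKS = {
    "identity": sm_links.Identity,
    "log": sm_links.Log,
    "sqrt": sm_links.Sqrt,
    "logit": sm_links.Logit,
    "probit": sm_links.Probit,
    "cloglog": sm_links.CLogLog,
}

SUPPORTED_PAIRS = {
    ("gaussian", "identity"),
    ("poisson", "log"),
    ("poisson", "identity"),
    ("poisson", "sqrt"),
    ("binomial", "logit"),
    ("binomial", "cloglog"),
    ("binomial", "probit"),
    ("binomial", "log"),
}


@dataclass
class GLMFamily:
    """An exponential-family distribution plus link for the QTL GLM."""

    family_name: str
    link_name: str
    _link: object = field(repr=False, default=None)
    _variance: object = field(repr=False, default=None)

    # -- link arithmetic ---------------------------------------------------
    def link(self, mu):
        return self._link(self.clip_mean(np.asarray(mu, dtype=float)))

    def inverse_link(self, eta):
        mu = self._link.inverse(np.asarray(eta, dtype=float))
        return self.clip_mean(mu)

    def link_deriv(self, mu):
        """g'(mu) = d eta / d mu, strictly positive on the open mean domain."""
        return self._link.deriv(self.clip_mean(np.asarray(mu, dtype=float)))

    def variance(self, mu):
        """Per-trial variance function V(mu)."""
        return self._variance(self.clip_mean(np.asarray(mu, dtype=float)))

    def clip_eta(self, eta):
        """Cap the linear predictor where the inverse link is exponential-ish,
        preventing runaway IRLS weights (|eta| <= 30 keeps everything finite)."""
        if self.family_name == "binomial" or (
            self.family_name == "poisson" and self.link_name == "log"
        ):
            return np.clip(eta, -30.0, 30.0)
        return eta

    def clip_mean(self, mu):
        if self.family_name == "binomial":
            return np.clip(mu, _EPS_BINOM, 1.0 - _EPS_BINOM)
        if self.family_name == "poisson":
            return np.clip(mu, _EPS_POISSON, _MAX_POISSON)
        return mu

    # -- likelihood --------------------------------------------------------
    def loglik(self, y, mu, trials=None, scale: float = 1.0):
        """Sum of exact per-observation log-densities.

        For the binomial family ``y`` is the success proportion and ``trials``
        the number of Bernoulli trials (default 1).  ``scale`` is the gaussian
        residual variance.
        """
        y = np.asarray(y, dtype=float)
        mu = self.clip_mean(np.asarray(mu, dtype=float))
        if self.family_name == "gaussian":
            return float(np.sum(stats.norm.logpdf(y, mu, np.sqrt(scale))))
        if self.family_name == "poisson":
            return float(np.sum(stats.poisson.logpmf(np.round(y).astype(int), mu)))
        n_trials = np.ones_like(y) if trials is None else np.asarray(trials, dtype=float)
        counts = np.round(y * n_trials).astype(int)
        return float(np.sum(stats.binom.logpmf(counts, np.round(n_trials).astype(int), mu)))

    def deviance(self, y, mu, trials=None):
        """Total deviance (binomial weighted by trials); used for CV."""
        y = np.asarray(y, dtype=float)
        mu = self.clip_mean(np.asarray(mu, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.family_name == "gaussian":
                unit = (y - mu) ** 2
            elif self.family_name == "poisson":
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
                unit = 2.0 * (term - (y - mu))
            else:
                n_trials = np.ones_like(y) if trials is None else np.asarray(trials, dtype=float)
                t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
                t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
                unit = 2.0 * n_trials * (t1 + t2)
        return float(np.sum(unit))

    @property
    def dispersion_fixed(self) -> bool:
        """True when a(phi) = 1 (binomial, Poisson)."""
        return self.family_name != "gaussian"

    def y_support_check(self, y, trials=None):
        """Raise ValueError when a phenotype lies outside the family support."""
        y = np.asarray(y, dtype=float)
        if self.family_name == "poisson":
            if np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-8):
                bad = int(np.flatnonzero((y < 0) | (np.abs(y - np.round(y)) > 1e-8))[0])
                raise ValueError(f"Poisson phenotype must be a non-negative integer (row {bad})")
        elif self.family_name == "binomial":
            if np.any((y < 0) | (y > 1)):
                bad = int(np.flatnonzero((y < 0) | (y > 1))[0])
                raise ValueError(
                    f"binomial phenotype (proportion scale) must lie in [0, 1] (row {bad})"
                )


def make_family(family_name: str, link_name: str | None = None) -> GLMFamily:
    """Build a :class:`GLMFamily` for a supported (family, link) pair.

    Default links are the canonical ones: identity (gaussian), log (Poisson),
    logit (binomial).
    """
    family_name = family_name.lower()
    if family_name in ("normal", "gauss"):
        family_name = "gaussian"
    if family_name in ("binary", "bernoulli"):
        family_name = "binomial"
    if link_name is None:
        link_name = {"gaussian": "identity", "poisson": "log", "binomial": "logit"}.get(
            family_name, ""
        )
    link_name = link_name.lower()
    if (family_name, link_name) not in SUPPORTED_PAIRS:
        supported = sorted(SUPPORTED_PAIRS)
        raise ValueError(
            f"unsupported family/link pair ({family_name}, {link_name}); "
            f"supported: {supported}"
        )
    link = _LINKS[link_name]()
    variance = {
        "gaussian": sm_families.varfuncs.constant,
        "poisson": sm_families.varfuncs.mu,
        "binomial": sm_families.varfuncs.binary,
    }[family_name]
    return GLMFamily(family_name=family_name, link_name=link_name, _link=link, _variance=variance)
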