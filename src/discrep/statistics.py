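"""Test quantities for posterior predictive checking.

Each statistic measures a specific footprint of irreplicability:

* ``modified_q`` — excess dispersion of study effects around the grand
  effect beyond what the sampling variances plus the allowed heterogeneity
  ``k^2 * beta_bar^2`` explain; targets batch effects and general
  heterogeneity.
* ``modified_egger`` — funnel-plot asymmetry: the squared standardized
  intercept of the regression of standardized effects on precisions, with
  precisions inflated by the allowed heterogeneity; targets publication
  bias.

Both are "modified" versions of classical meta-analysis statistics
(Cochran's Q, Egger's test) in which the nuisance parameters
``(beta_bar, k)`` come from the posterior of the reference replicability
model instead of plug-in point estimates.

A :class:`StatisticSpec` bundles a name with an evaluation contract
``T(effect_table, (beta_bar, k)) -> real``; user-defined statistics follow
the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .effects import EffectTable

__all__ = [
    "StatisticSpec",
    "EggerFit",
    "cochran_q",
    "modified_q",
    "modified_egger",
    "i_squared",
    "shared_fraction_bound",
    "q_statistic",
    "egger_statistic",
    "get_statistic",
    "STATISTICS",
]


@dataclass(frozen=True)
class StatisticSpec:
    """A pluggable test quantity ``T(beta_hat, (beta_bar, k))``.

    Attributes
    ----------
    name
        Short label used in results and on the command line.
    evaluate
        Maps ``(effects (m,), se (m,), beta_bar, k)`` to a real scalar.
    evaluate_batch
        Optional vectorized form mapping ``(effects (n, m), se (m,),
        beta_bar (n,), k (n,))`` to an ``(n,)`` vector; used by the
        sampler as a fast path and must agree with ``evaluate`` row-wise.
    """

    name: str
    evaluate: Callable[[np.ndarray, np.ndarray, float, float], float]
    evaluate_batch: Optional[
        Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    ] = None

    def __call__(self, data: EffectTable, beta_bar: float, k: float) -> float:
        return float(self.evaluate(data.beta_hat, data.se, beta_bar, k))


def cochran_q(data: EffectTable) -> float:
    """Classical Cochran's Q: inverse-variance-weighted dispersion.

    ``Q = sum_j w_j (beta_hat_j - mu)^2`` with ``w_j = 1/se_j^2`` and
    ``mu`` the precision-weighted mean.  Follows a chi-square with m - 1
    degrees of freedom under the fixed-effect model.
    """
    w = 1.0 / data.variances
    mu = np.sum(w * data.beta_hat) / np.sum(w)
    return float(np.sum(w * (data.beta_hat - mu) ** 2))


def modified_q(data: EffectTable, beta_bar: float, k: float) -> float:
    """Heterogeneity-adjusted Q statistic.

    ``sum_j w~_j (beta_hat_j - beta_bar)^2`` with
    ``w~_j = 1/(se_j^2 + k^2 beta_bar^2)``: deviations are taken from the
    grand effect and down-weighted by the heterogeneity the reference
    model allows.  Reduces to Cochran's Q at ``k = 0`` with ``beta_bar``
    at the precision-weighted mean.
    """
    return float(_modified_q_arrays(data.beta_hat, data.se, beta_bar, k))


def _modified_q_arrays(beta: np.ndarray, se: np.ndarray, beta_bar, k) -> np.ndarray:
    w = 1.0 / (se**2 + (np.asarray(k) * np.asarray(beta_bar)) ** 2)
    return np.sum(w * (beta - np.asarray(beta_bar)) ** 2, axis=-1)


def _modified_q_batch(
    beta: np.ndarray, se: np.ndarray, beta_bar: np.ndarray, k: np.ndarray
) -> np.ndarray:
    w = 1.0 / (se[None, :] ** 2 + (k * beta_bar)[:, None] ** 2)
    return np.sum(w * (beta - beta_bar[:, None]) ** 2, axis=1)


@dataclass(frozen=True)
class EggerFit:
    """Least-squares fit of the heterogeneity-adjusted Egger regression."""

    alpha0: float
    alpha1: float
    sigma_eps2: float
    var_alpha0: float
    t_e: float


def modified_egger(data: EffectTable, beta_bar: float, k: float) -> EggerFit:
    """Heterogeneity-adjusted Egger regression for funnel asymmetry.

    Regresses standardized effects ``r_j = beta_hat_j / sqrt(se_j^2 +
    k^2 beta_bar^2)`` on precisions ``d_j = 1 / sqrt(se_j^2 + k^2
    beta_bar^2)`` by ordinary least squares.  Without selective reporting
    the intercept ``alpha0`` is zero in expectation; the test quantity is
    ``T_E = alpha0^2 / var(alpha0)``.

    Requires ``m >= 3`` (the residual variance uses m - 2 degrees of
    freedom) and a non-constant precision vector.
    """
    m = data.m
    if m < 3:
        raise ValueError(
            f"Egger regression needs at least 3 studies (m-2 residual degrees "
            f"of freedom), got m={m}"
        )
    s = np.sqrt(data.variances + (k * beta_bar) ** 2)
    r = data.beta_hat / s
    d = 1.0 / s
    dc = d - d.mean()
    sdd = float(dc @ dc)
    if sdd <= 0 or not np.isfinite(sdd) or np.isclose(sdd, 0.0, atol=1e-30):
        raise ValueError(
            "precision vector is constant: the Egger intercept and slope are "
            "not separately identifiable"
        )
    alpha1 = float(dc @ (r - r.mean()) / sdd)
    alpha0 = float(r.mean() - alpha1 * d.mean())
    resid = r - alpha0 - alpha1 * d
    sigma_eps2 = float(resid @ resid) / (m - 2)
    var_alpha0 = sigma_eps2 * (1.0 / m + d.mean() ** 2 / sdd)
    t_e = alpha0**2 / var_alpha0 if var_alpha0 > 0 else np.inf
    return EggerFit(
        alpha0=alpha0,
        alpha1=alpha1,
        sigma_eps2=sigma_eps2,
        var_alpha0=var_alpha0,
        t_e=float(t_e),
    )


def _egger_te_batch(
    beta: np.ndarray, se: np.ndarray, beta_bar: np.ndarray, k: np.ndarray
) -> np.ndarray:
    """Vectorized T_E over rows of ``beta`` with per-row (beta_bar, k)."""
    m = se.size
    s = np.sqrt(se[None, :] ** 2 + (k * beta_bar)[:, None] ** 2)
    r = beta / s
    d = 1.0 / s
    dbar = d.mean(axis=1, keepdims=True)
    rbar = r.mean(axis=1, keepdims=True)
    dc = d - dbar
    sdd = np.sum(dc**2, axis=1)
    alpha1 = np.sum(dc * (r - rbar), axis=1) / sdd
    alpha0 = rbar[:, 0] - alpha1 * dbar[:, 0]
    resid = r - alpha0[:, None] - alpha1[:, None] * d
    sigma_eps2 = np.sum(resid**2, axis=1) / (m - 2)
    var_alpha0 = sigma_eps2 * (1.0 / m + dbar[:, 0] ** 2 / sdd)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_e = alpha0**2 / var_alpha0
    return np.where(var_alpha0 > 0, t_e, np.inf)


def i_squared(q: float, m: int) -> float:
    """Fraction of total variation due to between-study heterogeneity.

    ``I^2 = (Q - (m - 1)) / Q``, truncated at 0 when Q falls below its
    fixed-effect expectation m - 1 (and defined as 0 at Q = 0).  Returned
    as a fraction in [0, 1).
    """
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    if q < 0:
        raise ValueError(f"Q must be nonnegative, got {q}")
    if q == 0.0:
        return 0.0
    return float(max(0.0, (q - (m - 1)) / q))


def shared_fraction_bound(prps) -> float:
    """Empirical upper bound on the fraction of model-consistent effects.

    Under a two-group mixture in which consistent (replicable) instances
    have expected posterior-PRP 1/2 and the rest a nonnegative one,
    ``pi_r <= 2 * mean(posterior-PRP)``.  The estimate is capped at 1
    since it is a deliberate overestimate.
    """
    prps = np.asarray(prps, dtype=float)
    if prps.size == 0:
        raise ValueError("need at least one posterior-PRP value")
    return float(min(1.0, 2.0 * prps.mean()))


q_statistic = StatisticSpec(
    name="q",
    evaluate=lambda beta, se, beta_bar, k: float(
        _modified_q_arrays(beta, se, beta_bar, k)
    ),
    evaluate_batch=_modified_q_batch,
)

egger_statistic = StatisticSpec(
    name="egger",
    evaluate=lambda beta, se, beta_bar, k: float(
        _egger_te_batch(
            np.asarray(beta, float)[None, :],
            np.asarray(se, float),
            np.atleast_1d(float(beta_bar)),
            np.atleast_1d(float(k)),
        )[0]
    ),
    evaluate_batch=_egger_te_batch,
)

STATISTICS: dict[str, StatisticSpec] = {
    "q": q_statistic,
    "egger": egger_statistic,
}


def get_statistic(name: str) -> StatisticSpec:
    """Look up a registered statistic by name (``"q"`` or ``"egger"``)."""
    try:
        return STATISTICS[name]
    except KeyError:
        raise KeyError(
            f"unknown statistic {name!r}; registered: {sorted(STATISTICS)}"
        ) from None
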