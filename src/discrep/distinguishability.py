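"""Distinguishability criterion: the misclassification probability P_mis.

A replicated realization of a genuine effect is modelled as
``beta | beta_bar ~ N(beta_bar, phi^2)``.  Heterogeneity is acceptable as
long as such realizations remain distinguishable, with high probability,
from realizations of a *null* effect with the same heterogeneity.  The
probability of misclassifying a realization under the Bayes-optimal soft
classifier is

    P_mis(k) = E_Z[ (1 + exp(0.5 / k^2 + Z / k))^(-1) ],   Z ~ N(0, 1),

a strictly increasing function of the dimensionless heterogeneity ratio
``k = phi / |beta_bar|``.  P_mis runs from 0 (no heterogeneity: the effect
is always classified correctly) to 0.5 (infinite heterogeneity: a coin
flip).  Because it lives on a probability scale, P_mis is interpretable
across measurement scales, unlike phi^2 itself.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import optimize, special

__all__ = [
    "pmis_from_k",
    "k_from_pmis",
    "pmis_general",
    "HeterogeneityWarning",
]


class HeterogeneityWarning(UserWarning):
    """Raised when heterogeneity parameters hit a degenerate boundary."""


@lru_cache(maxsize=8)
def _gauss_hermite(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss–Hermite nodes and normalized weights.

    ``sum(w * f(z))`` approximates ``E[f(Z)]`` for standard normal Z.
    """
    z, w = np.polynomial.hermite_e.hermegauss(order)
    return z, w / np.sqrt(2.0 * np.pi)


def pmis_from_k(k: float, quadrature_order: int = 100) -> float:
    """Misclassification probability as a function of the heterogeneity ratio.

    Evaluates the standard-normal expectation by deterministic
    Gauss–Hermite quadrature.  ``k = 0`` returns exactly 0 (the limit);
    the value increases monotonically toward 0.5 as ``k`` grows.

    Parameters
    ----------
    k
        Heterogeneity ratio ``phi / |beta_bar| >= 0``.
    quadrature_order
        Number of Gauss–Hermite nodes (>= 20).
    """
    k = float(k)
    if not np.isfinite(k):
        if k == np.inf:
            return 0.5
        raise ValueError("k must be finite or +inf")
    if k < 0:
        raise ValueError(f"heterogeneity ratio k must be nonnegative, got {k}")
    if quadrature_order < 20:
        raise ValueError("quadrature_order must be at least 20")
    if k == 0.0:
        return 0.0
    z, w = _gauss_hermite(quadrature_order)
    # expit(-a) = 1 / (1 + exp(a)); numerically safe for large arguments
    return float(np.sum(w * special.expit(-(0.5 / k**2 + z / k))))


def k_from_pmis(pmis: float, tol: float = 1e-10, quadrature_order: int = 100) -> float:
    """Invert ``pmis_from_k``: the heterogeneity ratio with a given P_mis.

    Monotonicity of P_mis(k) guarantees a unique root, located by Brent's
    method on log(k) over the bracket [1e-8, 1e8].

    Parameters
    ----------
    pmis
        Target misclassification probability, strictly inside (0, 0.5).
    tol
        Absolute tolerance on P_mis at the returned ``k``.
    """
    pmis = float(pmis)
    if not 0.0 < pmis < 0.5:
        raise ValueError(
            f"pmis must lie strictly in (0, 0.5); got {pmis} "
            "(0 and 0.5 are limits with no finite positive preimage)"
        )
    lo, hi = np.log(1e-8), np.log(1e8)
    log_k = optimize.brentq(
        lambda lk: pmis_from_k(np.exp(lk), quadrature_order) - pmis,
        lo,
        hi,
        xtol=1e-14,
    )
    k = float(np.exp(log_k))
    if abs(pmis_from_k(k, quadrature_order) - pmis) > tol:
        raise RuntimeError(f"inversion did not reach tolerance {tol} at pmis={pmis}")
    return k


def pmis_general(beta_bar: float, phi: float, quadrature_order: int = 100) -> float:
    """P_mis for an effect ``beta_bar`` with heterogeneity scale ``phi``.

    Equals ``pmis_from_k(phi / |beta_bar|)``; invariant to the sign of
    ``beta_bar`` and to joint rescaling of ``(beta_bar, phi)``.  A zero
    grand effect with positive heterogeneity is indistinguishable from the
    null by construction: the boundary value 0.5 is returned with a
    :class:`HeterogeneityWarning`.
    """
    phi = float(phi)
    beta_bar = float(beta_bar)
    if phi < 0:
        raise ValueError(f"phi must be nonnegative, got {phi}")
    if phi == 0.0:
        return 0.0
    if beta_bar == 0.0:
        warnings.warn(
            "beta_bar = 0 with phi > 0: effect is indistinguishable from the "
            "null (P_mis at its 0.5 boundary)",
            HeterogeneityWarning,
            stacklevel=2,
        )
        return 0.5
    return pmis_from_k(phi / abs(beta_bar), quadrature_order)
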