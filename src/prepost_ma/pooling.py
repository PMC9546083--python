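"""Inverse-variance pooling: common-effect and random-effects (REML) models.

The random-effects model estimates the between-study variance tau^2 by
restricted maximum likelihood; the Hartung-Knapp refinement replaces the
usual standard error by a weighted residual-based one and uses a t
reference distribution with k-1 degrees of freedom.  The HK variance is
used untruncated (no floor at the non-HK variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PoolingResult",
    "pool_ce",
    "pool_re",
    "reml_tau2",
    "heterogeneity_stats",
    "reml_profile_loglik",
]


@dataclass(frozen=True)
class PoolingResult:
    """Summary of a meta-analysis.

    ``I2`` is on the percent scale.  For the common-effect model ``tau2`` is
    zero by definition and ``I2``/``H2`` take their degenerate values.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    tau2: float
    Q: float
    I2: float
    H2: float
    k: int
    model: str            # "CE" | "RE"
    hk: bool
    tau2_method: str = "REML"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "level": self.level, "tau2": self.tau2,
            "Q": self.Q, "I2": self.I2, "H2": self.H2,
            "k": self.k, "model": self.model, "hk": self.hk,
            "tau2_method": self.tau2_method,
        }


def _extract(effects) -> tuple[np.ndarray, np.ndarray]:
    """Accept TrialEffect-likes (``.estimate``/``.variance``) or (theta, v) pairs."""
    thetas, variances = [], []
    for eff in effects:
        if hasattr(eff, "estimate") and hasattr(eff, "variance"):
            thetas.append(float(eff.estimate))
            variances.append(float(eff.variance))
        else:
            t, v = eff
            thetas.append(float(t))
            variances.append(float(v))
    theta = np.asarray(thetas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if theta.size == 0:
        raise ValueError("no effects to pool")
    if np.any(v <= 0):
        raise ValueError("all within-study variances must be > 0")
    return theta, v


def heterogeneity_stats(effects, tau2: float) -> tuple[float, float, float]:
    """Cochran's Q (common-effect weights) and the I^2 / H^2 statistics.

    ``s^2 = (k-1) * sum(w) / (sum(w)^2 - sum(w^2))`` with ``w = 1/v`` is the
    'typical' within-study variance; ``I2 = 100 * tau2 / (tau2 + s2)`` and
    ``H2 = (tau2 + s2) / s2``.
    """
    theta, v = _extract(effects)
    k = theta.size
    w = 1.0 / v
    mu_ce = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - mu_ce) ** 2))
    if k < 2:
        return Q, 0.0, 1.0
    sw, sw2 = float(np.sum(w)), float(np.sum(w**2))
    s2 = (k - 1) * sw / (sw**2 - sw2)
    I2 = 100.0 * tau2 / (tau2 + s2)
    H2 = (tau2 + s2) / s2
    return Q, I2, H2


def reml_profile_loglik(tau2: float, theta: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    vt = v + tau2
    w = 1.0 / vt
    mu = np.sum(w * theta) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(vt)) + math.log(np.sum(w)) + np.sum(w * (theta - mu) ** 2)
    )


def reml_tau2(effects, upper: Optional[float] = None) -> float:
    """REML estimate of the between-study variance tau^2.

    Bounded scalar maximisation of the restricted log-likelihood over
    ``tau in [0, upper]`` (default upper: generous multiple of the data
    scale), with the boundary value tau = 0 compared explicitly.
    """
    theta, v = _extract(effects)
    if theta.size < 2:
        raise ValueError("tau^2 is unidentifiable with fewer than 2 studies")
    scale = math.sqrt(float(np.max(v))) + float(np.std(theta)) + 1e-12
    tau_hi = 10.0 * scale if upper is None else math.sqrt(upper)

    def neg(tau: float) -> float:
        return -reml_profile_loglik(tau * tau, theta, v)

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, tau_hi), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    tau2_hat = float(res.x) ** 2
    # Newton polish on tau^2 via tiny local refinement, then boundary check.
    if reml_profile_loglik(0.0, theta, v) >= reml_profile_loglik(tau2_hat, theta, v):
        return 0.0
    return tau2_hat


def _ci(estimate: float, se: float, level: float, df: Optional[int] = None) -> tuple[float, float]:
    if df is None:
        q = stats.norm.ppf(0.5 + level / 2.0)
    else:
        q = stats.t.ppf(0.5 + level / 2.0, df)
    return estimate - q * se, estimate + q * se


def pool_ce(effects, level: float = 0.95) -> PoolingResult:
    """Common (fixed)-effect inverse-variance pooling."""
    theta, v = _extract(effects)
    k = theta.size
    w = 1.0 / v
    estimate = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    lo, hi = _ci(estimate, se, level)
    Q, I2, H2 = heterogeneity_stats(effects, 0.0)
    return PoolingResult(
        estimate=estimate, se=se, ci_low=lo, ci_high=hi, level=level,
        tau2=0.0, Q=Q, I2=I2, H2=H2, k=k, model="CE", hk=False,
    )


def pool_re(
    effects,
    level: float = 0.95,
    hk: bool = False,
    tau2: Optional[float] = None,
) -> PoolingResult:
    """Random-effects pooling with REML tau^2 (or a supplied tau^2).

    With ``hk=True`` the Hartung-Knapp standard error
    ``se^2 = sum(w*(theta - mu)^2) / ((k-1) * sum(w))`` (weights
    ``w = 1/(v + tau2)``) is used together with a t(k-1) confidence
    interval.
    """
    theta, v = _extract(effects)
    k = theta.size
    if k < 2:
        raise ValueError("random-effects pooling needs at least 2 studies")
    if tau2 is None:
        tau2 = reml_tau2(effects)
    w = 1.0 / (v + tau2)
    estimate = float(np.sum(w * theta) / np.sum(w))
    if hk:
        q = float(np.sum(w * (theta - estimate) ** 2) / ((k - 1) * np.sum(w)))
        se = math.sqrt(q)
        lo, hi = _ci(estimate, se, level, df=k - 1)
    else:
        se = float(1.0 / math.sqrt(np.sum(w)))
        lo, hi = _ci(estimate, se, level)
    Q, I2, H2 = heterogeneity_stats(effects, tau2)
    return PoolingResult(
        estimate=estimate, se=se, ci_low=lo, ci_high=hi, level=level,
        tau2=float(tau2), Q=Q, I2=I2, H2=H2, k=k, model="RE", hk=hk,
    )
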