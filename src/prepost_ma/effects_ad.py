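"""Per-trial mean-difference effect sizes from aggregate data.

Three methods are provided, all returning the treatment-minus-control mean
difference with its variance:

* follow-up scores — ignores baselines entirely;
* change scores — uses follow-up minus baseline per arm;
* ANCOVA recovered estimates — reconstructs, from the summary statistics
  alone, the treatment coefficient (and its model-based variance) of a
  single-slope analysis of covariance, exactly as an OLS fit to
  moment-matched pseudo participant data would produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .data_model import CompleteDataset, DataError, TrialArmSummary

__all__ = [
    "TrialEffect",
    "DegenerateEffectError",
    "effect_followup",
    "effect_change",
    "effect_ancova_recovered",
    "compute_effects",
    "METHODS",
]

METHODS = ("followup", "change", "ancova_recovered")

TrialPair = tuple[TrialArmSummary, TrialArmSummary]


class DegenerateEffectError(DataError):
    """Effect variance is zero or the ANCOVA fit has no residual df."""


@dataclass(frozen=True)
class TrialEffect:
    """One trial's mean-difference estimate (treatment - control) and variance."""

    trial_id: str
    method: str
    estimate: float
    variance: float

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.variance > 0:
            raise DegenerateEffectError(
                f"trial {self.trial_id!r}: non-positive effect variance {self.variance}"
            )

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def _unpack(trial: TrialPair) -> TrialPair:
    control, treatment = trial
    for row in (control, treatment):
        if not row.is_complete():
            raise DataError(
                f"trial {row.trial_id!r}/{row.arm.value}: incomplete summary row; "
                "run the fill-in pipeline first"
            )
        if row.n < 1:
            raise DataError(f"trial {row.trial_id!r}: arm with n < 1")
    if control.arm.value != "control" or treatment.arm.value != "treatment":
        raise DataError("expected (control, treatment) pair in that order")
    return control, treatment


def effect_followup(trial: TrialPair) -> TrialEffect:
    """Mean difference of follow-up scores.

    estimate = mean_F,T - mean_F,C; variance = sd_F,T^2/n_T + sd_F,C^2/n_C.
    """
    c, t = _unpack(trial)
    return TrialEffect(
        trial_id=c.trial_id,
        method="followup",
        estimate=t.mean_F - c.mean_F,
        variance=t.sd_F**2 / t.n + c.sd_F**2 / c.n,
    )


def effect_change(trial: TrialPair) -> TrialEffect:
    """Mean difference of change scores (follow-up minus baseline per arm)."""
    c, t = _unpack(trial)
    variance = t.sd_CS**2 / t.n + c.sd_CS**2 / c.n
    if variance <= 0:
        raise DegenerateEffectError(
            f"trial {c.trial_id!r}: zero change-score variance in both arms "
            "(perfect baseline/follow-up correlation with equal SDs)"
        )
    return TrialEffect(
        trial_id=c.trial_id,
        method="change",
        estimate=t.mean_CS - c.mean_CS,
        variance=variance,
    )


def effect_ancova_recovered(trial: TrialPair) -> TrialEffect:
    """ANCOVA treatment effect recovered from summary statistics.

    With pooled within-group sums of squares/products

        S_xx = (n_T-1) sd_B,T^2 + (n_C-1) sd_B,C^2
        S_yy = (n_T-1) sd_F,T^2 + (n_C-1) sd_F,C^2
        S_xy = (n_T-1) r_T sd_B,T sd_F,T + (n_C-1) r_C sd_B,C sd_F,C

    the pooled within-group baseline slope is ``beta = S_xy / S_xx`` and

        estimate = (mean_F,T - mean_F,C) - beta * (mean_B,T - mean_B,C)
        sigma2   = (S_yy - S_xy^2 / S_xx) / (N - 3)
        variance = sigma2 * (1/n_T + 1/n_C + (mean_B,T - mean_B,C)^2 / S_xx)

    which reproduces, exactly, the treatment coefficient and model-based SE
    of a single-slope OLS ANCOVA fitted to participant data matching these
    summaries.
    """
    c, t = _unpack(trial)
    N = c.n + t.n
    if N <= 3:
        raise DegenerateEffectError(
            f"trial {c.trial_id!r}: N = {N} leaves no residual degrees of freedom (need N >= 4)"
        )
    s_xx = (t.n - 1) * t.sd_B**2 + (c.n - 1) * c.sd_B**2
    s_yy = (t.n - 1) * t.sd_F**2 + (c.n - 1) * c.sd_F**2
    s_xy = (t.n - 1) * t.r * t.sd_B * t.sd_F + (c.n - 1) * c.r * c.sd_B * c.sd_F
    if s_xx <= 0:
        raise DegenerateEffectError(f"trial {c.trial_id!r}: zero baseline variance")
    beta = s_xy / s_xx
    diff_b = t.mean_B - c.mean_B
    estimate = (t.mean_F - c.mean_F) - beta * diff_b
    sse = s_yy - s_xy**2 / s_xx
    if sse <= 0:
        raise DegenerateEffectError(
            f"trial {c.trial_id!r}: degenerate ANCOVA fit (zero residual variance)"
        )
    sigma2 = sse / (N - 3)
    variance = sigma2 * (1.0 / t.n + 1.0 / c.n + diff_b**2 / s_xx)
    return TrialEffect(
        trial_id=c.trial_id,
        method="ancova_recovered",
        estimate=estimate,
        variance=variance,
    )


_DISPATCH = {
    "followup": effect_followup,
    "change": effect_change,
    "ancova_recovered": effect_ancova_recovered,
    "ancova": effect_ancova_recovered,
}


def compute_effects(ds: CompleteDataset, method: str) -> list[TrialEffect]:
    """Per-trial effects for every trial in a complete dataset."""
    try:
        func = _DISPATCH[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None
    return [func((control, treatment)) for _, control, treatment in ds.trials()]
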