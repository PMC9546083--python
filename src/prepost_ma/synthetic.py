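"""Simulation of true participant data and derived summary datasets.

``simulate_ipd`` draws two-arm pretest-posttest trials from the same model
family the one-stage ANCOVA assumes; ``aggregate_ipd`` reduces any IPD
table to a complete long-format summary dataset; ``mask_summaries`` deletes
summary cells in controlled patterns to exercise the fill-in engine, while
recording the ground truth for recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_model import Arm, CompleteDataset, MetaDataset, TrialArmSummary, as_complete

__all__ = [
    "ResidSpec",
    "SimulatedIPD",
    "MaskResult",
    "simulate_ipd",
    "aggregate_ipd",
    "mask_summaries",
]

MASK_PATTERNS = ("drop_sdF", "drop_sdCS", "drop_r", "sd_to_se", "mixed")


@dataclass(frozen=True)
class ResidSpec:
    """Residual-error structure for the simulator.

    ``sd`` is interpreted according to ``structure``: a scalar for
    ``single``; ``(control, treatment)`` for ``arm``; a length-k sequence
    for ``study``; a k x 2 array-like (rows trials, columns control /
    treatment) for ``arm_study``.
    """

    structure: str = "single"
    sd: Union[float, Sequence[float], Sequence[Sequence[float]]] = 1.0

    def sd_for(self, trial: int, treated: bool) -> float:
        if self.structure == "single":
            return float(self.sd)
        if self.structure == "arm":
            return float(self.sd[1 if treated else 0])
        if self.structure == "study":
            return float(self.sd[trial])
        if self.structure == "arm_study":
            return float(self.sd[trial][1 if treated else 0])
        raise ValueError(f"unknown residual structure {self.structure!r}")


@dataclass
class SimulatedIPD:
    """Simulated participant data plus the per-trial ground truth."""

    frame: pd.DataFrame        # trial_id, arm, id, y_baseline, y_final
    truth: pd.DataFrame        # trial_id, theta_i, alpha_i, mu_B, imbalance_shift
    seed: int


def simulate_ipd(
    k: int,
    n_per_arm: Union[int, tuple[int, int]],
    theta: float = -0.5,
    tau2: float = 0.25,
    beta: float = 0.5,
    gamma_w: float = 0.0,
    baseline_imbalance_sd: float = 0.0,
    baseline_imbalance_mean: float = 0.0,
    mu_B_range: tuple[float, float] = (8.0, 12.0),
    sigma_B: float = 2.0,
    resid_spec: ResidSpec = ResidSpec(),
    seed: int = 0,
) -> SimulatedIPD:
    """Simulate two-arm pretest-posttest trials.

    Per trial i the true effect is ``theta_i ~ N(theta, tau2)``; baselines
    are ``N(mu_Bi, sigma_B^2)`` in the control arm and
    ``N(mu_Bi + shift_i, sigma_B^2)`` in the treatment arm, with
    ``shift_i ~ N(baseline_imbalance_mean, baseline_imbalance_sd^2)`` (a
    non-zero mean makes the imbalance systematic).  Follow-up scores obey

        y = alpha_i + beta * (b - bbar_i) + (theta_i + gamma_w * (b - bbar_i)) * T + eps,

    with ``bbar_i`` the realised trial baseline mean and ``eps`` drawn per
    ``resid_spec``.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau2 < 0 or sigma_B <= 0 or baseline_imbalance_sd < 0:
        raise ValueError("variance parameters must be non-negative (sigma_B > 0)")
    if isinstance(n_per_arm, int):
        n_lo = n_hi = n_per_arm
    else:
        n_lo, n_hi = n_per_arm
    if n_lo < 2:
        raise ValueError("need at least 2 participants per arm")
    rng = np.random.default_rng(seed)
    frames, truth = [], []
    for i in range(k):
        tid = f"trial_{i + 1}"
        n = int(rng.integers(n_lo, n_hi + 1))
        mu_B = float(rng.uniform(*mu_B_range))
        alpha_i = mu_B  # follow-up anchored at the trial's baseline level
        theta_i = float(rng.normal(theta, math.sqrt(tau2))) if tau2 > 0 else theta
        shift = float(rng.normal(baseline_imbalance_mean, baseline_imbalance_sd)) \
            if (baseline_imbalance_sd > 0 or baseline_imbalance_mean != 0.0) else 0.0
        b_c = rng.normal(mu_B, sigma_B, size=n)
        b_t = rng.normal(mu_B + shift, sigma_B, size=n)
        b_all = np.concatenate([b_c, b_t])
        bbar = b_all.mean()
        eps_c = rng.normal(0.0, resid_spec.sd_for(i, False), size=n)
        eps_t = rng.normal(0.0, resid_spec.sd_for(i, True), size=n)
        y_c = alpha_i + beta * (b_c - bbar) + eps_c
        y_t = alpha_i + beta * (b_t - bbar) + theta_i + gamma_w * (b_t - bbar) + eps_t
        for arm, b, y in (("control", b_c, y_c), ("treatment", b_t, y_t)):
            frames.append(
                pd.DataFrame(
                    {
                        "trial_id": tid, "arm": arm,
                        "id": np.arange(1, n + 1),
                        "y_baseline": b, "y_final": y,
                    }
                )
            )
        truth.append(
            {
                "trial_id": tid, "theta_i": theta_i, "alpha_i": alpha_i,
                "mu_B": mu_B, "imbalance_shift": shift, "n_per_arm": n,
            }
        )
    return SimulatedIPD(
        frame=pd.concat(frames, ignore_index=True),
        truth=pd.DataFrame.from_records(truth),
        seed=seed,
    )


def aggregate_ipd(ipd: Union[SimulatedIPD, pd.DataFrame]) -> CompleteDataset:
    """Reduce participant data to a complete long-format summary dataset.

    Change scores are recorded as follow-up minus baseline; all SDs use the
    n-1 denominator, so the change-score identities hold to machine
    precision by construction.
    """
    frame = ipd.frame if isinstance(ipd, SimulatedIPD) else ipd
    rows = []
    for tid in dict.fromkeys(frame["trial_id"]):
        for arm in ("control", "treatment"):
            sub = frame[(frame["trial_id"] == tid) & (frame["arm"] == arm)]
            if len(sub) < 2:
                raise ValueError(f"trial {tid!r}, arm {arm!r}: need n >= 2 to aggregate")
            b = sub["y_baseline"].to_numpy(dtype=float)
            y = sub["y_final"].to_numpy(dtype=float)
            cs = y - b
            if b.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                raise ValueError(f"trial {tid!r}, arm {arm!r}: degenerate (zero variance) arm")
            rows.append(
                TrialArmSummary(
                    trial_id=str(tid),
                    arm=Arm(arm),
                    n=len(sub),
                    mean_B=float(b.mean()), sd_B=float(b.std(ddof=1)),
                    mean_F=float(y.mean()), sd_F=float(y.std(ddof=1)),
                    mean_CS=float(cs.mean()), sd_CS=float(cs.std(ddof=1)),
                    r=float(np.corrcoef(b, y)[0, 1]),
                )
            )
    return as_complete(MetaDataset(rows))


@dataclass(frozen=True)
class MaskedCell:
    row: int
    field: str
    true_value: float


@dataclass
class MaskResult:
    """Masked dataset plus the ground truth of every deleted/derived cell."""

    dataset: MetaDataset
    masked: list[MaskedCell] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return len(self.masked)


def _mask_row(row: TrialArmSummary, pattern: str) -> tuple[TrialArmSummary, list[tuple[str, float]]]:
    deleted: list[tuple[str, float]] = []
    if pattern == "drop_sdF":
        if row.sd_F is not None:
            deleted.append(("sd_F", row.sd_F))
            row = row.replace(sd_F=None)
    elif pattern == "drop_sdCS":
        if row.sd_CS is not None:
            deleted.append(("sd_CS", row.sd_CS))
            row = row.replace(sd_CS=None)
    elif pattern == "drop_r":
        if row.r is not None:
            deleted.append(("r", row.r))
            row = row.replace(r=None)
    elif pattern == "sd_to_se":
        changes = {}
        for q in ("B", "F", "CS"):
            sd = getattr(row, f"sd_{q}")
            if sd is not None and row.n:
                changes[f"se_{q}"] = sd / math.sqrt(row.n)
                changes[f"sd_{q}"] = None
                deleted.append((f"sd_{q}", sd))
        row = row.replace(**changes)
    else:
        raise ValueError(f"unknown mask pattern {pattern!r}")
    return row, deleted


def mask_summaries(
    ds: CompleteDataset,
    pattern: str = "mixed",
    fraction: float = 0.5,
    seed: int = 0,
) -> MaskResult:
    """Delete summary cells from a fraction of rows, recording ground truth.

    Patterns: ``drop_sdF``, ``drop_sdCS``, ``drop_r``, ``sd_to_se``
    (convert every SD to its SE, then delete the SD — algebraically
    recoverable), or ``mixed`` (one of the above per selected row, chosen
    at random).
    """
    if pattern not in MASK_PATTERNS:
        raise ValueError(f"pattern must be one of {MASK_PATTERNS}, got {pattern!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rows = len(ds.rows)
    n_select = int(round(fraction * n_rows))
    selected = set(rng.choice(n_rows, size=n_select, replace=False)) if n_select else set()
    rows, masked = [], []
    for i, row in enumerate(ds.rows):
        if i in selected:
            pat = pattern
            if pattern == "mixed":
                pat = str(rng.choice(["drop_sdF", "drop_sdCS", "drop_r", "sd_to_se"]))
            row, deleted = _mask_row(row, pat)
            masked.extend(MaskedCell(i, fld, val) for fld, val in deleted)
        rows.append(row)
    return MaskResult(dataset=MetaDataset(rows), masked=masked)
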