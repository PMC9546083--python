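"""Exact-moment pseudo participant data from aggregate summaries.

For each trial arm, n (baseline, follow-up) pairs are constructed whose
sample means, sample SDs (n-1 denominator) and sample correlation equal
the summary statistics *exactly* (to floating-point rounding), not just in
expectation.  All downstream ANCOVA fits depend on the data only through
these matched sufficient statistics, so different seeds change the point
cloud but not any estimate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import Arm, CompleteDataset, DataError

__all__ = [
    "PseudoIPD",
    "MomentReport",
    "generate_arm",
    "generate_dataset",
    "verify_moments",
    "arm_seed_sequence",
]

#: Tolerance for the moment-matching contract.
MOMENT_TOL = 1e-10

IPD_COLUMNS = ["trial_id", "arm", "id", "y_baseline", "y_final"]


class PseudoIPDError(DataError):
    pass


@dataclass
class PseudoIPD:
    """Generated participant-level records plus the master seed used."""

    frame: pd.DataFrame   # columns: trial_id, arm, id, y_baseline, y_final
    seed: int

    def __len__(self) -> int:
        return len(self.frame)

    def trial(self, trial_id: str) -> pd.DataFrame:
        return self.frame[self.frame["trial_id"] == trial_id]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")


def arm_seed_sequence(master_seed: int, trial_id: str, arm: str) -> np.random.SeedSequence:
    """Stable per-arm seed derived from the master seed and the arm identity.

    Hash-based, so subsetting or reordering trials never changes another
    trial's pseudo data.
    """
    digest = hashlib.sha256(f"{master_seed}|{trial_id}|{arm}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.SeedSequence(entropy=[int(w) for w in words])


def generate_arm(
    n: int,
    mean_B: float,
    sd_B: float,
    mean_F: float,
    sd_F: float,
    r: float,
    seed,
) -> np.ndarray:
    """Generate an (n, 2) array of (baseline, follow-up) values with exact moments.

    Construction: draw an n x 2 standard-normal matrix, column-centre it,
    orthonormalise (QR), scale so the sample covariance is the identity,
    then map through the Cholesky factor of the target covariance and add
    the target means.  The five sample moments match by construction.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    """
    if n < 3:
        raise PseudoIPDError(
            f"n = {n}: at least 3 participants per arm are required to match "
            "two means, two SDs and a correlation"
        )
    if sd_B <= 0 or sd_F <= 0:
        raise PseudoIPDError("standard deviations must be > 0")
    if not -1.0 < r < 1.0:
        raise PseudoIPDError(
            f"|r| = {abs(r)} is not < 1: the target covariance is rank-deficient; "
            "perfect correlations cannot be represented by exact-moment data"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(64):
        z = rng.standard_normal((n, 2))
        zc = z - z.mean(axis=0)
        q, rr = np.linalg.qr(zc)
        if np.min(np.abs(np.diag(rr))) > 1e-8:
            break
    else:  # pragma: no cover - probability ~0
        raise PseudoIPDError("failed to draw a full-rank noise matrix")
    # Fix signs for determinism across LAPACK implementations.
    q = q * np.sign(np.diag(rr))
    cov = np.array([[sd_B**2, r * sd_B * sd_F], [r * sd_B * sd_F, sd_F**2]])
    chol = np.linalg.cholesky(cov)
    x = np.sqrt(n - 1.0) * q @ chol.T
    x += np.array([mean_B, mean_F])
    return x


def generate_dataset(ds: CompleteDataset, seed: int) -> PseudoIPD:
    """Pseudo-IPD for every arm of a complete dataset.

    Per-arm seeds are derived deterministically from ``seed`` and the
    (trial_id, arm) identity, so the same master seed always yields
    identical output.
    """
    parts = []
    for row in ds.rows:
        try:
            values = generate_arm(
                row.n, row.mean_B, row.sd_B, row.mean_F, row.sd_F, row.r,
                arm_seed_sequence(seed, row.trial_id, row.arm.value),
            )
        except PseudoIPDError as exc:
            raise PseudoIPDError(
                f"trial {row.trial_id!r}, arm {row.arm.value!r}: {exc}"
            ) from exc
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": row.trial_id,
                    "arm": row.arm.value,
                    "id": np.arange(1, row.n + 1),
                    "y_baseline": values[:, 0],
                    "y_final": values[:, 1],
                }
            )
        )
    frame = pd.concat(parts, ignore_index=True)
    return PseudoIPD(frame=frame, seed=seed)


@dataclass
class MomentReport:
    """Worst moment discrepancy per arm; pass iff all below ``MOMENT_TOL``."""

    discrepancies: pd.DataFrame  # columns trial_id, arm, worst, field
    tol: float = MOMENT_TOL

    @property
    def passed(self) -> bool:
        return bool((self.discrepancies["worst"] < self.tol).all())

    @property
    def worst(self) -> float:
        return float(self.discrepancies["worst"].max())


def verify_moments(p: PseudoIPD, ds: CompleteDataset) -> MomentReport:
    """Check the five sample moments of each arm against the summaries."""
    records = []
    grouped = dict(tuple(p.frame.groupby(["trial_id", "arm"], sort=False)))
    for row in ds.rows:
        key = (row.trial_id, row.arm.value)
        if key not in grouped:
            raise PseudoIPDError(f"no pseudo data for trial {key[0]!r}, arm {key[1]!r}")
        sub = grouped[key]
        if len(sub) != row.n:
            raise PseudoIPDError(f"arm {key}: expected n={row.n}, found {len(sub)} records")
        b = sub["y_baseline"].to_numpy()
        f = sub["y_final"].to_numpy()
        diffs = {
            "mean_B": abs(b.mean() - row.mean_B),
            "sd_B": abs(b.std(ddof=1) - row.sd_B),
            "mean_F": abs(f.mean() - row.mean_F),
            "sd_F": abs(f.std(ddof=1) - row.sd_F),
            "r": abs(np.corrcoef(b, f)[0, 1] - row.r),
        }
        worst_field = max(diffs, key=diffs.get)
        records.append(
            {
                "trial_id": row.trial_id,
                "arm": row.arm.value,
                "worst": diffs[worst_field],
                "field": worst_field,
            }
        )
    return MomentReport(pd.DataFrame.from_records(records))
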