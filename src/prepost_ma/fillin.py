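"""Sequential fill-in of missing summary data.

Pipeline order (fixed, not user-configurable):

1. ``sd_from_se`` for baseline, follow-up and change scores
2. ``impute_sdF_equals_sdB`` — missing follow-up SD assumed equal to baseline SD
3. ``correlation_from_sds`` where all three SDs are available and r is missing
4. ``fill_means`` — third mean from ``mean_CS = mean_F - mean_B``
5. ``impute_missing_correlations`` — weighted-mean or fixed-value imputation
6. ``sd_change_from_correlation`` for any remaining missing change-score SD
7. final consistency pass (complete-dataset invariants)

Every filled cell is recorded in a provenance report as *calculated*
(algebraically determined) or *imputed* (assumption-based); untouched cells
are *observed*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .data_model import (
    Arm,
    CompleteDataset,
    DataError,
    MetaDataset,
    MEASURE_COLUMNS,
    TrialArmSummary,
    as_complete,
)

#: |r| may exceed 1 by at most this before it is an error rather than a clamp.
CLAMP_TOL = 1e-8

OBSERVED = "observed"
CALCULATED = "calculated"
IMPUTED = "imputed"


class FillinError(DataError):
    """A row cannot be completed, or summaries are mutually inconsistent."""


class InconsistentSummariesError(FillinError):
    """The three SDs imply |r| > 1 beyond rounding tolerance."""


@dataclass(frozen=True)
class ProvenanceRecord:
    row: int
    trial_id: str
    arm: str
    fields: str          # field written (comma-joined when several)
    status: str          # calculated | imputed
    rule: str
    value: float


@dataclass
class FillinReport:
    """Cell-level provenance of a fill-in run, plus warnings."""

    records: list[ProvenanceRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)

    def add(self, row_index: int, row: TrialArmSummary, fields: str,
            status: str, rule: str, value: float) -> None:
        self.records.append(
            ProvenanceRecord(row_index, row.trial_id, row.arm.value, fields, status, rule, value)
        )

    def n_filled(self, status: Optional[str] = None) -> int:
        if status is None:
            return len(self.records)
        return sum(1 for rec in self.records if rec.status == status)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(rec) for rec in self.records],
            columns=["row", "trial_id", "arm", "fields", "status", "rule", "value"],
        )

    def cell_status(self, ds: MetaDataset) -> pd.DataFrame:
        """Full row x field status table (observed / calculated / imputed / missing)."""
        filled = {(rec.row, rec.fields): rec.status for rec in self.records}
        table = {}
        for i, row in enumerate(ds.rows):
            table[i] = {
                col: filled.get((i, col), OBSERVED if getattr(row, col) is not None else "missing")
                for col in MEASURE_COLUMNS
            }
        return pd.DataFrame(table).T


def sd_from_se(se: float, n: int) -> float:
    """Standard deviation from a standard error: ``sd = se * sqrt(n)``."""
    if se is None or se <= 0:
        raise FillinError(f"standard error must be > 0, got {se}")
    if n is None or n < 1:
        raise FillinError(f"sample size must be >= 1, got {n}")
    return se * math.sqrt(n)


def correlation_from_sds(
    sd_B: float, sd_F: float, sd_CS: float,
    context: str = "", report: Optional[FillinReport] = None,
) -> float:
    """Within-group correlation from the three SDs.

    ``r = (sd_B^2 + sd_F^2 - sd_CS^2) / (2 * sd_B * sd_F)``.  Values within
    ``CLAMP_TOL`` beyond +/-1 are clamped with a warning; anything further
    out raises :class:`InconsistentSummariesError`.
    """
    for name, v in (("sd_B", sd_B), ("sd_F", sd_F), ("sd_CS", sd_CS)):
        if v is None or v < 0 or (name != "sd_CS" and v == 0):
            raise FillinError(f"{name} must be positive, got {v}")
    r = (sd_B**2 + sd_F**2 - sd_CS**2) / (2.0 * sd_B * sd_F)
    if abs(r) > 1.0 + CLAMP_TOL:
        raise InconsistentSummariesError(
            f"SDs imply correlation {r:.8g} outside [-1, 1]"
            + (f" ({context})" if context else "")
        )
    if abs(r) > 1.0:
        clamped = math.copysign(1.0, r)
        msg = f"correlation {r:.12g} clamped to {clamped:+.0f}" + (
            f" ({context})" if context else ""
        )
        warnings.warn(msg, stacklevel=2)
        if report is not None:
            report.warnings.append(msg)
        r = clamped
    return r


def sd_change_from_correlation(sd_B: float, sd_F: float, r: float) -> float:
    """Change-score SD implied by the correlation:
    ``sd_CS = sqrt(sd_B^2 + sd_F^2 - 2*r*sd_B*sd_F)``.
    """
    if sd_B is None or sd_B <= 0 or sd_F is None or sd_F <= 0:
        raise FillinError("standard deviations must be > 0")
    if r is None or not -1.0 <= r <= 1.0:
        raise FillinError(f"correlation must be in [-1, 1], got {r}")
    radicand = sd_B**2 + sd_F**2 - 2.0 * r * sd_B * sd_F
    return math.sqrt(max(radicand, 0.0))


def fill_sds_from_ses(ds: MetaDataset, report: Optional[FillinReport] = None) -> MetaDataset:
    """Step 1: each missing SD computed from its SE and the sample size."""
    rows = []
    for i, row in enumerate(ds.rows):
        changes = {}
        for q in ("B", "F", "CS"):
            sd, se = getattr(row, f"sd_{q}"), getattr(row, f"se_{q}")
            if sd is None and se is not None and row.n is not None:
                value = sd_from_se(se, row.n)
                changes[f"sd_{q}"] = value
                if report is not None:
                    report.add(i, row, f"sd_{q}", CALCULATED, "sd_from_se", value)
        rows.append(row.replace(**changes) if changes else row)
    return MetaDataset(rows)


def impute_sdF_equals_sdB(ds: MetaDataset, report: Optional[FillinReport] = None) -> MetaDataset:
    """Step 2: missing follow-up SDs assumed equal to the baseline SDs."""
    rows = []
    for i, row in enumerate(ds.rows):
        if row.sd_F is None and row.sd_B is not None:
            if report is not None:
                report.add(i, row, "sd_F", IMPUTED, "sdF_equals_sdB", row.sd_B)
            row = row.replace(sd_F=row.sd_B)
        rows.append(row)
    return MetaDataset(rows)


def fill_correlations_from_sds(ds: MetaDataset, report: Optional[FillinReport] = None) -> MetaDataset:
    """Step 3: compute r from (sd_B, sd_F, sd_CS) wherever r is missing."""
    rows = []
    for i, row in enumerate(ds.rows):
        if (
            row.r is None
            and row.sd_B is not None and row.sd_F is not None and row.sd_CS is not None
        ):
            value = correlation_from_sds(
                row.sd_B, row.sd_F, row.sd_CS,
                context=f"row {i}, trial {row.trial_id!r}/{row.arm.value}",
                report=report,
            )
            if report is not None:
                report.add(i, row, "r", CALCULATED, "correlation_from_sds", value)
            row = row.replace(r=value)
        rows.append(row)
    return MetaDataset(rows)


def fill_means(ds: MetaDataset, report: Optional[FillinReport] = None) -> MetaDataset:
    """Step 4: complete the mean triple via ``mean_CS = mean_F - mean_B``.

    Rows with fewer than two means present are left alone and listed in the
    report's ``unresolved``.
    """
    rows = []
    for i, row in enumerate(ds.rows):
        present = sum(v is not None for v in (row.mean_B, row.mean_F, row.mean_CS))
        if present == 2:
            if row.mean_CS is None:
                value, which = row.mean_F - row.mean_B, "mean_CS"
            elif row.mean_F is None:
                value, which = row.mean_B + row.mean_CS, "mean_F"
            else:
                value, which = row.mean_F - row.mean_CS, "mean_B"
            if report is not None:
                report.add(i, row, which, CALCULATED, "mean_identity", value)
            row = row.replace(**{which: value})
        elif present < 2 and report is not None:
            report.unresolved.append(
                f"row {i} ({row.trial_id}/{row.arm.value}): fewer than two means present"
            )
        rows.append(row)
    return MetaDataset(rows)


def impute_missing_correlations(
    ds: MetaDataset,
    strategy: str = "weighted_mean",
    fixed_value: Optional[float] = None,
    report: Optional[FillinReport] = None,
) -> MetaDataset:
    """Step 5: impute correlations that could not be calculated.

    ``weighted_mean`` uses the (n-1)-weighted mean of all observed/calculated
    r values in the dataset; ``fixed`` uses ``fixed_value``.
    """
    if strategy not in ("weighted_mean", "fixed"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "fixed":
        if fixed_value is None or not -1.0 <= fixed_value <= 1.0:
            raise FillinError("strategy 'fixed' requires fixed_value in [-1, 1]")
        fill = fixed_value
        rule = "fixed_correlation"
    else:
        num = den = 0.0
        for row in ds.rows:
            if row.r is not None and row.n is not None and row.n > 1:
                num += (row.n - 1) * row.r
                den += row.n - 1
        if den == 0.0:
            if any(row.r is None for row in ds.rows):
                raise FillinError(
                    "no observed correlations to average; supply a fixed correlation "
                    "value (strategy='fixed')"
                )
            return ds
        fill = num / den
        rule = "weighted_mean_correlation"
    rows = []
    for i, row in enumerate(ds.rows):
        if row.r is None:
            if report is not None:
                report.add(i, row, "r", IMPUTED, rule, fill)
            row = row.replace(r=fill)
        rows.append(row)
    return MetaDataset(rows)


def fill_sd_change(ds: MetaDataset, report: Optional[FillinReport] = None) -> MetaDataset:
    """Step 6: remaining missing change-score SDs from (sd_B, sd_F, r)."""
    rows = []
    for i, row in enumerate(ds.rows):
        if row.sd_CS is None and None not in (row.sd_B, row.sd_F, row.r):
            value = sd_change_from_correlation(row.sd_B, row.sd_F, row.r)
            if report is not None:
                report.add(i, row, "sd_CS", CALCULATED, "sd_change_from_correlation", value)
            row = row.replace(sd_CS=value)
        rows.append(row)
    return MetaDataset(rows)


def run_fillin(
    ds: MetaDataset,
    corr_strategy: str = "weighted_mean",
    corr_value: Optional[float] = None,
) -> tuple[CompleteDataset, FillinReport]:
    """Run the full fill-in sequence and return a complete dataset + provenance.

    Raises :class:`FillinError` naming the offending rows when any row cannot
    be completed (e.g. missing sample size, or irrecoverable fields).
    """
    report = FillinReport()
    missing_n = [
        f"row {i} ({row.trial_id}/{row.arm.value})"
        for i, row in enumerate(ds.rows) if row.n is None
    ]
    if missing_n:
        raise FillinError("sample size n missing for: " + "; ".join(missing_n))

    ds = fill_sds_from_ses(ds, report)
    ds = impute_sdF_equals_sdB(ds, report)
    ds = fill_correlations_from_sds(ds, report)
    ds = fill_means(ds, report)
    ds = impute_missing_correlations(ds, corr_strategy, corr_value, report)
    ds = fill_sd_change(ds, report)

    # Final consistency pass: a row whose sd_F was imputed (assumed equal to
    # sd_B) but whose r and sd_CS were both observed is overdetermined and in
    # general inconsistent; the correlation is recomputed from the three SDs,
    # mirroring the fill-in workflow's formula step.
    imputed_sdF = {rec.row for rec in report.records
                   if rec.fields == "sd_F" and rec.rule == "sdF_equals_sdB"}
    rows = list(ds.rows)
    for i in imputed_sdF:
        row = rows[i]
        if None in (row.sd_B, row.sd_F, row.sd_CS, row.r):
            continue
        implied = row.sd_B**2 + row.sd_F**2 - 2 * row.r * row.sd_B * row.sd_F
        if abs(row.sd_CS**2 - implied) > 1e-9 * max(1.0, row.sd_CS**2):
            value = correlation_from_sds(
                row.sd_B, row.sd_F, row.sd_CS,
                context=f"row {i}, trial {row.trial_id!r}/{row.arm.value}",
                report=report,
            )
            report.add(i, row, "r", CALCULATED, "correlation_recomputed_after_sdF_imputation", value)
            rows[i] = row.replace(r=value)
    ds = MetaDataset(rows)

    incomplete = [
        f"row {i} ({row.trial_id}/{row.arm.value}): missing "
        + ", ".join(c for c in ("n", "mean_B", "sd_B", "mean_F", "sd_F", "mean_CS", "sd_CS", "r")
                    if getattr(row, c) is None)
        for i, row in enumerate(ds.rows)
        if not row.is_complete()
    ]
    if incomplete:
        raise FillinError(
            "rows could not be completed:\n" + "\n".join(incomplete)
        )
    return as_complete(ds), report
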