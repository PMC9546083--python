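"""Long-format data schema, I/O, validation and descriptive summaries.

A dataset has one row per trial arm.  The canonical column set, in order, is

    trial_id, arm, n,
    mean_B, sd_B, se_B,      (baseline)
    mean_F, sd_F, se_F,      (follow-up)
    mean_CS, sd_CS, se_CS,   (change score = follow-up - baseline)
    r                        (within-group baseline/follow-up correlation)

Blank cells denote missing values.  All standard deviations use the n-1
(sample) denominator.  Change scores follow the package-wide sign
convention ``mean_CS = mean_F - mean_B``; inputs recorded the other way
round can be negated on read (``negate_change=True``).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical column order for CSV/XLSX files.
COLUMNS = [
    "trial_id", "arm", "n",
    "mean_B", "sd_B", "se_B",
    "mean_F", "sd_F", "se_F",
    "mean_CS", "sd_CS", "se_CS",
    "r",
]

#: Numeric measurement columns (everything except identifiers).
MEASURE_COLUMNS = COLUMNS[3:]

#: Numeric columns including the sample size.
NUMERIC_COLUMNS = ["n"] + MEASURE_COLUMNS

#: Relative tolerance for internal-consistency checks (sd vs se, mean_CS, sd_CS).
CONSISTENCY_RTOL = 1e-6


class DataError(ValueError):
    """Base class for dataset errors."""


class SchemaError(DataError):
    """Header does not match the canonical column set."""


class ParseError(DataError):
    """A cell could not be parsed as a number."""


class StructureError(DataError):
    """Trial/arm structure is invalid (e.g. a trial without both arms)."""


class Arm(str, enum.Enum):
    control = "control"
    treatment = "treatment"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_ARM_ALIASES = {
    "control": Arm.control,
    "treatment": Arm.treatment,
    "0": Arm.control,
    "1": Arm.treatment,
    "c": Arm.control,
    "t": Arm.treatment,
}


def parse_arm(value: object) -> Arm:
    """Parse an arm label; accepts control/treatment (any case) and 0/1."""
    if isinstance(value, Arm):
        return value
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return Arm.treatment if value else Arm.control
    key = str(value).strip().lower()
    if key.endswith(".0"):  # numeric arm column read back as float
        key = key[:-2]
    try:
        return _ARM_ALIASES[key]
    except KeyError:
        raise ParseError(f"unrecognised arm label {value!r}") from None


@dataclass(frozen=True)
class TrialArmSummary:
    """Aggregate summary statistics for one arm of one trial.

    Every field except ``trial_id`` and ``arm`` may be missing (``None``).
    """

    trial_id: str
    arm: Arm
    n: Optional[int] = None
    mean_B: Optional[float] = None
    sd_B: Optional[float] = None
    se_B: Optional[float] = None
    mean_F: Optional[float] = None
    sd_F: Optional[float] = None
    se_F: Optional[float] = None
    mean_CS: Optional[float] = None
    sd_CS: Optional[float] = None
    se_CS: Optional[float] = None
    r: Optional[float] = None

    def get(self, name: str):
        return getattr(self, name)

    def replace(self, **changes) -> "TrialArmSummary":
        return dataclasses.replace(self, **changes)

    def missing_fields(self) -> list[str]:
        return [c for c in MEASURE_COLUMNS if getattr(self, c) is None]

    def is_complete(self) -> bool:
        """True when all fields needed for analysis are present (SEs excluded)."""
        required = ("n", "mean_B", "sd_B", "mean_F", "sd_F", "mean_CS", "sd_CS", "r")
        return all(getattr(self, c) is not None for c in required)


@dataclass
class MetaDataset:
    """An ordered collection of trial-arm summaries, two arms per trial."""

    rows: list[TrialArmSummary] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[TrialArmSummary]:
        return iter(self.rows)

    @property
    def trial_ids(self) -> list[str]:
        """Distinct trial ids in order of first appearance."""
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.trial_id, None)
        return list(seen)

    @property
    def k(self) -> int:
        return len(self.trial_ids)

    def trial(self, trial_id: str) -> tuple[TrialArmSummary, TrialArmSummary]:
        """Return the (control, treatment) pair for one trial."""
        control = treatment = None
        for row in self.rows:
            if row.trial_id == trial_id:
                if row.arm is Arm.control:
                    control = row
                else:
                    treatment = row
        if control is None or treatment is None:
            raise StructureError(f"trial {trial_id!r} does not have both arms")
        return control, treatment

    def trials(self) -> Iterator[tuple[str, TrialArmSummary, TrialArmSummary]]:
        for tid in self.trial_ids:
            control, treatment = self.trial(tid)
            yield tid, control, treatment

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {c: getattr(row, c) for c in COLUMNS}
            rec["arm"] = row.arm.value
            records.append(rec)
        frame = pd.DataFrame.from_records(records, columns=COLUMNS)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MetaDataset":
        missing = [c for c in COLUMNS if c not in frame.columns]
        extra = [c for c in frame.columns if c not in COLUMNS]
        if missing or extra:
            raise SchemaError(
                f"column mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}; "
                f"expected exactly {COLUMNS}"
            )
        rows = []
        for idx, rec in frame.iterrows():
            tid = str(rec["trial_id"]).strip()
            arm = parse_arm(rec["arm"])
            values: dict[str, object] = {}
            for col in NUMERIC_COLUMNS:
                raw = rec[col]
                if raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
                    isinstance(raw, str) and not raw.strip()
                ):
                    values[col] = None
                    continue
                try:
                    num = float(raw)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric value {raw!r} in column {col!r}, row {idx}"
                    ) from None
                if col == "n":
                    if not float(num).is_integer():
                        raise ParseError(f"sample size must be an integer, got {num} in row {idx}")
                    num = int(num)
                values[col] = num
            rows.append(TrialArmSummary(trial_id=tid, arm=arm, **values))  # type: ignore[arg-type]
        ds = cls(rows)
        _check_structure(ds)
        return ds


class CompleteDataset(MetaDataset):
    """A :class:`MetaDataset` with no missing analysis fields.

    Construct with :func:`as_complete`, which enforces the invariants
    (presence of all means/SDs/r, internal consistency of the change-score
    identities).
    """


def _check_structure(ds: MetaDataset) -> None:
    counts: dict[str, dict[Arm, int]] = {}
    for row in ds.rows:
        counts.setdefault(row.trial_id, {Arm.control: 0, Arm.treatment: 0})
        counts[row.trial_id][row.arm] += 1
    bad = [
        tid
        for tid, c in counts.items()
        if c[Arm.control] != 1 or c[Arm.treatment] != 1
    ]
    if bad:
        raise StructureError(
            "each trial must appear exactly twice, once per arm; offending trials: "
            + ", ".join(repr(t) for t in bad)
        )
    if not counts:
        raise StructureError("dataset has no rows")


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return "xlsx"
    return "csv"


def read_dataset(
    path: str | Path,
    format: str = "auto",
    negate_change: bool = False,
) -> MetaDataset:
    """Read a long-format dataset from CSV or XLSX.

    Parameters
    ----------
    path
        File to read; the header row must match the canonical column set.
    format
        ``"csv"``, ``"xlsx"`` or ``"auto"`` (by file extension).
    negate_change
        Negate ``mean_CS`` on read, for files recorded as baseline minus
        follow-up rather than the package convention follow-up minus
        baseline.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(
            path, dtype={"trial_id": str, "arm": str}, float_precision="round_trip"
        )
    elif fmt == "xlsx":
        frame = pd.read_excel(path, dtype={"trial_id": str, "arm": str})
    else:
        raise ValueError(f"unknown format {format!r}")
    ds = MetaDataset.from_frame(frame)
    if negate_change:
        ds = MetaDataset(
            [
                row.replace(mean_CS=None if row.mean_CS is None else -row.mean_CS)
                for row in ds.rows
            ]
        )
    return ds


def write_dataset(ds: MetaDataset, path: str | Path, format: str = "auto") -> Path:
    """Write a dataset to CSV or XLSX; missing values become blank cells.

    Round-trip guarantee: ``read_dataset(write_dataset(ds))`` reproduces the
    dataset field-for-field.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    frame = ds.to_frame()
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "xlsx":
        frame.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def template_frame() -> pd.DataFrame:
    """An empty template with the canonical header, for users to fill in."""
    return pd.DataFrame(columns=COLUMNS)


def describe(ds: MetaDataset) -> pd.DataFrame:
    """Per-column descriptive summary: presence, missingness and statistics.

    Returns a frame indexed by column with ``count``, ``missing_rate``,
    ``mean``, ``sd``, ``median``, ``min``, ``max`` over the present values
    (statistics are NaN for empty columns).
    """
    if not ds.rows:
        raise ValueError("cannot describe an empty dataset")
    total = len(ds.rows)
    out = {}
    for col in NUMERIC_COLUMNS:
        values = np.array(
            [getattr(row, col) for row in ds.rows if getattr(row, col) is not None],
            dtype=float,
        )
        count = values.size
        stats = {
            "count": count,
            "missing_rate": (total - count) / total,
            "mean": np.nan, "sd": np.nan, "median": np.nan,
            "min": np.nan, "max": np.nan,
        }
        if count:
            stats.update(
                mean=float(values.mean()),
                sd=float(values.std(ddof=1)) if count > 1 else 0.0,
                median=float(np.median(values)),
                min=float(values.min()),
                max=float(values.max()),
            )
        out[col] = stats
    return pd.DataFrame(out).T[["count", "missing_rate", "mean", "sd", "median", "min", "max"]]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    row: int               # positional index into ds.rows
    trial_id: str
    arm: str
    fields: str            # comma-joined field names involved
    rule: str              # short machine-readable rule id
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[row {self.row} {self.trial_id}/{self.arm}] {self.rule}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def add(self, row: int, r: TrialArmSummary, fields: str, rule: str, message: str) -> None:
        self.violations.append(Violation(row, r.trial_id, r.arm.value, fields, rule, message))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(v) for v in self.violations],
            columns=["row", "trial_id", "arm", "fields", "rule", "message"],
        )


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= CONSISTENCY_RTOL * max(1.0, abs(a), abs(b))


def validate_dataset(ds: MetaDataset, require_complete: bool = False) -> ValidationReport:
    """Check every invariant and return a report of violations.

    The report is the contract: an empty report means the dataset is valid.
    With ``require_complete`` the completeness invariants are enforced as
    well (no missing analysis fields, change-score identities hold).
    """
    report = ValidationReport()
    for i, row in enumerate(ds.rows):
        if row.n is not None and row.n < 1:
            report.add(i, row, "n", "n_positive", f"n must be >= 1, got {row.n}")
        for col in ("sd_B", "sd_F", "sd_CS", "se_B", "se_F", "se_CS"):
            v = getattr(row, col)
            if v is not None and v <= 0:
                report.add(i, row, col, "positive", f"{col} must be > 0, got {v}")
        if row.r is not None and not -1.0 <= row.r <= 1.0:
            report.add(i, row, "r", "r_range", f"r outside [-1, 1]: {row.r}")
        # sd/se cross-consistency when both present
        if row.n is not None and row.n >= 1:
            for q in ("B", "F", "CS"):
                sd, se = getattr(row, f"sd_{q}"), getattr(row, f"se_{q}")
                if sd is not None and se is not None and sd > 0 and se > 0:
                    if abs(sd - se * math.sqrt(row.n)) > 1e-6 * sd:
                        report.add(
                            i, row, f"sd_{q},se_{q}", "sd_se_consistency",
                            f"sd_{q}={sd} inconsistent with se_{q}*sqrt(n)={se * math.sqrt(row.n):.6g}",
                        )
        if require_complete:
            required = ["n", "mean_B", "sd_B", "mean_F", "sd_F", "mean_CS", "sd_CS", "r"]
            missing = [c for c in required if getattr(row, c) is None]
            if missing:
                report.add(
                    i, row, ",".join(missing), "complete_missing",
                    "missing required fields: " + ", ".join(missing),
                )
                continue
            if not _close(row.mean_CS, row.mean_F - row.mean_B):
                report.add(
                    i, row, "mean_CS", "mean_cs_identity",
                    f"mean_CS={row.mean_CS} but mean_F - mean_B = {row.mean_F - row.mean_B}",
                )
            implied = row.sd_B**2 + row.sd_F**2 - 2 * row.r * row.sd_B * row.sd_F
            if not _close(row.sd_CS**2, implied):
                report.add(
                    i, row, "sd_CS", "sd_cs_identity",
                    f"sd_CS^2={row.sd_CS**2:.6g} but sd_B^2+sd_F^2-2*r*sd_B*sd_F = {implied:.6g}",
                )
    return report


def as_complete(ds: MetaDataset) -> CompleteDataset:
    """Promote a dataset to :class:`CompleteDataset`, enforcing its invariants."""
    report = validate_dataset(ds, require_complete=True)
    if not report.valid:
        raise DataError(
            "dataset is not complete/consistent:\n"
            + "\n".join(str(v) for v in report.violations[:20])
        )
    return CompleteDataset(list(ds.rows))
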