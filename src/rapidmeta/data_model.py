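"""Domain types and delimited-text I/O for trial-level meta-analytic data.

The central object is a 2x2 table per randomized comparison (adverse-event
counts in a treatment and a control arm) annotated with two registry flags:
whether the trial was registered on the registry of interest and whether
summary results were posted there.  Trials are grouped into meta-analyses,
each pooling one safety outcome.  The CSV schema is fixed::

    ma_id, trial_id, comparison_index, events_trt, n_trt,
    events_ctl, n_ctl, registered, results_posted[, outcome_label]

Row order in the file is meaningful: it defines what "the first comparison"
of a multi-arm trial means when ``comparison_index`` ties or is absent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SchemaError",
    "ValidationError",
    "TrialRecord",
    "MetaAnalysisData",
    "PooledEstimate",
    "ComparisonResult",
    "AlphaConfig",
    "MIN_TRIALS_FULL",
    "read_trials_table",
    "write_trials_table",
    "validate_dataset",
]

#: A meta-analysis enters the full/rapid comparison only with at least this
#: many deduplicated trials; smaller syntheses are too unstable to grade.
MIN_TRIALS_FULL = 5

_COLUMNS = (
    "ma_id",
    "trial_id",
    "comparison_index",
    "events_trt",
    "n_trt",
    "events_ctl",
    "n_ctl",
    "registered",
    "results_posted",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


def _parse_bool(raw: str, column: str, row_number: int) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValidationError(
        f"row {row_number}: column {column!r} has non-boolean value {raw!r} "
        f"(accepted: 0/1, true/false, yes/no, case-insensitive)"
    )


def _parse_count(raw: str, column: str, row_number: int) -> int:
    try:
        value = int(str(raw).strip())
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row_number}: column {column!r} has non-integer value {raw!r}"
        ) from None
    return value


@dataclass(frozen=True)
class TrialRecord:
    """One randomized comparison: a 2x2 adverse-event table plus registry flags.

    ``comparison_index`` is the 0-based ordinal position of this comparison
    within its trial; multi-arm trials (e.g. two doses against one shared
    placebo arm) contribute several records with the same ``trial_id``.
    """

    ma_id: str
    trial_id: str
    comparison_index: int
    events_trt: int
    n_trt: int
    events_ctl: int
    n_ctl: int
    registered: bool
    results_posted: bool

    def __post_init__(self) -> None:
        if self.n_trt < 1 or self.n_ctl < 1:
            raise ValidationError(
                f"trial {self.trial_id}: arm sizes must be >= 1 "
                f"(got n_trt={self.n_trt}, n_ctl={self.n_ctl})"
            )
        if not 0 <= self.events_trt <= self.n_trt:
            raise ValidationError(
                f"trial {self.trial_id}: events_trt={self.events_trt} outside "
                f"[0, n_trt={self.n_trt}]"
            )
        if not 0 <= self.events_ctl <= self.n_ctl:
            raise ValidationError(
                f"trial {self.trial_id}: events_ctl={self.events_ctl} outside "
                f"[0, n_ctl={self.n_ctl}]"
            )
        if self.comparison_index < 0:
            raise ValidationError(
                f"trial {self.trial_id}: comparison_index must be >= 0"
            )
        if self.results_posted and not self.registered:
            raise ValidationError(
                f"trial {self.trial_id}: results_posted=true requires "
                f"registered=true"
            )

    @property
    def is_double_zero(self) -> bool:
        """True when neither arm observed any event (within-study OR undefined)."""
        return self.events_trt == 0 and self.events_ctl == 0

    @property
    def rapid_eligible(self) -> bool:
        """Registered on the registry with summary results posted."""
        return self.registered and self.results_posted


@dataclass(frozen=True)
class MetaAnalysisData:
    """An ordered collection of trial records pooling one safety outcome.

    List order is preserved from the source table; together with
    ``comparison_index`` it determines which record survives multi-arm
    deduplication.
    """

    ma_id: str
    trials: tuple[TrialRecord, ...]
    outcome_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        for t in self.trials:
            if t.ma_id != self.ma_id:
                raise ValidationError(
                    f"meta-analysis {self.ma_id}: trial {t.trial_id} carries "
                    f"foreign ma_id {t.ma_id!r}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_unique_trials(self) -> int:
        return len({t.trial_id for t in self.trials})

    @property
    def full_eligible(self) -> bool:
        """At least ``MIN_TRIALS_FULL`` distinct trials after deduplication."""
        return self.n_unique_trials >= MIN_TRIALS_FULL

    def with_trials(self, trials: Sequence[TrialRecord]) -> "MetaAnalysisData":
        return replace(self, trials=tuple(trials))


@dataclass(frozen=True)
class AlphaConfig:
    """Significance level and tolerable-bias cutoffs for the comparison."""

    alpha: float = 0.05
    thresholds: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        th = tuple(float(t) for t in self.thresholds)
        if any(not 0 < t < 1 for t in th):
            raise ValidationError(f"thresholds must lie in (0,1), got {th}")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValidationError(f"thresholds must be strictly increasing, got {th}")
        object.__setattr__(self, "thresholds", th)


@dataclass(frozen=True)
class PooledEstimate:
    """One synthesis method's pooled result for one meta-analysis.

    All point-estimate fields live on the log-odds-ratio scale internally;
    ``or_value`` and the confidence bounds are on the OR scale.  When
    ``converged`` is false every estimate field is ``None`` and
    ``failure_reason`` says why (all-zero data, degenerate sums, optimizer
    failure, sparse-data divergence, ...).
    """

    method: str
    k_input: int
    k_used: int
    converged: bool
    log_or: float | None = None
    se_log_or: float | None = None
    or_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    tau2: float | None = None
    q_stat: float | None = None
    i2: float | None = None
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if self.converged:
            if self.log_or is None or self.se_log_or is None:
                raise ValidationError(
                    f"{self.method}: converged estimate must carry log_or and se"
                )
            if self.se_log_or <= 0:
                raise ValidationError(f"{self.method}: se_log_or must be > 0")
        else:
            for name in ("log_or", "se_log_or", "or_value", "ci_low", "ci_high",
                         "p_value"):
                if getattr(self, name) is not None:
                    raise ValidationError(
                        f"{self.method}: non-converged estimate must leave "
                        f"{name} absent"
                    )
        if self.tau2 is not None and self.tau2 < 0:
            raise ValidationError(f"{self.method}: tau2 must be >= 0")
        if self.i2 is not None and not 0 <= self.i2 <= 100:
            raise ValidationError(f"{self.method}: i2 must be in [0,100]")

    def summary(self) -> str:
        """Plain-text summary table in the style of regression results."""
        lines = [
            "Pooled odds-ratio estimate",
            "=" * 46,
            f"method:          {self.method}",
            f"trials (input):  {self.k_input}",
            f"trials (used):   {self.k_used}",
            f"converged:       {self.converged}",
        ]
        if self.converged:
            lines += [
                f"OR:              {self.or_value:.4f}",
                f"95% CI:          ({self.ci_low:.4f}, {self.ci_high:.4f})",
                f"log OR (SE):     {self.log_or:.4f} ({self.se_log_or:.4f})",
                f"p-value:         {self.p_value:.4g}",
            ]
            if self.tau2 is not None:
                lines.append(f"tau^2:           {self.tau2:.4f}")
            if self.q_stat is not None:
                lines.append(f"Cochran Q:       {self.q_stat:.4f}")
            if self.i2 is not None:
                lines.append(f"I^2 (%):         {self.i2:.1f}")
        else:
            lines.append(f"failure:         {self.failure_reason}")
        lines.append("=" * 46)
        return "\n".join(lines)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired full/rapid synthesis outcome for one meta-analysis and method.

    ``status`` is ``ok`` when both fits converged and the rapid subset was
    non-empty; ``rapid_infeasible`` when no trial was registered with posted
    results; ``estimation_failed`` when either fit did not converge.  The
    bias/direction/significance fields are populated only for ``ok`` rows.
    """

    ma_id: str
    method: str
    status: str
    k_full: int
    k_rapid: int
    registration_fraction: float
    event_rate_full: float
    i2_full: float | None = None
    theta_full: float | None = None
    theta_rapid: float | None = None
    bias: float | None = None
    within_05: bool | None = None
    within_10: bool | None = None
    within_15: bool | None = None
    within_20: bool | None = None
    direction_full: str | None = None
    direction_rapid: str | None = None
    direction_change: str | None = None
    p_full: float | None = None
    p_rapid: float | None = None
    significance_change: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("ok", "rapid_infeasible", "estimation_failed"):
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status != "ok":
            for name in ("bias", "direction_change", "significance_change"):
                if getattr(self, name) is not None:
                    raise ValidationError(
                        f"{self.ma_id}/{self.method}: status={self.status} must "
                        f"leave {name} absent"
                    )
        else:
            flags = (self.within_05, self.within_10, self.within_15, self.within_20)
            for tighter, looser in zip(flags, flags[1:]):
                if tighter and not looser:
                    raise ValidationError(
                        f"{self.ma_id}/{self.method}: threshold flags must be "
                        f"monotone (within_05 => ... => within_20)"
                    )


# ---------------------------------------------------------------------------
# CSV I/O


def _group_rows(
    rows: Iterable[tuple[TrialRecord | None, Mapping[str, str]]],
) -> list[MetaAnalysisData]:
    order: list[str] = []
    grouped: dict[str, list[TrialRecord]] = {}
    labels: dict[str, str] = {}
    for record, raw in rows:
        assert record is not None
        if record.ma_id not in grouped:
            grouped[record.ma_id] = []
            order.append(record.ma_id)
        grouped[record.ma_id].append(record)
        label = (raw.get("outcome_label") or "").strip()
        if label and record.ma_id not in labels:
            labels[record.ma_id] = label
    return [
        MetaAnalysisData(ma_id=ma, trials=tuple(grouped[ma]),
                         outcome_label=labels.get(ma, ""))
        for ma in order
    ]


def read_trials_table(path: str | Path, *, delimiter: str = ",") -> list[MetaAnalysisData]:
    """Read a trial table, group rows by ``ma_id`` and validate every record.

    Rows are grouped preserving file order.  Blank ``comparison_index``
    entries are assigned by order of appearance within each trial.  Raises
    :class:`SchemaError` for a missing column and :class:`ValidationError`
    (naming the 1-based data row) for any invariant violation.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s) {', '.join(missing)}"
            )
        rows: list[tuple[TrialRecord, Mapping[str, str]]] = []
        seen_comparisons: dict[tuple[str, str], int] = {}
        for row_number, raw in enumerate(reader, start=1):
            ma_id = (raw["ma_id"] or "").strip()
            trial_id = (raw["trial_id"] or "").strip()
            if not ma_id or not trial_id:
                raise ValidationError(
                    f"row {row_number}: ma_id and trial_id must be non-empty"
                )
            ci_raw = (raw.get("comparison_index") or "").strip()
            if ci_raw:
                comparison_index = _parse_count(ci_raw, "comparison_index", row_number)
            else:
                key = (ma_id, trial_id)
                comparison_index = seen_comparisons.get(key, 0)
            seen_comparisons[(ma_id, trial_id)] = comparison_index + 1
            try:
                record = TrialRecord(
                    ma_id=ma_id,
                    trial_id=trial_id,
                    comparison_index=comparison_index,
                    events_trt=_parse_count(raw["events_trt"], "events_trt", row_number),
                    n_trt=_parse_count(raw["n_trt"], "n_trt", row_number),
                    events_ctl=_parse_count(raw["events_ctl"], "events_ctl", row_number),
                    n_ctl=_parse_count(raw["n_ctl"], "n_ctl", row_number),
                    registered=_parse_bool(raw["registered"], "registered", row_number),
                    results_posted=_parse_bool(
                        raw["results_posted"], "results_posted", row_number
                    ),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row_number}: {exc}") from None
            rows.append((record, raw))
    return _group_rows(rows)


def write_trials_table(data: Sequence[MetaAnalysisData], path: str | Path) -> Path:
    """Write meta-analyses as a flat CSV, one row per trial record.

    Booleans are serialized as literal ``true``/``false``; the column order is
    the fixed schema order plus ``outcome_label``.  Round-trips losslessly
    through :func:`read_trials_table`.
    """
    path = Path(path)
    columns = _COLUMNS + ("outcome_label",)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for ma in data:
            for t in ma.trials:
                writer.writerow(
                    [
                        t.ma_id,
                        t.trial_id,
                        t.comparison_index,
                        t.events_trt,
                        t.n_trt,
                        t.events_ctl,
                        t.n_ctl,
                        "true" if t.registered else "false",
                        "true" if t.results_posted else "false",
                        ma.outcome_label,
                    ]
                )
    return path


def validate_dataset(data: Sequence[MetaAnalysisData]) -> list[dict]:
    """Report-only dataset audit; never mutates its input.

    Returns one dict per meta-analysis with the deduplicated trial count,
    full-analysis eligibility (>= 5 distinct trials), the number of
    double-zero records and the fraction of records registered with results
    posted.
    """
    report = []
    for ma in data:
        n = len(ma.trials)
        report.append(
            {
                "ma_id": ma.ma_id,
                "n_records": n,
                "n_unique_trials": ma.n_unique_trials,
                "full_eligible": ma.full_eligible,
                "n_double_zero": sum(t.is_double_zero for t in ma.trials),
                "registration_fraction": (
                    sum(t.rapid_eligible for t in ma.trials) / n if n else math.nan
                ),
            }
        )
    return report
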