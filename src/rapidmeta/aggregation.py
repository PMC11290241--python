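"""Cross-meta-analysis concordance tables and subgroup breakdowns.

Aggregates per-meta-analysis :class:`~rapidmeta.data_model.ComparisonResult`
rows into the headline questions of the rapid-review emulation: what
fraction of rapid syntheses land within each tolerable-bias cutoff, how
often they agree with the full synthesis on direction and significance, and
how those proportions shift across event-rate quartiles and heterogeneity
strata.  Denominators use only ``status == ok`` rows for a given method;
rapid-infeasible and estimation-failure counts are reported alongside, so
nothing is silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AlphaConfig, ComparisonResult, MetaAnalysisData, ValidationError

__all__ = [
    "ConcordanceTable",
    "SubgroupSpec",
    "AggregateReport",
    "event_rate",
    "threshold_proportions",
    "concordance_table",
    "subgroup_by_event_rate",
    "subgroup_by_i2",
    "build_report",
    "comparisons_to_frame",
    "frame_to_comparisons",
]


@dataclass(frozen=True)
class SubgroupSpec:
    """Stratification rules: event-rate percentile cuts and the I^2 boundary."""

    event_rate_percentiles: tuple[float, ...] = (25.0, 50.0, 75.0)
    i2_cutoff: float = 25.0

    def __post_init__(self) -> None:
        pct = tuple(float(p) for p in self.event_rate_percentiles)
        if any(not 0 < p < 100 for p in pct):
            raise ValidationError("percentiles must lie in (0,100)")
        if any(b <= a for a, b in zip(pct, pct[1:])):
            raise ValidationError("percentiles must be strictly increasing")
        if not 0 < self.i2_cutoff < 100:
            raise ValidationError("i2_cutoff must lie in (0,100)")
        object.__setattr__(self, "event_rate_percentiles", pct)


@dataclass(frozen=True)
class ConcordanceTable:
    """One method's concordance summary over a set of comparison rows.

    Proportions are over evaluable (``status == ok``) rows; the discordance
    breakdowns are shares of the discordant rows only and sum to 1 whenever
    any discordance exists.
    """

    method: str
    n_evaluable: int
    n_rapid_infeasible: int
    n_estimation_failed: int
    prop_within: dict[float, float] = field(default_factory=dict)
    prop_direction_concordant: float | None = None
    discordant_beneficial_to_harmful: float | None = None
    discordant_harmful_to_beneficial: float | None = None
    prop_significance_concordant: float | None = None
    discordant_sig_to_nonsig: float | None = None
    discordant_nonsig_to_sig: float | None = None


def event_rate(ma: MetaAnalysisData) -> float:
    """Crude pooled event rate: total events over total sample, both arms."""
    total_events = sum(t.events_trt + t.events_ctl for t in ma.trials)
    total_n = sum(t.n_trt + t.n_ctl for t in ma.trials)
    if total_n == 0:
        raise ValidationError(f"meta-analysis {ma.ma_id} has zero total sample")
    return total_events / total_n


def threshold_proportions(
    results: Sequence[ComparisonResult], thresholds: Sequence[float]
) -> dict[float, float]:
    """Fraction of evaluable results with bias strictly below each cutoff."""
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        raise ValidationError("threshold proportions undefined on empty input")
    n = len(ok)
    return {
        float(t): sum(r.bias < t for r in ok) / n for t in thresholds
    }


def _breakdown(counts: Mapping[str, int], keys: tuple[str, str]):
    total = sum(counts.get(k, 0) for k in keys)
    if total == 0:
        return None, None
    return counts.get(keys[0], 0) / total, counts.get(keys[1], 0) / total


def concordance_table(
    results: Sequence[ComparisonResult],
    method: str,
    cfg: AlphaConfig | None = None,
) -> ConcordanceTable:
    """Aggregate one method's comparison rows into a concordance table."""
    cfg = cfg or AlphaConfig()
    rows = [r for r in results if r.method == method]
    if len(rows) != len(results):
        raise ValidationError(
            f"concordance_table for {method!r} received rows from other methods"
        )
    ok = [r for r in rows if r.status == "ok"]
    n_infeasible = sum(r.status == "rapid_infeasible" for r in rows)
    n_failed = sum(r.status == "estimation_failed" for r in rows)
    if not ok:
        return ConcordanceTable(
            method=method,
            n_evaluable=0,
            n_rapid_infeasible=n_infeasible,
            n_estimation_failed=n_failed,
        )
    n = len(ok)
    dir_counts: dict[str, int] = {}
    sig_counts: dict[str, int] = {}
    for r in ok:
        dir_counts[r.direction_change] = dir_counts.get(r.direction_change, 0) + 1
        sig_counts[r.significance_change] = sig_counts.get(r.significance_change, 0) + 1
    b2h, h2b = _breakdown(
        dir_counts, ("beneficial_to_harmful", "harmful_to_beneficial")
    )
    s2n, n2s = _breakdown(sig_counts, ("sig_to_nonsig", "nonsig_to_sig"))
    return ConcordanceTable(
        method=method,
        n_evaluable=n,
        n_rapid_infeasible=n_infeasible,
        n_estimation_failed=n_failed,
        prop_within=threshold_proportions(ok, cfg.thresholds),
        prop_direction_concordant=dir_counts.get("concordant", 0) / n,
        discordant_beneficial_to_harmful=b2h,
        discordant_harmful_to_beneficial=h2b,
        prop_significance_concordant=sig_counts.get("concordant", 0) / n,
        discordant_sig_to_nonsig=s2n,
        discordant_nonsig_to_sig=n2s,
    )




def _single_method(results: Sequence[ComparisonResult], method: str | None) -> str:
    seen = sorted({r.method for r in results})
    if len(seen) > 1:
        raise ValidationError("subgroup aggregation expects rows of one method")
    if seen and method is not None and seen[0] != method:
        raise ValidationError(
            f"rows carry method {seen[0]!r}, not the requested {method!r}"
        )
    if seen:
        return seen[0]
    if method is None:
        raise ValidationError("method must be given for empty inputs")
    return method


def subgroup_by_event_rate(
    results: Sequence[ComparisonResult],
    spec: SubgroupSpec | None = None,
    cfg: AlphaConfig | None = None,
    method: str | None = None,
) -> dict[str, ConcordanceTable]:
    """Quartile strata of the full-analysis crude event rate.

    Cutpoints are the empirical percentiles (linear interpolation) of the
    evaluable rows' event rates; strata are ``<=P25``, ``(P25,P50]``,
    ``(P50,P75]`` and ``>P75``.  Empty strata are reported as empty tables.
    """
    spec = spec or SubgroupSpec()
    method = _single_method(results, method)
    ok = [r for r in results if r.status == "ok"]
    rates = np.array([r.event_rate_full for r in ok], dtype=float)
    labels = _stratum_labels(spec.event_rate_percentiles)
    if rates.size == 0:
        return {lab: concordance_table([], method, cfg) for lab in labels}
    cuts = np.percentile(rates, spec.event_rate_percentiles, method="linear")
    strata: dict[str, list[ComparisonResult]] = {lab: [] for lab in labels}
    for r in ok:
        strata[_assign_stratum(r.event_rate_full, cuts, labels)].append(r)
    return {
        lab: concordance_table(rows, method, cfg) for lab, rows in strata.items()
    }


def _stratum_labels(percentiles: Sequence[float]) -> list[str]:
    labels = [f"<=P{int(percentiles[0])}"]
    for lo, hi in zip(percentiles, percentiles[1:]):
        labels.append(f"(P{int(lo)},P{int(hi)}]")
    labels.append(f">P{int(percentiles[-1])}")
    return labels


def _assign_stratum(value: float, cuts: np.ndarray, labels: Sequence[str]) -> str:
    for cut, lab in zip(cuts, labels):
        if value <= cut:
            return lab
    return labels[-1]


def subgroup_by_i2(
    results: Sequence[ComparisonResult],
    spec: SubgroupSpec | None = None,
    cfg: AlphaConfig | None = None,
    method: str | None = None,
) -> dict[str, ConcordanceTable]:
    """Heterogeneity strata: I^2 <= cutoff (low, boundary inclusive) vs > cutoff.

    Rows whose full-analysis I^2 is undefined (fewer than two estimable
    studies) land in an ``unclassified`` bucket rather than being dropped.
    """
    spec = spec or SubgroupSpec()
    method = _single_method(results, method)
    ok = [r for r in results if r.status == "ok"]
    buckets: dict[str, list[ComparisonResult]] = {
        "low": [],
        "high": [],
        "unclassified": [],
    }
    for r in ok:
        if r.i2_full is None:
            buckets["unclassified"].append(r)
        elif r.i2_full <= spec.i2_cutoff:
            buckets["low"].append(r)
        else:
            buckets["high"].append(r)
    return {
        lab: concordance_table(rows, method, cfg) for lab, rows in buckets.items()
    }


# ---------------------------------------------------------------------------
# Report assembly and serialization


@dataclass(frozen=True)
class AggregateReport:
    """Full emulation report: overall and subgroup tables plus bookkeeping."""

    overall: dict[str, ConcordanceTable]
    by_event_rate: dict[str, dict[str, ConcordanceTable]]
    by_i2: dict[str, dict[str, ConcordanceTable]]
    bookkeeping: dict[str, dict[str, int]]
    config: dict

    def to_dict(self) -> dict:
        def table_dict(t: ConcordanceTable) -> dict:
            d = asdict(t)
            d["prop_within"] = {f"{k:g}": v for k, v in sorted(t.prop_within.items())}
            return d

        return {
            "overall": {m: table_dict(t) for m, t in self.overall.items()},
            "by_event_rate": {
                m: {s: table_dict(t) for s, t in strata.items()}
                for m, strata in self.by_event_rate.items()
            },
            "by_i2": {
                m: {s: table_dict(t) for s, t in strata.items()}
                for m, strata in self.by_i2.items()
            },
            "bookkeeping": self.bookkeeping,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write report.json plus one CSV per table family; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = [out_dir / "report.json"]
        paths[0].write_text(self.to_json(), encoding="utf-8")

        def frame(tables: Mapping[str, ConcordanceTable], extra: dict) -> pd.DataFrame:
            rows = []
            for key, t in tables.items():
                row = {**extra, "stratum": key, **asdict(t)}
                within = row.pop("prop_within")
                for th, prop in sorted(within.items()):
                    row[f"prop_within_{int(round(th * 100))}"] = prop
                rows.append(row)
            return pd.DataFrame(rows)

        overall = frame(self.overall, {"family": "overall"})
        overall = overall.rename(columns={"stratum": "method_key"})
        p = out_dir / "concordance_overall.csv"
        overall.to_csv(p, index=False)
        paths.append(p)

        for family, data in (("event_rate", self.by_event_rate), ("i2", self.by_i2)):
            rows = []
            for method, strata in data.items():
                f = frame(strata, {"family": family, "method": method})
                rows.append(f)
            p = out_dir / f"subgroup_{family}.csv"
            pd.concat(rows, ignore_index=True).to_csv(p, index=False)
            paths.append(p)
        return paths


def build_report(results: Sequence[ComparisonResult], cfg) -> AggregateReport:
    """Assemble the aggregate report; a pure, deterministic function.

    ``cfg`` is a method-set-like object exposing ``methods``,
    ``alpha_config`` and optionally ``subgroup_spec``.
    """
    alpha_cfg: AlphaConfig = getattr(cfg, "alpha_config", None) or AlphaConfig()
    spec: SubgroupSpec = getattr(cfg, "subgroup_spec", None) or SubgroupSpec()
    methods = tuple(getattr(cfg, "methods", ()) or sorted({r.method for r in results}))

    overall = {}
    by_event_rate = {}
    by_i2 = {}
    bookkeeping = {}
    for method in methods:
        rows = [r for r in results if r.method == method]
        overall[method] = concordance_table(rows, method, alpha_cfg)
        by_event_rate[method] = subgroup_by_event_rate(rows, spec, alpha_cfg, method=method)
        by_i2[method] = subgroup_by_i2(rows, spec, alpha_cfg, method=method)
        bookkeeping[method] = {
            "total": len(rows),
            "n_evaluable": overall[method].n_evaluable,
            "n_rapid_infeasible": overall[method].n_rapid_infeasible,
            "n_estimation_failed": overall[method].n_estimation_failed,
        }
    config = {
        "alpha": alpha_cfg.alpha,
        "thresholds": list(alpha_cfg.thresholds),
        "event_rate_percentiles": list(spec.event_rate_percentiles),
        "i2_cutoff": spec.i2_cutoff,
        "methods": list(methods),
    }
    return AggregateReport(
        overall=overall,
        by_event_rate=by_event_rate,
        by_i2=by_i2,
        bookkeeping=bookkeeping,
        config=config,
    )


_FRAME_COLUMNS = [
    "ma_id", "method", "status", "k_full", "k_rapid", "registration_fraction",
    "event_rate_full", "i2_full", "theta_full", "theta_rapid", "bias",
    "within_05", "within_10", "within_15", "within_20", "direction_full",
    "direction_rapid", "direction_change", "p_full", "p_rapid",
    "significance_change",
]


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison rows into a DataFrame with a stable column order."""
    rows = [{c: getattr(r, c) for c in _FRAME_COLUMNS} for r in results]
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_comparisons(frame: pd.DataFrame) -> list[ComparisonResult]:
    """Inverse of :func:`comparisons_to_frame` (NaN becomes absent)."""
    missing = [c for c in _FRAME_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"comparison table missing column(s) {missing}")
    out = []
    bool_cols = {"within_05", "within_10", "within_15", "within_20"}
    for _, row in frame.iterrows():
        kwargs = {}
        for c in _FRAME_COLUMNS:
            v = row[c]
            if v is None or (isinstance(v, float) and np.isnan(v)) or (
                isinstance(v, str) and v == ""
            ):
                kwargs[c] = None
            elif c in bool_cols:
                kwargs[c] = str(v).strip().lower() in ("true", "1")
            else:
                kwargs[c] = v
        kwargs["k_full"] = int(kwargs["k_full"])
        kwargs["k_rapid"] = int(kwargs["k_rapid"])
        out.append(ComparisonResult(**kwargs))
    return out
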