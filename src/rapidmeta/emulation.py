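"""Rapid-review emulation: paired full/rapid syntheses and their comparison.

The procedure mirrors how a registry-only rapid meta-analysis would be run
against the full systematic-review synthesis of the same outcome:

1. deduplicate multi-arm trials, keeping only each trial's first comparison
   (multi-dose trials reuse the control arm, which double-counts it);
2. form the rapid subset — trials registered on the registry *and* with
   summary results posted;
3. run the same synthesis method on both sets;
4. compare the pooled ORs: relative bias against 5/10/15/20% tolerable-bias
   cutoffs, direction of effect (OR below/above 1), and statistical
   significance at alpha.

Meta-analyses where no trial is rapid-eligible are flagged
``rapid_infeasible``; method-level estimation failures (zero-event
degeneracies for the two-stage methods, sparse-data non-convergence for the
GLMM) are flagged ``estimation_failed`` and excluded from downstream
denominators, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from . import aggregation
from .data_model import (
    AlphaConfig,
    ComparisonResult,
    MetaAnalysisData,
    PooledEstimate,
    ValidationError,
)
from .synthesis import (
    METHODS,
    GlmmSpec,
    MetaAnalysis,
    study_log_or,
    cochran_q_i2,
)

__all__ = [
    "MethodSet",
    "dedup_first_comparison",
    "subset_rapid",
    "tolerable_bias",
    "classify_direction",
    "classify_direction_change",
    "classify_significance_change",
    "compare_pair",
    "RapidEmulation",
    "EmulationResults",
]


@dataclass(frozen=True)
class MethodSet:
    """Which synthesis methods to run, and the comparison configuration."""

    methods: tuple[str, ...] = METHODS
    alpha_config: AlphaConfig = field(default_factory=AlphaConfig)
    glmm_spec: GlmmSpec = field(default_factory=GlmmSpec)
    continuity_correction: float | None = 0.5
    bias_scale: str = "or"  # "or" (default) or "log"

    def __post_init__(self) -> None:
        methods = tuple(self.methods)
        if not methods:
            raise ValidationError("MethodSet needs at least one method")
        unknown = [m for m in methods if m not in METHODS]
        if unknown:
            raise ValidationError(f"unknown method(s) {unknown}; expected {METHODS}")
        object.__setattr__(self, "methods", methods)
        if self.bias_scale not in ("or", "log"):
            raise ValidationError("bias_scale must be 'or' or 'log'")


def dedup_first_comparison(ma: MetaAnalysisData) -> MetaAnalysisData:
    """Keep only each trial's first comparison (smallest ``comparison_index``).

    Multi-arm trials entered as several dose-vs-placebo comparisons share
    the control arm, so pooling them all double-counts control subjects and
    yields overconfident estimates.  Ties on ``comparison_index`` are broken
    by input order; output order preserves input order.  Idempotent.
    """
    best: dict[str, tuple[int, int]] = {}  # trial_id -> (comparison_index, position)
    for pos, t in enumerate(ma.trials):
        if t.trial_id not in best or t.comparison_index < best[t.trial_id][0]:
            best[t.trial_id] = (t.comparison_index, pos)
    keep = {pos for _, pos in best.values()}
    return ma.with_trials([t for pos, t in enumerate(ma.trials) if pos in keep])


def subset_rapid(ma: MetaAnalysisData) -> MetaAnalysisData:
    """Trials registered on the registry with summary results posted.

    Trials registered elsewhere or without posted results are excluded; an
    empty result is a value (the meta-analysis is then rapid-infeasible),
    not an error.  Order-preserving and idempotent.
    """
    return ma.with_trials([t for t in ma.trials if t.rapid_eligible])


def tolerable_bias(
    theta_full: float, theta_rapid: float, scale: str = "or"
) -> float:
    """Relative difference |theta - theta_r| / theta between pooled estimates.

    Computed on the OR scale by default: with a full-analysis pooled OR of
    0.58 and a rapid one of 0.62 the bias is |0.58-0.62|/0.58 = 6.9%.  The
    ``log`` scale variant uses |log ratio| of the two ORs instead.
    """
    if theta_full <= 0 or theta_rapid <= 0:
        raise ValidationError("pooled ORs must be positive")
    if scale == "or":
        return abs(theta_full - theta_rapid) / theta_full
    if scale == "log":
        return abs(math.log(theta_rapid) - math.log(theta_full))
    raise ValidationError("scale must be 'or' or 'log'")


def classify_direction(or_value: float) -> str:
    """beneficial (OR < 1: fewer adverse events under treatment), harmful, null."""
    if or_value <= 0:
        raise ValidationError("odds ratio must be positive")
    if or_value < 1.0:
        return "beneficial"
    if or_value > 1.0:
        return "harmful"
    return "null"


def classify_direction_change(full: str, rapid: str) -> str:
    """Direction concordance category for a (full, rapid) pair.

    The two named discordance categories follow the rapid-analysis
    perspective: ``beneficial_to_harmful`` means the rapid analysis showed a
    beneficial effect where the full analysis showed harm.  A pooled OR of
    exactly 1 falls in ``involves_null``.
    """
    if "null" in (full, rapid):
        return "involves_null"
    if full == rapid:
        return "concordant"
    if rapid == "beneficial" and full == "harmful":
        return "beneficial_to_harmful"
    return "harmful_to_beneficial"


def classify_significance_change(p_full: float, p_rapid: float, alpha: float) -> str:
    """Significance concordance at level alpha (significant iff p < alpha)."""
    sig_full = p_full < alpha
    sig_rapid = p_rapid < alpha
    if sig_full == sig_rapid:
        return "concordant"
    return "sig_to_nonsig" if sig_full else "nonsig_to_sig"


def _full_i2(ma: MetaAnalysisData, cc: float | None) -> float | None:
    """Two-stage I^2 of the full meta-analysis, for subgroup stratification."""
    from .synthesis import TwoByTwo

    pairs = []
    for t in ma.trials:
        table = TwoByTwo(t.events_trt, t.n_trt - t.events_trt,
                         t.events_ctl, t.n_ctl - t.events_ctl)
        p = study_log_or(table, cc=cc)
        if p is not None:
            pairs.append(p)
    if len(pairs) < 2:
        return None
    _, i2 = cochran_q_i2([p[0] for p in pairs], [p[1] for p in pairs])
    return i2


def compare_pair(ma: MetaAnalysisData, cfg: MethodSet | None = None) -> list[ComparisonResult]:
    """Run the full/rapid comparison for one meta-analysis, one row per method.

    Requires full-analysis eligibility (>= 5 distinct trials).  Deduplicates
    first, then fits each method on the full set and the rapid subset.
    """
    cfg = cfg or MethodSet()
    full = dedup_first_comparison(ma)
    if not full.full_eligible:
        raise ValidationError(
            f"meta-analysis {ma.ma_id} has {full.n_unique_trials} trials after "
            f"deduplication; the full/rapid comparison requires at least 5"
        )
    rapid = subset_rapid(full)
    k_full, k_rapid = len(full), len(rapid)
    registration_fraction = k_rapid / k_full
    event_rate_full = aggregation.event_rate(full)
    i2_full = _full_i2(full, cfg.continuity_correction)
    alpha_cfg = cfg.alpha_config

    results = []
    for method in cfg.methods:
        common = dict(
            ma_id=ma.ma_id,
            method=method,
            k_full=k_full,
            k_rapid=k_rapid,
            registration_fraction=registration_fraction,
            event_rate_full=event_rate_full,
            i2_full=i2_full,
        )
        if k_rapid == 0:
            results.append(ComparisonResult(status="rapid_infeasible", **common))
            continue
        fit_full = MetaAnalysis.from_data(full).fit(
            method, cc=cfg.continuity_correction, glmm_spec=cfg.glmm_spec
        )
        fit_rapid = MetaAnalysis.from_data(rapid).fit(
            method, cc=cfg.continuity_correction, glmm_spec=cfg.glmm_spec
        )
        if not (fit_full.converged and fit_rapid.converged):
            results.append(ComparisonResult(status="estimation_failed", **common))
            continue
        bias = tolerable_bias(fit_full.or_value, fit_rapid.or_value,
                              scale=cfg.bias_scale)
        direction_full = classify_direction(fit_full.or_value)
        direction_rapid = classify_direction(fit_rapid.or_value)
        th = alpha_cfg.thresholds
        results.append(
            ComparisonResult(
                status="ok",
                theta_full=fit_full.or_value,
                theta_rapid=fit_rapid.or_value,
                bias=bias,
                within_05=bias < th[0],
                within_10=bias < th[1],
                within_15=bias < th[2],
                within_20=bias < th[3],
                direction_full=direction_full,
                direction_rapid=direction_rapid,
                direction_change=classify_direction_change(
                    direction_full, direction_rapid
                ),
                p_full=fit_full.p_value,
                p_rapid=fit_rapid.p_value,
                significance_change=classify_significance_change(
                    fit_full.p_value, fit_rapid.p_value, alpha_cfg.alpha
                ),
                **common,
            )
        )
    return results


class EmulationResults:
    """Results container for a collection-level rapid-review emulation.

    Carries the per-meta-analysis comparison rows, bookkeeping about
    ineligible meta-analyses, and lazily builds the aggregate concordance
    report.
    """

    def __init__(
        self,
        comparisons: Sequence[ComparisonResult],
        cfg: MethodSet,
        n_ineligible: int = 0,
    ):
        self.comparisons = tuple(comparisons)
        self.cfg = cfg
        self.n_ineligible = n_ineligible
        self._report = None

    @property
    def report(self) -> "aggregation.AggregateReport":
        if self._report is None:
            self._report = aggregation.build_report(self.comparisons, self.cfg)
        return self._report

    def to_frame(self):
        return aggregation.comparisons_to_frame(self.comparisons)

    def summary(self) -> str:
        lines = [
            "Rapid-review emulation",
            "=" * 64,
            f"eligible meta-analyses:   "
            f"{len({c.ma_id for c in self.comparisons})}",
            f"ineligible (k < 5):       {self.n_ineligible}",
            "",
        ]
        for method in self.cfg.methods:
            table = self.report.overall[method]
            lines.append(f"[{method}]  evaluable={table.n_evaluable}  "
                         f"infeasible={table.n_rapid_infeasible}  "
                         f"failed={table.n_estimation_failed}")
            if table.n_evaluable:
                within = "  ".join(
                    f"<{int(round(t * 100))}%: {p:.1%}"
                    for t, p in sorted(table.prop_within.items())
                )
                lines.append(f"  bias {within}")
                lines.append(
                    f"  direction concordant: {table.prop_direction_concordant:.1%}"
                    f"   significance concordant: "
                    f"{table.prop_significance_concordant:.1%}"
                )
        lines.append("=" * 64)
        return "\n".join(lines)


class RapidEmulation:
    """Model object: a dataset of meta-analyses plus an emulation protocol.

    ``fit`` runs the paired full/rapid comparison over every
    full-analysis-eligible meta-analysis and returns
    :class:`EmulationResults`.
    """

    def __init__(self, datasets: Sequence[MetaAnalysisData], cfg: MethodSet | None = None):
        self.datasets = tuple(datasets)
        self.cfg = cfg or MethodSet()

    @classmethod
    def from_csv(cls, path, cfg: MethodSet | None = None) -> "RapidEmulation":
        from .data_model import read_trials_table

        return cls(read_trials_table(path), cfg=cfg)

    def fit(self) -> EmulationResults:
        comparisons: list[ComparisonResult] = []
        n_ineligible = 0
        for ma in self.datasets:
            if not dedup_first_comparison(ma).full_eligible:
                n_ineligible += 1
                continue
            comparisons.extend(compare_pair(ma, self.cfg))
        return EmulationResults(comparisons, self.cfg, n_ineligible=n_ineligible)
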