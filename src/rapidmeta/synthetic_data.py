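"""Seeded generator of meta-analysis collections with registry indicators.

Real safety meta-analyses of this kind pool roughly nine trials each
(quartiles about 6 to 14), total about 4,400 subjects per meta-analysis,
with low adverse-event rates (many zero-event arms), occasional multi-arm
trials that reuse the control arm, and 60-90% of trials registered on the
registry with results posted.  The generator reproduces that structure from
parametric laws so every pipeline stage is testable without any real
dataset:

* trials per meta-analysis: k = 5 + NegBinom(dispersion, mean), calibrated
  so k has quartiles (6, 9, 14);
* arm sizes: log-normal per trial;
* baseline (control) risk: Beta per meta-analysis, mean ~3%;
* true log OR: Normal(mu_theta, sigma_theta^2) per meta-analysis, with a
  trial-level Normal(theta, tau^2) spread creating heterogeneity;
* registration: Bernoulli per trial, optionally size-selective
  (``selection_beta_size`` links registration log-odds to standardized log
  trial size; 0 means missing-at-random); results posting is Bernoulli
  conditional on registration;
* a fraction of trials gains a second comparison sharing the control arm
  verbatim — the double-counting pathology multi-arm deduplication fixes.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from .data_model import MetaAnalysisData, TrialRecord, ValidationError

__all__ = ["SimulationConfig", "generate_dataset", "generate_fixture", "FIXTURES"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic meta-analysis collection.

    Defaults target the structure described above: median 9 trials per
    meta-analysis (IQR 6-14), median arm sizes giving ~4,400 subjects per
    meta-analysis, mean baseline risk 3%, registration probability 0.83 and
    posting probability 0.77 given registration (joint ~0.64).
    """

    n_meta_analyses: int = 100
    k_dispersion: float = 0.8          # NegBinom r; k = 5 + NB(r, mean)
    k_mean: float = 6.5                # NegBinom mean, calibrated for IQR 6-14
    arm_size_meanlog: float = math.log(230.0)
    arm_size_sdlog: float = 0.6
    arm_size_min: int = 10
    baseline_risk_shape1: float = 1.5  # Beta prior on control risk, mean 0.03
    baseline_risk_shape2: float = 48.5
    mu_theta: float = 0.0              # mean true log OR across meta-analyses
    sigma_theta: float = 0.4           # SD of true log OR across meta-analyses
    tau: float = 0.2                   # between-trial SD of log OR within a MA
    p_register: float = 0.83
    p_post_given_register: float = 0.77
    selection_beta_size: float = 0.0   # 0 = registration missing-at-random
    multi_arm_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_meta_analyses < 1:
            raise ValidationError("n_meta_analyses must be >= 1")
        for name in ("p_register", "p_post_given_register", "multi_arm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.tau < 0 or self.sigma_theta < 0:
            raise ValidationError("tau and sigma_theta must be >= 0")
        if self.k_dispersion <= 0 or self.k_mean <= 0:
            raise ValidationError("k law parameters must be positive")
        if self.baseline_risk_shape1 <= 0 or self.baseline_risk_shape2 <= 0:
            raise ValidationError("baseline risk Beta shapes must be positive")
        if self.arm_size_sdlog <= 0 or self.arm_size_min < 1:
            raise ValidationError("arm size law parameters invalid")


def _draw_k(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    # shifted negative binomial keeps every meta-analysis full-eligible (k >= 5)
    r = cfg.k_dispersion
    p = r / (r + cfg.k_mean)
    return 5 + int(rng.negative_binomial(r, p))


def _draw_arm(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    n = int(round(rng.lognormal(cfg.arm_size_meanlog, cfg.arm_size_sdlog)))
    return max(n, cfg.arm_size_min)


def generate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> list[MetaAnalysisData]:
    """Draw a collection of meta-analyses from the configured laws.

    ``seed`` overrides ``config.seed`` when given.  The draw order is fixed,
    so identical configs give record-for-record identical datasets.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    datasets = []
    for m in range(cfg.n_meta_analyses):
        ma_id = f"MA{m + 1:04d}"
        k = _draw_k(rng, cfg)
        theta = rng.normal(cfg.mu_theta, cfg.sigma_theta)
        p0 = float(rng.beta(cfg.baseline_risk_shape1, cfg.baseline_risk_shape2))
        p0 = min(max(p0, 1e-5), 0.5)
        logit_p0 = special.logit(p0)
        records = []
        for j in range(k):
            trial_id = f"{ma_id}-T{j + 1:03d}"
            delta = rng.normal(theta, cfg.tau)
            n_ctl = _draw_arm(rng, cfg)
            n_trt = _draw_arm(rng, cfg)
            events_ctl = int(rng.binomial(n_ctl, p0))
            p1 = float(special.expit(logit_p0 + delta))
            events_trt = int(rng.binomial(n_trt, p1))
            # standardized log total size drives optional selective registration
            z_size = (math.log(n_ctl + n_trt) - (cfg.arm_size_meanlog + math.log(2.0))) / cfg.arm_size_sdlog
            logit_reg = special.logit(min(max(cfg.p_register, 1e-12), 1 - 1e-12))
            p_reg = float(special.expit(logit_reg + cfg.selection_beta_size * z_size))
            registered = bool(rng.random() < p_reg)
            posted = bool(registered and rng.random() < cfg.p_post_given_register)
            records.append(
                TrialRecord(
                    ma_id=ma_id,
                    trial_id=trial_id,
                    comparison_index=0,
                    events_trt=events_trt,
                    n_trt=n_trt,
                    events_ctl=events_ctl,
                    n_ctl=n_ctl,
                    registered=registered,
                    results_posted=posted,
                )
            )
            # second dose arm sharing the control counts verbatim
            if rng.random() < cfg.multi_arm_fraction:
                delta2 = rng.normal(theta, cfg.tau)
                n_trt2 = _draw_arm(rng, cfg)
                p2 = float(special.expit(logit_p0 + delta2))
                events_trt2 = int(rng.binomial(n_trt2, p2))
                records.append(
                    TrialRecord(
                        ma_id=ma_id,
                        trial_id=trial_id,
                        comparison_index=1,
                        events_trt=events_trt2,
                        n_trt=n_trt2,
                        events_ctl=events_ctl,
                        n_ctl=n_ctl,
                        registered=registered,
                        results_posted=posted,
                    )
                )
        datasets.append(
            MetaAnalysisData(ma_id=ma_id, trials=tuple(records),
                             outcome_label=f"synthetic adverse event {m + 1}")
        )
    return datasets


# ---------------------------------------------------------------------------
# Deterministic hand-authored fixtures


def _ma(ma_id: str, rows: list[tuple], label: str = "") -> MetaAnalysisData:
    trials = [
        TrialRecord(
            ma_id=ma_id,
            trial_id=t[0],
            comparison_index=t[1],
            events_trt=t[2],
            n_trt=t[3],
            events_ctl=t[4],
            n_ctl=t[5],
            registered=t[6],
            results_posted=t[7],
        )
        for t in rows
    ]
    return MetaAnalysisData(ma_id=ma_id, trials=tuple(trials), outcome_label=label)


def _fixture_all_registered() -> MetaAnalysisData:
    rows = [
        (f"T{i}", 0, e_t, n_t, e_c, n_c, True, True)
        for i, (e_t, n_t, e_c, n_c) in enumerate(
            [(4, 100, 2, 100), (10, 200, 5, 200), (1, 50, 3, 50),
             (6, 150, 4, 150), (2, 80, 1, 80), (5, 120, 6, 120)]
        )
    ]
    return _ma("FIX-ALLREG", rows, "perfect registration identity")


def _fixture_none_registered() -> MetaAnalysisData:
    rows = [
        (f"T{i}", 0, e_t, n_t, e_c, n_c, False, False)
        for i, (e_t, n_t, e_c, n_c) in enumerate(
            [(4, 100, 2, 100), (10, 200, 5, 200), (1, 50, 3, 50),
             (6, 150, 4, 150), (2, 80, 1, 80)]
        )
    ]
    return _ma("FIX-NOREG", rows, "no registered trials: rapid infeasible")


def _fixture_sparse_glmm() -> MetaAnalysisData:
    # complete separation: every event sits in the treatment arm, so the
    # GLMM log OR diverges past the sparse-data guard
    rows = [
        (f"T{i}", 0, 2, 40, 0, 40, True, True) for i in range(5)
    ]
    return _ma("FIX-SPARSE", rows, "separation drives GLMM divergence")


def _fixture_multi_arm() -> MetaAnalysisData:
    rows = [
        ("T0", 0, 3, 90, 2, 100, True, True),
        ("T0", 1, 5, 95, 2, 100, True, True),   # second dose, shared control
        ("T1", 0, 4, 120, 3, 120, True, True),
        ("T2", 0, 1, 60, 2, 60, True, False),
        ("T2", 1, 2, 55, 2, 60, True, False),   # second dose, shared control
        ("T3", 0, 6, 200, 4, 200, False, False),
        ("T4", 0, 2, 75, 1, 75, True, True),
        ("T5", 0, 3, 110, 5, 110, True, True),
    ]
    return _ma("FIX-MULTI", rows, "multi-arm duplicates sharing control arms")


def _fixture_peto_symmetric() -> MetaAnalysisData:
    # a = c and equal arms in every trial: O - E = 0 per study, pooled OR 1
    rows = [
        (f"T{i}", 0, a, n, a, n, True, True)
        for i, (a, n) in enumerate([(3, 100), (5, 150), (2, 80), (4, 120), (1, 60)])
    ]
    return _ma("FIX-PETOSYM", rows, "symmetric tables: pooled Peto OR = 1")


FIXTURES = {
    "all_registered": _fixture_all_registered,
    "none_registered": _fixture_none_registered,
    "sparse_glmm": _fixture_sparse_glmm,
    "multi_arm": _fixture_multi_arm,
    "peto_symmetric": _fixture_peto_symmetric,
}


def generate_fixture(name: str) -> MetaAnalysisData:
    """Return a deterministic hand-authored fixture by tag."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
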