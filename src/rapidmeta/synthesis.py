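"""Rare-event binary-outcome meta-analysis engines.

Four pooled odds-ratio estimators chosen for their behaviour with sparse
adverse-event data:

``mh_fixed``
    Mantel-Haenszel fixed-effect OR on uncorrected counts with the
    Robins-Breslow-Greenland (RBG) variance of the log OR.  Single-zero
    studies contribute natively; double-zero studies carry no information
    about the OR and are excluded.
``iv_random_dl``
    Two-stage inverse-variance random-effects pooling of study log ORs with
    the DerSimonian-Laird moment estimator of the between-study variance
    tau^2.  Studies with any zero cell receive a 0.5 continuity correction
    on all four cells; double-zero studies are excluded.
``peto``
    Peto's one-step OR, ln OR = sum(O-E)/sum(V) with hypergeometric
    expectation and variance.  No continuity correction.
``glmm_random_slope``
    One-stage binomial GLMM on arm-level counts: fixed study intercepts, a
    fixed treatment effect beta and a normal random treatment slope with
    variance tau^2, fitted by maximum likelihood with adaptive Gauss-Hermite
    quadrature.  All trials are retained, including double-zero ones.

The :class:`MetaAnalysis` model class is a thin facade: build it from trial
records or a DataFrame, call :meth:`MetaAnalysis.fit` with a method tag, get
a :class:`~rapidmeta.data_model.PooledEstimate` back.  Estimation failures
(all-zero data, separation, non-convergence) are returned as non-converged
estimates with a ``failure_reason``, never raised — real safety datasets hit
these pathologies routinely and the downstream bookkeeping counts them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from .data_model import MetaAnalysisData, PooledEstimate, ValidationError

__all__ = [
    "TwoByTwo",
    "GlmmSpec",
    "METHODS",
    "study_log_or",
    "pool_mh_fixed",
    "pool_iv_random_dl",
    "pool_peto",
    "fit_glmm_random_slope",
    "cochran_q_i2",
    "wald_summary",
    "MetaAnalysis",
]

#: Recognized synthesis method tags, in canonical reporting order.
METHODS = ("mh_fixed", "iv_random_dl", "peto", "glmm_random_slope")

_Z975 = 1.959963984540054  # 97.5% normal quantile for Wald 95% intervals


@dataclass(frozen=True)
class TwoByTwo:
    """One study's 2x2 table: a/b treatment events/non-events, c/d control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be non-negative")
        if self.N < 2:
            raise ValidationError("2x2 table needs at least one subject per arm")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_trt(self) -> int:
        return self.a + self.b

    @property
    def n_ctl(self) -> int:
        return self.c + self.d

    @property
    def is_double_zero(self) -> bool:
        return self.a == 0 and self.c == 0

    @property
    def is_double_full(self) -> bool:
        return self.b == 0 and self.d == 0

    def swapped(self) -> "TwoByTwo":
        """Treatment and control arms exchanged."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class GlmmSpec:
    """Tuning knobs for the one-stage GLMM fit.

    ``quadrature_points`` is the number of Gauss-Hermite nodes per study
    (odd, so the posterior mode itself is a node); ``tau_floor`` bounds the
    between-study SD away from zero in the optimizer, and ``beta_guard``
    flags fits whose |log OR| exceeds it as sparse-data divergence.
    """

    max_iterations: int = 500
    convergence_tol: float = 1e-8
    quadrature_points: int = 15
    tau_floor: float = 1e-8
    tau_ceiling: float = 5.0
    beta_guard: float = 10.0

    def __post_init__(self) -> None:
        if self.quadrature_points < 7 or self.quadrature_points % 2 == 0:
            raise ValidationError("quadrature_points must be odd and >= 7")
        if self.max_iterations <= 0 or self.convergence_tol <= 0:
            raise ValidationError("iterations and tolerance must be positive")
        if self.tau_floor < 0:
            raise ValidationError("tau_floor must be >= 0")


def _as_tables(trials: Sequence[TwoByTwo | object]) -> list[TwoByTwo]:
    out = []
    for t in trials:
        if isinstance(t, TwoByTwo):
            out.append(t)
        else:  # TrialRecord-like
            out.append(
                TwoByTwo(
                    a=t.events_trt,
                    b=t.n_trt - t.events_trt,
                    c=t.events_ctl,
                    d=t.n_ctl - t.events_ctl,
                )
            )
    return out


def study_log_or(
    t: TwoByTwo, cc: float | None = 0.5
) -> tuple[float, float] | None:
    """Study-level log OR and its large-sample variance.

    A continuity correction ``cc`` is added to all four cells when any cell
    is zero (``cc=None`` disables it).  Double-zero and double-full tables
    have no defined OR and return ``None`` — a value, not an error.
    """
    if t.is_double_zero or t.is_double_full:
        return None
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if cc is None:
            return None
        a, b, c, d = a + cc, b + cc, c + cc, d + cc
    log_or = math.log(a * d / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return log_or, var


def wald_summary(log_or: float, se: float) -> tuple[float, float, float, float]:
    """OR, 95% Wald CI bounds and two-sided normal p from a log-OR estimate."""
    if not (math.isfinite(log_or) and math.isfinite(se)):
        raise ValidationError("wald_summary needs finite inputs")
    if se <= 0:
        raise ValidationError("standard error must be positive")
    or_value = math.exp(log_or)
    ci_low = math.exp(log_or - _Z975 * se)
    ci_high = math.exp(log_or + _Z975 * se)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return or_value, ci_low, ci_high, float(p)


def cochran_q_i2(
    log_ors: Sequence[float], variances: Sequence[float]
) -> tuple[float, float] | None:
    """Cochran's Q and I^2 (%) from study log ORs under fixed-effect weights.

    I^2 = max(0, (Q - (k-1)) / Q) * 100.  Returns ``None`` for k < 2, where
    heterogeneity is undefined.
    """
    if len(log_ors) != len(variances):
        raise ValidationError("log_ors and variances must have equal length")
    k = len(log_ors)
    if k < 2:
        return None
    y = np.asarray(log_ors, dtype=float)
    w = 1.0 / np.asarray(variances, dtype=float)
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, i2


def _failed(method: str, k_input: int, k_used: int, reason: str) -> PooledEstimate:
    return PooledEstimate(
        method=method,
        k_input=k_input,
        k_used=k_used,
        converged=False,
        failure_reason=reason,
    )


def _two_stage_het(tables: Sequence[TwoByTwo], cc: float | None = 0.5):
    """(Q, I2) from two-stage log ORs, or None when fewer than 2 are defined."""
    pairs = [study_log_or(t, cc=cc) for t in tables]
    pairs = [p for p in pairs if p is not None]
    if len(pairs) < 2:
        return None
    ys, vs = zip(*pairs)
    return cochran_q_i2(ys, vs)


def pool_mh_fixed(trials: Sequence[TwoByTwo]) -> PooledEstimate:
    """Mantel-Haenszel fixed-effect pooled OR with the RBG log-OR variance.

    OR_MH = sum(a_i d_i / N_i) / sum(b_i c_i / N_i) on uncorrected counts;
    the Robins-Breslow-Greenland variance uses the standard P/Q/R/S sums.
    Double-zero and double-full tables are excluded (reflected in ``k_used``).
    """
    tables = _as_tables(trials)
    k_input = len(tables)
    usable = [t for t in tables if not (t.is_double_zero or t.is_double_full)]
    k_used = len(usable)
    if k_used == 0:
        return _failed("mh_fixed", k_input, 0, "all-zero")

    a = np.array([t.a for t in usable], dtype=float)
    b = np.array([t.b for t in usable], dtype=float)
    c = np.array([t.c for t in usable], dtype=float)
    d = np.array([t.d for t in usable], dtype=float)
    n = a + b + c + d
    R_i = a * d / n
    S_i = b * c / n
    R, S = float(R_i.sum()), float(S_i.sum())
    if R <= 0 or S <= 0:
        # no events in one arm anywhere: the MH OR is 0 or infinite
        return _failed("mh_fixed", k_input, k_used, "degenerate-mh-sum")

    log_or = math.log(R / S)
    P_i = (a + d) / n
    Q_i = (b + c) / n
    var = (
        float(np.sum(P_i * R_i)) / (2 * R * R)
        + float(np.sum(P_i * S_i + Q_i * R_i)) / (2 * R * S)
        + float(np.sum(Q_i * S_i)) / (2 * S * S)
    )
    se = math.sqrt(var)
    or_value, ci_low, ci_high, p = wald_summary(log_or, se)
    het = _two_stage_het(usable)
    return PooledEstimate(
        method="mh_fixed",
        k_input=k_input,
        k_used=k_used,
        converged=True,
        log_or=log_or,
        se_log_or=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        q_stat=None if het is None else het[0],
        i2=None if het is None else het[1],
    )


def pool_iv_random_dl(
    trials: Sequence[TwoByTwo], cc: float | None = 0.5
) -> PooledEstimate:
    """Inverse-variance random-effects pooled OR with DerSimonian-Laird tau^2.

    Study log ORs get a 0.5 correction on all cells of any study with a zero
    cell; tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) from the
    fixed-effect Q, then random weights 1/(v_i + tau^2).  With a single
    usable study the result degenerates to that study's estimate (tau^2 = 0).
    """
    tables = _as_tables(trials)
    k_input = len(tables)
    pairs = [study_log_or(t, cc=cc) for t in tables]
    pairs = [p for p in pairs if p is not None]
    k_used = len(pairs)
    if k_used == 0:
        return _failed("iv_random_dl", k_input, 0, "all-zero")

    y = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    w = 1.0 / v
    sw = float(w.sum())
    ybar = float(np.sum(w * y) / sw)
    q = float(np.sum(w * (y - ybar) ** 2))
    if k_used == 1:
        tau2, i2 = 0.0, None
        q_out = None
    else:
        denom = sw - float(np.sum(w**2)) / sw
        tau2 = max(0.0, (q - (k_used - 1)) / denom) if denom > 0 else 0.0
        i2 = 0.0 if q <= 0 else max(0.0, (q - (k_used - 1)) / q) * 100.0
        q_out = q
    w_star = 1.0 / (v + tau2)
    log_or = float(np.sum(w_star * y) / w_star.sum())
    se = math.sqrt(1.0 / float(w_star.sum()))
    or_value, ci_low, ci_high, p = wald_summary(log_or, se)
    return PooledEstimate(
        method="iv_random_dl",
        k_input=k_input,
        k_used=k_used,
        converged=True,
        log_or=log_or,
        se_log_or=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        tau2=tau2,
        q_stat=q_out,
        i2=i2,
    )


def pool_peto(trials: Sequence[TwoByTwo]) -> PooledEstimate:
    """Peto's one-step pooled OR: ln OR = sum(O-E)/sum(V), SE = 1/sqrt(sum V).

    O_i = a_i, E_i and V_i are the hypergeometric mean and variance of the
    treatment-arm event count under the null.  No continuity correction;
    tables with V_i = 0 (double-zero or double-full) are excluded.
    """
    tables = _as_tables(trials)
    k_input = len(tables)
    usable = [t for t in tables if not (t.is_double_zero or t.is_double_full)]
    k_used = len(usable)
    if k_used == 0:
        return _failed("peto", k_input, 0, "all-zero")

    a = np.array([t.a for t in usable], dtype=float)
    b = np.array([t.b for t in usable], dtype=float)
    c = np.array([t.c for t in usable], dtype=float)
    d = np.array([t.d for t in usable], dtype=float)
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1.0))
    sv = float(v.sum())
    if sv <= 0:
        return _failed("peto", k_input, k_used, "zero-variance")
    log_or = float(np.sum(a - e)) / sv
    se = 1.0 / math.sqrt(sv)
    or_value, ci_low, ci_high, p = wald_summary(log_or, se)
    het = _two_stage_het(usable)
    return PooledEstimate(
        method="peto",
        k_input=k_input,
        k_used=k_used,
        converged=True,
        log_or=log_or,
        se_log_or=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        q_stat=None if het is None else het[0],
        i2=None if het is None else het[1],
    )


# ---------------------------------------------------------------------------
# One-stage random-slope binomial GLMM


def _glmm_nll(params: np.ndarray, data: dict, nodes: np.ndarray,
              weights: np.ndarray) -> float:
    """Negative marginal log-likelihood, adaptive Gauss-Hermite per study.

    params = (alpha_1..alpha_k, beta, log tau).  The control-arm binomial
    factors out of the integral; the treatment-arm likelihood is integrated
    over the random slope b ~ N(0, tau^2) after recentering the quadrature
    at the per-study posterior mode (safeguarded Newton, concave problem).
    """
    k = data["k"]
    alpha = params[:k]
    beta = params[k]
    tau = math.exp(params[k + 1])
    y0, n0, y1, n1 = data["y0"], data["n0"], data["y1"], data["n1"]

    # control arms: closed form
    ll = float(np.sum(y0 * alpha - n0 * np.logaddexp(0.0, alpha)))

    # posterior mode of b per study (Newton on a strictly concave function)
    eta0 = alpha + beta
    bhat = np.zeros(k)
    inv_tau2 = 1.0 / (tau * tau)
    for _ in range(50):
        mu = special.expit(eta0 + bhat)
        grad = y1 - n1 * mu - bhat * inv_tau2
        hess = -(n1 * mu * (1.0 - mu)) - inv_tau2
        step = grad / hess
        bhat = bhat - step
        if float(np.max(np.abs(step))) < 1e-10:
            break
    mu = special.expit(eta0 + bhat)
    sigma = 1.0 / np.sqrt(n1 * mu * (1.0 - mu) + inv_tau2)

    # adaptive GH: integral = sqrt(2)*sigma * sum_q w_q e^{z_q^2} f(bhat+sqrt(2)*sigma*z_q)
    b = bhat[:, None] + math.sqrt(2.0) * sigma[:, None] * nodes[None, :]
    eta = eta0[:, None] + b
    log_f = (
        y1[:, None] * eta
        - n1[:, None] * np.logaddexp(0.0, eta)
        - 0.5 * b * b * inv_tau2
        - 0.5 * math.log(2.0 * math.pi)
        - math.log(tau)
    )
    log_terms = np.log(weights)[None, :] + nodes[None, :] ** 2 + log_f
    log_int = special.logsumexp(log_terms, axis=1) + 0.5 * math.log(2.0) + np.log(sigma)
    ll += float(np.sum(log_int))
    if not math.isfinite(ll):
        return 1e12
    return -ll


def fit_glmm_random_slope(
    trials: Sequence[TwoByTwo], spec: GlmmSpec | None = None
) -> PooledEstimate:
    """Maximum-likelihood fit of the one-stage random-slope binomial GLMM.

    Model: logit p_ij = alpha_i + (beta + b_i) x_j with treatment indicator
    x_j in {0,1}, fixed study intercepts alpha_i, and b_i ~ N(0, tau^2).
    The marginal likelihood is maximized over (alpha, beta, log tau) by
    L-BFGS-B from two starts (the null and the two-stage estimate); the SE
    of beta comes from the observed information (numerical Hessian).  All
    trials are retained, including double-zero ones.  Non-convergence,
    singular information and sparse-data divergence (|beta| beyond the
    guard) are reported via ``converged=False``, never raised.
    """
    spec = spec or GlmmSpec()
    tables = _as_tables(trials)
    k = len(tables)
    if k < 2:
        return _failed("glmm_random_slope", k, k, "fewer than 2 trials")
    total_events = sum(t.a + t.c for t in tables)
    if total_events == 0:
        return _failed("glmm_random_slope", k, k, "no events")
    total_nonevents = sum(t.b + t.d for t in tables)
    if total_nonevents == 0:
        return _failed("glmm_random_slope", k, k, "no non-events")

    data = {
        "k": k,
        "y0": np.array([t.c for t in tables], dtype=float),
        "n0": np.array([t.n_ctl for t in tables], dtype=float),
        "y1": np.array([t.a for t in tables], dtype=float),
        "n1": np.array([t.n_trt for t in tables], dtype=float),
    }
    nodes, weights = np.polynomial.hermite.hermgauss(spec.quadrature_points)

    # starting intercepts: per-study pooled event odds with a 0.5 cushion
    p_start = (data["y0"] + data["y1"] + 0.5) / (data["n0"] + data["n1"] + 1.0)
    alpha0 = special.logit(np.clip(p_start, 1e-6, 1 - 1e-6))
    two_stage = pool_iv_random_dl(tables)
    starts = [np.concatenate([alpha0, [0.0, math.log(0.05)]])]
    if two_stage.converged:
        tau_start = max(math.sqrt(two_stage.tau2 or 0.0), 0.05)
        starts.append(
            np.concatenate([alpha0, [two_stage.log_or, math.log(tau_start)]])
        )

    bound_alpha = [(-30.0, 30.0)] * k
    bounds = bound_alpha + [
        (-30.0, 30.0),
        (math.log(spec.tau_floor), math.log(spec.tau_ceiling)),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _glmm_nll,
            x0,
            args=(data, nodes, weights),
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": spec.max_iterations,
                "ftol": spec.convergence_tol,
                "gtol": 1e-7,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not best.success:
        return _failed("glmm_random_slope", k, k, f"optimizer: {best.message}")

    beta = float(best.x[k])
    tau = math.exp(float(best.x[k + 1]))
    if abs(beta) > spec.beta_guard:
        return _failed("glmm_random_slope", k, k, "sparse-data divergence")

    # Observed-information SE of beta.  When tau sits at its boundary the
    # log-tau direction of the Hessian degenerates, so the variance component
    # is then held fixed and the information is taken over (alpha, beta) only.
    tau_interior = float(best.x[k + 1]) > math.log(spec.tau_floor) + 1e-6
    var_beta = math.nan
    if tau_interior:
        try:
            hess = approx_hess1(best.x, _glmm_nll, args=(data, nodes, weights))
            var_beta = float(np.linalg.inv(hess)[k, k])
        except np.linalg.LinAlgError:
            var_beta = math.nan
    if not math.isfinite(var_beta) or var_beta <= 0:
        log_tau_hat = float(best.x[k + 1])

        def nll_fixed_tau(x: np.ndarray) -> float:
            return _glmm_nll(np.concatenate([x, [log_tau_hat]]),
                             data, nodes, weights)

        try:
            hess = approx_hess1(best.x[: k + 1], nll_fixed_tau)
            var_beta = float(np.linalg.inv(hess)[k, k])
        except np.linalg.LinAlgError:
            return _failed("glmm_random_slope", k, k, "singular information")
    if not math.isfinite(var_beta) or var_beta <= 0:
        return _failed("glmm_random_slope", k, k, "singular information")

    se = math.sqrt(var_beta)
    or_value, ci_low, ci_high, p = wald_summary(beta, se)
    return PooledEstimate(
        method="glmm_random_slope",
        k_input=k,
        k_used=k,
        converged=True,
        log_or=beta,
        se_log_or=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        tau2=tau * tau,
    )


def glmm_loglik(trials: Sequence[TwoByTwo], beta: float, tau: float,
                alpha: Sequence[float] | None = None,
                spec: GlmmSpec | None = None) -> float:
    """Marginal log-likelihood at given (beta, tau), profiling intercepts.

    When ``alpha`` is omitted each study intercept is optimized at the fixed
    (beta, tau); used for likelihood-ordering diagnostics.
    """
    spec = spec or GlmmSpec()
    tables = _as_tables(trials)
    k = len(tables)
    data = {
        "k": k,
        "y0": np.array([t.c for t in tables], dtype=float),
        "n0": np.array([t.n_ctl for t in tables], dtype=float),
        "y1": np.array([t.a for t in tables], dtype=float),
        "n1": np.array([t.n_trt for t in tables], dtype=float),
    }
    nodes, weights = np.polynomial.hermite.hermgauss(spec.quadrature_points)
    log_tau = math.log(max(tau, spec.tau_floor))
    if alpha is not None:
        params = np.concatenate([np.asarray(alpha, float), [beta, log_tau]])
        return -_glmm_nll(params, data, nodes, weights)

    p_start = (data["y0"] + data["y1"] + 0.5) / (data["n0"] + data["n1"] + 1.0)
    alpha0 = special.logit(np.clip(p_start, 1e-6, 1 - 1e-6))

    def nll_alpha(a: np.ndarray) -> float:
        return _glmm_nll(np.concatenate([a, [beta, log_tau]]), data, nodes, weights)

    res = optimize.minimize(nll_alpha, alpha0, method="L-BFGS-B",
                            bounds=[(-30.0, 30.0)] * k)
    return -float(res.fun)


# ---------------------------------------------------------------------------
# Model facade


class MetaAnalysis:
    """A single meta-analysis of 2x2 tables, statsmodels-style.

    Build from :class:`TwoByTwo` tables, trial records, a
    :class:`~rapidmeta.data_model.MetaAnalysisData`, or a DataFrame with
    ``events_trt/n_trt/events_ctl/n_ctl`` columns; then ``fit`` any of the
    method tags in :data:`METHODS`.

    Examples
    --------
    >>> ma = MetaAnalysis([TwoByTwo(10, 90, 5, 95), TwoByTwo(4, 96, 2, 98)])
    >>> res = ma.fit("mh_fixed")
    >>> round(res.or_value, 3)
    2.091
    """

    def __init__(self, tables: Sequence[TwoByTwo | object]):
        self.tables = tuple(_as_tables(tables))
        if not self.tables:
            raise ValidationError("MetaAnalysis needs at least one table")

    @classmethod
    def from_data(cls, ma: MetaAnalysisData) -> "MetaAnalysis":
        return cls(ma.trials)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "MetaAnalysis":
        tables = [
            TwoByTwo(
                a=int(r.events_trt),
                b=int(r.n_trt) - int(r.events_trt),
                c=int(r.events_ctl),
                d=int(r.n_ctl) - int(r.events_ctl),
            )
            for r in frame.itertuples()
        ]
        return cls(tables)

    def fit(
        self,
        method: str = "mh_fixed",
        *,
        cc: float | None = 0.5,
        glmm_spec: GlmmSpec | None = None,
    ) -> PooledEstimate:
        if method == "mh_fixed":
            return pool_mh_fixed(self.tables)
        if method == "iv_random_dl":
            return pool_iv_random_dl(self.tables, cc=cc)
        if method == "peto":
            return pool_peto(self.tables)
        if method == "glmm_random_slope":
            return fit_glmm_random_slope(self.tables, spec=glmm_spec)
        raise ValidationError(
            f"unknown method {method!r}; expected one of {METHODS}"
        )
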