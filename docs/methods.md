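# Methods

## The estimand and the comparison

Each meta-analysis pools `k` randomized comparisons of a treatment against
control on one binary safety outcome, as 2×2 tables `(a, b, c, d)` (events
and non-events in the treatment and control arm). The **full** synthesis
uses all trials; the **rapid** synthesis uses the subset with
`registered = true` and `results_posted = true` — trials whose summary
results could be pulled from the registry without literature screening.
Trials registered elsewhere, or whose sources could not be resolved, carry
`registered = false` and are therefore excluded from the rapid arm only;
this is deliberately conservative and, if anything, understates rapid
performance.

Before any synthesis, multi-arm trials are deduplicated to their first
comparison (smallest `comparison_index`, ties by input order). Multi-dose
trials entered as several comparisons reuse the same control arm; pooling
them all double-counts control subjects and shrinks the pooled CI
artificially. Only meta-analyses with ≥ 5 distinct trials after
deduplication enter the comparison.

The paired result per meta-analysis × method is:

- **tolerable bias** `|θ̂ − θ̂_r| / θ̂` on the OR scale, compared strictly
  (`<`) against the 5/10/15/20% cutoffs. The OR scale is the primary one
  (the case study's 0.58 vs 0.62 → 6.9% is an OR-scale computation; the
  log-scale variant would give ≈ 12%) but `bias_scale="log"` is available.
- **direction**: OR < 1 beneficial (fewer adverse events under treatment),
  OR > 1 harmful, OR = 1 null. A null OR is classified `involves_null` and
  excluded from the two named discordance categories
  (`beneficial_to_harmful` = rapid beneficial, full harmful; and its
  mirror). It is measure-zero in practice.
- **significance**: significant iff `p < α` strictly, default α = 0.05;
  discordance split into `sig_to_nonsig` and `nonsig_to_sig`.

Statuses: `rapid_infeasible` (no registry-eligible trial),
`estimation_failed` (either fit non-converged for that method), else `ok`.
Only `ok` rows enter the concordance denominators; the other counts are
reported alongside so the accounting always closes:
`n_evaluable + n_rapid_infeasible + n_estimation_failed = total`.

## Synthesis engines

All two-stage estimates, CIs and p-values are Wald-type on the log-OR scale
(`z₀.₉₇₅ = 1.959964`); no method in this literature reports its test
construction more precisely, and Wald is what mainstream software prints.

**Mantel–Haenszel fixed-effect.** `OR_MH = Σ(aᵢdᵢ/Nᵢ) / Σ(bᵢcᵢ/Nᵢ)` on
uncorrected counts; SE of `ln OR_MH` by Robins–Breslow–Greenland. Single-zero
trials contribute natively. Double-zero and double-full tables carry no
within-study information about the OR and are excluded (tracked as
`k_used < k_input`). If every event sits in one arm overall, the MH sums
degenerate (OR of 0 or ∞) and the fit reports `converged=false,
"degenerate-mh-sum"` rather than a number.

**Inverse-variance random effects (DerSimonian–Laird).** Two-stage pooling
of study log ORs. Studies with any zero cell get +0.5 on all four cells
(the classic correction, applied per-study, "only-zero" style); double-zero
studies are excluded. `τ²_DL` from Cochran's Q with fixed-effect weights;
random weights `1/(vᵢ + τ²)`. `k = 1` degenerates to the single study with
`τ² = 0`. This is the "random model" companion to MH; the τ² estimator is
the DL moment estimator, the default in mainstream meta-analysis software.

**Peto.** `O = a`, `E = (a+b)(a+c)/N`, `V = (a+b)(c+d)(a+c)(b+d)/(N²(N−1))`;
`ln OR = Σ(O−E)/ΣV`, `SE = 1/√ΣV`. No continuity correction — the O−E
construction absorbs single-zero studies. Exact symmetry: tables with
`a = c` and equal arms give `O − E = 0` and pooled OR exactly 1.

**One-stage random-slope binomial GLMM.**
`logit p_ij = αᵢ + (β + bᵢ)xⱼ`, `xⱼ ∈ {0,1}`, fixed study intercepts `αᵢ`,
random slope `bᵢ ~ N(0, τ²)`. The marginal likelihood integrates the
treatment-arm binomial over `bᵢ` per study (the control-arm factor is
closed-form); the integral uses *adaptive* Gauss–Hermite quadrature —
15 nodes by default, recentred at the per-study posterior mode found by
safeguarded Newton (the mode problem is strictly concave) and rescaled by
the local curvature, all in log space. Maximization is L-BFGS-B over
`(α₁..αₖ, β, log τ)` with `τ ∈ [1e-8, 5]`, two starts (null; two-stage
DL estimate), objective tolerance 1e-8. All trials are retained, including
double-zero ones (their intercepts drift to the box bound and contribute
no slope information — the one-stage model's advertised advantage).

SE of `β̂` comes from the observed information (numerical Hessian over all
parameters). When `τ̂` sits at its lower bound the log-τ direction is
degenerate, so the information is taken over `(α, β)` with τ held at its
boundary estimate — the same conditioning lme4 applies in singular fits.
Failure modes are values, not exceptions: `"no events"`, `"fewer than 2
trials"`, optimizer failure, `"singular information"`, and a sparse-data
divergence guard at `|β̂| > 10` (an OR beyond e¹⁰ on safety data is a
separation artifact, not an estimate).

Verification: the engines reproduce R `metafor`'s `rma.mh`, `rma(method
="DL")` and `rma.peto` to ~1e-7 on a mixed fixture with a zero-cell study
(tests/test_reference_oracles.py), and the GLMM matches `lme4::glmer`
(`cbind(y, n−y) ~ study + trt + (0 + trt | study)`) to < 3e-4 on `β̂` across
simulated datasets, with identical boundary behaviour for τ̂. At τ = 0 on
large balanced trials the GLMM agrees with a study-dummy logistic
regression to < 1e-4.

### Known small-sample behaviour of the GLMM

Two properties matter for interpreting simulation results, and both were
confirmed against lme4 on the same data (they are properties of the
estimator, not of this implementation):

- With `k ≈ 10` rare-event trials and τ comparable to the within-study
  noise, the ML estimate of τ² collapses to the boundary in the large
  majority of replicates. The Wald SE then omits between-study
  variability and the nominal 95% CI covers at roughly 80–88% in such
  regimes (e.g. measured ≈ 78–84% at k=10, 200/arm, p₀=0.05, β=ln 2,
  τ=0.3; the analytic approximation
  `2Φ(1.96·se/√(se² + τ²/k)) − 1 ≈ 0.88` explains most of the gap).
- Fixed study intercepts in a nonlinear model incur incidental-parameter
  bias, here ≈ +0.04 on β̂ in the same regime.

The acceptance suite states the coverage check at its nominal [90%, 98%]
band and therefore documents this shortfall rather than masking it.

## Heterogeneity and subgroups

`Q` and `I² = max(0, (Q − (k−1))/Q)·100` are computed from two-stage
log ORs under fixed-effect weights. For stratification, every comparison
row carries the *full* meta-analysis's two-stage I² (0.5-corrected IV log
ORs), a single value per meta-analysis independent of the pooling method.
Strata: I² ≤ 25% (none/mild heterogeneity, boundary inclusive) vs > 25%;
rows with undefined I² (fewer than two estimable studies) go to an
`unclassified` bucket. Event-rate subgroups cut the crude pooled rate
(total events / total sample over both arms) at the empirical 25th/50th/
75th percentiles of the evaluable rows (linear-interpolation quantiles),
into `≤P25, (P25,P50], (P50,P75], >P75`. Percentiles are computed after
excluding non-converged cases, since only evaluable rows can be tabulated.

## Synthetic data generator

The generator emulates the *structure* of real safety meta-analysis
collections, not any particular dataset:

| parameter | default | rationale |
|---|---|---|
| trials per MA | `k = 5 + NegBinom(r=0.8, μ=6.5)` | quartiles exactly (6, 9, 14), the shape reported for real collections; the +5 shift enforces full-analysis eligibility by construction |
| arm size | LogNormal(log 230, 0.6), min 10 | median total ≈ 4,000–5,000 per MA |
| control risk | Beta(1.5, 48.5) per MA (mean 3%) | rare adverse events; zero-event arms arise naturally |
| true log OR | N(0, 0.4²) per MA | effects centred on null, occasionally strong |
| between-trial SD τ | 0.2 | mild-to-moderate heterogeneity (I² straddles the 25% boundary) |
| P(registered) | 0.83 | typical registry registration rates |
| P(posted \| registered) | 0.77 | joint eligibility ≈ 0.64, matching reported medians ~0.64–0.70 |
| selection_beta_size | 0 (MAR) | optional: links registration log-odds to standardized log trial size, for studying selective registration |
| multi_arm_fraction | 0.10 | second dose comparison duplicated with the control arm shared verbatim |

What it does **not** emulate: correlated outcomes across meta-analyses from
the same review, time trends in registration (pre-2004 trials), outcome
misclassification, or any relationship between effect size and
registration other than the optional size selection. Passing emulation
tests therefore demonstrate internal consistency of the pipeline under a
faithful structural model — not external validity for any specific
empirical collection, whose headline percentages depend on its own
registration patterns.

## Numerical conventions and edge cases

- Bias cutoffs compared strictly (`bias < t`); a bias of exactly 0.05 is
  *not* within the 5% threshold.
- `p = α` exactly is non-significant (strict `p < α`).
- Threshold flags are monotone by construction (`within_05 ⇒ … ⇒ within_20`)
  and validated on the result type.
- Blank `comparison_index` values are assigned by order of appearance per
  trial; file row order is authoritative for "first comparison" ties.
- Empty rapid subsets, all-zero meta-analyses and GLMM non-convergence are
  values with explicit reasons, not exceptions; they flow into the report's
  exclusion bookkeeping.
- All randomness flows from one seed (`SimulationConfig.seed` / `--seed`);
  the simulate → emulate → report pipeline is byte-identical across reruns.

## Design choices that were genuinely open

- **"Random MH model"** is implemented as inverse-variance random effects
  with DL τ² — the standard random-effects companion reported alongside MH
  in mainstream software. The τ² estimator and correction policy are
  arguments, not constants.
- **GLMM intercepts fixed, not random**: avoids a joint distributional
  assumption on baseline risks, keeps the likelihood per-study concave in
  the random effect, and makes the model exactly checkable against
  `glmer(… study + (0 + trt | study))`. The cost is the incidental-parameter
  bias documented above.
- **Arm-swap symmetry** is exact for MH/IV-DL/Peto. For the GLMM it is
  exact only at τ̂ = 0: the random slope rides on the treatment indicator,
  so swapping arms changes the model family, and inversion holds only
  approximately (observed ~1e-4 on homogeneous data, within a few percent
  otherwise).
- **Rapid subsets of size 1** are analyzed (no minimum is imposed on the
  rapid arm); the GLMM then reports `estimation_failed` while the
  two-stage methods degenerate to the single-study estimate, and `k_rapid`
  is recorded so downstream users can filter.
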