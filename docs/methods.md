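# Methods

This note records the statistical model, the numerical methods and the
deliberate modelling choices behind `gslond`. All levels, boundaries and
p-values are one-sided.

## 1. Online FDR and budget sequences

The online FDR after the i-th decision is

```
FDR_i = E[ V(i) / max(R(i), 1) ]
```

with `V(i)` the number of falsely rejected and `R(i)` the number of rejected
hypotheses among the first i. LOND tests H_i at
`alpha_i = beta_i * (1 + R(i-1))`; the "updated" variant uses
`beta_i * max(R(i-1), 1)`, which carries the FDR proof under positive
dependence (PRDS). Both rules are online: the level for H_i depends only on
decisions about H_1..H_{i-1}.

Budget sequences (`gslond.beta_sequences`):

* **descending** — `beta_j = C * alpha * log(max(j,2)) / (j * exp(sqrt(log j)))`
  with the conventional constant `C = 0.07720838`. Recomputing the normalizer
  from the series itself gives `1/S ≈ 0.079082` (see the numerical notes
  below); with the
  conventional constant the budgets sum to about `0.976 * alpha`, which is
  slightly conservative and therefore keeps FDR control. Both constants are
  available (`JM_CONSTANT`, `normalizing_constant()`).
* **descending_truncated** — when the number of hypotheses is bounded by N,
  the first N budgets are rescaled by `alpha / sum_{j<=N} beta_j` so they sum
  to alpha exactly (and are zero beyond N). Rescaling preserves the ratios
  `beta_i / beta_1`; smaller N means larger budgets and more power.
* **equal** — `beta_i = alpha / N`.
* **dependent adjustment** — any sequence divided by the harmonic number
  `H_i = sum_{j<=i} 1/j` (computed via the digamma identity), restoring FDR
  control under arbitrary dependence.

## 2. Two-stage boundaries by alpha spending

Each hypothesis is analysed at an interim (information fraction `t1`,
default 0.5) and a final look. Given a nominal level `a`, the interim
boundary on the p-value scale is the spend `a1 = f(t1, a)` with

* approximate O'Brien-Fleming: `f(t, a) = 2 * (1 - Phi(Phi^{-1}(1 - a/2) / sqrt(t)))`
* approximate Pocock: `f(t, a) = a * ln(1 + (e - 1) * t)`

and the final boundary `a2` solves

```
P(Z1 < z_{a1}, Zf >= z_{a2}) = a - a1,     corr(Z1, Zf) = sqrt(t1),
```

so the two-stage design exhausts `a` exactly under the null. The correlation
`sqrt(t1)` follows from the pooled final analysis of a two-sample comparison
with proportional per-stage allocation. The bivariate-normal rectangle
probability is evaluated in closed form through Owen's T function
(`scipy.special.owens_t`, absolute accuracy ~1e-15), and `a2` is found by
bracketed Brent root-finding to ~1e-12 on the probability scale. Solved plans
are memoised (`functools.lru_cache`), which is what makes the simulator fast:
within a scenario only a handful of distinct nominal levels occur.

`exhaust_increment_boundary(level, a1_spent, t1)` solves the same equation
with a *fixed* first-stage threshold: it spends the increment
`level - a1_spent` entirely at the final look. When the level did not change
it reproduces the standard plan exactly.

Futility: an arm stops at interim without rejection when `p >= futility`
(default 0.5). The bound is non-binding — efficacy boundaries are computed
ignoring it — so stopping for futility can only make the procedures more
conservative.

## 3. Scheduling rules for interleaved analyses

Analyses arrive as a chronologically ordered event stream
`(time, hypothesis, stage, p)`. The rejection count feeding H_i's level is
taken over hypotheses decided strictly before the current analysis:

* **gsLOND** counts rejections among earlier-entering hypotheses (j < i);
  both boundaries are re-derived from the chosen spending function at the
  current level.
* **gsLOND.II** additionally recomputes the final boundary with the
  increment-exhausting rule whenever the j < i rejection count grew between
  H_i's interim and final analysis: the interim was already tested at the
  old (smaller) `a1`, and the difference to the updated level is spent at the
  final look. This can only enlarge the final boundary, so its rejection set
  contains gsLOND's.
* **gsLOND.III** counts rejections among *all* other hypotheses (j ≠ i),
  including later entries decided earlier in calendar time. This leaves the
  pre-fixed LOND ordering and carries no formal online-FDR guarantee; it is
  assessed empirically (the FDR simulations in the test suite cover it).
* **gsLOND.II.III** uses the j ≠ i count for the nominal level and applies
  the increment-exhausting recalculation when the j < i count grew between
  the two looks. (Triggering on the full j ≠ i count instead would spend
  level increments caused by later-entering hypotheses that were already
  known at the interim, and does not reproduce the worked-example boundary
  0.0190 for the case "H3 rejected at its interim before H2's final".)

Comparators: `level_alpha` (every test at the unadjusted level alpha) and
`bonferroni` (every test at alpha/K).

Decisions are never revised; a rejection counts from its timestamp onward and
a futility stop contributes a permanent zero. Ties in calendar time are
broken by entry order upstream (the runner requires strictly increasing
timestamps).

## 4. Platform-trial simulator

The control-patient index is the platform clock. Arm i (i = 1..K) opens at
`(i-1) * n_delta` and accrues one observation per control patient; its
interim occurs after `n1` of its patients and its final analysis after `n`
(defaults 25/50, `n_delta = 20`). Observations are `N(delta_i, 1)`;
`delta_i = 0` for controls and true nulls, `delta_i = Delta` (default 0.6,
optionally drawn from a set) for alternatives. Truth labels are i.i.d.
Bernoulli(pi0) nulls, or deterministic blocks (`alternatives_first` /
`alternatives_last` with `m1 = round(K * (1 - pi0))` alternatives).

Each analysis is a pooled-variance one-sided two-sample t-test against

* **CC** — concurrent controls: the window accrued in parallel with the arm,
  or
* **NCC_CC** — all controls accrued so far (non-concurrent + concurrent),
  which enlarges the control sample for later arms.

The boundaries use `t1 = n1/n` for both control configurations; the larger
NCC control sample at the interim is deliberately not exploited (a mildly
conservative choice). Under the null the t-test p-values are exactly uniform,
and the interim/final z-statistics have correlation ~`sqrt(t1)` (verified
empirically in the test suite).

Treatment-arm draws do not depend on the control configuration, the spending
function, the procedure variant or the bound N, so comparisons across those
settings at the same seed are paired (common random numbers);
`run_replicates(scenario, variants=[...])` evaluates several procedures on
identical data. Replicates use independent `numpy` SeedSequence spawns of the
scenario seed, making all outputs reproducible bit-for-bit.

**Metrics.** Empirical FDR averages the false discovery proportion
`V / max(R, 1)` at the final decision step over replicates; average power is
the mean fraction of rejected alternatives among replicates containing at
least one alternative; Monte-Carlo standard errors are per-replicate sample
standard errors. Saved sample size is `stops * n2 / (K * n)` per replicate
(in %): the stage-2 observations freed by interim stops relative to the
*total* planned treatment observations. Under the global null with futility
bound 0.5 the interim stop probability is ≈ 0.5, giving the ≈ 25% headline;
`saved_sample_size(result, denominator="stage2")` reports the alternative
normalisation by `K * n2` (≈ 50% in the same setting).

**Fixed-budget mode.** The platform budget is `B = K0 * n + C` with
`C = (K0 - 1) * n_delta + n` pre-planned control patients. Every interim stop
frees that arm's `n2` stage-2 observations; once a full `n` has accumulated in
the freed pool, a replacement arm opens immediately (event-driven via a heap;
controls are generated lazily). Replacement-arm truth follows the configured
scenario: (1) same pi0/Delta as the initial arms, (2) Delta drawn from
{0.4, 0.8, 1.2}, (3) the m-th added arm uses `max(pi0 - m/80, 0)`, (4) added
alternatives get Delta = 1. Budget accounting covers treatment observations
plus the planned controls; replacement arms are funded solely from freed
treatment allocations, so usage never exceeds B.

## 5. Numerical notes

* The descending series converges extremely slowly (terms ~
  `log j / (j * e^{sqrt(log j)})`): the first 10⁶ terms cover only ~53% of the
  total. `series_total` therefore adds the analytic integral tail
  `∫_m^∞ log x / (x e^{sqrt(log x)}) dx = 2 * Γ(4, sqrt(log m))` (upper
  incomplete gamma, midpoint-corrected) to an exact partial sum; the result is
  stable to <1e-4 relative between m = 10⁵ and 10⁶. This yields the
  recomputed normalizer `1/S ≈ 0.079082`; the package nevertheless defaults
  to the conventional `0.07720838` for comparability, accepting the ~2.4%
  under-spend.
* With a bound N, the reference values for the rescaled budgets match
  `beta_1' = 0.00446` and `beta_3' = 0.00083` at `alpha = 0.025, N = 1000`,
  but the middle value is `beta_2' = beta_1' * beta_2 / beta_1 ≈ 0.00097`
  (rescaling preserves ratios); a reference value of 0.00099 is not
  consistent with any single rescale factor.
* Boundary solutions are validated three ways: analytic exhaustion of the
  nominal level to 1e-8, agreement of the closed-form bivariate normal CDF
  with `scipy.stats.multivariate_normal`, and a 10⁷-draw Monte-Carlo oracle
  simulating the correlated z-statistics directly.
* All simulation seeds derive from a single integer through
  `numpy.random.SeedSequence`; identical configuration and seed give
  byte-identical CLI output.

## 6. Limitations

* One interim per arm; normal endpoints with unit variance; 1:1 allocation
  per open arm.
* `gsLOND.III` / `gsLOND.II.III` have no formal FDR guarantee (empirically
  controlled in all tested scenarios).
* The futility bound is applied on the interim p-value only and is
  non-binding.
* Boundaries are not recomputed for the actually available control
  information under NCC_CC (conservative).
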