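# Methods

## Model and estimand

The data-generating and analysis model is a two-level growth model for a
two-arm trial with a common measurement schedule:

```
Y_ij = β₀ + β₁ T_j + β₂ C_i T_j + u0_i + u1_i T_j + e_ij
(u0_i, u1_i) ~ N(0, Σ_u),  e_ij ~ N(0, σ²_e),  C_i ∈ {0, 1}
```

The estimand is the treatment-by-time interaction β₂. Randomization makes
the arms exchangeable at baseline, so the structural model carries no
condition main effect; the *fitted* model nevertheless includes one by
default (`condition_main_effect=True`). Two reasons. First, estimating the
baseline contrast is standard practice and costs almost nothing. Second, and
decisive here: the analytic design formula for the standard error of β̂₂
(below) is exact for the main-effect parameterization, so design formula,
fitted model and simulation agree by construction. The reduced
parameterization (common intercept across arms) is available as an option;
its exact GLS standard error `sqrt(4 / (N · TᵀV⁻¹T))` is implemented in
`gls_se_beta2`.

Log-linear growth is handled by replacing the time axis with
`log(T + shift)` once, at design construction; simulation and fitting only
ever see the transformed axis. A grid containing time 0 cannot be
log-transformed; the package rejects it and recommends `shift = 1`, which
keeps the baseline at `log(1) = 0`.

## Analytic standard error and the sum-of-squares convention

For a balanced design the sampling variance of β̂₂ is

```
Var(β̂₂) = 4 (σ²_e + σ²_u1 · S) / (N · S)
```

where `S` is a time sum of squares. Two conventions circulate: the raw
`S = Σ T_j²` and the centered `S = Σ (T_j − T̄)²`. They are not
interchangeable: the centered version is the exact variance of the
interaction coefficient in the main-effect model (algebraically, via the
per-arm information `WᵀV⁻¹W` with `W = [1, T]`), while the raw version is
exact only when the intercept variance is zero. The package defaults to
**centered**; the empirical check in the test suite (10⁴ simulated REML fits
at N = 704) finds the centered value within 0.5% of the observed sampling
SD, with the raw variant ~17% too small for the same components. The raw
variant is kept as an option (`centered=False`) for comparison with sources
that print it.

## Effective sample size and the prior fraction

The default prior uses a fraction `b = J / N_eff` of the information, with
`J ∈ {1, 2, 3}` the constraint-count multiplier. `N_eff` measures how many
*independent* observations the correlated longitudinal sample is worth for
estimating β₂: a weight `w` is the ratio of the OLS variance of the
interaction under an independence working model (all `N·n` observations
independent with variance equal to the average marginal variance
`σ̄² = σ²_e + σ²_u0 + (2/n) Σ T_j σ_u0u1 + (1/n) Σ T_j² σ²_u1`) to the
actual design variance above, and `N_eff = w · N · n`, clamped to
`[N, N·n]` because the information content must lie between fully dependent
and fully independent observations. The weight construction behind the
clamp is this package's concrete choice; the clamp itself is principled and
binds in practice (for the replication example the raw weight slightly
exceeds 1, so `N_eff = N·n`).

## The Bayes factor

With posterior `N(β̂₂, σ²_β̂₂)` and prior `N(0, σ²_β̂₂ / b)`:

- `fit₀` = posterior density at 0; `comp₀` = prior density at 0
- `fit₁` = posterior mass above 0; `comp₁ = 0.5` exactly (the prior is
  symmetric about the constraint boundary for every `b`)
- `BF₀ᵤ = fit₀/comp₀` (the Savage–Dickey ratio), `BF₁ᵤ = fit₁/0.5`,
  `BF₀₁ = BF₀ᵤ/BF₁ᵤ`, `BF₁c = fit₁/(1−fit₁)`

Useful consequences, all enforced as tests: `BF₁ᵤ < 2` for any data (so a
threshold ≥ 2 can never be reached against the unconstrained hypothesis — a
warning is raised); inequality-only comparisons (`BF₁ᵤ`, `BF₁c`) are exactly
independent of `b`; `BF₀ᵤ` strictly decreases in `b`. A `β₂ < 0` research
hypothesis is evaluated by sign reflection, which is exact. The complement
of the *equality* hypothesis is, up to a null set, the unconstrained
hypothesis, so under `test="Hc"` the H0 branch compares H0 against Hu. All
densities are evaluated on the log scale; at extreme `|β̂₂|/SE` the
exponentiated BF saturates to `inf`/`0` rather than producing NaN.

## Estimation

Balanced designs make the marginal covariance
`V = σ²_e (I + W Γ Wᵀ)`, `Γ = Σ_u/σ²_e`, identical across subjects, so the
(RE)ML deviance depends on the data only through per-arm sufficient
statistics (`Σ yᵀy`, `Wᵀ(Σ y yᵀ)W`, `WᵀΣy`, counts). The deviance is
profiled over the fixed effects and the residual scale, leaving three free
parameters (the Cholesky factor of Γ, so the boundary σ²_u1 = 0 is inside
the parameter space), minimized by Nelder–Mead from moment starting values
(per-subject OLS intercepts/slopes). The whole fit is numba-compiled and
costs well under a millisecond, which makes ~50,000 fits per sample-size
search routine. REML is the default; ML is selectable, and the acceptance
suite checks the two give indistinguishable power. Agreement of the fitter
with an independent general-purpose mixed-model implementation (statsmodels
MixedLM) is asserted to ~1e−6 on the estimate and SE.

Degenerate inputs: exactly noise-free data are detected (GLS residual ~ 0 at
Γ = 0) and returned as an exact OLS solution flagged `singular`; boundary
variance estimates are retained but flagged. A dataset whose fit fails is
re-simulated once from a dedicated retry stream; if it fails again it is
excluded, the power denominator counts only successful fits, and the
exclusion count is reported.

## Power and the sample-size search

`η_h` is the exact fraction of successful-fit BFs above the threshold among
`m` simulated datasets under truth `h`; the criterion is the minimum over
the requested truths. Fitted estimates are computed once per (truth, N) and
shared across the three prior fractions, since the posterior does not depend
on `b`.

The binary search halves `[n_min, n_max]` (defaults 30/1000), evaluating
each midpoint with fresh datasets; the returned N is the upper bound when
the interval reaches width one. If that bound was never directly evaluated
(every midpoint failed), it is evaluated, and an error reports the achieved
power when it misses the target. If the result lands at `n_min + 1`, the
lower bound itself is evaluated and returned with a note when it already
meets the target. Monte-Carlo non-monotonicities across evaluated sizes are
tolerated (the trace records every evaluation) and surfaced as a single
summarized warning.

Reproducibility: dataset `k` under truth `h` at size `N` uses the child
stream `SeedSequence(master, key=(h, N, k, retry))`, so results are
independent of evaluation order and any single dataset can be regenerated in
isolation.

## Semi-analytic oracle

For testing, power is also computed without simulation: every supported BF
is a smooth function of `z = β̂₂/SE` and `b` alone, so with the SE held
fixed at its analytic value, `z ~ N(β₂/SE, 1)` and the exceedance region is
found by root-bracketing the log-BF and accumulating normal tail masses.
The oracle's one approximation is ignoring the sampling noise of the
estimated SE; empirically this costs up to ~0.01 absolute in power at
N = 100 and less at larger N, which is why the simulation-vs-oracle test
allows three binomial standard errors at m = 5000.

## Synthetic data: what it does and does not emulate

The generator draws exactly from the assumed model: bivariate-normal random
effects, homoscedastic normal residuals, a common schedule, no attrition,
deterministic near-balanced allocation (extra subject to control for odd N).
Passing tests therefore certify the machinery under the model's own
assumptions — not robustness to dropout, irregular individual schedules,
non-normal effects or residual autocorrelation, none of which the method
models. Default problem sizes used by the test suite (m = 1000–5000 per
power estimate, 10⁴ fits for the SE validation) were chosen to keep
Monte-Carlo error a small fraction of each tolerance.

## Known limitations

- One constrained parameter only; no simultaneous or about-equality
  (interval) constraints.
- Two-level designs; a third nesting level (e.g. therapists) is out of
  scope.
- Power assumes the design's variance components are the truth; there is no
  assurance-style averaging over parameter uncertainty.
- The binary search presumes power is monotone in N; severe Monte-Carlo
  noise (small m) can still return a neighboring N.
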