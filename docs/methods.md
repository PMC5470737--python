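# Methods

## Observation model

All four substantive models share one observation model. The data are a
divorce-centred series `y(t)` of 3-month antidepressant-purchase
prevalences on the 41-point lattice `t = −60, −57, …, +60` months (bins are
half-open `[t, t+3)`, labelled by their left edge; divorce at `t = 0` falls
in bin 0). Before fitting, the never-divorced stratum's linear secular
trend (OLS slope per calendar month) is subtracted as a function of
divorce-centred time, and the series minimum is then subtracted so the
preprocessed series touches zero. Both operations are affine, so second
differences — and hence the curvature-mismatch statistic — are unaffected.

A model's latent episode prevalence `g(t)` is linked to purchases by a
causal impulse response `h(t; λ, α) = αλe^(−λt)`, `t ≥ 0`: an episode
triggers purchasing that continues with exponentially decaying probability
(rate `λ` per month); the gain `α = ∫h` converts episode prevalence into
purchase prevalence. The prediction is the discrete causal convolution
`(h*g)(t) = Σ_τ g(τ)h(t−τ)Δ` with `Δ = 3` months and `g` taken as zero
left of its grid.

**Numerical choice — bin-averaged kernel.** The convolution kernel is the
bin average `(1/Δ)∫_lag^{lag+Δ} h`, i.e. `αλe^(−λ·lag)·(1−e^(−λΔ))/(λΔ)`,
rather than the point value `h(lag)`. Point evaluation inflates the
discrete gain by `λΔ/(1−e^(−λΔ))` (≈6% at the fitted `λ ≈ 0.04/month`);
bin averaging conserves `α` exactly up to window truncation. The kernel
shape (`∝ e^(−λ·lag)`) is identical under both conventions, so fitted
`λ, μ, σ`, R² and all model orderings are unchanged; only the absolute
scale of `α` depends on this convention, which is why cross-study
comparisons of `α` require stating it.

## Diathesis-stress shapes

`g1` (stress-relief), `g2` (stress-induction) and `g3` (peak-stress) are
normal densities with mode `μ` and dispersion `σ` (months), right-truncated
at −6, left-truncated at −6, and untruncated respectively, each rescaled so
its maximum over the evaluation grid is exactly 1. The −6-month truncation
encodes the Finnish statutory six-month consideration period between the
divorce decision and registration. Truncation is a hard support restriction
(values exactly zero beyond the point); the truncated density's normalising
constant is irrelevant because max-standardisation and the fitted gain
absorb it. A right-truncation at 0 is exposed as a non-default option for
sensitivity work. Densities come from `scipy.stats.truncnorm`/`norm`.

## The adaptive life-history model

States: seeking partner, married, relationship at risk, dead (absorbing);
3-month periods `t = 0..T−1`, default `T = 80` (ages 20–40). Per-period
transition probabilities (defaults in parentheses):

* seeking → married: `ρ = 1 − (1−0.028)^(1/4)` (annual first-union hazard
  0.028), removed under the depressed mode by default (a toggle);
* married → at-risk: `d1 = 0.07`;
* at-risk → seeking (divorce): `d2 = 0.07`, reduced to `d2 − s` under the
  depressed mode (`s = 0.007`, the mode's social-leverage benefit);
* at-risk → married (reconciliation): `d2` — on average as many at-risk
  relationships reconcile as divorce;
* any alive state → dead: `m = 1 − (1 − 1/8)^(1/81) ≈ 0.0016` (one in
  eight die between ages 20 and 40), plus `z = 0.0024` under the depressed
  mode (≈2.5-fold hazard, a deliberately high cost estimate: if depression
  is adaptive under a conservative cost it is adaptive under a lower one);
* residual mass self-loops.

Reproduction yields a constant payoff (1 per period) while married or
at-risk, zero in the final period; any positive constant induces the same
policy. Backward induction from `V(·, T) = 0` computes the mode values
`Q(u) = payoff + Σ P(x'|x,u)V(x', t+1)` and the reproductive values `V`
under an error-prone policy that picks the Q-maximising mode with
probability `1 − δ` (`δ = 0.0005`).

**Design choices where the design was open.**

* *Error model*: ε-greedy with ε = δ, and `V` propagated under the
  error-prone policy. A payoff-weighted (softmax) error model is an
  alternative reading; at δ = 5·10⁻⁴ the predictions are insensitive to
  the form, so the simplest one is used. Ties resolve to the non-depressed
  mode.
* *Divorce event*: the at-risk → seeking transition, recorded at the
  period of arrival in the seeking state. The last depressed period of a
  divorcing individual is therefore centred time −1.
* *First divorces only* are used for centring; later divorces of the same
  individual are simulated but not re-centred.
* *Time-varying hooks*: `m`, `ρ` and fertility accept per-period vectors
  for age-dependent demographic schedules; no calibrated schedule ships
  with the package.

The forward simulation tracks 50,000 individuals (default) from the
initial state distribution (0.97, 0.02, 0.01, 0) through `T` periods.
Divorces within 20 periods of either end of the simulated interval are
excluded, removing horizon artefacts (near `T` the depressed mode stops
being optimal because no future benefit remains). The curve `g4(t')` is
the prevalence of the depressed mode among the usable divorcees, alive at
centred period `t'`, for `t' ∈ [−20, +20]` periods; its maximum is ≈1 by
construction (almost every divorcee is in the at-risk state, where the
mode is optimal, just before divorcing), so no rescaling is applied.
Finally the curve is shifted one period (3 months) leftward — the
registration lag: the modelled breakdown precedes the registered divorce
by the consideration period — with the right edge padded by repeating the
final value (the curve is flat and near zero there).

With the default environment the depressed mode is optimal in the at-risk
state for 78 of 80 periods and in no other state; at `z = 0.06` (≈38-fold
mortality) it is optimal nowhere. The measured annual divorce hazard among
intact couples is exposed for calibration inspection but not asserted
against any external value, because the mapping from `(d1, d2)` to an
annual population hazard depends on denominator conventions that are not
fixed here.

## Estimation and comparison

Stress families estimate `θ = (α, λ, μ, σ)` (`k = 4`); the adaptive curve
is a fixed input (its simulation seed recorded) and only `(α, λ)` are
estimated (`k = 2`; `k = 3` available for treating `s` as profiled).
RSS is minimised by bounded L-BFGS-B from a deterministic multi-start grid
(`μ ∈ {−24, −12, −6, 0, 12}`, `σ ∈ {2, 5, 10}`, `λ ∈ {0.02, 0.05, 0.1}`,
`α` from a mass match `Σy/Σg`), bounds `α ∈ (0, 10]`, `λ ∈ (10⁻⁴, 2]`,
`μ ∈ [−60, 60]`, `σ ∈ (0.1, 60]`, followed by a trust-region
least-squares polish (the finite-difference quasi-Newton optimum is
accurate to ~10⁻⁶ in the parameters; the polish brings noise-free
self-recovery below 10⁻¹² RSS). Multi-start matters: the badly fitting
stress-induction family has a nearly flat objective with boundary optima.

AIC and BIC use `n = 41` series points. R² can be negative for nonlinear
fits worse than the mean. CM uses unit spacing per 3-month step; absolute
CM values scale with that convention, orderings do not. When two models
share `k`, ΔBIC = ΔAIC exactly.

## Synthetic register generator

The generator emulates the structure the analysis assumes, at the original
study's scale by default: 304,112 individuals of whom 23,956 divorce,
observed 156 months, purchases binned 3-monthly with within-bin dedup.
Divorce months are uniform over the lattice positions where the full
±60-month window fits. Each divorcee has a divorce-locked depressive
episode with probability `episode_probability`; onsets are drawn from the
configured shape renormalised to a discrete density over the grid (the
shape is standardised, generation needs a density); at most one episode
per individual. A treated episode purchases in its onset bin and continues
bin-to-bin with probability `e^(−3λ)` — the geometric discretisation of
exponential persistence, matching the impulse-response decay exactly.
Background purchases occur independently per bin at
`background_rate + trend_slope·month`.

Free knobs without an empirical anchor were fixed once at values that
reproduce the magnitudes of the original raw series: background 3-month
prevalence 0.02 rising by 1.5·10⁻⁴/month (to ≈0.043 over 13 years), and
`episode_probability = 0.06`, giving a divorce-locked excess peak of ≈4
percentage points over background. What fraction of divorcees actually has
a treated episode is unknown; this knob is a generator convenience, not an
estimate.

**What the generator does not emulate:** attrition (denominators are
constant), mortality, sociodemographic covariates, repeat episodes,
remarriage effects on purchasing, seasonal structure, and any
selection-into-divorce mechanism (episodes are divorce-locked by
construction). Passing tests therefore show that the pipeline recovers the
structure it assumes — not that the assumed structure is true of registry
data.

## Identifiability of (μ, σ) at the truncation boundary

When the true episode mode coincides with the truncation point (μ = −6 for
the right-truncated family), the observable shape is a boundary-peaked
half-Gaussian, and moving μ to the right of the boundary while inflating σ
changes the shape only weakly: (μ, σ) sit on a nearly flat RSS ridge even
though the curve itself is well determined. Two consequences follow.
First, at low signal (episode rate 0.06, ≈24,000 divorcees) the fitted μ
can wander several months along the ridge from seed to seed — additionally
pushed by the small positive offset that minimum-subtraction injects into
every bin (the convolution model cannot represent a constant), which the
fit accommodates by widening σ. Shape-level quantities (R², predicted peak
location, λ) remain stable and are what the fixture-based comparison tests
assert. Second, the parameter-recovery study is powered accordingly:
100,000 individuals with a ≈24,000-strong divorced stratum (matching the
register) and an episode rate of 0.25, under which recovered μ and σ are
stable to a few tenths of a month across seeds and λ to a few percent —
comfortably inside the ±1.5-month and ±30% recovery tolerances the test
suite enforces.

## Problem sizes and determinism

Default problem sizes — 50,000 simulated individuals, register-scale
(304,112) or 100,000-person synthetic cohorts, 135-start stress-family
fits — were chosen so the full pipeline runs in well under a minute per
stage on a single CPU while keeping Monte-Carlo error far below every
asserted tolerance. All randomness flows from one root seed split into
named streams (cohort, simulation); identical configuration and seed give
byte-identical outputs. Hypothesis-based property tests run derandomised.

## Known limitations

* The adaptive model is unilateral; divorce is a bilateral (game-theoretic)
  process.
* `g4` inherits Monte-Carlo noise from the forward simulation; the fit
  treats it as fixed and `k = 2` does not count the simulation.
* The prevalence CSV reader infers raw-versus-preprocessed status from a
  zero/negative minimum, which a raw series of exactly-zero prevalences
  would fool (such a series is degenerate for fitting anyway).
* Absolute α, AIC, BIC and CM depend on the measurement scale of `y` and
  the discretisation conventions above; only differences, orderings and
  scale-invariant quantities are meaningful across implementations.
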