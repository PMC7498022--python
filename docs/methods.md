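# Methods

## Model

### Single cell

Protein amount `x` in one cell obeys

    dx/dt = α z − x/β,        z = exp(y − σ²/2),

where `y` is an Ornstein–Uhlenbeck (OU) process with relaxation time `τ`
and — **by the convention fixed throughout this package** — stationary
variance `σ²`, i.e. diffusion amplitude `σ·sqrt(2/τ) dW`. This convention
is forced by two facts that the rest of the framework depends on: at
stationarity `z ~ LN(−σ²/2, σ)` and `E[z] = 1`, making `α` the *mean*
production rate and `E[x] = αβ`. Any other amplitude convention breaks
both. All processes upstream of translation (promoter state, transcription,
…) are lumped into `α` and `z`; degradation is deterministic first-order
with mean lifetime `β`; there is no cell division.

At stationarity the log-moments are

    μ_log = log(αβ) − σ_W²/2,
    v_log = g(σ², τ/β) = σ_W²,

where `g` has **no closed form**; it is *defined* by simulation
(`stationary_log_moments`) and inverted numerically (`calibrate_sigma`).
Empirically `g` is increasing in both arguments and saturates at `σ²` for
`τ/β → ∞` (expression slaved to the production rate) and vanishes for
`τ/β → 0` (fluctuations averaged out by the protein's lifetime).

### Population

A population is a mixture of `N` subpopulations; a cell never changes
subpopulation. Subpopulations share (β, σ, τ) — hence share σ_W² — and
differ only in α, with `log α ~ N(μ_α, σ_α)`. On the log scale the law of
total variance then separates exactly:

    σ_T² = σ_α² + σ_W²,      R²_α = σ_α²/σ_T².

The package works exclusively on log-transformed values; on the raw scale
the within-subpopulation variance depends on α and the decomposition gains
a cross term, so raw-scale analysis is not offered (the inference layer
accepts raw cohort means only through the documented log-fold-ratio
approximation).

### Sorted-cohort relaxation

Sorting a percentile window of expression indirectly selects
subpopulations. After isolation, each cell relaxes to its own
subpopulation's stationary distribution: the among-subpopulation part of a
cohort's mean offset persists forever, the within part decays. The
high–low cohort-mean contrast is modelled as

    Δ_{H,L}(t) = δ₀ (R²_α + (1 − R²_α) e^{−t/τ_T}),

an approximation (the true decay is a mixture of timescales) whose
effective timescale satisfies `τ_T ≈ τ + β`; in our simulations the median
relative mismatch over `τ/β ∈ {0.1, 1, 10}` and `R²_α ≤ 0.75` is ~3%,
comfortably within the ~10% typical bias the approximation is known to
carry. Two exact consequences of the fitted form are used as checks:
`Ω(∞) = R²_α` and `1 − Ω(τ_T) = (1 − e⁻¹)(1 − R²_α)`; the plateau is
reached in practice at `5 τ_T` (residual `e⁻⁵ < 1%`).

## Numerical choices

**Integrator.** Exact OU transition for `y`
(`y ← y e^{−dt/τ} + σ sqrt(1 − e^{−2dt/τ}) ξ`) and exact
integrating-factor update for `x` with `z` frozen over the substep
(`x ← x e^{−dt/β} + αβz(1 − e^{−dt/β})`). The substep is
`min(τ, β)/20`. The scheme is unconditionally positive in `x` and stable
for stiff `τ/β`; the only discretisation error is freezing `z`, which is
first-order in the substep and negligible at the chosen resolution.
`σ = 0` is treated as the deterministic limit `z ≡ 1` in closed form, with
no simulation and no random draws.

**Stationary initialisation.** `y` is drawn from its exact stationary law
N(0, σ²), `x` is started at the quasi-static level `αβz`, and the ensemble
is relaxed for a burn-in of `10·max(τ, β)` (shorter burn-ins are honoured
but recorded as warnings on the result, never silently).

**Calibration of σ.** `calibrate_sigma` inverts `g` by Brent root finding
on a *common-random-numbers* simulator: every objective evaluation reuses
the identical noise stream, so σ ↦ v_log is deterministic and smooth. The
default bracket σ ∈ [10⁻³, 3] is expanded geometrically when the target
lies outside it. Each evaluation pools 8 snapshots spaced `2(τ + β)` apart
(beyond the autocorrelation time of log x) over 4000 cells, giving a
Monte-Carlo SE of ≈0.8% on v_log. The returned σ is re-validated with an
independent seed; because the validation measurement itself carries
Monte-Carlo error of the same order as the 1% relative target tolerance,
the validation band is `tol·target + 3·SE` — tightening it below the
sampling noise of any affordable ensemble would only produce false alarms.

**Population construction.** Cell counts per subpopulation are multinomial
with *equal* probabilities 1/N — the simplest allocation that makes
frequencies independent of subpopulation means, the condition under which
the between/within decomposition holds without cross terms. `μ_α` is set
to `mean_log_level − log β + σ_W²/2` so the full-population log-mean hits
the requested level (default 0; instrument-like offsets belong to the
fixture generator). A single σ calibration is shared by all subpopulations.

**Sorting.** Percentile windows are half-open `[p1, p2)` on the ranked
sorting measurement, ties broken by stable cell index (the convention is
arbitrary; only window mass matters at these population sizes). Default
sorting is noiseless; a log-normal sorting-noise mode and a
"reuse-the-sorting-measurement at t = 0" quantification mode exist to
demonstrate the regression-to-the-mean bias, which strictly lowers the
fitted R²_α relative to the independent-measurement protocol. Replicate
splitting is random without replacement; replicates under 50 cells warn.

**Fitting.** Δ(t) is fitted (not Ω — normalising by the noisy Δ(0) would
correlate the points); per-experiment δ₀ absorbs gate-placement variation.
Multi-start trust-region least squares: 20 starts, δ₀ jittered around the
observed Δ(0), R²_α uniform on [0, 1], τ_T log-uniform between a tenth of
the smallest time spacing and ten times the horizon; bounds R²_α ∈ [0, 1],
τ_T positive; best SSR wins, ties to the smaller τ_T. The degenerate
boundary R²_α = 1 (flat series, τ_T undefined) has the closed form
δ₀ = mean(Δ) and is compared explicitly against the best interior start,
then flagged; boundary estimates are always flagged rather than silently
reported. Ensemble fits scale each experiment's residuals by `1/√n_e`
(equal total weight per experiment); scenario 4 (all experiments
independent) pools per-experiment fits under the same weighting.

**Model selection.** `AICc = n ln(SSR/n) + 2K + 2K(K+1)/(n−K−1)` with
`K = k + 1`, counting the residual variance as an effective parameter; SSR
is the weighted objective (a uniform rescaling, so ΔAICc between scenarios
is unaffected by the weighting when experiments are equally sized). ΔAICc
is reported against scenario 1. For the standard 2-population ×
3-experiment layout the parameter counts are 8, 9, 10, 18 for scenarios
1–4.

**Bootstrap.** Default unit: time points, resampled with replacement
within each experiment independently (the t = 0 anchor is always retained
so Δ(0) stays defined), then the ensemble is refitted; percentile
intervals, R²_α clipped to [0, 1]. A replicate-level unit (resampling
replicates within each experiment × cohort of the tidy summary) is
available behind a flag, since which unit the sampling distribution should
reflect is a design choice, not a fact. More than 20% failed refits
triggers a warning. At ~10 time points per experiment the percentile
method shows its usual mild undercoverage (~90% observed for a nominal
95% in our simulations); the coverage test bands this expectation rather
than pretending exact nominality.

**Randomness.** Every routine takes an integer seed; independent labelled
streams are derived via `SeedSequence(seed, spawn_key=crc32(labels))`
(`stablevar._random.spawn`), so sorting noise, quantification noise,
replicate splitting and trajectory noise never share draws, and all
outputs are bit-reproducible for a given seed.

## Synthetic fixtures

`generate_ensemble` emulates the *structure* of a sorted-cohort
time-course study on T-cell receptor expression: two biological
populations — "polyclonal" (default true R²_α = 0.70, σ_T = 0.30) and
"monoclonal" (R²_α = 0.20, σ_T = 0.22, the smaller spread matching the
qualitative ordering seen in genetically uniform populations) — sharing
τ + β = 32 h (τ = 28, β = 4); 3 experiments per population; 10% high/low
cohorts in 3 replicates; snapshots at 0/24/48/72/96 h; independent
quantification noise (log-SD 0.02, a plausible per-well staining
variation); and exponential, expression-independent cell death with a 24 h
half-life, so viable-cell counts collapse over 3–4 days and late
replicates go jagged or missing, as unstimulated primary cells do. Default
fixture populations use 2×10⁴ cells / 500 subpopulations.

What the generator does **not** emulate: cytometer optics and gating
artifacts, cell division, expression-*dependent* death (independence is an
explicit assumption; if death correlated with expression level, late
cohort means would be biased in a way these fixtures cannot reveal),
day-to-day instrument scale drift (the inference is provably invariant to
it, and a test asserts that), and multimodal or hierarchical population
structure. Passing tests on these fixtures therefore validate the
machinery and its statistical behaviour under the model's own assumptions
— they do not certify the exponential-relaxation approximation on real
populations that violate mixture stationarity.

## Problem sizes

Simulation-backed tests and the acceptance script run populations of 10⁵
cells / 2×10³ subpopulations (pipeline recovery, degenerate limits),
5×10⁴ / 10³ (the τ_T-vs-τ+β grid) and fixture-scale ensembles — sizes at
which the Monte-Carlo error of a fitted plateau is ~1 percentage point,
an order of magnitude below the tolerances being asserted, and a full
pipeline run takes seconds. The builder's own defaults (1.2×10⁶ cells,
2×10⁴ subpopulations) reproduce the reference in-silico setup when more
precision is wanted.

## Known limitations

- The exponential form of Δ(t) is an approximation; its bias on τ_T grows
  toward `τ/β ≈ 1` (we observe up to ~15% there) and the fitted τ_T is
  undefined at R²_α = 1.
- `g` is simulation-defined; calibration accuracy is bounded by
  Monte-Carlo noise (~1% relative on σ_W² at default settings).
- No cell division, content partitioning, or flow between subpopulations;
  the stable component is permanent by construction.
- The cohort-variance time series is reported for exploration only; no
  estimator of R²_α is derived from it.
- Raw-scale (untransformed) variance decomposition is out of scope.
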