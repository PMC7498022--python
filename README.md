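# stablevar

Partition the variance of single-cell expression levels into a **stable**
component — permanent differences between cells — and an **unstable**
component — fluctuations that relax over time — from the dynamics of sorted
cell cohorts.

## The problem

Flow-cytometry histograms of a protein (say, the T-cell receptor on CD4
T cells) are broad: cells in one population can differ ten-fold in
expression. How much of that spread reflects *persistent* differences
(genetic diversity, stable epigenetic states) and how much is *transient*
noise that any one cell wanders through? Juxtaposing histograms of sorted
cells before and after reculture cannot answer this quantitatively.

`stablevar` implements a quantitative framework for this question. A cell
population is modelled as a mixture of subpopulations; each cell stays in
its subpopulation forever. On the log scale the law of total variance
separates exactly,

    σ_T² = σ_α² + σ_W²,

where σ_α² is the variance *among* subpopulation mean levels (the stable
component) and σ_W² the variance *within* subpopulations (the unstable
component). The single parameter of interest is the **stable fraction**

    R²_α = σ_α² / σ_T²  ∈ [0, 1].

Within a subpopulation, protein amount x follows a stochastic production /
first-order-decay model,

    dx/dt = α·z − x/β,      z = exp(y − σ²/2),

with y an Ornstein–Uhlenbeck process of relaxation time τ and stationary
variance σ², so the normalised production rate z is lognormal with mean 1.
The subpopulations differ only in their mean production rate α, with
log α ~ N(μ_α, σ_α).

**The measurable consequence:** sort out "high" and "low" expressor cohorts
(top and bottom 10%), reculture them, and track the difference of their
mean log expression, Δ_{H,L}(t). It decays approximately exponentially,

    Δ_{H,L}(t) = δ₀ · (R²_α + (1 − R²_α)·exp(−t/τ_T)),      τ_T ≈ τ + β,

so the normalised contrast Ω(t) = Δ(t)/Δ(0) plateaus exactly at R²_α, and
the relaxation time τ_T measures the fluctuation timescale. Fitting this
three-parameter model to cohort-mean time series — jointly across
experiments and biological populations, with AICc model selection over
parameter-sharing scenarios and per-experiment bootstrap confidence
intervals — yields R²_α and τ_T with quantified uncertainty.

## What is in the package

| module | contents |
|---|---|
| `stablevar.stochastic_cell` | exact-transition OU + exponential-integrator cell simulator; stationary log-moments; calibration of σ to a target σ_W² |
| `stablevar.population_mixture` | variance decomposition; mixture-population builder; empirical between/within summary |
| `stablevar.cohort_experiment` | percentile sorting (with optional sorting noise), replicate splitting, relaxation snapshots, independent quantification noise |
| `stablevar.inference` | Δ/Ω series, multi-start nonlinear least squares, scenario fits, AICc comparison, bootstrap CIs, cohort-variance tracking |
| `stablevar.synthetic_data` | fully synthetic two-population experiment ensembles with ground-truth manifests; exact worked-example tables |
| `stablevar.cli` | `stablevar` command: simulate-population, sort-evolve, fit, select-scenarios, bootstrap, make-fixtures |

## Worked example

An exact relaxation table with δ₀ = 0.5, R²_α = 0.25, τ_T = 55, and its
round-trip fit:

```python
import stablevar as sv

table = sv.generate_worked_example(delta0=0.5, r2=0.25, tau_T=55.0)
print(table.to_string(index=False))
ds = sv.DeltaSeries(times=table["t"].values, delta=table["delta"].values)
fit = sv.fit_single(ds, seed=0)
print(fit.delta0["exp1"], fit.r2["pop1"], fit.tau_T["pop1"])
```

```
    t    delta    omega
  0.0 0.500000 1.000000
 27.5 0.352449 0.704898
 55.0 0.262955 0.525910
 82.5 0.208674 0.417348
110.0 0.175751 0.351501
165.0 0.143670 0.287340
275.0 0.127527 0.255053
550.0 0.125017 0.250034
0.5 0.25 54.999997
```

The `omega` column starts at exactly 1 and plateaus at the stable fraction
0.25; the fit recovers all three generating parameters to optimizer
tolerance.

A full in-silico experiment — build a σ_T = 0.3 population with
R²_α = 0.25 (τ = 50, β = 5), gate the 10% tails, relax to 5·(τ+β) and fit:

```python
import numpy as np, stablevar as sv

sigma = sv.calibrate_sigma(0.75 * 0.09, tau=50, beta=5, seed=3)
pop = sv.build_population(vT=0.09, r2=0.25, tau=50, beta=5,
                          n_subpops=2000, n_cells=100_000, seed=1, sigma=sigma)
summary = sv.run_sort_relax_experiment(pop, np.linspace(0, 275, 12), seed=2)
fit = sv.fit_single(sv.delta_from_summary(summary)[0], seed=4)
print(fit.r2["pop1"], fit.tau_T["pop1"])   # -> 0.236 56.7
```

The fitted plateau (23.6%) matches the built stable fraction (25%) within
Monte-Carlo error of one run, and τ_T ≈ 56.7 ≈ τ + β = 55.

The same pipeline from the shell:

```bash
stablevar make-fixtures --seed 42 --out fixtures/
stablevar select-scenarios fixtures/ensemble.csv --seed 2 --out results/
stablevar bootstrap fixtures/ensemble.csv --scenario 2 --seed 3 --out results/boot.json
```

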