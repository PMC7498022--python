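"""Estimation of the stable variance fraction R2_alpha and timescale tau_T.

The observable is the difference between the mean log expression of two
sorted cohorts (high minus low),

    Delta_HL(t) = mu_H(t) - mu_L(t),        Omega_HL(t) = Delta(t) / Delta(0).

Delta decays approximately exponentially from Delta(0) to
R2_alpha * Delta(0) with an effective timescale tau_T ~= tau + beta, so the
three-parameter model fitted to each experiment's Delta series is

    Delta(t) = delta0 * (R2 + (1 - R2) * exp(-t / tau_T)),

with delta0 the fitted "true" initial contrast.  Fitting is done on Delta
(not Omega) so data points stay statistically independent; Omega is for
display.  Ensembles of experiments from multiple biological populations are
fitted jointly under four parameter-sharing scenarios, compared by
small-sample-corrected AIC, with per-experiment bootstrap confidence
intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._random import spawn
from .cohort_experiment import CohortSnapshot

__all__ = [
    "DeltaSeries",
    "ScenarioSpec",
    "FitResult",
    "delta_model",
    "compute_delta",
    "delta_from_summary",
    "fit_single",
    "fit_ensemble",
    "aicc",
    "aicc_compare",
    "bootstrap_ci",
    "track_cohort_variance",
]

R2_BOUNDARY_TOL = 1e-6


@dataclass
class DeltaSeries:
    """Cohort-contrast time series for one experiment.

    ``delta`` holds Delta_HL(t) = (replicate-averaged mean log of the high
    cohort) minus (same for low).  Requires Delta(0) != 0.
    """

    times: np.ndarray
    delta: np.ndarray
    experiment_id: str = "exp1"
    population_id: str = "pop1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.times.shape != self.delta.shape:
            raise ValueError("times and delta must have equal length")
        if 0.0 not in self.times:
            raise ValueError("series must include t = 0")
        if self.delta0 == 0.0:
            raise ValueError("Delta(0) must be non-zero")

    @property
    def delta0(self) -> float:
        return float(self.delta[np.argmin(np.abs(self.times))])

    @property
    def omega(self) -> np.ndarray:
        return self.delta / self.delta0

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameter-sharing layout for joint fits over two or more populations.

    delta0 is always per experiment.  The four standard scenarios:

    1. R2 and tau_T shared across populations (null model);
    2. R2 per population, tau_T shared;
    3. R2 and tau_T both per population;
    4. every experiment fitted independently (lower bound on the residual).
    """

    scenario_id: int
    share_r2: bool
    share_tau: bool
    independent: bool = False

    @classmethod
    def from_id(cls, scenario_id: int) -> "ScenarioSpec":
        table = {
            1: cls(1, share_r2=True, share_tau=True),
            2: cls(2, share_r2=False, share_tau=True),
            3: cls(3, share_r2=False, share_tau=False),
            4: cls(4, share_r2=False, share_tau=False, independent=True),
        }
        if scenario_id not in table:
            raise ValueError("scenario_id must be 1, 2, 3 or 4")
        return table[scenario_id]

    def param_count(self, n_experiments: int, n_populations: int) -> int:
        if self.independent:
            return 3 * n_experiments
        k = n_experiments  # delta0 per experiment
        k += 1 if self.share_r2 else n_populations
        k += 1 if self.share_tau else n_populations
        return k


@dataclass
class FitResult:
    """Result of a single- or ensemble-fit of the relaxation model."""

    delta0: dict[str, float]           # per experiment_id
    r2: dict[str, float]               # per population_id (or 'shared')
    tau_T: dict[str, float]            # per population_id (or 'shared')
    ssr: float                         # weighted SSR (the minimised objective)
    ssr_unweighted: float
    n_points: int
    k: int                             # fitted parameters (AICc adds +1)
    scenario_id: int | None = None
    aicc: float | None = None
    boundary_flags: dict[str, str] = field(default_factory=dict)
    tau_defined: dict[str, bool] = field(default_factory=dict)
    success: bool = True

    def single_r2(self) -> float:
        (value,) = set(self.r2.values()) if len(set(self.r2.values())) == 1 else (None,)
        if value is None:
            raise ValueError("fit has multiple distinct r2 values")
        return value


def delta_model(
    t: np.ndarray | float, delta0: float, r2: float, tau_T: float
) -> np.ndarray | float:
    """Relaxation model delta0 * (r2 + (1 - r2) * exp(-t / tau_T))."""
    return delta0 * (r2 + (1.0 - r2) * np.exp(-np.asarray(t, dtype=float) / tau_T))


def compute_delta(
    high_series: pd.DataFrame,
    low_series: pd.DataFrame,
    experiment_id: str = "exp1",
    population_id: str = "pop1",
    from_raw_means: bool = False,
) -> DeltaSeries:
    """Build Delta_HL(t) from per-replicate cohort summaries.

    Both inputs need columns (t, mean_log) — replicates are averaged per
    time point — and matching time grids.  ``from_raw_means=True`` accepts
    raw-scale cohort means in a ``raw_mean`` column and uses the log of
    their fold-ratio instead (an approximation to the mean-log difference
    that is exact when the two cohorts have equal log-scale variances).
    """
    col = "raw_mean" if from_raw_means else "mean_log"
    h = high_series.groupby("t", sort=True)[col].mean()
    l = low_series.groupby("t", sort=True)[col].mean()
    if not np.array_equal(h.index.values, l.index.values):
        raise ValueError("high and low series must share the same time grid")
    if from_raw_means:
        delta = np.log(h.values) - np.log(l.values)
    else:
        delta = h.values - l.values
    return DeltaSeries(
        times=h.index.values.astype(float),
        delta=delta,
        experiment_id=experiment_id,
        population_id=population_id,
    )


def delta_from_summary(summary: pd.DataFrame, from_raw_means: bool = False) -> list[DeltaSeries]:
    """Split a tidy summary frame into one DeltaSeries per experiment.

    Expects the schema written by the cohort-experiment layer:
    experiment_id, population_id, cohort in {high, low}, replicate, t,
    mean_log (or raw_mean), n.
    """
    out: list[DeltaSeries] = []
    for (exp_id, pop_id), grp in summary.groupby(
        ["experiment_id", "population_id"], sort=True
    ):
        high = grp[grp["cohort"] == "high"]
        low = grp[grp["cohort"] == "low"]
        if high.empty or low.empty:
            raise ValueError(f"experiment {exp_id!r} lacks a high or low cohort")
        out.append(
            compute_delta(
                high, low, experiment_id=str(exp_id), population_id=str(pop_id),
                from_raw_means=from_raw_means,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Nonlinear least squares


def _tau_start_grid(series: list[DeltaSeries]) -> tuple[float, float]:
    """(low, high) range for log-uniform tau_T starting values."""
    dts = np.concatenate([np.diff(np.sort(s.times)) for s in series])
    t_max = max(float(s.times.max()) for s in series)
    dt_min = float(dts[dts > 0].min())
    return dt_min / 10.0, 10.0 * t_max


def _fit_nls(
    series: list[DeltaSeries],
    scenario: ScenarioSpec,
    starts: int,
    seed: int,
    weighted: bool,
) -> FitResult:
    """Joint NLS over an ensemble of Delta series under a sharing layout."""
    exp_ids = [s.experiment_id for s in series]
    pop_ids = sorted({s.population_id for s in series})
    n_exp, n_pop = len(series), len(pop_ids)
    pop_of = {s.experiment_id: s.population_id for s in series}

    r2_index = {p: (0 if scenario.share_r2 else i) for i, p in enumerate(pop_ids)}
    n_r2 = 1 if scenario.share_r2 else n_pop
    tau_index = {p: (0 if scenario.share_tau else i) for i, p in enumerate(pop_ids)}
    n_tau = 1 if scenario.share_tau else n_pop

    weights = np.concatenate(
        [np.full(s.n, 1.0 / math.sqrt(s.n) if weighted else 1.0) for s in series]
    )
    all_t = np.concatenate([s.times for s in series])
    all_delta = np.concatenate([s.delta for s in series])
    exp_slice_idx = np.repeat(np.arange(n_exp), [s.n for s in series])

    tau_lo_b, tau_hi_b = _tau_start_grid(series)
    tau_bounds = (tau_lo_b / 100.0, tau_hi_b * 100.0)

    def unpack(theta: np.ndarray):
        d0 = theta[:n_exp]
        r2 = theta[n_exp:n_exp + n_r2]
        tau = theta[n_exp + n_r2:n_exp + n_r2 + n_tau]
        return d0, r2, tau

    def residuals(theta: np.ndarray) -> np.ndarray:
        d0, r2, tau = unpack(theta)
        r2_cell = np.array([r2[r2_index[pop_of[e]]] for e in exp_ids])
        tau_cell = np.array([tau[tau_index[pop_of[e]]] for e in exp_ids])
        model = (
            d0[exp_slice_idx]
            * (r2_cell[exp_slice_idx]
               + (1.0 - r2_cell[exp_slice_idx]) * np.exp(-all_t / tau_cell[exp_slice_idx]))
        )
        return (model - all_delta) * weights

    lb = np.concatenate([np.full(n_exp, -np.inf), np.zeros(n_r2), np.full(n_tau, tau_bounds[0])])
    ub = np.concatenate([np.full(n_exp, np.inf), np.ones(n_r2), np.full(n_tau, tau_bounds[1])])

    rng = spawn(seed, "fit", scenario.scenario_id or 0)
    d0_obs = np.array([s.delta0 for s in series])
    best = None
    for i in range(max(1, starts)):
        if i == 0:
            theta0 = np.concatenate(
                [d0_obs, np.full(n_r2, 0.5),
                 np.full(n_tau, max(all_t.max() / 2.0, tau_bounds[0] * 2))]
            )
        else:
            theta0 = np.concatenate(
                [
                    d0_obs * (1.0 + 0.2 * rng.standard_normal(n_exp)),
                    rng.uniform(0.0, 1.0, n_r2),
                    np.exp(rng.uniform(math.log(tau_lo_b), math.log(tau_hi_b), n_tau)),
                ]
            )
        try:
            sol = least_squares(residuals, theta0, bounds=(lb, ub), method="trf")
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if not sol.success:
            continue
        ssr = float(np.sum(sol.fun**2))
        tau_sol = unpack(sol.x)[2]
        if best is None or ssr < best[0] - 1e-12 or (
            abs(ssr - best[0]) <= 1e-12 and float(np.max(tau_sol)) < float(np.max(best[2]))
        ):
            best = (ssr, sol.x, tau_sol)
    if best is None:
        raise RuntimeError("all optimizer starts failed to converge")

    # Degenerate boundary candidate r2 = 1 (flat model): closed-form
    # delta0_e = mean(Delta_e).  A flat series otherwise stalls the
    # optimizer in the flat-gradient valley just inside the bound.
    flat_theta = np.concatenate(
        [
            np.array([float(s.delta.mean()) for s in series]),
            np.ones(n_r2),
            np.full(n_tau, math.sqrt(tau_bounds[0] * tau_bounds[1])),
        ]
    )
    flat_ssr = float(np.sum(residuals(flat_theta) ** 2))
    if flat_ssr <= best[0]:
        best = (flat_ssr, flat_theta, unpack(flat_theta)[2])

    ssr_w, theta, _ = best
    d0, r2, tau = unpack(theta)
    raw_resid = residuals(theta) / weights
    ssr_unw = float(np.sum(raw_resid**2))

    r2_out = {p: float(r2[r2_index[p]]) for p in pop_ids}
    tau_out = {p: float(tau[tau_index[p]]) for p in pop_ids}
    flags: dict[str, str] = {}
    tau_defined: dict[str, bool] = {}
    for p in pop_ids:
        at_one = r2_out[p] >= 1.0 - R2_BOUNDARY_TOL
        at_zero = r2_out[p] <= R2_BOUNDARY_TOL
        if at_one:
            flags[p] = "r2 at upper bound; tau_T undefined"
        elif at_zero:
            flags[p] = "r2 at lower bound"
        tau_defined[p] = not at_one
    return FitResult(
        delta0={e: float(v) for e, v in zip(exp_ids, d0)},
        r2=r2_out,
        tau_T=tau_out,
        ssr=ssr_w,
        ssr_unweighted=ssr_unw,
        n_points=int(all_t.size),
        k=scenario.param_count(n_exp, n_pop),
        scenario_id=scenario.scenario_id,
        boundary_flags=flags,
        tau_defined=tau_defined,
    )


def fit_single(series: DeltaSeries, starts: int = 20, seed: int = 0) -> FitResult:
    """Fit the three-parameter relaxation model to one Delta series.

    Multi-start NLS (default 20 starts: delta0 jittered around the observed
    Delta(0), r2 uniform in [0, 1], tau_T log-uniform between a tenth of the
    smallest time spacing and ten times the horizon); best SSR wins, ties
    broken by the smaller tau_T.  An r2 estimate pinned at 1 flags tau_T as
    undefined (a flat series carries no timescale information).
    """
    if series.n < 4:
        raise ValueError("need at least 4 time points to fit 3 parameters")
    scenario = ScenarioSpec(scenario_id=0, share_r2=True, share_tau=True)
    res = _fit_nls([series], scenario, starts=starts, seed=seed, weighted=False)
    res.k = 3
    res.scenario_id = None
    return res


def fit_ensemble(
    experiments: list[DeltaSeries],
    scenario: ScenarioSpec | int,
    starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Joint fit of several experiments under a parameter-sharing scenario.

    Residuals of experiment e are scaled by 1 / sqrt(n_e) so every
    experiment contributes equal total weight regardless of its number of
    time points.  Scenario 4 fits each experiment independently and pools
    the (equally weighted) residuals.
    """
    if isinstance(scenario, int):
        scenario = ScenarioSpec.from_id(scenario)
    if not experiments:
        raise ValueError("need at least one experiment")
    if scenario.independent:
        parts = [
            _fit_nls([s], ScenarioSpec(4, False, False), starts=starts,
                     seed=seed + j, weighted=False)
            for j, s in enumerate(experiments)
        ]
        delta0, flags, tau_defined = {}, {}, {}
        r2, tau = {}, {}
        ssr_w = ssr_unw = 0.0
        for s, part in zip(experiments, parts):
            delta0.update(part.delta0)
            # keyed per experiment since nothing is shared
            r2[s.experiment_id] = part.r2[s.population_id]
            tau[s.experiment_id] = part.tau_T[s.population_id]
            if s.population_id in part.boundary_flags:
                flags[s.experiment_id] = part.boundary_flags[s.population_id]
            tau_defined[s.experiment_id] = part.tau_defined[s.population_id]
            ssr_w += part.ssr / s.n
            ssr_unw += part.ssr_unweighted
        return FitResult(
            delta0=delta0, r2=r2, tau_T=tau, ssr=ssr_w, ssr_unweighted=ssr_unw,
            n_points=sum(s.n for s in experiments),
            k=scenario.param_count(len(experiments), len({s.population_id for s in experiments})),
            scenario_id=4, boundary_flags=flags, tau_defined=tau_defined,
        )
    return _fit_nls(experiments, scenario, starts=starts, seed=seed, weighted=True)


# ---------------------------------------------------------------------------
# Model selection


def aicc(ssr: float, n: int, k_fitted: int) -> float:
    """Small-sample-corrected AIC for a least-squares fit.

    K = k_fitted + 1 counts the residual variance as an extra effective
    parameter:  AICc = n ln(SSR / n) + 2K + 2K(K+1) / (n - K - 1).
    """
    K = k_fitted + 1
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for K={K}")
    return n * math.log(ssr / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def aicc_compare(fits: list[FitResult]) -> pd.DataFrame:
    """Tabulate AICc across scenario fits of the same data ensemble.

    Delta-AICc is reported relative to scenario 1 when present (otherwise
    relative to the minimum); the smallest value marks the preferred
    scenario.
    """
    if len({f.n_points for f in fits}) != 1:
        raise ValueError("all fits must be on the same ensemble (equal n)")
    rows = []
    for f in fits:
        f.aicc = aicc(f.ssr, f.n_points, f.k)
        rows.append(
            {
                "scenario": f.scenario_id,
                "ssr": f.ssr,
                "k": f.k,
                "aicc": f.aicc,
            }
        )
    table = pd.DataFrame(rows)
    ref_rows = table[table["scenario"] == 1]
    ref = float(ref_rows["aicc"].iloc[0]) if len(ref_rows) else float(table["aicc"].min())
    table["delta_aicc"] = table["aicc"] - ref
    table["best"] = table["aicc"] == table["aicc"].min()
    return table


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_ci(
    experiments: list[DeltaSeries],
    scenario: ScenarioSpec | int,
    n_boot: int = 1000,
    level: float = 95.0,
    seed: int = 0,
    starts: int = 5,
    unit: str = "timepoint",
    summary: pd.DataFrame | None = None,
) -> dict:
    """Percentile bootstrap confidence intervals for r2 and tau_T.

    Each experiment is resampled separately, then the ensemble is refitted.
    ``unit='timepoint'`` (default) resamples time points with replacement
    within each experiment; ``unit='replicate'`` resamples replicates within
    each (experiment, cohort) of the tidy ``summary`` frame and rebuilds the
    Delta series.  r2 intervals are clipped to [0, 1].  More than 20% failed
    refits triggers a warning.
    """
    if isinstance(scenario, int):
        scenario = ScenarioSpec.from_id(scenario)
    if unit not in ("timepoint", "replicate"):
        raise ValueError("unit must be 'timepoint' or 'replicate'")
    if unit == "replicate" and summary is None:
        raise ValueError("replicate-level bootstrap needs the tidy summary frame")
    point = fit_ensemble(experiments, scenario, seed=seed)
    rng = spawn(seed, "bootstrap")
    r2_draws: dict[str, list[float]] = {p: [] for p in point.r2}
    tau_draws: dict[str, list[float]] = {p: [] for p in point.tau_T}
    failures = 0
    for b in range(n_boot):
        try:
            if unit == "timepoint":
                resampled = []
                for s in experiments:
                    idx = rng.integers(0, s.n, size=s.n)
                    if 0.0 not in s.times[idx] or s.delta[idx][
                        np.argmin(np.abs(s.times[idx]))
                    ] == 0.0:
                        # keep the t=0 anchor so Delta(0) stays defined
                        idx[0] = int(np.argmin(np.abs(s.times)))
                    resampled.append(
                        DeltaSeries(
                            times=s.times[idx], delta=s.delta[idx],
                            experiment_id=s.experiment_id,
                            population_id=s.population_id,
                        )
                    )
            else:
                parts = []
                for (exp_id, pop_id, cohort), grp in summary.groupby(
                    ["experiment_id", "population_id", "cohort"], sort=True
                ):
                    reps = grp["replicate"].unique()
                    chosen = rng.choice(reps, size=reps.size, replace=True)
                    parts.extend(
                        grp[grp["replicate"] == r].assign(replicate=j)
                        for j, r in enumerate(chosen)
                    )
                resampled = delta_from_summary(pd.concat(parts, ignore_index=True))
            fit = fit_ensemble(resampled, scenario, starts=starts, seed=seed + 1000 + b)
        except Exception:  # noqa: BLE001 - failed replicate counted, not fatal
            failures += 1
            continue
        for p in r2_draws:
            r2_draws[p].append(fit.r2[p])
            tau_draws[p].append(fit.tau_T[p])
    if failures > 0.2 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap replicates failed to fit", stacklevel=2
        )
    lo_q, hi_q = (100.0 - level) / 2.0, 100.0 - (100.0 - level) / 2.0
    out = {
        "point": point,
        "n_boot": n_boot,
        "failures": failures,
        "level": level,
        "r2_ci": {},
        "tau_T_ci": {},
    }
    for p in r2_draws:
        draws = np.asarray(r2_draws[p])
        lo, hi = np.percentile(draws, [lo_q, hi_q])
        out["r2_ci"][p] = (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))
        tlo, thi = np.percentile(np.asarray(tau_draws[p]), [lo_q, hi_q])
        out["tau_T_ci"][p] = (float(tlo), float(thi))
    return out


def track_cohort_variance(snapshots: list[CohortSnapshot]) -> pd.DataFrame:
    """Empirical per-cohort log-variance over time (exploratory only).

    Returns a tidy frame (cohort, replicate, t, var_log, n); no ratio
    estimator is derived from it.
    """
    rows = [
        {
            "cohort": s.label,
            "replicate": s.replicate,
            "t": s.t,
            "var_log": float(s.log_x.var()),
            "n": s.n,
        }
        for s in snapshots
    ]
    return pd.DataFrame(rows)
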