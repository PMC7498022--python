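"""In-silico cell-sorting experiment: isolate percentile cohorts, evolve, snapshot.

Mirrors a FACS sort-and-reculture design: cells are ranked on a sorting
measurement (true log expression plus optional sorting noise), a percentile
window is gated out, the cohort is split into replicates, cultured without
division, and re-measured ("re-stained") at a grid of times.  The
quantification measurement carries its own noise, independent of the
sorting noise unless a correlated mode is explicitly requested — reusing
the sorting measurement is exactly the regression-to-the-mean trap this
module lets you demonstrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._random import spawn
from .population_mixture import Population
from .stochastic_cell import evolve_ensemble

__all__ = [
    "SortSpec",
    "Cohort",
    "CohortSnapshot",
    "isolate_cohort",
    "evolve_cohorts",
    "quantify_snapshot",
    "snapshots_to_summary",
    "run_sort_relax_experiment",
]

HIGH_DEFAULT = (90.0, 100.0)
LOW_DEFAULT = (0.0, 10.0)


@dataclass(frozen=True)
class SortSpec:
    """Percentile gate for sorting.

    The window [p1, p2) is half-open on the ranked order statistics; ties are
    broken by the stable cell index.  ``label='reference'`` takes a simple
    random sample of the same fraction instead of a gate.
    ``measurement_noise_sd`` is the log-scale SD of the sorting measurement
    (0 sorts on true values).
    """

    p1: float
    p2: float
    label: str = "cohort"
    measurement_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 < self.p2 <= 100.0):
            raise ValueError("need 0 <= p1 < p2 <= 100")
        if self.p1 == 0.0 and self.p2 == 100.0 and self.label != "reference":
            raise ValueError(
                "full-window gate selects the whole population; only the "
                "'reference' label may span [0, 100]"
            )
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be non-negative")

    @classmethod
    def high(cls, noise_sd: float = 0.0) -> "SortSpec":
        return cls(*HIGH_DEFAULT, label="high", measurement_noise_sd=noise_sd)

    @classmethod
    def low(cls, noise_sd: float = 0.0) -> "SortSpec":
        return cls(*LOW_DEFAULT, label="low", measurement_noise_sd=noise_sd)

    @classmethod
    def reference(cls, fraction: float = 10.0, noise_sd: float = 0.0) -> "SortSpec":
        return cls(0.0, fraction, label="reference", measurement_noise_sd=noise_sd)


@dataclass
class Cohort:
    """Cells gated out of a population, with their sorting measurements."""

    label: str
    x: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    subpop_index: np.ndarray
    sort_scores: np.ndarray  # measured log intensity used for gating
    tau: float
    beta: float
    sigma: float

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class CohortSnapshot:
    """Per-cell log expression of one cohort replicate at one time."""

    t: float
    replicate: int
    label: str
    log_x: np.ndarray
    sort_scores: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = self.log_x.size


def isolate_cohort(pop: Population, sort_spec: SortSpec, seed: int = 0) -> Cohort:
    """Gate a percentile cohort (or random reference sample) out of ``pop``."""
    if not pop.stationary:
        raise ValueError("population must be stationary before sorting")
    rng = spawn(seed, "sort", sort_spec.label)
    log_x = pop.log_x
    scores = log_x
    if sort_spec.measurement_noise_sd > 0:
        scores = log_x + sort_spec.measurement_noise_sd * rng.standard_normal(log_x.size)
    n = log_x.size
    if sort_spec.label == "reference":
        k = int(round((sort_spec.p2 - sort_spec.p1) / 100.0 * n))
        idx = rng.choice(n, size=k, replace=False)
    else:
        order = np.argsort(scores, kind="stable")
        lo = int(np.floor(sort_spec.p1 / 100.0 * n))
        hi = int(np.floor(sort_spec.p2 / 100.0 * n))
        idx = order[lo:hi]
    if idx.size == 0:
        raise ValueError(f"empty selection for window [{sort_spec.p1}, {sort_spec.p2})")
    return Cohort(
        label=sort_spec.label,
        x=pop.x[idx].copy(),
        y=pop.y[idx].copy(),
        alpha=pop.alpha_per_cell[idx].copy(),
        subpop_index=pop.subpop_index[idx].copy(),
        sort_scores=scores[idx].copy(),
        tau=pop.params.tau,
        beta=pop.params.beta,
        sigma=pop.params.sigma,
    )


def evolve_cohorts(
    cohorts: list[Cohort],
    t_grid: np.ndarray,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[CohortSnapshot]:
    """Split each cohort into replicates and record snapshots along ``t_grid``.

    Each cohort is partitioned at random (without replacement) into
    ``n_replicates`` near-equal replicates; each replicate's cells evolve
    under the single-cell model with their own subpopulation alpha_i.  No
    cell divides or dies here (death thinning is layered on by the fixture
    generator).  The grid must start at 0 so every cohort has a t = 0
    snapshot.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    snapshots: list[CohortSnapshot] = []
    for cohort in cohorts:
        rng_split = spawn(seed, "split", cohort.label)
        perm = rng_split.permutation(cohort.n)
        parts = np.array_split(perm, n_replicates)
        for rep, part in enumerate(parts):
            if part.size < 50:
                warnings.warn(
                    f"replicate {rep} of cohort '{cohort.label}' has only "
                    f"{part.size} cells; cohort means will be noisy",
                    stacklevel=2,
                )
            x = cohort.x[part].copy()
            y = cohort.y[part].copy()
            a = cohort.alpha[part]
            scores = cohort.sort_scores[part]
            rng_evo = spawn(seed, "evolve", cohort.label, rep)
            t_prev = 0.0
            for t in t_grid:
                if t > t_prev:
                    x, y = evolve_ensemble(
                        x, y, a, cohort.beta, cohort.sigma, cohort.tau,
                        t - t_prev, rng_evo,
                    )
                snapshots.append(
                    CohortSnapshot(
                        t=float(t), replicate=rep, label=cohort.label,
                        log_x=np.log(x), sort_scores=scores,
                    )
                )
                t_prev = float(t)
    return snapshots


def quantify_snapshot(
    snapshot: CohortSnapshot,
    quant_noise_sd: float = 0.0,
    seed: int = 0,
    reuse_sort_measurement: bool = False,
) -> tuple[float, float, int]:
    """Measure a snapshot: (mean_log, var_log, n) after fresh measurement noise.

    Fresh log-scale noise of SD ``quant_noise_sd`` models independent
    re-staining; its stream is keyed separately from every sorting stream.
    ``reuse_sort_measurement=True`` instead quantifies the *sorting* scores
    (a deliberately wrong protocol that inflates the t = 0 cohort contrast
    through regression to the mean).
    """
    if reuse_sort_measurement:
        vals = snapshot.sort_scores
    else:
        vals = snapshot.log_x
        if quant_noise_sd > 0:
            rng = spawn(seed, "quantify", snapshot.label, snapshot.replicate,
                        int(round(snapshot.t * 1e6)))
            vals = vals + quant_noise_sd * rng.standard_normal(vals.size)
    return float(vals.mean()), float(vals.var()), vals.size


def snapshots_to_summary(
    snapshots: list[CohortSnapshot],
    quant_noise_sd: float = 0.0,
    seed: int = 0,
    experiment_id: str = "exp1",
    population_id: str = "pop1",
    reuse_sort_measurement: bool = False,
) -> pd.DataFrame:
    """Quantify every snapshot into the tidy summary schema.

    Columns: experiment_id, population_id, cohort, replicate, t, mean_log,
    var_log, n.  With ``reuse_sort_measurement=True`` only the t = 0
    quantification reuses the sorting scores (the flawed protocol in which
    the sorter's own readout doubles as the first measurement); later
    timepoints are always freshly measured.
    """
    rows = []
    for snap in snapshots:
        mean_log, var_log, n = quantify_snapshot(
            snap, quant_noise_sd=quant_noise_sd, seed=seed,
            reuse_sort_measurement=reuse_sort_measurement and snap.t == 0.0,
        )
        rows.append(
            {
                "experiment_id": experiment_id,
                "population_id": population_id,
                "cohort": snap.label,
                "replicate": snap.replicate,
                "t": snap.t,
                "mean_log": mean_log,
                "var_log": var_log,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def run_sort_relax_experiment(
    pop: Population,
    t_grid: np.ndarray,
    seed: int = 0,
    n_replicates: int = 3,
    sort_noise_sd: float = 0.0,
    quant_noise_sd: float = 0.0,
    include_reference: bool = False,
    experiment_id: str = "exp1",
    population_id: str = "pop1",
    reuse_sort_measurement: bool = False,
) -> pd.DataFrame:
    """Convenience pipeline: sort 10% high / 10% low, evolve, quantify.

    Returns the tidy summary frame consumed by the inference layer.
    """
    specs = [SortSpec.high(sort_noise_sd), SortSpec.low(sort_noise_sd)]
    if include_reference:
        specs.append(SortSpec.reference(10.0, sort_noise_sd))
    cohorts = [isolate_cohort(pop, s, seed=seed) for s in specs]
    snapshots = evolve_cohorts(cohorts, t_grid, n_replicates=n_replicates, seed=seed)
    return snapshots_to_summary(
        snapshots, quant_noise_sd=quant_noise_sd, seed=seed,
        experiment_id=experiment_id, population_id=population_id,
        reuse_sort_measurement=reuse_sort_measurement,
    )
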