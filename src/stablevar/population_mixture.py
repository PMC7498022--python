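"""Mixture-of-subpopulations population model and its variance decomposition.

A full cell population is modelled as a mixture of N subpopulations.  Each
subpopulation i has its own mean production rate alpha_i, drawn once and
fixed (cells never change subpopulation), with log alpha ~ N(mu_alpha,
sigma_alpha).  Within a subpopulation, expression fluctuates per the
single-cell model with a shared noise level sigma, calibrated so every
subpopulation has the same stationary log-variance sigma_W**2.

On the log scale the law of total variance separates exactly:

    sigma_T**2 = sigma_alpha**2 + sigma_W**2,

and the *stable fraction* R2_alpha = sigma_alpha**2 / sigma_T**2 is the
share of total variance carried by permanent among-subpopulation
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._random import spawn
from .stochastic_cell import (
    ModelParams,
    calibrate_sigma,
    sample_stationary_ensemble,
)

__all__ = [
    "VarianceDecomposition",
    "SubPopulation",
    "Population",
    "decompose_variance",
    "build_population",
    "population_summary",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Split of total log-variance vT into among (vA) and within (vW) parts.

    Invariants: vT = vA + vW exactly; r2 = vA / vT in [0, 1].
    """

    vT: float
    vA: float
    vW: float
    r2: float


@dataclass(frozen=True)
class SubPopulation:
    index: int
    alpha_i: float
    n_i: int
    w_i: float
    mu_i_log: float  # log(alpha_i * beta) - vW / 2
    v_i_log: float   # sigma_W**2, identical across subpopulations


@dataclass
class Population:
    """A realized stationary population of cells grouped into subpopulations."""

    decomposition: VarianceDecomposition
    params: ModelParams          # template: alpha field holds exp(mu_alpha)
    mu_alpha: float
    n_subpops: int
    n_cells: int
    subpopulations: list[SubPopulation]
    x: np.ndarray                # protein amount per cell
    y: np.ndarray                # latent OU value per cell
    subpop_index: np.ndarray     # subpopulation id per cell
    alpha_per_cell: np.ndarray
    stationary: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def log_x(self) -> np.ndarray:
        return np.log(self.x)

    def cells_frame(self) -> pd.DataFrame:
        """Snapshot export: one row per cell."""
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "subpop_id": self.subpop_index,
                "log_x": self.log_x,
            }
        )

    def subpopulations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subpop_id": [s.index for s in self.subpopulations],
                "alpha_i": [s.alpha_i for s in self.subpopulations],
                "n_i": [s.n_i for s in self.subpopulations],
                "w_i": [s.w_i for s in self.subpopulations],
            }
        )


def decompose_variance(vT: float, r2: float) -> VarianceDecomposition:
    """Split total log-variance ``vT`` by the stable fraction ``r2``.

    vA = r2 * vT (among-subpopulation), vW = (1 - r2) * vT (within).
    """
    if vT <= 0:
        raise ValueError("vT must be strictly positive")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    vA = r2 * vT
    return VarianceDecomposition(vT=vT, vA=vA, vW=vT - vA, r2=r2)


def build_population(
    vT: float,
    r2: float,
    tau: float,
    beta: float,
    n_subpops: int = 20_000,
    n_cells: int = 1_200_000,
    mean_log_level: float = 0.0,
    seed: int = 0,
    sigma: float | None = None,
    burn_in_factor: float = 10.0,
    calibration_kwargs: dict | None = None,
) -> Population:
    """Build a stationary mixture population with the requested decomposition.

    Steps: split vT into (vA, vW); calibrate the single-cell noise sigma to
    vW (shared across subpopulations; pass ``sigma`` to reuse a previous
    calibration); draw log alpha_i i.i.d. N(mu_alpha, sqrt(vA)) with
    mu_alpha = mean_log_level - log(beta) + vW / 2 so that
    E[log x] = mean_log_level; allocate cells to subpopulations by a
    multinomial with equal probabilities 1/N (which guarantees frequencies
    are uncorrelated with subpopulation means, as the law-of-total-variance
    split requires); initialise every cell at its subpopulation's
    stationary distribution.

    Defaults (N = 2e4 subpopulations, 1.2e6 cells) match the reference
    in-silico sorting setup; scale down for interactive use.
    """
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    if n_cells < n_subpops:
        raise ValueError("n_cells must be >= n_subpops")
    dec = decompose_variance(vT, r2)
    if sigma is None:
        sigma = calibrate_sigma(
            dec.vW, tau=tau, beta=beta, seed=seed, **(calibration_kwargs or {})
        )
    sigma_alpha = math.sqrt(dec.vA)
    mu_alpha = mean_log_level - math.log(beta) + dec.vW / 2.0

    rng_alpha = spawn(seed, "population", "alpha")
    rng_counts = spawn(seed, "population", "counts")
    rng_cells = spawn(seed, "population", "cells")

    log_alpha = mu_alpha + sigma_alpha * rng_alpha.standard_normal(n_subpops)
    alpha_i = np.exp(log_alpha)
    n_i = rng_counts.multinomial(n_cells, np.full(n_subpops, 1.0 / n_subpops))
    w_i = n_i / n_cells

    subpop_index = np.repeat(np.arange(n_subpops), n_i)
    alpha_per_cell = alpha_i[subpop_index]

    params = ModelParams(alpha=float(np.exp(mu_alpha)), beta=beta, sigma=sigma, tau=tau)
    burn_in = burn_in_factor * max(tau, beta)
    notes: list[str] = []
    if burn_in_factor < 10.0:
        notes.append(
            f"burn_in_factor={burn_in_factor:g} below recommended 10; "
            "population may not be fully stationary"
        )
    x, y = sample_stationary_ensemble(
        params, n_cells, rng_cells, burn_in=burn_in, alpha=alpha_per_cell
    )

    subpops = [
        SubPopulation(
            index=i,
            alpha_i=float(alpha_i[i]),
            n_i=int(n_i[i]),
            w_i=float(w_i[i]),
            mu_i_log=float(log_alpha[i] + math.log(beta) - dec.vW / 2.0),
            v_i_log=dec.vW,
        )
        for i in range(n_subpops)
    ]
    return Population(
        decomposition=dec,
        params=params,
        mu_alpha=mu_alpha,
        n_subpops=n_subpops,
        n_cells=n_cells,
        subpopulations=subpops,
        x=x,
        y=y,
        subpop_index=subpop_index,
        alpha_per_cell=alpha_per_cell,
        notes=notes,
    )


def population_summary(pop: Population) -> tuple[float, float, float, float]:
    """Empirical (mu_F_log, v_F_log, vA_hat, vW_hat) of a stationary population.

    Uses population (ddof=0) variances weighted by realized frequencies
    w_i = n_i / n, under which vA_hat + vW_hat = v_F_log holds exactly
    (law of total variance as an algebraic identity).
    """
    if not pop.stationary:
        raise ValueError("population_summary requires a stationary population")
    log_x = pop.log_x
    mu_F = float(log_x.mean())
    v_F = float(log_x.var())
    # Per-subpopulation means/variances over realized cells.
    n = pop.n_cells
    counts = np.bincount(pop.subpop_index, minlength=pop.n_subpops)
    sums = np.bincount(pop.subpop_index, weights=log_x, minlength=pop.n_subpops)
    sq_sums = np.bincount(pop.subpop_index, weights=log_x**2, minlength=pop.n_subpops)
    occupied = counts > 0
    m_i = sums[occupied] / counts[occupied]
    v_i = sq_sums[occupied] / counts[occupied] - m_i**2
    w = counts[occupied] / n
    m_bar = float(np.sum(w * m_i))
    vA_hat = float(np.sum(w * (m_i - m_bar) ** 2))
    vW_hat = float(np.sum(w * v_i))
    return mu_F, v_F, vA_hat, vW_hat
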