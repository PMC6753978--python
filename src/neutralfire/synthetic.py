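"""Synthetic metacommunities and mapped-census series.

Emulates the statistical structure of fine-scale groundcover monitoring in
frequently burned pine woodland: many small plots surveyed yearly on a
10-cm grid, a strongly right-skewed species abundance distribution
(log-series by default), and cell-wise turnover between surveys driven by
fixed mortality and colonization probabilities.  Because the generating
rates are known, the census series doubles as ground truth for the
demographic-rate estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .metacommunity import CensusGrid, SpeciesFrequencyDistribution


@dataclass(frozen=True)
class SyntheticCensusConfig:
    """Configuration of a synthetic monitoring campaign.

    Defaults mirror a two-habitat campaign of 15 plots each (1 m x 3 m at
    10-cm grain), four yearly surveys, ~123 species and >7,000 recorded
    individuals overall.
    """

    n_plots: int = 30
    plot_cells: tuple[int, int] = (10, 30)  # (width, height): 1 m x 3 m
    n_species_target: int = 123
    n_individuals_target: int = 7000
    fisher_alpha: float = 20.0
    occupancy: float = 0.65
    n_surveys: int = 4
    true_mortality: float = 0.4
    true_birth: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_plots, self.n_species_target, self.n_individuals_target, self.n_surveys) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must be in (0, 1]")
        for name in ("true_mortality", "true_birth"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.fisher_alpha <= 0:
            raise ValueError("fisher_alpha must be positive")


def generate_metacommunity(
    n_species: int,
    alpha: float,
    total_count: int,
    rng: np.random.Generator,
    *,
    abundance_model: Literal["logseries", "geometric", "uniform"] = "logseries",
    prefix: str = "sp",
) -> SpeciesFrequencyDistribution:
    """Draw a right-skewed species frequency distribution.

    Species abundances are sampled from a log-series whose shape parameter
    follows from Fisher's alpha via x = total / (total + alpha), then
    rescaled so that each of the ``n_species`` species keeps a count >= 1
    and the counts sum exactly to ``total_count``.  Smaller alpha gives a
    more uneven (skewed) community.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if total_count < n_species:
        raise ValueError(
            f"total_count={total_count} cannot give every one of {n_species} species a count >= 1"
        )
    if abundance_model == "logseries":
        x = total_count / (total_count + alpha)
        raw = stats.logser.rvs(x, size=n_species, random_state=rng).astype(float)
    elif abundance_model == "geometric":
        raw = stats.geom.rvs(min(0.5, alpha / (alpha + total_count)), size=n_species,
                             random_state=rng).astype(float)
    elif abundance_model == "uniform":
        raw = np.ones(n_species)
    else:
        raise ValueError(f"unknown abundance model {abundance_model!r}")

    # one guaranteed individual per species; distribute the remainder
    # proportionally to the raw draws (largest-remainder rounding)
    spare = total_count - n_species
    quota = spare * raw / raw.sum()
    counts = np.ones(n_species, dtype=np.int64) + np.floor(quota).astype(np.int64)
    short = total_count - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        counts[order[:short]] += 1
    species = tuple(f"{prefix}{i:03d}" for i in range(n_species))
    return SpeciesFrequencyDistribution(species, counts, scale_cm=10)


def generate_census_series(
    config: SyntheticCensusConfig,
    meta: SpeciesFrequencyDistribution,
    *,
    start_year: int = 2012,
) -> list[list[CensusGrid]]:
    """Simulate repeated plot censuses: one list of per-plot grids per survey.

    Survey 1 fills each plot's cells at the configured occupancy with
    species drawn i.i.d. from the metacommunity.  Each later survey kills
    every occupant independently with ``true_mortality`` and colonizes every
    empty cell with ``true_birth`` (recruit species again from the
    metacommunity) — the same cell-wise transition process the rate
    estimator assumes.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.plot_cells
    n_cells = w * h
    freqs = meta.frequencies
    species = np.asarray(meta.species_ids)

    # per-plot occupancy state: species index or -1
    state = np.full((config.n_plots, n_cells), -1, dtype=np.int64)
    occupied0 = rng.random((config.n_plots, n_cells)) < config.occupancy
    n0 = int(occupied0.sum())
    state[occupied0] = rng.choice(len(species), size=n0, p=freqs)

    surveys: list[list[CensusGrid]] = []
    for s in range(config.n_surveys):
        year = start_year + s
        if s > 0:
            occ = state >= 0
            dies = occ & (rng.random(state.shape) < config.true_mortality)
            state[dies] = -1
            empty = state < 0
            colonize = empty & (rng.random(state.shape) < config.true_birth)
            k = int(colonize.sum())
            state[colonize] = rng.choice(len(species), size=k, p=freqs)
        plots = []
        for p in range(config.n_plots):
            grid = CensusGrid(f"plot{p + 1:02d}", w, h)
            occ_idx = np.flatnonzero(state[p] >= 0)
            for i in occ_idx:
                grid.add(year, int(i % w), int(i // w), str(species[state[p, i]]))
            plots.append(grid)
        surveys.append(plots)
    return surveys
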