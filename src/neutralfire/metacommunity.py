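"""Species frequency distributions and demographic rates from mapped censuses.

Field censuses map every groundcover individual to a 10 cm x 10 cm cell of a
plot grid (one individual per cell per survey).  This module turns such
censuses into metacommunity species frequency distributions — optionally
coarsened to larger grains by presence-absence — and estimates per-step
mortality and birth probabilities from consecutive surveys of the same plot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: grains (cell side length, cm) at which distributions may be tallied
SUPPORTED_SCALES_CM = (10, 20, 50, 100, 200)

#: side length of a fine census cell, cm
FINE_CELL_CM = 10


class EmptyCensusError(ValueError):
    """Raised when an operation receives a census with no usable records."""


class UndefinedRateError(ValueError):
    """Raised when a demographic rate has a zero denominator.

    A rate with no at-risk cells is undefined, not zero; callers that
    average over many plot-year pairs may catch this and drop the pair.
    """

    def __init__(self, which: str, message: str):
        self.which = which
        super().__init__(message)


@dataclass(frozen=True)
class SpeciesFrequencyDistribution:
    """A species pool: per-species occupied-cell (or occupied-block) counts.

    Relative frequencies derived from the counts are the sampling weights
    used for community initialization and for immigration.
    """

    species_ids: tuple[str, ...]
    counts: np.ndarray  # int64, one per species
    scale_cm: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        if len(self.species_ids) != counts.size:
            raise ValueError("species_ids and counts length mismatch")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species_ids must be unique")
        if counts.size == 0 or (counts < 0).any() or counts.sum() == 0:
            raise ValueError("counts must be nonnegative with at least one positive")
        if self.scale_cm not in SUPPORTED_SCALES_CM:
            raise ValueError(f"unsupported scale_cm {self.scale_cm}; use one of {SUPPORTED_SCALES_CM}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return int((self.counts > 0).sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Relative frequencies; sums to 1."""
        return self.counts / self.counts.sum()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species_ids, "count": self.counts, "scale_cm": self.scale_cm}
        )

    def to_csv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "species_ids": list(self.species_ids),
                    "counts": self.counts.tolist(),
                    "scale_cm": self.scale_cm,
                },
                indent=1,
            )
        )

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], scale_cm: int = FINE_CELL_CM) -> "SpeciesFrequencyDistribution":
        species = tuple(counts)
        return cls(species, np.array([counts[s] for s in species], dtype=np.int64), scale_cm)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesFrequencyDistribution":
        df = pd.read_csv(path)
        scale = int(df["scale_cm"].iloc[0]) if "scale_cm" in df else FINE_CELL_CM
        return cls(tuple(df["species"].astype(str)), df["count"].to_numpy(np.int64), scale)

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeciesFrequencyDistribution":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["species_ids"]), np.asarray(d["counts"], dtype=np.int64), int(d["scale_cm"]))


@dataclass
class CensusGrid:
    """Mapped individuals of one plot: (year, x, y) cell -> species label.

    Cell indices are 0-based at the 10-cm grain; at most one individual per
    cell per survey year.
    """

    plot_id: str
    width_cells: int
    height_cells: int
    records: dict[tuple[int, int, int], str] = field(default_factory=dict)

    def __post_init__(self):
        if self.width_cells <= 0 or self.height_cells <= 0:
            raise ValueError("plot dimensions must be positive")
        for (year, x, y), sp in self.records.items():
            self._check_cell(x, y)

    def _check_cell(self, x: int, y: int) -> None:
        if not (0 <= x < self.width_cells and 0 <= y < self.height_cells):
            raise ValueError(
                f"cell ({x},{y}) outside plot {self.plot_id!r} "
                f"({self.width_cells} x {self.height_cells})"
            )

    @property
    def n_cells(self) -> int:
        return self.width_cells * self.height_cells

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({year for (year, _, _) in self.records}))

    def add(self, year: int, x: int, y: int, species: str) -> None:
        self._check_cell(x, y)
        key = (int(year), int(x), int(y))
        if key in self.records:
            raise ValueError(f"cell ({x},{y}) already occupied in year {year} of plot {self.plot_id!r}")
        self.records[key] = str(species)

    def occupancy(self, year: int) -> dict[tuple[int, int], str]:
        """Cell -> species map for one survey year."""
        return {(x, y): sp for (yr, x, y), sp in self.records.items() if yr == year}


def read_census_csv(path: str | Path, plot_cells: tuple[int, int] = (10, 30)) -> list[CensusGrid]:
    """Read a mapped-census table (`plot,year,x_cm,y_cm,species`; cm coords).

    Coordinates are the lower-left corner of the occupied 10-cm cell.
    `plot_cells` gives the (width, height) of every plot in cells.
    """
    df = pd.read_csv(path, dtype={"plot": str, "species": str})
    grids: dict[str, CensusGrid] = {}
    w, h = plot_cells
    for row in df.itertuples(index=False):
        grid = grids.setdefault(str(row.plot), CensusGrid(str(row.plot), w, h))
        grid.add(int(row.year), int(row.x_cm) // FINE_CELL_CM, int(row.y_cm) // FINE_CELL_CM, row.species)
    return list(grids.values())


def write_census_csv(grids: Iterable[CensusGrid], path: str | Path) -> None:
    rows = [
        (g.plot_id, year, x * FINE_CELL_CM, y * FINE_CELL_CM, sp)
        for g in grids
        for (year, x, y), sp in sorted(g.records.items())
    ]
    pd.DataFrame(rows, columns=["plot", "year", "x_cm", "y_cm", "species"]).to_csv(path, index=False)


def build_distribution(
    censuses: CensusGrid | Sequence[CensusGrid], year: int
) -> SpeciesFrequencyDistribution:
    """Tally one survey year into a fine-grain species frequency distribution.

    The count of a species is the number of occupied 10-cm cells holding it,
    pooled across all supplied plots.
    """
    return coarsen_distribution(censuses, year, FINE_CELL_CM)


def coarsen_distribution(
    censuses: CensusGrid | Sequence[CensusGrid], year: int, scale_cm: int
) -> SpeciesFrequencyDistribution:
    """Presence-absence regrid of one survey year to a coarser grain.

    Each plot is tiled with scale_cm x scale_cm blocks anchored at the plot
    origin (edge blocks may be partial); a species is counted once per block
    in which it occupies at least one fine cell.  ``scale_cm=10`` reproduces
    the raw tally.  Several species may share a block, so coarse counts are
    occupied-block counts per species, not an occupancy partition.
    """
    if scale_cm not in SUPPORTED_SCALES_CM:
        raise ValueError(f"unsupported scale_cm {scale_cm}; use one of {SUPPORTED_SCALES_CM}")
    if isinstance(censuses, CensusGrid):
        censuses = [censuses]
    factor = scale_cm // FINE_CELL_CM
    seen: set[tuple[str, int, int, str]] = set()  # (plot, block_x, block_y, species)
    for grid in censuses:
        for (x, y), sp in grid.occupancy(year).items():
            seen.add((grid.plot_id, x // factor, y // factor, sp))
    if not seen:
        raise EmptyCensusError(f"no census records for year {year}")
    counts: dict[str, int] = {}
    for (_, _, _, sp) in seen:
        counts[sp] = counts.get(sp, 0) + 1
    species = tuple(sorted(counts))
    return SpeciesFrequencyDistribution(
        species, np.array([counts[s] for s in species], dtype=np.int64), scale_cm
    )


@dataclass(frozen=True)
class DemographicRates:
    """Per-time-step mortality and birth probabilities estimated from censuses."""

    mortality: float
    birth: float
    n_transitions: int
    n_replacements: int = 0  # same-cell species turnover events (scored as deaths only)

    def __post_init__(self):
        if not (0.0 <= self.mortality <= 1.0 and 0.0 <= self.birth <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_transitions < 0:
            raise ValueError("n_transitions must be nonnegative")


@dataclass(frozen=True)
class TransitionCounts:
    """Raw cell-transition tallies between two surveys of one plot."""

    deaths: int  # occupied at t0, original species gone from the cell at t1
    births: int  # empty at t0, occupied at t1
    replacements: int  # occupied at t0 and t1 by different species (subset of deaths)
    occupied_t0: int
    empty_t0: int


def transition_counts(census_t0: CensusGrid, census_t1: CensusGrid) -> TransitionCounts:
    """Tally cell transitions between two single-year censuses of one plot.

    An individual is dead if its species is not found in its original cell at
    t1; a birth is a cell empty at t0 and occupied at t1.  A cell whose
    occupant changed species is one death plus a separately logged
    replacement — it does not enter the birth numerator, whose denominator is
    cells empty at t0.
    """
    if (census_t0.width_cells, census_t0.height_cells) != (
        census_t1.width_cells,
        census_t1.height_cells,
    ):
        raise ValueError("censuses must share the same plot geometry")
    for c in (census_t0, census_t1):
        if len(c.years) != 1:
            raise ValueError(f"census for plot {c.plot_id!r} must hold exactly one survey year")
    occ0 = census_t0.occupancy(census_t0.years[0])
    occ1 = census_t1.occupancy(census_t1.years[0])
    deaths = sum(1 for cell, sp in occ0.items() if occ1.get(cell) != sp)
    replacements = sum(1 for cell, sp in occ0.items() if cell in occ1 and occ1[cell] != sp)
    births = sum(1 for cell in occ1 if cell not in occ0)
    occupied_t0 = len(occ0)
    return TransitionCounts(
        deaths=deaths,
        births=births,
        replacements=replacements,
        occupied_t0=occupied_t0,
        empty_t0=census_t0.n_cells - occupied_t0,
    )


def estimate_rates(census_t0: CensusGrid, census_t1: CensusGrid) -> DemographicRates:
    """Estimate mortality and birth probabilities from one census pair.

    mortality = deaths / occupied cells at t0;
    birth = births into empty cells / empty cells at t0.
    Raises :class:`UndefinedRateError` if either denominator is zero.
    """
    t = transition_counts(census_t0, census_t1)
    if t.occupied_t0 == 0:
        raise UndefinedRateError("mortality", "no occupied cells at t0: mortality undefined")
    if t.empty_t0 == 0:
        raise UndefinedRateError("birth", "no empty cells at t0: birth undefined")
    return DemographicRates(
        mortality=t.deaths / t.occupied_t0,
        birth=t.births / t.empty_t0,
        n_transitions=t.occupied_t0 + t.empty_t0,
        n_replacements=t.replacements,
    )


def average_rates(pairs: Sequence[tuple[CensusGrid, CensusGrid]]) -> DemographicRates:
    """Unweighted mean of per-plot-pair rates across plots and survey intervals.

    Pairs in which a rate is undefined (zero denominator) are dropped from
    that rate's mean; if every pair is undefined for a rate the error
    propagates.
    """
    morts, births, n_tr, n_rep = [], [], 0, 0
    last_err: UndefinedRateError | None = None
    for c0, c1 in pairs:
        t = transition_counts(c0, c1)
        n_tr += t.occupied_t0 + t.empty_t0
        n_rep += t.replacements
        if t.occupied_t0 > 0:
            morts.append(t.deaths / t.occupied_t0)
        else:
            last_err = UndefinedRateError("mortality", "no occupied cells at t0 in any pair")
        if t.empty_t0 > 0:
            births.append(t.births / t.empty_t0)
        else:
            last_err = UndefinedRateError("birth", "no empty cells at t0 in any pair")
    if not morts:
        raise UndefinedRateError("mortality", "mortality undefined in every pair")
    if not births:
        raise UndefinedRateError("birth", "birth undefined in every pair")
    del last_err
    return DemographicRates(
        mortality=float(np.mean(morts)),
        birth=float(np.mean(births)),
        n_transitions=n_tr,
        n_replacements=n_rep,
    )
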