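"""Neutral lattice simulator of groundcover community assembly.

Communities are square-cell lattices (one individual per 100 cm^2 cell, the
grain of the field censuses).  Each yearly time step applies synchronous
mortality to every individual, then synchronous recruitment into the empty
cells.  A recruit immigrates from the metacommunity with probability
``immigration``; otherwise it is drawn from the local pool — the realized
composition of the area (non-spatial model) or a distance-weighted choice
among occupied neighbors under a negative-exponential kernel with periodic
boundaries (spatial model).  Fire is implicit in the mortality and birth
probabilities, which correspond to a high-frequency prescribed-burn regime.

All stochasticity flows from one seed through per-step substreams, so runs
are bit-reproducible and trajectories of different lengths share their
common prefix of random draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np

from .metacommunity import SpeciesFrequencyDistribution

EMPTY = -1

#: side of a lattice cell in metres (100 cm^2 cells)
CELL_SIDE_M = 0.1


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulation run.

    The five head parameters (birth, mortality, immigration, area_m2,
    n_areas) are the factors varied in the sensitivity experiment; the
    remainder configure the dispersal kernel and run length.
    """

    birth: float
    mortality: float
    immigration: float
    area_m2: float = 1.0
    n_areas: int = 1
    model: Literal["spatial", "nonspatial"] = "nonspatial"
    kernel_scale_cells: float = 1.0
    max_dispersal_cells: int = 5
    n_steps: int = 50
    seed: int = 0
    initial_occupancy: float = 1.0
    local_pool: Literal["realized", "initial"] = "realized"

    def __post_init__(self):
        for name in ("birth", "mortality", "immigration"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.area_m2 <= 0:
            raise ValueError("area_m2 must be positive")
        if self.n_areas < 1 or self.n_steps < 1:
            raise ValueError("n_areas and n_steps must be >= 1")
        if self.kernel_scale_cells <= 0 or self.max_dispersal_cells < 1:
            raise ValueError("kernel_scale_cells must be > 0 and max_dispersal_cells >= 1")
        if not (0.0 < self.initial_occupancy <= 1.0):
            raise ValueError("initial_occupancy must be in (0, 1]")
        if self.model not in ("spatial", "nonspatial"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class CommunityLattice:
    """One simulated area: a grid of species indices (EMPTY = vacant cell).

    ``grid[row, col]`` indexes into ``species_ids``; the spatial model uses
    periodic boundaries, the non-spatial model bounded ones (boundaries are
    irrelevant to its frequency-based recruitment).
    """

    grid: np.ndarray
    species_ids: tuple[str, ...]
    boundary: Literal["periodic", "bounded"]

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")

    @property
    def richness(self) -> int:
        return int(np.unique(self.grid[self.grid >= 0]).size)

    @property
    def n_occupied(self) -> int:
        return int((self.grid >= 0).sum())


@dataclass(frozen=True)
class RichnessTrajectory:
    """Richness through time for one run, pooled over all areas."""

    richness_by_step: np.ndarray  # length n_steps + 1; index 0 = initial state
    occupied_by_step: np.ndarray
    normalized_richness: float
    per_area_richness: np.ndarray | None = None  # (n_steps + 1, n_areas) if tracked


def area_to_dims(area_m2: float) -> tuple[int, int]:
    """Lattice (width, height) in cells realizing a target area in m^2.

    The cell count is area * 100 rounded to the nearest integer, laid out as
    the most-square grid whose cell count is at least the target; the excess
    never exceeds width - 1 cells.
    """
    n_cells = round(area_m2 * 100)
    if n_cells < 1:
        raise ValueError(f"area {area_m2} m^2 is smaller than one 100 cm^2 cell")
    width = int(math.floor(math.sqrt(n_cells)))
    height = int(math.ceil(n_cells / width))
    return width, height


def max_dispersal_distance_m(
    max_dispersal_cells: int, cell_side_m: float = CELL_SIDE_M
) -> float:
    """Maximum center-to-center dispersal distance in metres.

    The farthest reachable parent sits on the diagonal corner of the
    dispersal window, sqrt(2) * radius cells away; radius 5 on 10-cm cells
    gives 0.7071 m (reported as 0.71 m).
    """
    if max_dispersal_cells < 1:
        raise ValueError("max_dispersal_cells must be >= 1")
    if cell_side_m < 0:
        raise ValueError("cell_side_m must be nonnegative")
    return math.sqrt(2.0) * max_dispersal_cells * cell_side_m


def _cumulative_frequencies(meta: SpeciesFrequencyDistribution) -> np.ndarray:
    cum = np.cumsum(meta.frequencies)
    cum[-1] = 1.0  # guard searchsorted against rounding
    return cum


def _draw_species(cum: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.searchsorted(cum, rng.random(n), side="right").astype(np.int64)


def initialize_community(
    meta: SpeciesFrequencyDistribution,
    dims: tuple[int, int],
    rng: np.random.Generator,
    *,
    boundary: Literal["periodic", "bounded"] = "bounded",
    occupancy: float = 1.0,
) -> CommunityLattice:
    """Populate a lattice by i.i.d. draws from the metacommunity frequencies."""
    if meta.richness == 0:
        raise ValueError("metacommunity is empty")
    width, height = dims
    grid = _draw_species(_cumulative_frequencies(meta), width * height, rng)
    if occupancy < 1.0:
        grid[rng.random(grid.size) >= occupancy] = EMPTY
    return CommunityLattice(grid.reshape(height, width), meta.species_ids, boundary)


def mortality_step(
    lattice: CommunityLattice, mortality: float, rng: np.random.Generator
) -> CommunityLattice:
    """Empty each occupied cell independently with the given probability."""
    grid = lattice.grid.copy()
    _apply_mortality(grid, mortality, rng)
    return replace(lattice, grid=grid)


def _apply_mortality(state: np.ndarray, mortality: float, rng: np.random.Generator) -> None:
    occ = state >= 0
    # one uniform per occupied cell, in C order — fixed draw order for reproducibility
    dead = np.zeros_like(occ)
    dead[occ] = rng.random(int(occ.sum())) < mortality
    state[dead] = EMPTY


@lru_cache(maxsize=64)
def _dispersal_window(
    radius: int, kernel_scale: float, height: int, width: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wrapped neighbor offsets and kernel weights for a periodic lattice.

    Offsets span the Chebyshev window of the given radius, excluding the
    focal cell.  On lattices smaller than the window, distinct offsets can
    wrap onto the same cell; each wrapped target is kept once at its minimal
    Euclidean image distance, so no parent is double-weighted.
    """
    best: dict[tuple[int, int], float] = {}
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy == 0 and dx == 0:
                continue
            tgt = (dy % height, dx % width)
            if tgt == (0, 0):
                continue  # offset wraps onto the focal cell itself
            d = math.hypot(dy, dx)
            if tgt not in best or d < best[tgt]:
                best[tgt] = d
    dys = np.array([t[0] for t in best], dtype=np.int64)
    dxs = np.array([t[1] for t in best], dtype=np.int64)
    w = np.exp(-np.array(list(best.values())) / kernel_scale)
    return dys, dxs, w


def recruit_nonspatial(
    lattice: CommunityLattice,
    params: SimulationParams,
    meta: SpeciesFrequencyDistribution,
    rng: np.random.Generator,
    *,
    local_cum: np.ndarray | None = None,
) -> CommunityLattice:
    """Fill empty cells by frequency-based recruitment (one area).

    Each empty cell attempts a birth with probability ``params.birth``; the
    recruit is an immigrant (metacommunity draw) with probability
    ``params.immigration`` and otherwise copies a uniformly random survivor
    of this area — equivalent to sampling the realized relative frequencies.
    """
    h, w = lattice.grid.shape
    state = lattice.grid.reshape(1, h * w).copy()
    _recruit_nonspatial_flat(
        state, params.birth, params.immigration, _cumulative_frequencies(meta), rng,
        local_cum=local_cum,
    )
    return replace(lattice, grid=state.reshape(h, w))


def _recruit_nonspatial_flat(
    state: np.ndarray,
    birth: float,
    immigration: float,
    meta_cum: np.ndarray,
    rng: np.random.Generator,
    *,
    local_cum: np.ndarray | None = None,
) -> None:
    """Synchronous non-spatial recruitment on a (n_areas, n_cells) state.

    Mutates ``state`` in place.  ``local_cum`` switches the local pool from
    the realized survivor composition to a fixed per-area cumulative
    frequency vector (the area's initial composition).
    """
    survivors = state.copy()
    ar, ac = np.nonzero(state < 0)  # empty cells, C order
    if ar.size == 0:
        return
    born = rng.random(ar.size) < birth
    ar, ac = ar[born], ac[born]
    if ar.size == 0:
        return
    imm = rng.random(ar.size) < immigration
    n_imm = int(imm.sum())
    if n_imm:
        state[ar[imm], ac[imm]] = _draw_species(meta_cum, n_imm, rng)
    lr, lc = ar[~imm], ac[~imm]
    if lr.size == 0:
        return
    u = rng.random(lr.size)
    if local_cum is not None:
        state[lr, lc] = np.searchsorted(local_cum, u, side="right").astype(np.int64)
        return
    occ = survivors >= 0
    counts = occ.sum(axis=1)
    rows, cols = np.nonzero(occ)  # grouped by area
    offsets = np.cumsum(counts) - counts
    cnt = counts[lr]
    has_parent = cnt > 0
    lr, lc, u, cnt = lr[has_parent], lc[has_parent], u[has_parent], cnt[has_parent]
    if lr.size == 0:
        return
    pick = offsets[lr] + np.minimum((u * cnt).astype(np.int64), cnt - 1)
    state[lr, lc] = survivors[lr, cols[pick]]


def recruit_spatial(
    lattice: CommunityLattice,
    params: SimulationParams,
    meta: SpeciesFrequencyDistribution,
    rng: np.random.Generator,
) -> CommunityLattice:
    """Fill empty cells by kernel-weighted local recruitment (one area).

    Non-immigrant recruits copy an occupied cell within Chebyshev radius
    ``params.max_dispersal_cells`` of the focal cell, chosen with probability
    proportional to exp(-d / kernel_scale_cells) where d is the wrapped
    Euclidean center-to-center distance in cell units.  An empty neighborhood
    leaves the cell vacant (immigration is the only metacommunity channel).
    """
    if lattice.boundary != "periodic":
        raise ValueError("spatial recruitment requires periodic boundaries")
    state = lattice.grid.copy()
    _recruit_spatial_grid(
        state, params.birth, params.immigration, _cumulative_frequencies(meta), rng,
        params.max_dispersal_cells, params.kernel_scale_cells,
    )
    return replace(lattice, grid=state)


def _recruit_spatial_grid(
    state: np.ndarray,
    birth: float,
    immigration: float,
    meta_cum: np.ndarray,
    rng: np.random.Generator,
    radius: int,
    kernel_scale: float,
) -> None:
    """Synchronous spatial recruitment on one (h, w) periodic grid, in place."""
    h, w = state.shape
    survivors = state.copy()
    ys, xs = np.nonzero(state < 0)
    if ys.size == 0:
        return
    born = rng.random(ys.size) < birth
    ys, xs = ys[born], xs[born]
    if ys.size == 0:
        return
    imm = rng.random(ys.size) < immigration
    n_imm = int(imm.sum())
    if n_imm:
        state[ys[imm], xs[imm]] = _draw_species(meta_cum, n_imm, rng)
    ly, lx = ys[~imm], xs[~imm]
    if ly.size == 0:
        return
    dys, dxs, weights = _dispersal_window(radius, kernel_scale, h, w)
    nbr = survivors[(ly[:, None] + dys) % h, (lx[:, None] + dxs) % w]
    wmat = np.where(nbr >= 0, weights, 0.0)
    cum = np.cumsum(wmat, axis=1)
    tot = cum[:, -1]
    u = rng.random(ly.size) * tot
    idx = np.minimum((cum < u[:, None]).sum(axis=1), wmat.shape[1] - 1)
    chosen = nbr[np.arange(ly.size), idx]
    ok = tot > 0
    state[ly[ok], lx[ok]] = chosen[ok]


def kernel_weights(
    radius: int, kernel_scale: float, height: int, width: int
) -> dict[tuple[int, int], float]:
    """Exposed dispersal-kernel weights per wrapped (dy, dx) offset."""
    dys, dxs, w = _dispersal_window(radius, kernel_scale, height, width)
    return {(int(dy), int(dx)): float(wt) for dy, dx, wt in zip(dys, dxs, w)}


def simulate(
    params: SimulationParams,
    meta: SpeciesFrequencyDistribution,
    *,
    normalized: Literal["ratio", "relative_change"] = "ratio",
    track_per_area: bool = False,
    return_lattices: bool = False,
) -> RichnessTrajectory | tuple[RichnessTrajectory, list[CommunityLattice]]:
    """Run one simulation: n_areas replicate communities over n_steps years.

    Richness per step is the pooled count of distinct species across all
    areas; normalized richness is richness at the final step divided by
    richness at step 1 (after the first update), or the relative change
    (S_end - S_1) / S_1 under ``normalized="relative_change"``.  If richness
    at step 1 is zero, normalized richness is reported as 0.
    """
    if meta.richness == 0:
        raise ValueError("metacommunity is empty")
    width, height = area_to_dims(params.area_m2)
    n_cells = width * height
    meta_cum = _cumulative_frequencies(meta)
    ss = np.random.SeedSequence(params.seed)
    streams = ss.spawn(params.n_steps + 1)  # stream 0: init; stream t: step t

    rng0 = np.random.default_rng(streams[0])
    if params.model == "spatial":
        state = np.empty((params.n_areas, height, width), dtype=np.int64)
    else:
        state = np.empty((params.n_areas, n_cells), dtype=np.int64)
    for a in range(params.n_areas):  # per-area init draws, fixed order
        cells = _draw_species(meta_cum, n_cells, rng0)
        if params.initial_occupancy < 1.0:
            cells[rng0.random(n_cells) >= params.initial_occupancy] = EMPTY
        state[a] = cells.reshape(state.shape[1:])

    local_cum = None
    if params.local_pool == "initial":
        flat0 = state.reshape(params.n_areas, n_cells)
        local_cum = np.empty((params.n_areas, meta_cum.size))
        for a in range(params.n_areas):
            occ = flat0[a][flat0[a] >= 0]
            cnt = np.bincount(occ, minlength=meta_cum.size).astype(float)
            tot = cnt.sum()
            local_cum[a] = np.cumsum(cnt / tot) if tot else meta_cum

    richness = np.zeros(params.n_steps + 1, dtype=np.int64)
    occupied = np.zeros(params.n_steps + 1, dtype=np.int64)
    per_area = (
        np.zeros((params.n_steps + 1, params.n_areas), dtype=np.int64)
        if track_per_area
        else None
    )

    def record(t: int) -> None:
        flat = state.reshape(params.n_areas, -1)
        richness[t] = np.unique(flat[flat >= 0]).size
        occupied[t] = int((flat >= 0).sum())
        if per_area is not None:
            for a in range(params.n_areas):
                per_area[t, a] = np.unique(flat[a][flat[a] >= 0]).size

    record(0)
    for t in range(1, params.n_steps + 1):
        rng = np.random.default_rng(streams[t])
        _apply_mortality(state, params.mortality, rng)
        if params.model == "spatial":
            for a in range(params.n_areas):
                _recruit_spatial_grid(
                    state[a], params.birth, params.immigration, meta_cum, rng,
                    params.max_dispersal_cells, params.kernel_scale_cells,
                )
        elif params.local_pool == "initial":
            for a in range(params.n_areas):
                _recruit_nonspatial_flat(
                    state[a : a + 1], params.birth, params.immigration, meta_cum, rng,
                    local_cum=local_cum[a],
                )
        else:
            _recruit_nonspatial_flat(
                state, params.birth, params.immigration, meta_cum, rng
            )
        record(t)

    s1, s_end = richness[1], richness[params.n_steps]
    if s1 == 0:
        norm = 0.0
    elif normalized == "ratio":
        norm = s_end / s1
    else:
        norm = (s_end - s1) / s1
    traj = RichnessTrajectory(
        richness_by_step=richness,
        occupied_by_step=occupied,
        normalized_richness=float(norm),
        per_area_richness=per_area,
    )
    if not return_lattices:
        return traj
    boundary = "periodic" if params.model == "spatial" else "bounded"
    lattices = [
        CommunityLattice(state[a].reshape(height, width), meta.species_ids, boundary)
        for a in range(params.n_areas)
    ]
    return traj, lattices
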