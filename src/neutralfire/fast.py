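"""Fourier amplitude sensitivity test (FAST) for the lattice simulator.

Each parameter is oscillated along the arcsine search curve at an integer
frequency; in the extended scheme used here the design has one block of N
points per parameter, with the parameter of interest carrying the high
frequency in its block and all others low complementary frequencies.  The
first-order index of a parameter is the share of its block's output spectral
variance found at the first M harmonics of its frequency.

The experiment driver evaluates normalized richness of the simulator at
every design row over a scenario grid (model variant x habitat
metacommunity x input grain) with replicate seeds, mirroring the study
design of 2 models x 2 habitats x 5 grains x 3 replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metacommunity import SpeciesFrequencyDistribution
from .simulate import SimulationParams, simulate

PARAMETER_NAMES = ("birth", "mortality", "immigration", "area_m2", "n_areas")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "birth": (0.2, 0.6),
    "mortality": (0.2, 0.6),
    "immigration": (0.01, 0.25),
    "area_m2": (1.0, 25.0),
    "n_areas": (1.0, 30.0),
}


@dataclass(frozen=True)
class FASTDesign:
    """A FAST sampling design over the five simulator parameters.

    ``samples_per_parameter`` (N) points are placed along the search curve in
    each parameter's block; the interference factor M bounds the harmonics
    read per parameter, and N > 4 M^2 is required so those harmonics stay
    below the Nyquist limit and clear of complementary-frequency harmonics.
    """

    parameter_names: tuple[str, ...] = PARAMETER_NAMES
    bounds: tuple[tuple[float, float], ...] = tuple(DEFAULT_BOUNDS[p] for p in PARAMETER_NAMES)
    samples_per_parameter: int = 100
    interference_factor: int = 4
    phases: tuple[float, ...] | None = None  # default: all zero

    def __post_init__(self):
        if len(self.bounds) != len(self.parameter_names):
            raise ValueError("one (low, high) pair per parameter required")
        for name, (lo, hi) in zip(self.parameter_names, self.bounds):
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy low < high (got {lo}, {hi})")
        N, M = self.samples_per_parameter, self.interference_factor
        if N <= 4 * M * M:
            raise ValueError(
                f"samples_per_parameter={N} must exceed 4*M^2={4 * M * M} to avoid aliasing"
            )
        if self.phases is not None and len(self.phases) != len(self.parameter_names):
            raise ValueError("one phase per parameter required")

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_rows(self) -> int:
        return self.samples_per_parameter * self.n_parameters

    def frequencies(self) -> tuple[int, np.ndarray]:
        """(high frequency for the parameter of interest, complementary set).

        The high frequency is floor((N-1) / 2M), the largest whose M-th
        harmonic stays below the Nyquist index; complementary frequencies
        fill 1..floor(w_max / 2M) so their harmonics cannot collide with the
        read harmonics.
        """
        N, M, D = self.samples_per_parameter, self.interference_factor, self.n_parameters
        w_max = (N - 1) // (2 * M)
        m = w_max // (2 * M)
        if m >= D - 1:
            comp = np.floor(np.linspace(1, m, D - 1)).astype(np.int64)
        else:
            comp = np.arange(D - 1, dtype=np.int64) % max(m, 1) + 1
        return w_max, comp


def degenerate_bounds(design: FASTDesign, fixed: Mapping[str, float]) -> FASTDesign:
    """Pin parameters to constants (low = high is rejected by FASTDesign, so
    pinned parameters get an epsilon-wide band around the fixed value)."""
    bounds = []
    for name, (lo, hi) in zip(design.parameter_names, design.bounds):
        if name in fixed:
            v = fixed[name]
            eps = max(abs(v), 1.0) * 1e-9
            bounds.append((v - eps, v + eps))
        else:
            bounds.append((lo, hi))
    return FASTDesign(
        parameter_names=design.parameter_names,
        bounds=tuple(bounds),
        samples_per_parameter=design.samples_per_parameter,
        interference_factor=design.interference_factor,
        phases=design.phases,
    )


def fast_sample(design: FASTDesign) -> np.ndarray:
    """Sample the design: an (N * D, D) matrix of parameter values.

    Block i (rows i*N .. (i+1)*N) assigns the high frequency to parameter i.
    Every value is produced by the search curve
    x = low + (high - low) * (1/2 + arcsin(sin(w s + phi)) / pi)
    over N equispaced s in (-pi, pi).  Integer-valued parameters are kept
    continuous here and discretized only at simulator evaluation, preserving
    the Fourier structure of the design.
    """
    N, D = design.samples_per_parameter, design.n_parameters
    w_max, comp = design.frequencies()
    phases = np.asarray(design.phases if design.phases is not None else np.zeros(D))
    s = (2.0 * (np.arange(N) + 0.5) / N - 1.0) * np.pi
    lows = np.array([b[0] for b in design.bounds])
    highs = np.array([b[1] for b in design.bounds])
    X = np.empty((N * D, D))
    for i in range(D):
        w = np.empty(D, dtype=np.int64)
        w[i] = w_max
        w[np.arange(D) != i] = comp
        g = 0.5 + np.arcsin(np.sin(w[None, :] * s[:, None] + phases[None, :])) / np.pi
        X[i * N : (i + 1) * N] = lows + (highs - lows) * g
    return X


def first_order_indices(outputs: np.ndarray, design: FASTDesign) -> np.ndarray:
    """First-order sensitivity index per parameter, as variance fractions.

    For parameter i the output block is Fourier-transformed and the power at
    harmonics 1..M of the block's high frequency is divided by the block's
    total spectral power (all frequencies up to Nyquist).  Constant output
    yields all-zero indices with a warning.
    """
    y = np.asarray(outputs, dtype=float)
    N, D = design.samples_per_parameter, design.n_parameters
    if y.shape != (N * D,):
        raise ValueError(f"outputs must have length {N * D}, got {y.shape}")
    if not np.isfinite(y).all():
        raise ValueError("outputs contain non-finite values")
    w_max, _ = design.frequencies()
    M = design.interference_factor
    S = np.zeros(D)
    for i in range(D):
        block = y[i * N : (i + 1) * N]
        spectrum = np.fft.rfft(block - block.mean())
        power = np.abs(spectrum[1 : (N - 1) // 2 + 1]) ** 2
        total = power.sum()
        if total == 0.0:
            warnings.warn(
                f"zero output variance in block for {design.parameter_names[i]}; index set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        S[i] = power[np.arange(1, M + 1) * w_max - 1].sum() / total
    return S


@dataclass(frozen=True)
class SensitivityResult:
    """First-order indices for one scenario and replicate."""

    model: str
    habitat: str
    scale_cm: int
    replicate_seed: int
    first_order: dict[str, float]

    def __post_init__(self):
        for name, v in self.first_order.items():
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"first-order index for {name} outside [0, 1]: {v}")


def _evaluate_rows(
    X: np.ndarray,
    design: FASTDesign,
    meta: SpeciesFrequencyDistribution,
    model: str,
    replicate_seed: int,
    n_steps: int,
    max_area_m2: float | None,
) -> np.ndarray:
    """Normalized richness of the simulator at every design row."""
    idx = {p: j for j, p in enumerate(design.parameter_names)}
    row_seeds = np.random.SeedSequence(replicate_seed).generate_state(X.shape[0]) % (2**31)
    y = np.empty(X.shape[0])
    for r in range(X.shape[0]):
        area = float(X[r, idx["area_m2"]])
        if max_area_m2 is not None:
            area = min(area, max_area_m2)
        params = SimulationParams(
            birth=float(X[r, idx["birth"]]),
            mortality=float(X[r, idx["mortality"]]),
            immigration=float(np.clip(X[r, idx["immigration"]], 0.0, 1.0)),
            area_m2=area,
            n_areas=max(1, int(round(X[r, idx["n_areas"]]))),
            model=model,  # type: ignore[arg-type]
            n_steps=n_steps,
            seed=int(row_seeds[r]),
        )
        y[r] = simulate(params, meta).normalized_richness
    return y


def enumerate_scenarios(
    models: Sequence[str],
    metacommunities: Mapping[str, Mapping[int, SpeciesFrequencyDistribution]],
) -> list[tuple[str, str, int]]:
    """The scenario grid: every (model, habitat, scale_cm) combination."""
    return [
        (model, habitat, scale_cm)
        for model in models
        for habitat, by_scale in metacommunities.items()
        for scale_cm in sorted(by_scale)
    ]


def run_experiment(
    design: FASTDesign,
    metacommunities: Mapping[str, Mapping[int, SpeciesFrequencyDistribution]],
    models: Sequence[str] = ("spatial", "nonspatial"),
    replicate_seeds: Sequence[int] = (1, 2, 3),
    *,
    n_steps: int = 50,
    max_area_m2: float | None = None,
) -> list[SensitivityResult]:
    """FAST experiment over the scenario grid (models x habitats x grains).

    ``metacommunities`` maps habitat label -> {scale_cm -> distribution}.
    Replicates share the design matrix; only the simulator seeds differ.
    ``max_area_m2`` caps the realized community area for scaled-down runs
    (the design values themselves are unchanged).
    """
    for habitat, by_scale in metacommunities.items():
        for scale, meta in by_scale.items():
            if meta.richness == 0:
                raise ValueError(f"empty metacommunity for habitat {habitat!r} scale {scale}")
    X = fast_sample(design)
    results: list[SensitivityResult] = []
    for model, habitat, scale_cm in enumerate_scenarios(models, metacommunities):
        meta = metacommunities[habitat][scale_cm]
        for seed in replicate_seeds:
            try:
                y = _evaluate_rows(X, design, meta, model, seed, n_steps, max_area_m2)
                S = first_order_indices(y, design)
            except Exception as exc:  # noqa: BLE001 - re-tag with scenario context
                raise RuntimeError(
                    f"scenario failed: model={model} habitat={habitat} "
                    f"scale_cm={scale_cm} replicate_seed={seed}"
                ) from exc
            results.append(
                SensitivityResult(
                    model=model,
                    habitat=habitat,
                    scale_cm=scale_cm,
                    replicate_seed=seed,
                    first_order=dict(zip(design.parameter_names, S)),
                )
            )
    return results


def results_to_frame(results: Iterable[SensitivityResult]) -> pd.DataFrame:
    """Tidy long-form table: one row per scenario x replicate x parameter."""
    rows = [
        {
            "model": r.model,
            "habitat": r.habitat,
            "scale_cm": r.scale_cm,
            "replicate": r.replicate_seed,
            "parameter": p,
            "first_order": v,
            "first_order_pct": 100.0 * v,
        }
        for r in results
        for p, v in r.first_order.items()
    ]
    return pd.DataFrame(rows)


def design_to_frame(design: FASTDesign) -> pd.DataFrame:
    X = fast_sample(design)
    df = pd.DataFrame(X, columns=list(design.parameter_names))
    df.insert(0, "row", np.arange(len(df)))
    return df
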