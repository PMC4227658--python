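"""Crosslinker-parameter calibration against bulk shear rheology.

The two free parameters of the network model — crosslinker strength
(Pa) and crosslinker density (multiples of the fiber count, "xN") —
are fitted by sweeping shear simulations over a (strength, density)
grid at several collagen concentrations, computing the sum of squared
residuals (SSR) against experimental shear moduli, iteratively
refining the SSR surface with bicubic spline interpolation on grids of
halved spacing, and re-simulating candidate minima to pick the
best-fit pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .params import (
    BoxSpec,
    CrosslinkerParams,
    EquilibriumCriterion,
    FiberSpec,
    InvalidParameterError,
)

__all__ = [
    "ExperimentalModuli",
    "SSRSurface",
    "load_experimental_moduli",
    "sweep_moduli",
    "ssr",
    "refine_surface",
    "validate_candidates",
]


@dataclass(frozen=True)
class ExperimentalModuli:
    """Experimental elastic shear moduli per collagen density (Pa)."""

    table: Mapping[float, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.table.values()):
            raise InvalidParameterError("moduli must be >= 0")

    @property
    def densities(self) -> tuple[float, ...]:
        return tuple(sorted(self.table))


def load_experimental_moduli() -> ExperimentalModuli:
    """Load the packaged shear-rheology moduli (1–4 mg/ml)."""
    with resources.files("fibernet.data").joinpath(
        "shear_rheology_moduli.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return ExperimentalModuli(
        dict(
            zip(df["collagen_density_mg_ml"], df["elastic_modulus_pa"])
        )
    )


def ssr(
    simulated: Mapping[float, float], experimental: ExperimentalModuli
) -> float:
    """Sum of squared residuals between simulated and experimental moduli.

    Pa².  The simulated table must cover every experimental density.
    """
    missing = [d for d in experimental.table if d not in simulated]
    if missing:
        raise KeyError(f"simulated moduli missing densities: {missing}")
    return float(
        sum(
            (simulated[d] - g) ** 2
            for d, g in experimental.table.items()
        )
    )


def sweep_moduli(
    densities: Sequence[float],
    strengths: Sequence[float],
    xl_densities: Sequence[float],
    replicates: int = 5,
    seed: int = 0,
    modulus_fn: Callable[[float, float, float, int], float] | None = None,
    **run_kwargs,
) -> pd.DataFrame:
    """Mean shear modulus over a (collagen, strength, xl-density) grid.

    Runs ``replicates`` independent networks per combination (each from
    its own spawned seed, logged in the output) and returns a long-form
    DataFrame with one row per cell: collagen_density, strength,
    xl_density, modulus (replicate mean, Pa), modulus_std, seeds.

    ``modulus_fn(collagen_density, strength, xl_density, seed)`` may be
    injected to replace the full simulation (testing, surrogates); by
    default :func:`fibernet.workflows.shear_modulus_run` is used with
    ``run_kwargs`` forwarded.
    """
    if not (len(densities) and len(strengths) and len(xl_densities)):
        raise InvalidParameterError("all parameter grids must be non-empty")
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    if modulus_fn is None:
        from .workflows import shear_modulus_run

        def modulus_fn(cd, s, xd, sd):  # pragma: no cover - thin default
            return shear_modulus_run(
                cd,
                CrosslinkerParams(strength=s, density_multiplier=xd),
                seed=sd,
                **run_kwargs,
            ).modulus

    ss = np.random.SeedSequence(seed)
    rows = []
    for cd in densities:
        for s in strengths:
            for xd in xl_densities:
                children = ss.spawn(replicates)
                seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]
                values = []
                errors = []
                for sd in seeds:
                    try:
                        values.append(float(modulus_fn(cd, s, xd, sd)))
                    except Exception as err:  # keep sweeping
                        errors.append(f"seed {sd}: {err}")
                rows.append(
                    dict(
                        collagen_density=cd,
                        strength=s,
                        xl_density=xd,
                        modulus=float(np.mean(values)) if values else np.nan,
                        modulus_std=(
                            float(np.std(values, ddof=1))
                            if len(values) > 1
                            else 0.0
                        ),
                        n_ok=len(values),
                        seeds=tuple(seeds),
                        errors="; ".join(errors),
                    )
                )
    return pd.DataFrame(rows)


@dataclass
class SSRSurface:
    """SSR as a function of crosslinker strength and density.

    ``ssr_values[i, j]`` corresponds to ``strength_grid[i]``,
    ``density_grid[j]``.  ``minima`` lists (strength, density, ssr,
    is_boundary) for every grid point not larger than its neighbors,
    sorted by SSR; the first entry is the global minimum.
    """

    strength_grid: np.ndarray
    density_grid: np.ndarray
    ssr_values: np.ndarray
    refinement_level: int = 0
    minima: list[tuple[float, float, float, bool]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.strength_grid = np.asarray(self.strength_grid, dtype=float)
        self.density_grid = np.asarray(self.density_grid, dtype=float)
        self.ssr_values = np.asarray(self.ssr_values, dtype=float)
        if self.ssr_values.shape != (
            self.strength_grid.size,
            self.density_grid.size,
        ):
            raise InvalidParameterError("ssr grid shape mismatch")
        for g in (self.strength_grid, self.density_grid):
            if g.size > 1 and not (np.diff(g) > 0).all():
                raise InvalidParameterError("grids must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.ssr_values) < 0:
                raise InvalidParameterError("SSR values must be >= 0")

    @classmethod
    def from_sweep(
        cls, sweep: pd.DataFrame, experimental: ExperimentalModuli
    ) -> "SSRSurface":
        """Collapse a sweep table into an SSR grid.

        The sweep must cover every experimental collagen density at
        every (strength, xl_density) cell; per-cell SSR uses the
        replicate-mean moduli.
        """
        strengths = np.sort(sweep["strength"].unique())
        xl_densities = np.sort(sweep["xl_density"].unique())
        values = np.empty((strengths.size, xl_densities.size))
        for i, s in enumerate(strengths):
            for j, xd in enumerate(xl_densities):
                cell = sweep[
                    (sweep["strength"] == s) & (sweep["xl_density"] == xd)
                ]
                simulated = dict(
                    zip(cell["collagen_density"], cell["modulus"])
                )
                values[i, j] = ssr(simulated, experimental)
        surface = cls(strengths, xl_densities, values)
        surface.minima = _find_minima(strengths, xl_densities, values)
        return surface


def _find_minima(
    sgrid: np.ndarray, dgrid: np.ndarray, values: np.ndarray
) -> list[tuple[float, float, float, bool]]:
    """Grid points not exceeded by any of their (up to 8) neighbors."""
    ni, nj = values.shape
    out = []
    for i in range(ni):
        for j in range(nj):
            v = values[i, j]
            if not np.isfinite(v):
                continue
            neigh = values[
                max(0, i - 1) : i + 2, max(0, j - 1) : j + 2
            ]
            if v <= np.nanmin(neigh):
                boundary = i in (0, ni - 1) or j in (0, nj - 1)
                out.append((float(sgrid[i]), float(dgrid[j]), float(v), boundary))
    out.sort(key=lambda t: t[2])
    return out


def _halved(grid: np.ndarray) -> np.ndarray:
    return np.linspace(grid[0], grid[-1], 2 * grid.size - 1)


def refine_surface(surface: SSRSurface, iterations: int = 7) -> SSRSurface:
    """Iterative spline refinement of the SSR surface.

    Each iteration fits a bicubic spline to the current grid and
    evaluates it on a grid with halved spacing.  Grids with fewer than
    4 points per axis fall back to the highest spline order they
    support.  Returns a new surface with located minima.
    """
    if iterations < 1:
        raise InvalidParameterError("iterations must be >= 1")
    sgrid = surface.strength_grid
    dgrid = surface.density_grid
    values = surface.ssr_values
    if np.isnan(values).any():
        raise InvalidParameterError(
            "SSR surface contains NaN cells; re-run the failed sweep cells"
        )
    for _ in range(iterations):
        kx = min(3, sgrid.size - 1)
        ky = min(3, dgrid.size - 1)
        if kx < 3 or ky < 3:
            import warnings

            warnings.warn(
                f"grid too small for bicubic spline; using orders ({kx},{ky})",
                stacklevel=2,
            )
        spline = RectBivariateSpline(sgrid, dgrid, values, kx=kx, ky=ky)
        sgrid = _halved(sgrid)
        dgrid = _halved(dgrid)
        values = spline(sgrid, dgrid)
    values = np.maximum(values, 0.0)  # spline overshoot below zero
    return SSRSurface(
        sgrid,
        dgrid,
        values,
        refinement_level=surface.refinement_level + iterations,
        minima=_find_minima(sgrid, dgrid, values),
    )


def validate_candidates(
    candidates: Sequence[tuple[float, float]],
    experimental: ExperimentalModuli,
    replicates: int = 5,
    seed: int = 0,
    surface: SSRSurface | None = None,
    modulus_fn: Callable[[float, float, float, int], float] | None = None,
    **run_kwargs,
) -> pd.DataFrame:
    """Re-simulate candidate (strength, density) pairs and rank by SSR.

    Returns a DataFrame with, per candidate, the spline-estimated SSR
    (if a refined surface is supplied) and the simulated SSR from
    ``replicates`` fresh networks per collagen density; the row with
    the lowest simulated SSR is flagged ``best_fit``.
    """
    if not candidates:
        raise InvalidParameterError("need at least one candidate")
    spline = None
    if surface is not None:
        spline = RectBivariateSpline(
            surface.strength_grid,
            surface.density_grid,
            surface.ssr_values,
            kx=min(3, surface.strength_grid.size - 1),
            ky=min(3, surface.density_grid.size - 1),
        )
    rows = []
    for n, (s, xd) in enumerate(candidates):
        sweep = sweep_moduli(
            experimental.densities,
            [s],
            [xd],
            replicates=replicates,
            seed=np.random.SeedSequence([seed, n]).generate_state(1)[0]
            % 2**31,
            modulus_fn=modulus_fn,
            **run_kwargs,
        )
        simulated = dict(
            zip(sweep["collagen_density"], sweep["modulus"])
        )
        rows.append(
            dict(
                strength=s,
                xl_density=xd,
                spline_ssr=(
                    float(spline(s, xd)[0, 0]) if spline is not None else np.nan
                ),
                simulated_ssr=ssr(simulated, experimental),
            )
        )
    df = pd.DataFrame(rows)
    df["best_fit"] = df["simulated_ssr"] == df["simulated_ssr"].min()
    return df
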