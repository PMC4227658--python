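"""Hookean network energy, forces, and quasi-static relaxation.

The total elastic potential energy is a sum over all fiber segments
and crosslinks of ½ k (ΔL)², with ΔL the deviation of the current
spring length from its rest length.  Relaxation moves only free
(unanchored) beads and uses nonlinear conjugate gradients
(Polak–Ribière+ with steepest-descent restarts and a secant line
search on the directional derivative, which is exact for quadratic
energy profiles).  The stopping rule is the quasi-equilibrium
criterion: the maximum free-bead force must drop to a small fraction
(default 1e-5) of its value in the strained state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import energy_gradient, lbfgs_relax, max_bead_force
from .network import FREE, NetworkState
from .params import EquilibriumCriterion

__all__ = [
    "EnergyReport",
    "ConvergenceRecord",
    "DegenerateGeometryError",
    "ConvergenceError",
    "energy_and_forces",
    "minimize",
]


class DegenerateGeometryError(RuntimeError):
    """Two bonded beads coincide; the spring direction is undefined."""


class ConvergenceError(RuntimeError):
    """Minimizer hit the iteration cap before reaching quasi-equilibrium.

    Carries the best state reached (``.state``) and its convergence
    record (``.record``).
    """

    def __init__(self, state: NetworkState, record: "ConvergenceRecord"):
        self.state = state
        self.record = record
        super().__init__(
            f"no quasi-equilibrium after {record.iterations} iterations "
            f"(max force {record.final_max_force:.3e} nN, "
            f"threshold {record.threshold:.3e} nN)"
        )


@dataclass
class EnergyReport:
    """Energy and per-bead forces of a network configuration.

    ``max_force`` is taken over all beads (anchored beads report the
    reaction force holding them in place); ``max_free_force`` is the
    quantity the quasi-equilibrium criterion acts on.
    """

    total_energy: float
    per_bead_forces: np.ndarray
    max_force: float
    max_free_force: float


@dataclass
class ConvergenceRecord:
    """Bookkeeping for one relaxation."""

    iterations: int
    converged: bool
    baseline_max_force: float
    threshold: float
    final_max_force: float
    final_energy: float
    n_evaluations: int
    energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def energy_and_forces(state: NetworkState) -> EnergyReport:
    """Evaluate the total elastic energy and all bead forces."""
    edges, k, rest = state.all_edges()
    grad = np.empty_like(state.positions)
    energy, degenerate = energy_gradient(
        state.positions, edges, k, rest, grad
    )
    if degenerate >= 0:
        i, j = edges[degenerate]
        raise DegenerateGeometryError(
            f"beads {i} and {j} coincide (spring {degenerate})"
        )
    forces = -grad
    norms = np.linalg.norm(forces, axis=1)
    free_idx = np.flatnonzero(state.anchor_label == FREE)
    max_free = float(norms[free_idx].max()) if free_idx.size else 0.0
    return EnergyReport(
        total_energy=float(energy),
        per_bead_forces=forces,
        max_force=float(norms.max()) if norms.size else 0.0,
        max_free_force=max_free,
    )


def minimize(
    state: NetworkState,
    criterion: EquilibriumCriterion | None = None,
    baseline_max_force: float | None = None,
    initial_positions: np.ndarray | None = None,
    keep_energy_trace: bool = False,
    method: str = "lbfgs",
) -> tuple[NetworkState, ConvergenceRecord]:
    """Relax free beads to quasi-equilibrium; anchored beads never move.

    Parameters
    ----------
    baseline_max_force
        Maximum free-bead force of the strained state (recorded right
        after the most recent boundary displacement).  If omitted it is
        measured on the input configuration.
    initial_positions
        Optional starting guess for the optimizer (e.g. an affine
        displacement field).  Anchored rows are ignored; the guess does
        not affect which minimum counts as converged, only how fast it
        is reached.
    method
        ``"lbfgs"`` (default): compiled limited-memory BFGS descent.
        ``"cg"``: preconditioned Polak–Ribière+ conjugate gradients
        with a secant line search.  Both minimize the same energy to
        the same force criterion; CG is kept as an independent engine
        for cross-validation and convergence-trace logging.

    Returns the relaxed state and a :class:`ConvergenceRecord`.  Raises
    :class:`ConvergenceError` (carrying the best state) if the
    iteration cap is reached first.
    """
    if criterion is None:
        criterion = EquilibriumCriterion()
    if method not in ("lbfgs", "cg"):
        raise ValueError(f"unknown method {method!r}")
    out = state.copy()
    pos = out.positions
    free = np.flatnonzero(out.anchor_label == FREE)
    edges, k, rest = out.all_edges()
    grad = np.empty_like(pos)
    n_evals = 0

    def full_eval() -> tuple[float, np.ndarray]:
        nonlocal n_evals
        energy, degenerate = energy_gradient(pos, edges, k, rest, grad)
        n_evals += 1
        if degenerate >= 0:
            i, j = edges[degenerate]
            raise DegenerateGeometryError(
                f"beads {i} and {j} coincide (spring {degenerate})"
            )
        return energy, grad[free].ravel().copy()

    if baseline_max_force is None:
        energy_gradient(pos, edges, k, rest, grad)
        n_evals += 1
        baseline_max_force = float(max_bead_force(grad, free))
    threshold = criterion.force_threshold(baseline_max_force)

    if initial_positions is not None:
        pos[free] = initial_positions[free]

    if free.size == 0 or edges.shape[0] == 0:
        rec = ConvergenceRecord(
            iterations=0,
            converged=True,
            baseline_max_force=baseline_max_force,
            threshold=threshold,
            final_max_force=0.0,
            final_energy=energy_and_forces(out).total_energy,
            n_evaluations=n_evals,
        )
        return out, rec

    if method == "lbfgs":
        iterations, converged, final_max, energy, evals, degen = lbfgs_relax(
            pos,
            free.astype(np.int64),
            edges,
            k,
            rest,
            threshold,
            criterion.max_iterations,
            10,
        )
        n_evals += evals
        if degen >= 0:
            i, j = edges[degen]
            raise DegenerateGeometryError(
                f"beads {i} and {j} coincide (spring {degen})"
            )
        record = ConvergenceRecord(
            iterations=iterations,
            converged=bool(converged),
            baseline_max_force=float(baseline_max_force),
            threshold=float(threshold),
            final_max_force=float(final_max),
            final_energy=float(energy),
            n_evaluations=n_evals,
        )
        if not record.converged:
            raise ConvergenceError(out, record)
        return out, record

    def bead_max(gflat: np.ndarray) -> float:
        gf = gflat.reshape(-1, 3)
        return float(np.sqrt(np.einsum("ij,ij->i", gf, gf).max()))

    x = pos[free].ravel().copy()

    def set_x(vec: np.ndarray) -> None:
        pos[free] = vec.reshape(-1, 3)

    # Jacobi preconditioner: per-bead sum of incident spring constants
    # approximates the Hessian diagonal; crosslink constants span two
    # orders of magnitude, so this substantially evens out the spectrum.
    stiff = np.zeros(pos.shape[0])
    np.add.at(stiff, edges[:, 0], k)
    np.add.at(stiff, edges[:, 1], k)
    minv = np.repeat(1.0 / np.maximum(stiff[free], 1e-30), 3)

    set_x(x)
    energy, g = full_eval()
    trace: list[float] = [energy] if keep_energy_trace else []
    y = minv * g
    d = -y
    gy = float(g @ y)
    # preconditioned steepest descent has natural step scale ~1
    alpha_prev = 1.0
    iterations = 0
    converged = bead_max(g) <= threshold

    while not converged and iterations < criterion.max_iterations:
        iterations += 1
        dg0 = float(d @ g)
        if dg0 >= 0.0:  # lost descent direction: restart
            d = -y
            dg0 = -gy
        if dg0 == 0.0:
            break

        # --- secant line search on h(a) = g(x + a d) . d ------------
        a1 = alpha_prev
        set_x(x + a1 * d)
        e1, g1 = full_eval()
        h1 = float(d @ g1)
        if abs(h1) <= 0.5 * abs(dg0) and e1 <= energy:
            a, e_new, g_new = a1, e1, g1
        else:
            denom = dg0 - h1
            a = a1 * dg0 / denom if denom != 0.0 else 0.5 * a1
            if not np.isfinite(a) or a <= 0.0:
                a = 0.5 * a1
            set_x(x + a * d)
            e_new, g_new = full_eval()
            # backtrack on energy increase (rare: strong nonlinearity)
            shrink = 0
            while e_new > energy and shrink < 40:
                a *= 0.5
                set_x(x + a * d)
                e_new, g_new = full_eval()
                shrink += 1
            if e_new > energy:  # no progress along d: restart next iter
                set_x(x)
                d = -y
                continue

        x = x + a * d
        set_x(x)
        alpha_prev = a
        if keep_energy_trace:
            trace.append(e_new)

        if bead_max(g_new) <= threshold:
            energy, g = e_new, g_new
            converged = True
            break
        y_new = minv * g_new
        gy_new = float(g_new @ y_new)
        beta = max(0.0, float(g_new @ (y_new - y)) / gy) if gy > 0 else 0.0
        d = -y_new + beta * d
        energy, g, y, gy = e_new, g_new, y_new, gy_new

    final_max = bead_max(g)
    record = ConvergenceRecord(
        iterations=iterations,
        converged=bool(converged or final_max <= threshold),
        baseline_max_force=float(baseline_max_force),
        threshold=float(threshold),
        final_max_force=final_max,
        final_energy=float(energy),
        n_evaluations=n_evals,
        energy_trace=np.asarray(trace),
    )
    if not record.converged:
        raise ConvergenceError(out, record)
    return out, record
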