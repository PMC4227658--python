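"""Quasi-static loading protocols: shear, tensile, and local poke.

Each protocol is a sequence of imposed rigid boundary displacements,
each followed by relaxation of the free beads to quasi-equilibrium.
Strain is defined relative to the free (unanchored) height of the box,
so with the default geometry one 0.01 strain step displaces the top
grip by 2 µm.  The poke test instead anchors a small test cube at the
box center and the outer shell of the box, then drags the cube upward
step by step, mimicking a pseudopod pulling on the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mechanics import (
    ConvergenceError,
    ConvergenceRecord,
    EnergyReport,
    energy_and_forces,
    minimize,
)
from .network import BOTTOM, CUBE, FREE, SHELL, TOP, NetworkState
from .params import BoxSpec, EquilibriumCriterion, InvalidParameterError

__all__ = [
    "DeformationProtocol",
    "TrajectoryRecord",
    "Trajectory",
    "ProtocolError",
    "apply_shear_step",
    "apply_tensile_step",
    "label_poke_anchors",
    "apply_poke_step",
    "run_protocol",
]


class ProtocolError(RuntimeError):
    """Protocol misconfiguration or mid-run failure.

    When raised because a relaxation did not converge, the partial
    trajectory accumulated so far is attached as ``.trajectory``.
    """

    def __init__(self, msg: str, trajectory: "Trajectory | None" = None):
        self.trajectory = trajectory
        super().__init__(msg)


@dataclass(frozen=True)
class DeformationProtocol:
    """One loading experiment.

    ``strain_step`` is dimensionless for shear/tensile modes and µm of
    cube displacement for poke mode.  ``test_cube`` is (center xyz,
    edge length) and only meaningful for poke; ``outer_anchor_depth``
    is the thickness of the fixed outer shell in the poke test.
    """

    mode: str  # shear_y | tensile_z | poke_z
    strain_step: float = 0.01
    n_steps: int = 10
    test_cube: Optional[tuple[tuple[float, float, float], float]] = None
    outer_anchor_depth: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("shear_y", "tensile_z", "poke_z"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.strain_step <= 0:
            raise InvalidParameterError("strain_step must be > 0")
        if self.mode == "poke_z" and self.test_cube is None:
            raise InvalidParameterError("poke_z requires test_cube")


@dataclass
class TrajectoryRecord:
    step: int
    strain: float  # cumulative strain (or µm displacement for poke)
    state: NetworkState
    energy: EnergyReport
    convergence: ConvergenceRecord


@dataclass
class Trajectory:
    """Relaxed snapshots of one protocol run, plus the initial state."""

    mode: str
    initial_state: NetworkState
    records: list[TrajectoryRecord] = field(default_factory=list)

    def strains(self) -> np.ndarray:
        return np.array([r.strain for r in self.records])

    def at_strain(self, strain: float, atol: float = 1e-9) -> TrajectoryRecord:
        for r in self.records:
            if abs(r.strain - strain) <= atol:
                return r
        raise KeyError(f"no trajectory record at strain {strain}")


def _require_anchors(state: NetworkState, labels: tuple[int, ...]) -> None:
    present = set(np.unique(state.anchor_label).tolist())
    missing = [l for l in labels if l not in present]
    if missing:
        raise ProtocolError(f"missing anchor labels {missing}; assign them first")


def apply_shear_step(
    state: NetworkState, box: BoxSpec, step: float
) -> NetworkState:
    """Translate the top grip rigidly by step x free_height along +y."""
    _require_anchors(state, (BOTTOM, TOP))
    out = state.copy()
    if step != 0.0:
        out.positions[out.anchor_label == TOP, 1] += step * box.free_height
    return out


def apply_tensile_step(
    state: NetworkState, box: BoxSpec, step: float
) -> NetworkState:
    """Move top grip +z and bottom grip -z, each by half the step."""
    _require_anchors(state, (BOTTOM, TOP))
    out = state.copy()
    if step != 0.0:
        dz = 0.5 * step * box.free_height
        out.positions[out.anchor_label == TOP, 2] += dz
        out.positions[out.anchor_label == BOTTOM, 2] -= dz
    return out


def label_poke_anchors(
    state: NetworkState, box: BoxSpec, protocol: DeformationProtocol
) -> NetworkState:
    """Relabel anchors for the local-deformation test.

    Beads inside the test cube become the rigidly displaced group;
    beads within ``outer_anchor_depth`` of any box face are fixed.
    Membership is decided once, on the configuration given here.
    """
    if protocol.test_cube is None:
        raise ProtocolError("poke protocol needs a test_cube")
    (cx, cy, cz), edge = protocol.test_cube
    half = edge / 2.0
    out = state.copy()
    p = out.positions
    labels = np.full(state.n_beads, FREE, dtype=np.int8)
    d = protocol.outer_anchor_depth
    shell = (
        (p[:, 0] < d)
        | (p[:, 0] > box.length_x - d)
        | (p[:, 1] < d)
        | (p[:, 1] > box.width_y - d)
        | (p[:, 2] < d)
        | (p[:, 2] > box.height_z - d)
    )
    cube = (
        (np.abs(p[:, 0] - cx) <= half)
        & (np.abs(p[:, 1] - cy) <= half)
        & (np.abs(p[:, 2] - cz) <= half)
    )
    labels[shell] = SHELL
    labels[cube] = CUBE  # cube wins if the two ever overlapped
    out.anchor_label = labels
    return out


def apply_poke_step(state: NetworkState, step_um: float) -> NetworkState:
    """Displace the test cube rigidly by ``step_um`` along +z."""
    _require_anchors(state, (CUBE,))
    out = state.copy()
    out.positions[out.anchor_label == CUBE, 2] += step_um
    return out


def _affine_guess(
    positions: np.ndarray,
    labels: np.ndarray,
    box: BoxSpec,
    mode: str,
    step: float,
) -> np.ndarray:
    """Affine displacement of free beads matching the boundary step.

    Used only as the optimizer's starting guess; the relaxed state it
    converges to is defined by the energy, not by this map.
    """
    guess = positions.copy()
    freem = labels == FREE
    z = positions[freem, 2]
    h = box.free_height
    if mode == "shear_y":
        frac = np.clip((z - box.anchor_depth) / h, 0.0, 1.0)
        guess[freem, 1] += step * h * frac
    elif mode == "tensile_z":
        zc = box.height_z / 2.0
        frac = np.clip((z - zc) / (h / 2.0), -1.0, 1.0)
        guess[freem, 2] += 0.5 * step * h * frac
    return guess


def run_protocol(
    state: NetworkState,
    protocol: DeformationProtocol,
    criterion: EquilibriumCriterion | None = None,
    box: BoxSpec | None = None,
) -> Trajectory:
    """Run a full loading experiment from a relaxed initial state.

    For each step: impose the boundary displacement, record the maximum
    free-bead force of that strained state (the baseline of the
    quasi-equilibrium criterion), relax, and append a record.  Poke
    mode expects anchor labels from :func:`label_poke_anchors`.
    """
    if box is None:
        box = BoxSpec()
    if criterion is None:
        criterion = EquilibriumCriterion()
    traj = Trajectory(mode=protocol.mode, initial_state=state.copy())
    current = state
    cumulative = 0.0
    for istep in range(1, protocol.n_steps + 1):
        if protocol.mode == "shear_y":
            strained = apply_shear_step(current, box, protocol.strain_step)
        elif protocol.mode == "tensile_z":
            strained = apply_tensile_step(current, box, protocol.strain_step)
        else:
            strained = apply_poke_step(current, protocol.strain_step)
        cumulative += protocol.strain_step

        baseline = energy_and_forces(strained).max_free_force
        guess = None
        if protocol.mode in ("shear_y", "tensile_z"):
            guess = _affine_guess(
                strained.positions,
                strained.anchor_label,
                box,
                protocol.mode,
                protocol.strain_step,
            )
        try:
            relaxed, record = minimize(
                strained,
                criterion,
                baseline_max_force=baseline,
                initial_positions=guess,
            )
        except ConvergenceError as err:
            raise ProtocolError(
                f"step {istep} (strain {cumulative:g}) did not converge: {err}",
                trajectory=traj,
            ) from err
        traj.records.append(
            TrajectoryRecord(
                step=istep,
                strain=cumulative,
                state=relaxed,
                energy=energy_and_forces(relaxed),
                convergence=record,
            )
        )
        current = relaxed
    return traj
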