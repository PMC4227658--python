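"""High-level experiment runners shared by the CLI, tests, and scripts.

Each runner builds a network from a single seed, applies one protocol,
and reduces the trajectory to the observable of interest.  They are
deliberately thin compositions of the lower-level modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ExperimentalModuli
from .network import NetworkState, build_network
from .observables import (
    ForceStats,
    PoissonRecord,
    StressStrainCurve,
    force_statistics,
    modulus_from_curve,
    poisson_ratio,
)
from .params import BoxSpec, CrosslinkerParams, EquilibriumCriterion, FiberSpec
from .protocols import (
    DeformationProtocol,
    Trajectory,
    label_poke_anchors,
    run_protocol,
)

__all__ = [
    "shear_modulus_run",
    "tensile_run",
    "poisson_run",
    "poke_run",
    "PokeResult",
]


def shear_modulus_run(
    density: float,
    xl_params: CrosslinkerParams | None = None,
    seed: int = 0,
    geometry: str = "random",
    box: BoxSpec | None = None,
    fiber_spec: FiberSpec | None = None,
    criterion: EquilibriumCriterion | None = None,
    n_steps: int = 10,
    strain_step: float = 0.01,
    strain_window: tuple[float, float] = (0.01, 0.10),
) -> StressStrainCurve:
    """Build a network, shear it step-wise, return the stress-strain
    curve with the regression modulus (Pa) filled in."""
    box = box or BoxSpec()
    fiber_spec = fiber_spec or FiberSpec()
    xl_params = xl_params or CrosslinkerParams()
    state = build_network(density, box, fiber_spec, xl_params, geometry, seed)
    proto = DeformationProtocol(
        mode="shear_y", strain_step=strain_step, n_steps=n_steps
    )
    traj = run_protocol(state, proto, criterion, box)
    curve = StressStrainCurve.from_trajectory(traj, box, replicate_id=seed)
    curve.modulus = modulus_from_curve(curve, strain_window)
    return curve


def tensile_run(
    density: float,
    xl_params: CrosslinkerParams | None = None,
    seed: int = 0,
    geometry: str = "random",
    box: BoxSpec | None = None,
    fiber_spec: FiberSpec | None = None,
    criterion: EquilibriumCriterion | None = None,
    n_steps: int = 10,
    strain_step: float = 0.01,
) -> Trajectory:
    """Build a network and run a step-wise tensile test."""
    box = box or BoxSpec()
    fiber_spec = fiber_spec or FiberSpec()
    xl_params = xl_params or CrosslinkerParams()
    state = build_network(density, box, fiber_spec, xl_params, geometry, seed)
    proto = DeformationProtocol(
        mode="tensile_z", strain_step=strain_step, n_steps=n_steps
    )
    return run_protocol(state, proto, criterion, box)


def poisson_run(
    density: float,
    at_strain: float,
    xl_params: CrosslinkerParams | None = None,
    seed: int = 0,
    geometry: str = "random",
    box: BoxSpec | None = None,
    fiber_spec: FiberSpec | None = None,
    criterion: EquilibriumCriterion | None = None,
    strain_step: float = 0.01,
) -> PoissonRecord:
    """Tensile test up to ``at_strain``; Poisson's ratio there."""
    n_steps = int(round(at_strain / strain_step))
    if abs(n_steps * strain_step - at_strain) > 1e-9:
        raise ValueError("at_strain must be a multiple of strain_step")
    box = box or BoxSpec()
    traj = tensile_run(
        density,
        xl_params,
        seed,
        geometry,
        box,
        fiber_spec,
        criterion,
        n_steps=n_steps,
        strain_step=strain_step,
    )
    return poisson_ratio(traj, box, at_strain)


@dataclass
class PokeResult:
    trajectory: Trajectory
    stats: list[ForceStats]  # at the final displacement


def poke_run(
    density: float = 2.0,
    xl_params: CrosslinkerParams | None = None,
    seed: int = 0,
    box: BoxSpec | None = None,
    fiber_spec: FiberSpec | None = None,
    criterion: EquilibriumCriterion | None = None,
    cube_edge: float = 20.0,
    displacement: float = 60.0,
    step: float = 2.0,
    outer_anchor_depth: float = 50.0,
) -> PokeResult:
    """Local-deformation test: drag a small anchored cube through the gel.

    Default geometry is a 300³ µm box with a 20 µm test cube at the
    center displaced 60 µm upward in 2 µm steps, with the outer 50 µm
    shell fixed.
    """
    box = box or BoxSpec(
        length_x=300.0, width_y=300.0, height_z=300.0, anchor_depth=50.0
    )
    fiber_spec = fiber_spec or FiberSpec()
    xl_params = xl_params or CrosslinkerParams()
    n_steps = int(round(displacement / step))
    center = (box.length_x / 2.0, box.width_y / 2.0, box.height_z / 2.0)
    proto = DeformationProtocol(
        mode="poke_z",
        strain_step=step,
        n_steps=n_steps,
        test_cube=(center, cube_edge),
        outer_anchor_depth=outer_anchor_depth,
    )
    state = build_network(density, box, fiber_spec, xl_params, "random", seed)
    state = label_poke_anchors(state, box, proto)
    traj = run_protocol(state, proto, criterion, box)
    final = traj.records[-1]
    stats = force_statistics(
        final.state, forces=final.energy.per_bead_forces
    )
    return PokeResult(trajectory=traj, stats=stats)
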