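"""Small deterministic networks for tests, demos, and sanity checks.

``two_fiber``  — the minimal schematic: two fibers joined by a single
crosslinker, one anchored bead; useful for reasoning about fiber
rotation vs stretching.

``ladder``     — parallel vertical fibers spanning both grips with
horizontal rungs; under tension the rungs stay at rest length, so the
stress follows the series/parallel spring closed form exactly.

``mini_random``— a seeded ~20-fiber random network in a 60x60x90 µm
box, small enough for exhaustive invariant checks.
"""

from __future__ import annotations

import numpy as np

from .network import (
    BOTTOM,
    FREE,
    NetworkState,
    generate_fibers,
    place_crosslinkers,
    segment_spring_constant,
)
from .params import BoxSpec, CrosslinkerParams, FiberSpec

__all__ = ["make_fixture", "FIXTURE_NAMES", "ladder_tensile_stress"]

FIXTURE_NAMES = ("two_fiber", "ladder", "mini_random")

#: Geometry shared by the fixtures (µm).
MINI_BOX = BoxSpec(length_x=60.0, width_y=60.0, height_z=90.0, anchor_depth=15.0)
MINI_FIBER = FiberSpec(length=30.0)
LADDER_FIBER = FiberSpec(length=90.0, beads_per_fiber=4)
LADDER_XL = CrosslinkerParams(strength=400e3, density_multiplier=0.0)


def make_fixture(name: str, seed: int = 0) -> NetworkState:
    if name == "two_fiber":
        return _two_fiber()
    if name == "ladder":
        return _ladder()
    if name == "mini_random":
        return _mini_random(seed)
    raise ValueError(
        f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
    )


def _two_fiber() -> NetworkState:
    """Two 2-bead fibers, one crosslinker, bottom bead anchored."""
    spec = FiberSpec(length=10.0, beads_per_fiber=2)
    xl = CrosslinkerParams(strength=400e3)
    positions = np.array(
        [
            [0.0, 0.0, 0.0],  # fiber 0, anchored end
            [6.0, 0.0, 8.0],
            [7.0, 0.0, 9.0],  # fiber 1
            [13.0, 0.0, 17.0],
        ]
    )
    k_seg = segment_spring_constant(spec)
    rest_xl = float(np.linalg.norm(positions[2] - positions[1]))
    labels = np.array([BOTTOM, FREE, FREE, FREE], dtype=np.int8)
    return NetworkState(
        positions=positions,
        fiber_of_bead=np.array([0, 0, 1, 1], dtype=np.int32),
        seg_edges=np.array([[0, 1], [2, 3]], dtype=np.int32),
        seg_rest=np.full(2, spec.length),
        seg_k=np.full(2, k_seg),
        xl_edges=np.array([[1, 2]], dtype=np.int32),
        xl_rest=np.array([rest_xl]),
        xl_k=np.array([xl.spring_constant(rest_xl, spec)]),
        anchor_label=labels,
        rng_seed=0,
    )


def _ladder(n_rails: int = 4) -> NetworkState:
    """Vertical rails spanning the box, rungs between neighbors.

    Rails sit on a line in x at mid-box y; each rail's 4 beads are at
    z = 0, 30, 60, 90, so the end beads fall in the anchor slabs.
    Rungs (crosslinks) join beads of adjacent rails at equal heights
    and stay at rest under any uniform vertical stretch.
    """
    box = MINI_BOX
    spec = LADDER_FIBER
    nb = spec.beads_per_fiber
    xs = np.linspace(20.0, 40.0, n_rails)
    positions = []
    fiber_of_bead = []
    for f, x in enumerate(xs):
        for b in range(nb):
            positions.append([x, box.width_y / 2.0, b * spec.segment_length])
            fiber_of_bead.append(f)
    positions = np.array(positions)
    fiber_of_bead = np.array(fiber_of_bead, dtype=np.int32)
    seg_edges = []
    for f in range(n_rails):
        for b in range(nb - 1):
            seg_edges.append([f * nb + b, f * nb + b + 1])
    seg_edges = np.array(seg_edges, dtype=np.int32)
    k_seg = segment_spring_constant(spec)

    xl_edges = []
    for f in range(n_rails - 1):
        for b in range(nb):
            xl_edges.append([f * nb + b, (f + 1) * nb + b])
    xl_edges = np.array(xl_edges, dtype=np.int32)
    rung = float(xs[1] - xs[0])
    xl_rest = np.full(len(xl_edges), rung)
    xl_k = np.full(
        len(xl_edges), LADDER_XL.spring_constant(rung, spec)
    )

    labels = np.full(positions.shape[0], FREE, dtype=np.int8)
    labels[positions[:, 2] < box.anchor_depth] = BOTTOM
    labels[positions[:, 2] > box.height_z - box.anchor_depth] = 2  # TOP
    return NetworkState(
        positions=positions,
        fiber_of_bead=fiber_of_bead,
        seg_edges=seg_edges,
        seg_rest=np.full(len(seg_edges), spec.segment_length),
        seg_k=np.full(len(seg_edges), k_seg),
        xl_edges=xl_edges,
        xl_rest=xl_rest,
        xl_k=xl_k,
        anchor_label=labels,
        rng_seed=0,
    )


def ladder_tensile_stress(strain: float, n_rails: int = 4) -> float:
    """Closed-form mid-plane tensile stress of the ladder fixture, Pa.

    Each rail is a chain of ``beads_per_fiber - 1`` equal springs in
    series between the grips; rungs carry no load under uniform
    vertical stretch.  Tension per rail = k/(nb-1) * strain*free_height,
    stress = n_rails * tension / box cross-section.
    """
    spec = LADDER_FIBER
    box = MINI_BOX
    k_seg = segment_spring_constant(spec)
    n_series = spec.beads_per_fiber - 1
    elongation = strain * box.free_height
    tension = k_seg / n_series * elongation  # nN
    return n_rails * tension / box.cross_area * 1e3  # Pa


def _mini_random(seed: int) -> NetworkState:
    xl = CrosslinkerParams(
        strength=400e3,
        density_multiplier=8.0,
        max_binding_distance=20.0,
    )
    state = generate_fibers(20, MINI_BOX, MINI_FIBER, "random", seed)
    return place_crosslinkers(state, xl, MINI_FIBER, seed=seed + 1)
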