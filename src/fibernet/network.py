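"""Network construction: fibers, anchors, and crosslinker placement.

A network is built in two stages: :func:`generate_fibers` lays down
straight bead chains (random or prealigned orientations) at the fiber
count implied by the bulk collagen concentration, then
:func:`place_crosslinkers` wires beads on different fibers together
with Hookean crosslink springs by rejection sampling under distance and
valence constraints.  A freshly built network has every spring exactly
at rest, so its elastic energy is zero and it is already at a minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    BoxSpec,
    CrosslinkerParams,
    FiberSpec,
    InvalidParameterError,
)
from .units import MG_PER_ML_TO_G_PER_UM3, PA_TO_NN_PER_UM2

__all__ = [
    "FREE",
    "BOTTOM",
    "TOP",
    "CUBE",
    "SHELL",
    "ANCHOR_LABELS",
    "NetworkState",
    "CrosslinkSaturationError",
    "fiber_count_from_density",
    "segment_spring_constant",
    "generate_fibers",
    "place_crosslinkers",
    "build_network",
]

# Anchor labels.  FREE beads are moved by the minimizer; all other
# labels denote beads owned by a rigid boundary group.  CUBE and SHELL
# are the "custom" labels used by the local-deformation (poke) test.
FREE, BOTTOM, TOP, CUBE, SHELL = 0, 1, 2, 3, 4
ANCHOR_LABELS = {
    FREE: "free",
    BOTTOM: "bottom",
    TOP: "top",
    CUBE: "cube",
    SHELL: "shell",
}


class CrosslinkSaturationError(RuntimeError):
    """Crosslinker placement could not reach the requested count."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"crosslink placement saturated: {achieved}/{requested} placed"
        )


@dataclass
class NetworkState:
    """Mutable simulation state: beads, springs, anchor labels.

    Arrays
    ------
    positions : (n_beads, 3) float64, µm.
    fiber_of_bead : (n_beads,) int32, fiber index of each bead.
    seg_edges / xl_edges : (m, 2) int32 bead-index pairs for fiber
        segments and crosslinks respectively.
    seg_rest, seg_k, xl_rest, xl_k : rest lengths (µm) and spring
        constants (nN/µm).
    anchor_label : (n_beads,) int8, one of FREE/BOTTOM/TOP/CUBE/SHELL.
    """

    positions: np.ndarray
    fiber_of_bead: np.ndarray
    seg_edges: np.ndarray
    seg_rest: np.ndarray
    seg_k: np.ndarray
    xl_edges: np.ndarray
    xl_rest: np.ndarray
    xl_k: np.ndarray
    anchor_label: np.ndarray
    rng_seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fibers(self) -> int:
        return int(self.fiber_of_bead.max()) + 1 if self.n_beads else 0

    @property
    def n_crosslinks(self) -> int:
        return self.xl_edges.shape[0]

    def all_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated (edges, spring constants, rest lengths)."""
        edges = np.vstack([self.seg_edges, self.xl_edges]).astype(np.int64)
        k = np.concatenate([self.seg_k, self.xl_k])
        rest = np.concatenate([self.seg_rest, self.xl_rest])
        return edges, k, rest

    def copy(self) -> "NetworkState":
        return NetworkState(
            positions=self.positions.copy(),
            fiber_of_bead=self.fiber_of_bead,
            seg_edges=self.seg_edges,
            seg_rest=self.seg_rest,
            seg_k=self.seg_k,
            xl_edges=self.xl_edges,
            xl_rest=self.xl_rest,
            xl_k=self.xl_k,
            anchor_label=self.anchor_label.copy(),
            rng_seed=self.rng_seed,
        )

    def validate(self) -> None:
        """Check structural invariants; raise ``AssertionError`` on failure."""
        assert self.positions.shape == (self.n_beads, 3)
        if self.seg_edges.size:
            same = (
                self.fiber_of_bead[self.seg_edges[:, 0]]
                == self.fiber_of_bead[self.seg_edges[:, 1]]
            )
            assert same.all(), "segment endpoints must share a fiber"
            assert (self.seg_k > 0).all()
            assert (self.seg_rest > 0).all()
        if self.xl_edges.size:
            diff = (
                self.fiber_of_bead[self.xl_edges[:, 0]]
                != self.fiber_of_bead[self.xl_edges[:, 1]]
            )
            assert diff.all(), "crosslink endpoints must be on different fibers"
            assert (self.xl_rest > 0).all()
            assert (self.xl_k >= 0).all()


def fiber_count_from_density(
    density: float, box: BoxSpec, spec: FiberSpec
) -> int:
    """Number of fibers at a bulk collagen concentration (mg/ml).

    The box must hold a total fiber mass equal to density x volume;
    the per-fiber mass follows from the fibril molecular weight and the
    fibril/fiber cylinder volumes (see :attr:`FiberSpec.mass`).
    """
    if density <= 0:
        raise InvalidParameterError("collagen density must be > 0")
    total_mass = density * MG_PER_ML_TO_G_PER_UM3 * box.volume  # g
    return int(round(total_mass / spec.mass))


def segment_spring_constant(spec: FiberSpec) -> float:
    """Hookean constant k = E*A/L of one fiber segment, nN/µm."""
    e_internal = spec.youngs_modulus * PA_TO_NN_PER_UM2  # nN/µm²
    return e_internal * spec.cross_section / spec.segment_length


def _anchor_labels_from_z(z: np.ndarray, box: BoxSpec) -> np.ndarray:
    labels = np.full(z.shape, FREE, dtype=np.int8)
    labels[z < box.anchor_depth] = BOTTOM
    labels[z > box.height_z - box.anchor_depth] = TOP
    return labels


def generate_fibers(
    n_fibers: int,
    box: BoxSpec,
    spec: FiberSpec,
    geometry: str = "random",
    seed: int = 0,
) -> NetworkState:
    """Lay down straight fibers; no crosslinks yet.

    Each fiber is a chain of ``spec.beads_per_fiber`` equally spaced
    beads.  Fiber centers are uniform in the box; orientations are
    uniform on the unit sphere (``geometry="random"``) or fixed along
    +z (``geometry="prealigned"``).  Beads may protrude outside the box
    (fibers do not interact with the walls).  Anchor labels are set by
    bead height: bottom slab, top slab, free in between.
    """
    if n_fibers < 1:
        raise InvalidParameterError("n_fibers must be >= 1")
    if geometry not in ("random", "prealigned"):
        raise InvalidParameterError(
            f"geometry must be 'random' or 'prealigned', got {geometry!r}"
        )
    rng = np.random.default_rng(seed)
    nb = spec.beads_per_fiber
    centers = rng.uniform(
        low=[0.0, 0.0, 0.0],
        high=[box.length_x, box.width_y, box.height_z],
        size=(n_fibers, 3),
    )
    if geometry == "prealigned":
        unit = np.zeros((n_fibers, 3))
        unit[:, 2] = 1.0
    else:
        v = rng.normal(size=(n_fibers, 3))
        unit = v / np.linalg.norm(v, axis=1, keepdims=True)

    # bead offsets along the fiber axis, centered on the fiber midpoint
    offsets = (np.arange(nb) - (nb - 1) / 2.0) * spec.segment_length
    positions = (
        centers[:, None, :] + offsets[None, :, None] * unit[:, None, :]
    ).reshape(-1, 3)

    fiber_of_bead = np.repeat(np.arange(n_fibers, dtype=np.int32), nb)
    base = np.arange(n_fibers, dtype=np.int32)[:, None] * nb
    local = np.arange(nb - 1, dtype=np.int32)[None, :]
    seg_i = (base + local).ravel()
    seg_edges = np.stack([seg_i, seg_i + 1], axis=1)
    n_segs = seg_edges.shape[0]
    k_seg = segment_spring_constant(spec)

    return NetworkState(
        positions=positions,
        fiber_of_bead=fiber_of_bead,
        seg_edges=seg_edges,
        seg_rest=np.full(n_segs, spec.segment_length),
        seg_k=np.full(n_segs, k_seg),
        xl_edges=np.empty((0, 2), dtype=np.int32),
        xl_rest=np.empty(0),
        xl_k=np.empty(0),
        anchor_label=_anchor_labels_from_z(positions[:, 2], box),
        rng_seed=seed,
    )


def place_crosslinkers(
    state: NetworkState,
    params: CrosslinkerParams,
    spec: FiberSpec,
    seed: int = 0,
    max_consecutive_rejections: int = 1_000_000,
    _batch: int = 20_000,
) -> NetworkState:
    """Add crosslink springs between beads on different fibers.

    The target count is round(density_multiplier x n_fibers).  Pairs
    are drawn uniformly at random and accepted when the beads sit on
    distinct fibers, their distance lies inside the binding window,
    neither bead is at its valence cap, and the pair is not already
    linked.  The rest length of an accepted crosslink is the distance
    at creation, so insertion adds no prestress.  Raises
    :class:`CrosslinkSaturationError` after ``max_consecutive_rejections``
    rejected draws in a row.
    """
    if state.n_crosslinks:
        raise InvalidParameterError("state already has crosslinks")
    target = int(round(params.density_multiplier * state.n_fibers))
    out = state.copy()
    if target == 0:
        return out

    rng = np.random.default_rng(seed)
    n = state.n_beads
    pos = state.positions
    fiber = state.fiber_of_bead
    valence = np.zeros(n, dtype=np.int64)
    linked: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    rests: list[float] = []
    placed = 0
    rejected_streak = 0

    while placed < target:
        ii = rng.integers(0, n, size=_batch)
        jj = rng.integers(0, n, size=_batch)
        d = np.linalg.norm(pos[jj] - pos[ii], axis=1)
        ok = (
            (fiber[ii] != fiber[jj])
            & (d >= params.min_binding_distance)
            & (d <= params.max_binding_distance)
        )
        # sequential pass: valence and duplicate constraints are
        # order-dependent, so they cannot be vectorized
        for m in range(_batch):
            if not ok[m]:
                rejected_streak += 1
                if rejected_streak >= max_consecutive_rejections:
                    raise CrosslinkSaturationError(target, placed)
                continue
            i, j = int(ii[m]), int(jj[m])
            key = (i, j) if i < j else (j, i)
            if (
                valence[i] >= params.max_per_bead
                or valence[j] >= params.max_per_bead
                or key in linked
            ):
                rejected_streak += 1
                if rejected_streak >= max_consecutive_rejections:
                    raise CrosslinkSaturationError(target, placed)
                continue
            linked.add(key)
            valence[i] += 1
            valence[j] += 1
            edges.append(key)
            rests.append(float(d[m]))
            rejected_streak = 0
            placed += 1
            if placed == target:
                break

    out.xl_edges = np.array(edges, dtype=np.int32)
    out.xl_rest = np.array(rests)
    out.xl_k = np.array(
        [params.spring_constant(r, spec) for r in rests]
    )
    return out


def build_network(
    density: float,
    box: BoxSpec,
    fiber_spec: FiberSpec,
    xl_params: CrosslinkerParams,
    geometry: str = "random",
    seed: int = 0,
) -> NetworkState:
    """Convenience: fibers at the given collagen density + crosslinks.

    Fiber generation and crosslink placement draw from independent
    streams spawned from ``seed`` so that the fiber geometry for a seed
    is identical across crosslinker settings.
    """
    ss = np.random.SeedSequence(seed)
    s_fib, s_xl = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    n = fiber_count_from_density(density, box, fiber_spec)
    state = generate_fibers(n, box, fiber_spec, geometry=geometry, seed=s_fib)
    state = place_crosslinkers(state, xl_params, fiber_spec, seed=s_xl)
    state.rng_seed = seed
    return state
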