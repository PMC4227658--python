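"""Mechanical observables: stress, moduli, Poisson's ratio, force stats.

Stress is measured as the spring-force flux through the horizontal
mid-plane of the box: every spring whose endpoints straddle the plane
contributes the component of its tension along the loading direction
(oriented lower-to-upper), and the sum is divided by the box
cross-sectional area.  At equilibrium this equals the reaction force
on the top grip divided by the same area, which is asserted as an
invariant in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BOTTOM, CUBE, FREE, SHELL, TOP, NetworkState
from .params import BoxSpec, InvalidParameterError
from .protocols import Trajectory
from .units import NN_PER_UM2_TO_PA

__all__ = [
    "StressStrainCurve",
    "PoissonRecord",
    "ForceStats",
    "InsufficientDataError",
    "DegenerateSamplingError",
    "network_stress",
    "modulus_from_curve",
    "poisson_ratio",
    "lateral_widths",
    "force_statistics",
]


class InsufficientDataError(ValueError):
    """Too few points for the requested fit."""


class DegenerateSamplingError(RuntimeError):
    """A sampling slab contained no beads; widen the slab."""


@dataclass
class StressStrainCurve:
    """Per-step strain and stress of one protocol run.

    ``modulus`` is filled by :func:`modulus_from_curve` (Pa).
    """

    strains: np.ndarray
    stresses: np.ndarray  # Pa
    modulus: float | None = None
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        if self.strains.shape != self.stresses.shape:
            raise InvalidParameterError("strains and stresses must align")
        if self.strains.size > 1 and not (np.diff(self.strains) > 0).all():
            raise InvalidParameterError("strains must be strictly increasing")

    @classmethod
    def from_trajectory(
        cls, traj: Trajectory, box: BoxSpec, replicate_id: int = 0
    ) -> "StressStrainCurve":
        mode = traj.mode
        if mode not in ("shear_y", "tensile_z"):
            raise InvalidParameterError(
                "stress-strain curves are defined for shear/tensile runs"
            )
        stresses = [
            network_stress(r.state, box, mode) for r in traj.records
        ]
        return cls(traj.strains(), np.array(stresses), replicate_id=replicate_id)


@dataclass
class PoissonRecord:
    """Poisson's ratio measurement at one longitudinal strain."""

    longitudinal_strain: float
    lateral_strain_x: float
    lateral_strain_y: float
    poisson_ratio: float
    z_planes: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ForceStats:
    """Force magnitude summary for one bead group."""

    group: str
    n_beads: int
    mean_force: float  # nN
    bin_edges: np.ndarray
    counts: np.ndarray


def network_stress(state: NetworkState, box: BoxSpec, mode: str) -> float:
    """Stress transmitted through the mid-plane of the free region, Pa.

    Sums, over all springs crossing z = height_z/2, the component of
    the spring tension along the loading axis (y for shear, z for
    tensile), with the spring vector oriented from the lower to the
    upper endpoint, then divides by the full box cross-section.
    """
    if mode == "shear_y":
        axis = 1
    elif mode == "tensile_z":
        axis = 2
    else:
        raise InvalidParameterError(f"unknown stress mode {mode!r}")
    z_mid = box.height_z / 2.0
    edges, k, rest = state.all_edges()
    if edges.shape[0] == 0:
        return 0.0
    pos = state.positions
    zi = pos[edges[:, 0], 2]
    zj = pos[edges[:, 1], 2]
    crossing = (zi - z_mid) * (zj - z_mid) < 0.0
    if not crossing.any():
        return 0.0
    e = edges[crossing]
    kk = k[crossing]
    r0 = rest[crossing]
    d = pos[e[:, 1]] - pos[e[:, 0]]
    # orient lower -> upper
    flip = pos[e[:, 0], 2] > pos[e[:, 1], 2]
    d[flip] *= -1.0
    length = np.linalg.norm(d, axis=1)
    tension = kk * (length - r0)  # nN, >0 when stretched
    flux = float(np.sum(tension * d[:, axis] / length))  # nN
    return flux / box.cross_area * NN_PER_UM2_TO_PA


def modulus_from_curve(
    curve: StressStrainCurve,
    strain_window: tuple[float, float] = (0.01, 0.10),
) -> float:
    """Elastic modulus: OLS slope of stress vs strain in the window, Pa."""
    lo, hi = strain_window
    eps = 1e-12
    m = (curve.strains >= lo - eps) & (curve.strains <= hi + eps)
    if m.sum() < 2:
        raise InsufficientDataError(
            f"need >=2 points in strain window [{lo}, {hi}], have {m.sum()}"
        )
    slope, _intercept = np.polyfit(curve.strains[m], curve.stresses[m], 1)
    return float(slope)


def _boundary_bead_sets(
    pos: np.ndarray,
    z_planes: np.ndarray,
    slab_half: float,
    axis: int,
    n_extreme: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per plane: index arrays of the low-side and high-side boundary beads.

    Within each z-slab the ``n_extreme`` beads with the smallest and the
    largest coordinate along ``axis`` define the lateral box edges (a
    mean-of-extremes rectangle fit robust to single outliers).
    """
    sets = []
    for z in z_planes:
        idx = np.flatnonzero(np.abs(pos[:, 2] - z) <= slab_half)
        if idx.size == 0:
            raise DegenerateSamplingError(
                f"no beads within {slab_half} µm of z = {z} µm; "
                "widen the slab"
            )
        q = min(n_extreme, idx.size)
        order = np.argsort(pos[idx, axis])
        sets.append((idx[order[:q]], idx[order[-q:]]))
    return sets


def lateral_widths(
    state: NetworkState,
    box: BoxSpec,
    z_planes: np.ndarray | None = None,
    slab_half: float = 12.5,
    boundary_fraction: float = 0.025,
    bead_sets: tuple[list, list] | None = None,
) -> tuple[float, float, tuple[list, list]]:
    """Mean lateral box widths (W_x, W_y) over the sampling planes.

    The per-side quota of boundary beads is ``boundary_fraction`` of
    the total fiber count (default 2.5%).  If ``bead_sets`` (from a
    previous call on the reference state) is given, those same material
    beads are measured instead of re-selecting extremes — this keeps
    the strained and unstrained measurements comparable and makes the
    estimate exact under affine deformations.  Returns (W_x, W_y,
    bead_sets).
    """
    if z_planes is None:
        z_planes = np.linspace(
            box.anchor_depth, box.height_z - box.anchor_depth, 9
        )
    n_extreme = max(1, round(boundary_fraction * state.n_fibers))
    pos = state.positions
    if bead_sets is None:
        sets_x = _boundary_bead_sets(pos, z_planes, slab_half, 0, n_extreme)
        sets_y = _boundary_bead_sets(pos, z_planes, slab_half, 1, n_extreme)
    else:
        sets_x, sets_y = bead_sets
    wx = np.mean([pos[hi, 0].mean() - pos[lo, 0].mean() for lo, hi in sets_x])
    wy = np.mean([pos[hi, 1].mean() - pos[lo, 1].mean() for lo, hi in sets_y])
    return float(wx), float(wy), (sets_x, sets_y)


def poisson_ratio(
    trajectory: Trajectory,
    box: BoxSpec,
    at_strain: float,
    slab_half: float = 12.5,
    boundary_fraction: float = 0.025,
) -> PoissonRecord:
    """Poisson's ratio of a tensile run at a given longitudinal strain.

    A rectangular lateral box is fitted to boundary beads at nine
    heights (50, 75, ..., 250 µm for the default box).  The boundary
    beads are selected once, on the zero-strain reference state, and
    tracked through the deformation; the lateral strain is the relative
    change of the mean box width, and the ratio is
    -lateral/longitudinal averaged over x and y.
    """
    if trajectory.mode != "tensile_z":
        raise InvalidParameterError("Poisson's ratio requires a tensile run")
    if at_strain == 0:
        raise InvalidParameterError(
            "Poisson's ratio is undefined at zero longitudinal strain"
        )
    record = trajectory.at_strain(at_strain)
    z_planes = np.linspace(
        box.anchor_depth, box.height_z - box.anchor_depth, 9
    )
    wx0, wy0, bead_sets = lateral_widths(
        trajectory.initial_state, box, z_planes, slab_half, boundary_fraction
    )
    wx, wy, _ = lateral_widths(
        record.state, box, z_planes, slab_half, boundary_fraction,
        bead_sets=bead_sets,
    )
    lat_x = (wx - wx0) / wx0
    lat_y = (wy - wy0) / wy0
    nu_x = -lat_x / at_strain
    nu_y = -lat_y / at_strain
    return PoissonRecord(
        longitudinal_strain=at_strain,
        lateral_strain_x=lat_x,
        lateral_strain_y=lat_y,
        poisson_ratio=0.5 * (nu_x + nu_y),
        z_planes=z_planes,
    )


_GROUPS = {
    "test_box": (CUBE,),
    "anchored": (BOTTOM, TOP, SHELL),
    "interior": (FREE,),
}


def force_statistics(
    state: NetworkState,
    forces: np.ndarray | None = None,
    groups: dict[str, tuple[int, ...]] | None = None,
    n_bins: int = 50,
) -> list[ForceStats]:
    """Per-group force-magnitude statistics (mean + histogram).

    Default groups: ``test_box`` (poke cube), ``anchored`` (bottom/top
    grips and the poke shell), ``interior`` (free beads).  Empty groups
    are reported with zero beads rather than dropped.
    """
    from .mechanics import energy_and_forces

    if forces is None:
        forces = energy_and_forces(state).per_bead_forces
    if groups is None:
        groups = _GROUPS
    mags = np.linalg.norm(forces, axis=1)
    out = []
    for name, labels in groups.items():
        mask = np.isin(state.anchor_label, labels)
        gm = mags[mask]
        if gm.size == 0:
            out.append(
                ForceStats(name, 0, 0.0, np.empty(0), np.empty(0, dtype=int))
            )
            continue
        counts, edges = np.histogram(gm, bins=n_bins)
        out.append(
            ForceStats(name, int(gm.size), float(gm.mean()), edges, counts)
        )
    return out
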