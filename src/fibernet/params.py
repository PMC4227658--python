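"""Physical and numerical parameter objects.

Defaults reproduce a type-I collagen gel: homogeneous 100 µm x 0.3 µm
fibers with a Young's modulus of 32 MPa, discretized as 5 beads per
fiber, in a 200 x 200 x 300 µm simulation box whose top and bottom
50 µm slabs act as rigid grips.  Crosslinker defaults are the best-fit
values obtained by calibrating against bulk shear rheology
(634.38 kPa strength, 11.18 crosslinkers per fiber).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import AVOGADRO, MG_PER_ML_TO_G_PER_UM3, PA_TO_NN_PER_UM2

__all__ = [
    "FiberSpec",
    "CrosslinkerParams",
    "BoxSpec",
    "EquilibriumCriterion",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """A parameter object violates one of its physical invariants."""


@dataclass(frozen=True)
class FiberSpec:
    """Geometry and elasticity of a (homogeneous) collagen fiber.

    Parameters
    ----------
    length : float
        Fiber contour length, µm.
    diameter : float
        Fiber diameter, µm.
    youngs_modulus : float
        Fiber Young's modulus, Pa.
    beads_per_fiber : int
        Number of beads discretizing one fiber (>= 2).
    fibril_molecular_weight : float
        Molecular weight of a single collagen fibril, g/mol.  Used to
        convert a bulk collagen concentration into a fiber count.
    fibril_length, fibril_diameter : float
        Dimensions of a single fibril, nm.
    """

    length: float = 100.0
    diameter: float = 0.3
    youngs_modulus: float = 32e6
    beads_per_fiber: int = 5
    fibril_molecular_weight: float = 8.05e5
    fibril_length: float = 300.0
    fibril_diameter: float = 1.5

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise InvalidParameterError("fiber length and diameter must be > 0")
        if self.youngs_modulus <= 0:
            raise InvalidParameterError("fiber Young's modulus must be > 0")
        if self.beads_per_fiber < 2:
            raise InvalidParameterError("beads_per_fiber must be >= 2")
        if (
            self.fibril_molecular_weight <= 0
            or self.fibril_length <= 0
            or self.fibril_diameter <= 0
        ):
            raise InvalidParameterError("fibril parameters must be > 0")

    @property
    def segment_length(self) -> float:
        """Rest length of one bead-bead segment, µm."""
        return self.length / (self.beads_per_fiber - 1)

    @property
    def cross_section(self) -> float:
        """Fiber cross-sectional area, µm²."""
        return math.pi * self.diameter**2 / 4.0

    @property
    def mass(self) -> float:
        """Mass of one fiber, grams.

        The fiber is treated as a solid cylinder packed with fibrils at
        fibril density: mass = (V_fiber / V_fibril) * MW / N_A.
        """
        v_fibril = (
            math.pi * (self.fibril_diameter * 1e-3 / 2.0) ** 2
            * (self.fibril_length * 1e-3)
        )  # µm³
        v_fiber = self.cross_section * self.length  # µm³
        n_fibrils = v_fiber / v_fibril
        return n_fibrils * self.fibril_molecular_weight / AVOGADRO


@dataclass(frozen=True)
class CrosslinkerParams:
    """Inter-fiber crosslinker model parameters.

    ``strength`` is the crosslinker Young's modulus (Pa); the
    crosslinker cross-section equals the fiber cross-section, so a
    crosslink of rest length L0 gets spring constant
    k = strength * A_fiber / L0.  ``density_multiplier`` expresses the
    crosslinker count as a multiple of the total fiber count (the
    "xN" unit).  ``strength`` and ``density_multiplier`` are the two
    free parameters of the network model; all other fields are
    placement constraints.
    """

    strength: float = 634.38e3
    density_multiplier: float = 11.18
    min_binding_distance: float = 0.45
    max_binding_distance: float = 50.0
    max_per_bead: int = 10

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise InvalidParameterError("crosslinker strength must be >= 0")
        if self.density_multiplier < 0:
            raise InvalidParameterError("density_multiplier must be >= 0")
        if not 0 < self.min_binding_distance < self.max_binding_distance:
            raise InvalidParameterError(
                "need 0 < min_binding_distance < max_binding_distance"
            )
        if self.max_per_bead < 1:
            raise InvalidParameterError("max_per_bead must be >= 1")

    def spring_constant(self, rest_length: float, fiber: FiberSpec) -> float:
        """Spring constant of a crosslink with given rest length, nN/µm."""
        e_internal = self.strength * PA_TO_NN_PER_UM2  # nN/µm²
        return e_internal * fiber.cross_section / rest_length


@dataclass(frozen=True)
class BoxSpec:
    """Simulation box geometry (origin at a corner, z up, lengths µm).

    ``anchor_depth`` is the thickness of the top and bottom slabs whose
    beads are gripped rigidly during shear and tensile tests.
    """

    length_x: float = 200.0
    width_y: float = 200.0
    height_z: float = 300.0
    anchor_depth: float = 50.0

    def __post_init__(self) -> None:
        if min(self.length_x, self.width_y, self.height_z) <= 0:
            raise InvalidParameterError("box dimensions must be > 0")
        if self.anchor_depth <= 0 or 2 * self.anchor_depth >= self.height_z:
            raise InvalidParameterError(
                "need 0 < 2*anchor_depth < height_z"
            )

    @property
    def volume(self) -> float:
        """Box volume, µm³."""
        return self.length_x * self.width_y * self.height_z

    @property
    def free_height(self) -> float:
        """Height of the unanchored central region, µm.

        Strain is defined relative to this height: with the default box
        a strain step of 0.01 displaces the top grip by 2 µm.
        """
        return self.height_z - 2 * self.anchor_depth

    @property
    def cross_area(self) -> float:
        """Horizontal cross-sectional area, µm²."""
        return self.length_x * self.width_y


@dataclass(frozen=True)
class EquilibriumCriterion:
    """Quasi-equilibrium stopping rule for the minimizer.

    Relaxation stops when the largest per-bead force among free beads
    has dropped below ``relative_force_tolerance`` times the maximum
    force recorded in the strained state (immediately after the last
    imposed boundary displacement), or below ``absolute_force_floor``
    (nN), whichever is larger.  The floor guards steps where the
    baseline itself is essentially zero.
    """

    relative_force_tolerance: float = 1e-5
    absolute_force_floor: float = 1e-9
    max_iterations: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.relative_force_tolerance < 1:
            raise InvalidParameterError(
                "relative_force_tolerance must be in (0, 1)"
            )
        if self.absolute_force_floor < 0:
            raise InvalidParameterError("absolute_force_floor must be >= 0")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")

    def force_threshold(self, baseline_max_force: float) -> float:
        """Absolute stopping threshold (nN) for a given baseline."""
        return max(
            self.relative_force_tolerance * baseline_max_force,
            self.absolute_force_floor,
        )
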