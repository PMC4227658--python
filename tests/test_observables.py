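"""Stress, modulus regression, Poisson's ratio, force statistics."""

import numpy as np
import pytest

from fibernet import (
    BoxSpec,
    DeformationProtocol,
    EquilibriumCriterion,
    FiberSpec,
    NetworkState,
    energy_and_forces,
    generate_fibers,
    run_protocol,
)
from fibernet.network import BOTTOM, CUBE, FREE, TOP
from fibernet.observables import (
    DegenerateSamplingError,
    InsufficientDataError,
    StressStrainCurve,
    force_statistics,
    modulus_from_curve,
    network_stress,
    poisson_ratio,
)
from fibernet.params import InvalidParameterError
from fibernet.protocols import Trajectory, TrajectoryRecord


def single_vertical_fiber(box, stretch):
    """One fiber spanning both grips, uniformly stretched by ``stretch``."""
    n = 5
    rest = box.height_z / (n - 1)
    z = np.arange(n) * rest * (1 + stretch)
    positions = np.stack(
        [np.full(n, 100.0), np.full(n, 100.0), z], axis=1
    )
    labels = np.full(n, FREE, dtype=np.int8)
    labels[z < box.anchor_depth] = BOTTOM
    labels[z > box.height_z - box.anchor_depth] = TOP
    return NetworkState(
        positions=positions,
        fiber_of_bead=np.zeros(n, dtype=np.int32),
        seg_edges=np.stack(
            [np.arange(n - 1), np.arange(1, n)], axis=1
        ).astype(np.int32),
        seg_rest=np.full(n - 1, rest),
        seg_k=np.full(n - 1, 10.0),
        xl_edges=np.empty((0, 2), dtype=np.int32),
        xl_rest=np.empty(0),
        xl_k=np.empty(0),
        anchor_label=labels,
    )


class TestNetworkStress:
    def test_single_fiber_tension_oracle(self, box):
        # tension T = k * rest * stretch crosses the mid-plane once:
        # stress = T / area exactly (in Pa, 1 nN/µm² = 1e3 Pa)
        stretch = 0.02
        state = single_vertical_fiber(box, stretch)
        tension = 10.0 * (box.height_z / 4) * stretch
        expected = tension / box.cross_area * 1e3
        assert network_stress(state, box, "tensile_z") == pytest.approx(
            expected
        )

    def test_zero_at_rest(self, mini_network, mini_box):
        # all springs at rest length: only float rounding remains
        assert network_stress(mini_network, mini_box, "shear_y") == (
            pytest.approx(0.0, abs=1e-9)
        )
        assert network_stress(mini_network, mini_box, "tensile_z") == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_equals_anchor_reaction_at_equilibrium(self, dense_network,
                                                   mini_box):
        # momentum balance: mid-plane force flux = net reaction on the
        # top grip, at every converged step.  The gap is bounded by the
        # residual forces still on free beads above the plane, each at
        # most the convergence threshold.
        proto = DeformationProtocol(mode="shear_y", strain_step=0.02,
                                    n_steps=3)
        traj = run_protocol(dense_network, proto,
                            EquilibriumCriterion(), mini_box)
        top = dense_network.anchor_label == TOP
        free = dense_network.anchor_label == FREE
        z_mid = mini_box.height_z / 2.0
        for rec in traj.records:
            stress = network_stress(rec.state, mini_box, "shear_y")
            flux = stress * mini_box.cross_area / 1e3  # nN
            reaction = -rec.energy.per_bead_forces[top, 1].sum()
            n_above = int(
                (free & (rec.state.positions[:, 2] > z_mid)).sum()
            )
            bound = n_above * rec.convergence.threshold
            assert abs(flux - reaction) <= bound


class TestModulusFromCurve:
    def test_exact_line(self):
        strains = 0.01 * np.arange(1, 11)
        curve = StressStrainCurve(strains, 100.0 * strains)
        assert modulus_from_curve(curve) == pytest.approx(100.0)

    def test_zero_stress(self):
        strains = 0.01 * np.arange(1, 11)
        curve = StressStrainCurve(strains, np.zeros(10))
        assert modulus_from_curve(curve) == 0.0

    def test_symmetric_noise_bounded(self):
        rng = np.random.default_rng(0)
        strains = 0.01 * np.arange(1, 11)
        eps = 0.05
        noise = rng.uniform(-eps, eps, size=10)
        curve = StressStrainCurve(strains, 80.0 * strains + noise)
        # OLS slope error bound: |sum(x-xbar)*e| / sum (x-xbar)^2
        xc = strains - strains.mean()
        bound = eps * np.abs(xc).sum() / (xc**2).sum()
        assert abs(modulus_from_curve(curve) - 80.0) <= bound

    def test_too_few_points(self):
        curve = StressStrainCurve([0.05], [1.0])
        with pytest.raises(InsufficientDataError):
            modulus_from_curve(curve)


def affine_trajectory(state, box, scale_xy, scale_z, strain):
    """Trajectory whose final state is an affine map of the initial."""
    mapped = state.copy()
    center = np.array([box.length_x / 2, box.width_y / 2, 0.0])
    rel = mapped.positions - center
    rel[:, 0] *= scale_xy
    rel[:, 1] *= scale_xy
    rel[:, 2] *= scale_z
    mapped.positions = rel + center
    report = energy_and_forces(mapped)
    from fibernet.mechanics import ConvergenceRecord

    rec = TrajectoryRecord(
        step=1,
        strain=strain,
        state=mapped,
        energy=report,
        convergence=ConvergenceRecord(
            iterations=0, converged=True, baseline_max_force=0.0,
            threshold=0.0, final_max_force=0.0, final_energy=0.0,
            n_evaluations=0,
        ),
    )
    return Trajectory(mode="tensile_z", initial_state=state, records=[rec])


class TestPoissonRatio:
    def test_affine_contraction_recovered(self, box, fiber_spec):
        # (x,y,z) -> (0.97x, 0.97y, 1.10z) at strain 0.10: lateral
        # strain -0.03, Poisson's ratio 0.30 by construction
        state = generate_fibers(400, box, fiber_spec, "random", seed=17)
        traj = affine_trajectory(state, box, 0.97, 1.10, 0.10)
        rec = poisson_ratio(traj, box, 0.10)
        assert rec.poisson_ratio == pytest.approx(0.30, abs=1e-9)
        assert rec.lateral_strain_x == pytest.approx(-0.03, abs=1e-9)

    def test_zero_strain_rejected(self, box, fiber_spec):
        state = generate_fibers(50, box, fiber_spec, "random", seed=17)
        traj = affine_trajectory(state, box, 1.0, 1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            poisson_ratio(traj, box, 0.0)

    def test_empty_slab_raises(self, box, fiber_spec):
        # all fibers squeezed near the bottom: top sampling planes empty
        state = generate_fibers(5, box, fiber_spec, "random", seed=17)
        state.positions[:, 2] = np.linspace(0, 20, state.n_beads)
        traj = affine_trajectory(state, box, 0.97, 1.1, 0.1)
        with pytest.raises(DegenerateSamplingError):
            poisson_ratio(traj, box, 0.1)

    def test_nine_default_planes(self, box, fiber_spec):
        state = generate_fibers(400, box, fiber_spec, "random", seed=18)
        traj = affine_trajectory(state, box, 0.99, 1.05, 0.05)
        rec = poisson_ratio(traj, box, 0.05)
        assert np.allclose(rec.z_planes, np.arange(50.0, 251.0, 25.0))


class TestForceStatistics:
    def test_all_at_rest_means_zero(self, mini_network):
        stats = force_statistics(mini_network)
        for s in stats:
            if s.n_beads:
                assert s.mean_force == pytest.approx(0.0, abs=1e-9)

    def test_single_stretched_spring_between_groups(self):
        # one spring between a cube bead and an interior bead: both
        # groups' mean force equals the spring tension
        positions = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        state = NetworkState(
            positions=positions,
            fiber_of_bead=np.array([0, 1], dtype=np.int32),
            seg_edges=np.empty((0, 2), dtype=np.int32),
            seg_rest=np.empty(0),
            seg_k=np.empty(0),
            xl_edges=np.array([[0, 1]], dtype=np.int32),
            xl_rest=np.array([1.0]),
            xl_k=np.array([2.0]),
            anchor_label=np.array([CUBE, FREE], dtype=np.int8),
        )
        stats = {s.group: s for s in force_statistics(state)}
        tension = 2.0 * 2.0
        assert stats["test_box"].mean_force == pytest.approx(tension)
        assert stats["interior"].mean_force == pytest.approx(tension)
        assert stats["anchored"].n_beads == 0

    def test_histogram_counts_cover_group(self, mini_network, mini_box):
        proto = DeformationProtocol(mode="shear_y", strain_step=0.02,
                                    n_steps=1)
        traj = run_protocol(
            mini_network, proto, EquilibriumCriterion(), mini_box
        )
        stats = force_statistics(traj.records[-1].state)
        for s in stats:
            if s.n_beads:
                assert s.counts.sum() == s.n_beads
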