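"""Boundary-displacement protocols: shear, tensile, poke."""

import numpy as np
import pytest

from fibernet import (
    BoxSpec,
    CrosslinkerParams,
    DeformationProtocol,
    EquilibriumCriterion,
    FiberSpec,
    apply_shear_step,
    apply_tensile_step,
    energy_and_forces,
    generate_fibers,
    label_poke_anchors,
    place_crosslinkers,
    run_protocol,
)
from fibernet.network import BOTTOM, CUBE, FREE, SHELL, TOP
from fibernet.observables import network_stress
from fibernet.params import InvalidParameterError
from fibernet.protocols import ProtocolError


class TestBoundarySteps:
    def test_shear_step_moves_top_grip_two_microns(self, mini_network,
                                                   mini_box):
        # strain defined on the free height: 0.01 x 60 µm = 0.6 µm here;
        # with the standard 300 µm box the same step is exactly 2 µm
        out = apply_shear_step(mini_network, mini_box, 0.01)
        top = mini_network.anchor_label == TOP
        dy = out.positions[top, 1] - mini_network.positions[top, 1]
        assert np.allclose(dy, 0.01 * mini_box.free_height)
        assert np.array_equal(
            out.positions[~top], mini_network.positions[~top]
        )
        box = BoxSpec()
        assert 0.01 * box.free_height == pytest.approx(2.0)

    def test_zero_step_is_identity(self, mini_network, mini_box):
        out = apply_shear_step(mini_network, mini_box, 0.0)
        assert np.array_equal(out.positions, mini_network.positions)
        out = apply_tensile_step(mini_network, mini_box, 0.0)
        assert np.array_equal(out.positions, mini_network.positions)

    def test_steps_are_additive(self, mini_network, mini_box):
        once = apply_shear_step(
            apply_shear_step(mini_network, mini_box, 0.01), mini_box, 0.01
        )
        twice = apply_shear_step(mini_network, mini_box, 0.02)
        assert np.allclose(once.positions, twice.positions)

    def test_tensile_step_symmetric(self, mini_network, mini_box):
        out = apply_tensile_step(mini_network, mini_box, 0.01)
        top = mini_network.anchor_label == TOP
        bot = mini_network.anchor_label == BOTTOM
        half = 0.5 * 0.01 * mini_box.free_height
        assert np.allclose(
            out.positions[top, 2] - mini_network.positions[top, 2], half
        )
        assert np.allclose(
            out.positions[bot, 2] - mini_network.positions[bot, 2], -half
        )

    def test_missing_anchors_raise(self, mini_network, mini_box):
        state = mini_network.copy()
        state.anchor_label = np.full(state.n_beads, FREE, dtype=np.int8)
        with pytest.raises(ProtocolError):
            apply_shear_step(state, mini_box, 0.01)


class TestRunProtocol:
    def test_shear_reaches_target_strain(self, mini_network, mini_box,
                                         loose_criterion):
        proto = DeformationProtocol(mode="shear_y", strain_step=0.01,
                                    n_steps=10)
        traj = run_protocol(mini_network, proto, loose_criterion, mini_box)
        assert len(traj.records) == 10
        assert traj.records[-1].strain == pytest.approx(0.1)
        assert all(r.convergence.converged for r in traj.records)
        strains = traj.strains()
        assert (np.diff(strains) > 0).all()

    def test_top_anchor_moves_as_rigid_body(self, mini_network, mini_box,
                                            loose_criterion):
        proto = DeformationProtocol(mode="shear_y", strain_step=0.02,
                                    n_steps=3)
        traj = run_protocol(mini_network, proto, loose_criterion, mini_box)
        top = mini_network.anchor_label == TOP
        p0 = mini_network.positions[top]
        p1 = traj.records[-1].state.positions[top]
        # mutual distances preserved exactly (pure translation)
        d0 = np.linalg.norm(p0[:, None] - p0[None, :], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-12)
        bottom = mini_network.anchor_label == BOTTOM
        assert np.array_equal(
            traj.records[-1].state.positions[bottom],
            mini_network.positions[bottom],
        )

    def test_shear_reversal_recovers_energy(self, dense_network, mini_box):
        # pure elasticity: strain up, strain back, re-relax -> energy
        # returns to (near) its pre-step value; the small residual sits
        # in floppy modes below the force criterion
        criterion = EquilibriumCriterion()
        proto = DeformationProtocol(mode="shear_y", strain_step=0.02,
                                    n_steps=1)
        traj = run_protocol(dense_network, proto, criterion, mini_box)
        e_strained = traj.records[-1].energy.total_energy
        back = apply_shear_step(traj.records[-1].state, mini_box, -0.02)
        from fibernet import minimize

        baseline = energy_and_forces(back).max_free_force
        relaxed, _ = minimize(back, criterion, baseline_max_force=baseline)
        e_back = energy_and_forces(relaxed).total_energy
        assert e_back < 0.02 * e_strained

    def test_uncrosslinked_fibers_carry_no_load(self, mini_box, mini_fiber):
        # 30 µm fibers cannot span the 60 µm between the grips, so with
        # no crosslinkers nothing transmits load: the relaxed network
        # stores essentially no energy and the mid-plane stress is
        # negligible against the crosslinked-network scale (~0.1 Pa)
        state = generate_fibers(30, mini_box, mini_fiber, "random", seed=5)
        proto = DeformationProtocol(mode="shear_y", strain_step=0.02,
                                    n_steps=2)
        traj = run_protocol(state, proto, EquilibriumCriterion(), mini_box)
        final = traj.records[-1]
        assert final.energy.total_energy < 1e-6
        assert abs(network_stress(final.state, mini_box, "shear_y")) < 5e-3


class TestPoke:
    @pytest.fixture
    def poke_setup(self, mini_fiber):
        box = BoxSpec(length_x=90, width_y=90, height_z=90, anchor_depth=20)
        xl = CrosslinkerParams(
            strength=400e3, density_multiplier=8.0, max_binding_distance=20.0
        )
        proto = DeformationProtocol(
            mode="poke_z",
            strain_step=1.0,
            n_steps=3,
            test_cube=((45.0, 45.0, 45.0), 24.0),
            outer_anchor_depth=20.0,
        )
        state = generate_fibers(150, box, mini_fiber, "random", seed=13)
        state = place_crosslinkers(state, xl, mini_fiber, seed=14)
        return box, proto, state

    def test_labels_and_cube_displacement(self, poke_setup, loose_criterion):
        box, proto, state = poke_setup
        labeled = label_poke_anchors(state, box, proto)
        p = labeled.positions
        cube = labeled.anchor_label == CUBE
        shell = labeled.anchor_label == SHELL
        assert cube.any() and shell.any()
        assert np.abs(p[cube] - 45.0).max() <= 12.0
        traj = run_protocol(labeled, proto, loose_criterion, box)
        moved = traj.records[-1].state.positions[cube]
        assert np.allclose(moved[:, 2] - p[cube, 2], 3.0)
        assert np.allclose(moved[:, :2], p[cube, :2])
        # fixed shell never moves
        assert np.array_equal(
            traj.records[-1].state.positions[shell], p[shell]
        )

    def test_poke_requires_cube(self):
        with pytest.raises(InvalidParameterError):
            DeformationProtocol(mode="poke_z", strain_step=2.0, n_steps=3)


class TestProtocolValidation:
    def test_bad_mode(self):
        with pytest.raises(InvalidParameterError):
            DeformationProtocol(mode="twist", strain_step=0.01, n_steps=1)

    def test_nonconvergence_carries_partial_trajectory(self, mini_network,
                                                       mini_box):
        criterion = EquilibriumCriterion(max_iterations=2)
        proto = DeformationProtocol(mode="shear_y", strain_step=0.05,
                                    n_steps=3)
        with pytest.raises(ProtocolError) as err:
            run_protocol(mini_network, proto, criterion, mini_box)
        assert err.value.trajectory is not None
        assert len(err.value.trajectory.records) == 0
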