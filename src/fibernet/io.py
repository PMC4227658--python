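"""Serialization: HDF5 network store, XYZ-with-bonds export, CSV curves.

HDF5 layout (one group per network)::

    /positions        (n, 3) float64, µm
    /fiber_of_bead    (n,)   int32
    /anchor_label     (n,)   int8
    /segments/edges   (ms, 2) int32     /segments/rest, /segments/k
    /crosslinks/edges (mx, 2) int32     /crosslinks/rest, /crosslinks/k
    attrs: rng_seed, format_version

Datasets are written with ``track_times=False`` so identical states
produce identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .network import ANCHOR_LABELS, NetworkState
from .observables import StressStrainCurve
from .protocols import Trajectory

__all__ = [
    "save_network",
    "load_network",
    "export_xyz_bonds",
    "save_trajectory",
    "curve_to_csv",
    "write_json_summary",
]

_FORMAT_VERSION = 1


def _write_state(grp: h5py.Group, state: NetworkState) -> None:
    opts = dict(track_times=False)
    grp.create_dataset("positions", data=state.positions, **opts)
    grp.create_dataset("fiber_of_bead", data=state.fiber_of_bead, **opts)
    grp.create_dataset("anchor_label", data=state.anchor_label, **opts)
    seg = grp.create_group("segments")
    seg.create_dataset("edges", data=state.seg_edges, **opts)
    seg.create_dataset("rest", data=state.seg_rest, **opts)
    seg.create_dataset("k", data=state.seg_k, **opts)
    xl = grp.create_group("crosslinks")
    xl.create_dataset("edges", data=state.xl_edges, **opts)
    xl.create_dataset("rest", data=state.xl_rest, **opts)
    xl.create_dataset("k", data=state.xl_k, **opts)
    grp.attrs["rng_seed"] = state.rng_seed
    grp.attrs["format_version"] = _FORMAT_VERSION


def _read_state(grp: h5py.Group) -> NetworkState:
    return NetworkState(
        positions=grp["positions"][()],
        fiber_of_bead=grp["fiber_of_bead"][()],
        seg_edges=grp["segments/edges"][()],
        seg_rest=grp["segments/rest"][()],
        seg_k=grp["segments/k"][()],
        xl_edges=grp["crosslinks/edges"][()].reshape(-1, 2),
        xl_rest=grp["crosslinks/rest"][()],
        xl_k=grp["crosslinks/k"][()],
        anchor_label=grp["anchor_label"][()],
        rng_seed=int(grp.attrs["rng_seed"]),
    )


def save_network(state: NetworkState, path: str | Path) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        _write_state(fh, state)


def load_network(path: str | Path) -> NetworkState:
    with h5py.File(path, "r") as fh:
        return _read_state(fh)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Store the initial state plus every relaxed snapshot and a manifest."""
    with h5py.File(path, "w", track_order=True) as fh:
        fh.attrs["mode"] = traj.mode
        _write_state(fh.create_group("initial"), traj.initial_state)
        steps = fh.create_group("steps")
        for r in traj.records:
            grp = steps.create_group(f"{r.step:04d}")
            _write_state(grp, r.state)
            grp.attrs["strain"] = r.strain
            grp.attrs["energy"] = r.energy.total_energy
            grp.attrs["max_force"] = r.energy.max_force
            grp.attrs["iterations"] = r.convergence.iterations
            grp.attrs["converged"] = r.convergence.converged


def trajectory_manifest(traj: Trajectory) -> pd.DataFrame:
    """Per-step summary: strain, energy, max force, iterations."""
    return pd.DataFrame(
        [
            dict(
                step=r.step,
                strain=r.strain,
                energy=r.energy.total_energy,
                max_force=r.energy.max_force,
                max_free_force=r.energy.max_free_force,
                iterations=r.convergence.iterations,
                converged=r.convergence.converged,
            )
            for r in traj.records
        ]
    )


def export_xyz_bonds(state: NetworkState, path: str | Path) -> None:
    """Plain-text XYZ export with a trailing bond list.

    Beads are written as one XYZ frame (element column = anchor label);
    after the coordinates a ``# BONDS`` section lists one bond per line
    as ``type i j`` with type ``F`` (fiber segment) or ``X``
    (crosslink).  Readable by standard XYZ viewers (which ignore the
    comment section) and by simple parsers.
    """
    lines = [str(state.n_beads), "fibernet network export"]
    for p, lab in zip(state.positions, state.anchor_label):
        name = ANCHOR_LABELS[int(lab)][:2].upper()
        lines.append(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    lines.append("# BONDS type i j")
    for i, j in state.seg_edges:
        lines.append(f"# F {i} {j}")
    for i, j in state.xl_edges:
        lines.append(f"# X {i} {j}")
    Path(path).write_text("\n".join(lines) + "\n")


def curve_to_csv(curve: StressStrainCurve, path: str | Path) -> None:
    pd.DataFrame(
        dict(strain=curve.strains, stress_pa=curve.stresses)
    ).to_csv(path, index=False)


def write_json_summary(payload: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
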