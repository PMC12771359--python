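"""Shared fixtures: hand-built frames, toy complexes and synthetic tables."""

from __future__ import annotations

import numpy as np
import pytest

from gagbind.mol_io import AtomRecord, ComplexFrame, Role, Topology, Trajectory
from gagbind.synthetic import (
    TableSpec,
    ToyComplexSpec,
    gen_feature_table,
    gen_toy_complex,
    paper_like_spec,
)

_DEFAULTS = {
    "H": (1.008, 0.6, 0.0157, 1.2),
    "C": (12.011, 1.908, 0.1094, 1.7),
    "N": (14.007, 1.824, 0.17, 1.55),
    "O": (15.999, 1.6612, 0.21, 1.52),
    "S": (32.06, 2.0, 0.25, 1.8),
}


def build_frame(atoms, frame_index: int = 0) -> ComplexFrame:
    """Build a frame from compact per-atom tuples.

    Each atom is ``(name, element, residue_name, residue_id, role, xyz)`` with
    optional trailing ``charge`` and ``mass`` entries; LJ parameters and radii
    default to element-typical values.
    """
    records, coords = [], []
    for serial, atom in enumerate(atoms, start=1):
        name, element, resname, resid, role, xyz = atom[:6]
        charge = atom[6] if len(atom) > 6 else 0.0
        mass_default, rmin, eps, vdw = _DEFAULTS[element]
        mass = atom[7] if len(atom) > 7 else mass_default
        records.append(
            AtomRecord(serial, name, element, resname, resid,
                       Role[role], mass, charge, rmin, eps, vdw)
        )
        coords.append(xyz)
    return ComplexFrame(Topology(records), np.array(coords, dtype=float),
                        frame_index=frame_index)


def frame_to_trajectory(frames: list[ComplexFrame], system_id: str = "sys") -> Trajectory:
    coords = np.stack([f.coords for f in frames])
    return Trajectory(frames[0].topology, coords, system_id=system_id)


@pytest.fixture(scope="session")
def toy_complex():
    """A bound toy complex with contacts, near residues and scripted H-bonds."""
    spec = ToyComplexSpec(seed=1, n_frames=2, jitter=0.05)
    traj, oracles = gen_toy_complex(spec)
    return spec, traj, oracles


@pytest.fixture(scope="session")
def linear_table():
    """Noiseless y = 2 f1 - 3 f2 over independent standard-normal features."""
    spec = TableSpec(
        n_rows=2000,
        feature_names=("f1", "f2"),
        weights={"f1": 2.0, "f2": -3.0},
        noise_sigma=1e-12,
        seed=0,
    )
    return gen_feature_table(spec)


@pytest.fixture(scope="session")
def paper_table():
    """A small paper-like table with a CatS validation group."""
    spec = paper_like_spec(n_rows=4000, n_validation_rows=1500, seed=11)
    table, truth = gen_feature_table(spec)
    return spec, table, truth
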