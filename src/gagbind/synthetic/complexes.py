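"""Toy receptor-ligand complexes with scripted, oracle-checkable geometry.

The generator builds a miniature protein receptor (a helical or rod-like
chain of five/six-atom residue templates with configurable residue classes)
and a linear sulfated-oligosaccharide analogue (repeating seven-atom units
whose partial charges sum exactly to a configurable per-unit charge), places
the ligand at one of six pose directions at a configurable centre-of-mass
offset, and emits a multi-frame trajectory with small seeded thermal jitter.

No attempt is made at physically realistic folds or glycan conformers -- the
geometry only needs to exercise the descriptor mathematics.  Each frame's
descriptors are also computed by the independent brute-force oracle
(:mod:`gagbind.synthetic.oracle`) so the production engine can be validated
value by value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gagbind.descriptors import DescriptorConfig
from gagbind.mol_io import AtomRecord, ComplexFrame, Role, Topology, Trajectory
from gagbind.synthetic.oracle import oracle_descriptor_vector

# element -> (mass amu, LJ Rmin/2 A, LJ epsilon kcal/mol, vdW radius A)
_ELEMENT_PARAMS = {
    "H": (1.008, 0.6000, 0.0157, 1.20),
    "C": (12.011, 1.9080, 0.1094, 1.70),
    "N": (14.007, 1.8240, 0.1700, 1.55),
    "O": (15.999, 1.6612, 0.2100, 1.52),
    "S": (32.06, 2.0000, 0.2500, 1.80),
}

# residue template: (atom name, element, offset A, partial charge e)
_RESIDUE_TEMPLATE = (
    ("N", "N", (-0.8, 0.6, 0.0), -0.40),
    ("H", "H", (-1.4, 1.4, 0.0), 0.30),
    ("CA", "C", (0.0, 0.0, 0.0), 0.03),
    ("C", "C", (1.2, 0.4, 0.0), 0.55),
    ("O", "O", (1.6, 1.5, 0.3), -0.55),
    # side-chain pseudo-atom; charge adjusted per residue class below
    ("CB", "C", (0.2, -1.4, 0.5), 0.07),
)

_POSITIVE = {"LYS", "ARG", "HIS", "HIE"}
_NEGATIVE = {"ASP", "GLU"}

# sugar-unit template; the last oxygen's charge balances to the unit charge
_UNIT_TEMPLATE = (
    ("C1", "C", (0.0, 0.0, 0.0), 0.30),
    ("O5", "O", (0.8, 1.0, 0.0), -0.55),
    ("O1", "O", (-0.9, -0.9, 0.3), -0.70),
    ("HO1", "H", (-1.45, -1.6, 0.5), 0.42),
    ("S1", "S", (1.5, -1.0, -0.5), 0.90),
    ("OS1", "O", (2.4, -1.7, -0.1), -0.80),
    ("OS2", "O", (1.2, -2.2, -1.2), None),  # balance atom
)

_POSE_DIRECTIONS = {
    "front": np.array([1.0, 0.0, 0.0]),
    "back": np.array([-1.0, 0.0, 0.0]),
    "left": np.array([0.0, 1.0, 0.0]),
    "right": np.array([0.0, -1.0, 0.0]),
    "top": np.array([0.0, 0.0, 1.0]),
    "bottom": np.array([0.0, 0.0, -1.0]),
}

_DEFAULT_CLASSES = ("LYS", "SER", "ALA", "ASP", "GLY", "ARG", "LEU", "THR")

_MIN_INTERFACE_DISTANCE = 1.8  # Angstrom; closer placements count as clashes


@dataclass
class ToyComplexSpec:
    """Parameters of a generated toy complex."""

    n_receptor_residues: int = 10
    residue_classes: tuple[str, ...] | None = None  # cycled if shorter
    receptor_fold: str = "helix"  # or "rod"
    ligand_units: int = 4         # dp2-dp8 analogue (units, not monosaccharides)
    unit_charge: float = -2.0     # sulfation analogue, e per unit
    pose: str = "front"
    com_offset: float = 11.0      # receptor-ligand COM distance, A
    n_frames: int = 1
    jitter: float = 0.03          # per-atom thermal jitter, A
    ligand_drift: float = 0.3     # rigid ligand displacement per frame, A
    script_hbonds: bool = True    # pose one donor and one acceptor H-bond
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pose not in _POSE_DIRECTIONS:
            raise ValueError(f"unknown pose {self.pose!r}")
        if self.receptor_fold not in ("helix", "rod"):
            raise ValueError(f"unknown receptor fold {self.receptor_fold!r}")

    @property
    def ligand_formal_charge(self) -> float:
        """Exact ligand charge sum (each unit balances to unit_charge)."""
        return self.ligand_units * self.unit_charge


def _residue_class(spec: ToyComplexSpec, i: int) -> str:
    classes = spec.residue_classes or _DEFAULT_CLASSES
    return classes[i % len(classes)]


def _receptor_anchor(spec: ToyComplexSpec, i: int) -> np.ndarray:
    if spec.receptor_fold == "rod":
        return np.array([3.5 * i, 0.0, 0.0])
    theta = np.radians(40.0) * i
    return np.array([6.0 * np.cos(theta), 6.0 * np.sin(theta), 1.6 * i])


def _build_topology_and_base(spec: ToyComplexSpec) -> tuple[Topology, np.ndarray]:
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1

    for i in range(spec.n_receptor_residues):
        resname = _residue_class(spec, i)
        net = 1.0 if resname in _POSITIVE else (-1.0 if resname in _NEGATIVE else 0.0)
        anchor = _receptor_anchor(spec, i)
        for name, element, offset, charge in _RESIDUE_TEMPLATE:
            mass, rmin, eps, vdw = _ELEMENT_PARAMS[element]
            q = round(charge + net, 6) if name == "CB" else charge
            atoms.append(
                AtomRecord(serial, name, element, resname, i + 1, Role.RECEPTOR,
                           mass, q, rmin, eps, vdw)
            )
            coords.append(anchor + np.asarray(offset))
            serial += 1

    rec_coords = np.array(coords)
    rec_masses = np.array([a.mass for a in atoms])
    rec_com = (rec_masses[:, None] * rec_coords).sum(axis=0) / rec_masses.sum()

    direction = _POSE_DIRECTIONS[spec.pose]
    # ligand axis perpendicular to the pose direction
    axis = np.array([0.0, 0.0, 1.0])
    if abs(direction @ axis) > 0.9:
        axis = np.array([1.0, 0.0, 0.0])
    axis = axis - (axis @ direction) * direction
    axis /= np.linalg.norm(axis)
    perp = np.cross(direction, axis)

    balance = round(
        spec.unit_charge - sum(q for *_rest, q in _UNIT_TEMPLATE if q is not None), 6
    )
    lig_local: list[np.ndarray] = []
    resid0 = spec.n_receptor_residues
    for k in range(spec.ligand_units):
        unit_anchor = 4.6 * k * axis + 0.8 * np.sin(1.1 * k) * perp + 0.6 * np.cos(1.3 * k) * direction
        for name, element, offset, charge in _UNIT_TEMPLATE:
            mass, rmin, eps, vdw = _ELEMENT_PARAMS[element]
            q = balance if charge is None else charge
            atoms.append(
                AtomRecord(serial, name, element, "SGU", resid0 + k + 1, Role.LIGAND,
                           mass, q, rmin, eps, vdw)
            )
            lig_local.append(unit_anchor + np.asarray(offset))
            serial += 1

    lig_local = np.array(lig_local)
    lig_masses = np.array([a.mass for a in atoms[len(rec_coords):]])
    lig_com = (lig_masses[:, None] * lig_local).sum(axis=0) / lig_masses.sum()
    lig_coords = lig_local - lig_com + rec_com + spec.com_offset * direction

    topology = Topology(atoms)
    return topology, np.vstack([rec_coords, lig_coords])


def _script_hbonds(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Re-pose one ligand hydroxyl as a donor and one sulfate O as an acceptor.

    The closest ligand O1/HO1 pair is placed collinear with the closest
    receptor carbonyl O (donor-acceptor 2.9 A, angle 180 degrees), and one
    ligand sulfate oxygen is placed 2.0 A beyond the closest receptor amide
    hydrogen along its N-H vector (donor-acceptor 3.0 A).  If any move would
    create a clash, the original coordinates are kept for that move.
    """
    coords = coords.copy()
    lig = topology.is_ligand
    names = topology.names
    lig_com = coords[lig].mean(axis=0)

    def _closest(mask: np.ndarray, to: np.ndarray) -> int | None:
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return None
        return int(idx[np.argmin(((coords[idx] - to) ** 2).sum(axis=1))])

    # ligand-donor bond: O1-HO1 ... O=C (receptor)
    rec_o = _closest(~lig & (names == "O"), lig_com)
    if rec_o is not None:
        o1 = _closest(lig & (names == "O1"), coords[rec_o])
        if o1 is not None:
            ho1 = o1 + 1  # HO1 directly follows O1 in the unit template
            u = lig_com - coords[rec_o]
            u /= np.linalg.norm(u)
            trial = coords.copy()
            trial[o1] = coords[rec_o] + 2.9 * u
            trial[ho1] = coords[rec_o] + 1.9 * u
            if not _has_clash(trial, lig):
                coords = trial

    # ligand-acceptor bond: N-H (receptor) ... O (ligand sulfate)
    rec_h = _closest(~lig & (names == "H"), lig_com)
    if rec_h is not None:
        rec_n = rec_h - 1  # N directly precedes H in the residue template
        os2 = _closest(lig & (names == "OS2"), coords[rec_h])
        if os2 is not None:
            w = coords[rec_h] - coords[rec_n]
            w /= np.linalg.norm(w)
            trial = coords.copy()
            trial[os2] = coords[rec_n] + 3.0 * w
            if not _has_clash(trial, lig):
                coords = trial
    return coords


def _has_clash(coords: np.ndarray, is_ligand: np.ndarray) -> bool:
    rec, lig = coords[~is_ligand], coords[is_ligand]
    d2 = ((rec[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
    return bool((d2 < _MIN_INTERFACE_DISTANCE**2).any())


def gen_toy_complex(
    spec: ToyComplexSpec,
    config: DescriptorConfig | None = None,
) -> tuple[Trajectory, list[pd.Series]]:
    """Generate a toy trajectory plus brute-force oracle descriptors per frame.

    Deterministic for a fixed seed.  Raises ``RuntimeError`` if a
    clash-free placement cannot be found within 100 jitter attempts.
    """
    config = config or DescriptorConfig()
    rng = np.random.default_rng(spec.seed)
    topology, base = _build_topology_and_base(spec)
    if spec.script_hbonds:
        base = _script_hbonds(topology, base)
    lig = topology.is_ligand

    frames = np.empty((spec.n_frames, len(topology), 3))
    cursor = base
    for f in range(spec.n_frames):
        for attempt in range(100):
            coords = cursor.copy()
            if f > 0:
                coords[lig] += spec.ligand_drift * rng.standard_normal(3)
            if spec.jitter > 0 and (f > 0 or attempt > 0):
                coords += spec.jitter * rng.standard_normal(coords.shape)
            if not _has_clash(coords, lig):
                break
        else:
            raise RuntimeError(
                f"could not place frame {f} without clashes after 100 attempts"
            )
        frames[f] = coords
        cursor = coords

    traj = Trajectory(
        topology,
        frames,
        system_id=f"toy_{spec.pose}_{spec.seed}",
        metadata={
            "protein_id": "toy",
            "gag_type": "SGU",
            "gag_length": f"dp{2 * spec.ligand_units}",
            "pose": spec.pose,
        },
    )
    oracles = [
        oracle_descriptor_vector(ComplexFrame(topology, frames[f], f), config)
        for f in range(spec.n_frames)
    ]
    return traj, oracles
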