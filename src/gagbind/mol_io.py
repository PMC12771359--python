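"""Structure and topology I/O for protein-GAG complexes.

The canonical on-disk representation of a trajectory is a multi-model PDB
file (one ``MODEL``/``ENDMDL`` block per frame) accompanied by a *topology
sidecar* -- a CSV or JSON table with one row per atom carrying the per-atom
force-field parameters the descriptor engine needs (partial charge,
Lennard-Jones Rmin/2 and epsilon, mass, van der Waals radius) plus the
receptor/ligand role assignment.

Units follow force-field conventions throughout: coordinates and radii in
Angstrom, masses in amu, charges in elementary-charge units, energies in
kcal/mol.  Receptor/ligand roles come from the sidecar ``role`` column rather
than from chain identifiers, because glycan residue names are nonstandard and
chain conventions vary between preparation pipelines.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class TopologyError(ValueError):
    """Raised when a topology sidecar is malformed or inconsistent."""


class StructureError(ValueError):
    """Raised when a structure file disagrees with its topology."""


class Role(enum.Enum):
    RECEPTOR = "RECEPTOR"
    LIGAND = "LIGAND"


SIDECAR_COLUMNS = (
    "serial",
    "name",
    "residue_name",
    "residue_id",
    "role",
    "mass",
    "charge",
    "lj_rmin_half",
    "lj_epsilon",
    "vdw_radius",
)


def guess_element(name: str) -> str:
    """Guess the element symbol from a PDB atom name.

    Leading digits are stripped (e.g. ``1HB1`` -> hydrogen); the first
    remaining alphabetic character is taken.  This covers the H/C/N/O/S/P
    inventory of protein-glycan solutes; two-letter elements would need an
    explicit ``element`` sidecar column.
    """
    stripped = name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise TopologyError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its force-field parameters and interface role."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    role: Role
    mass: float          # amu
    charge: float        # e
    lj_rmin_half: float  # Angstrom
    lj_epsilon: float    # kcal/mol
    vdw_radius: float    # Angstrom

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise TopologyError(f"atom serial must be >= 1, got {self.serial}")
        if self.mass <= 0:
            raise TopologyError(f"atom {self.serial}: mass must be > 0, got {self.mass}")
        if self.lj_rmin_half < 0 or self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.serial}: negative LJ parameter")
        if self.vdw_radius <= 0:
            raise TopologyError(f"atom {self.serial}: vdw_radius must be > 0")


class Topology:
    """An ordered atom list with vectorised column access.

    Wraps a sequence of :class:`AtomRecord` and exposes NumPy views of every
    per-atom column so the descriptor and energetics code can stay fully
    vectorised.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        if len(atoms) == 0:
            raise TopologyError("no atoms")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        serials = np.array([a.serial for a in self.atoms], dtype=np.int64)
        if len(np.unique(serials)) != len(serials):
            dupes = serials[pd.Series(serials).duplicated().to_numpy()]
            raise TopologyError(f"duplicate atom serials: {sorted(set(dupes.tolist()))[:10]}")
        self.serials = serials
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=np.int64)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.vdw_radii = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        self.is_ligand = np.array([a.role is Role.LIGAND for a in self.atoms], dtype=bool)
        self.is_hydrogen = self.elements == "H"
        if not self.is_hydrogen.any():
            warnings.warn(
                "topology contains no hydrogens; hydrogen-bond counts will be 0",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.atoms)

    def mask(self, role: Role) -> np.ndarray:
        return self.is_ligand if role is Role.LIGAND else ~self.is_ligand

    def to_frame(self) -> pd.DataFrame:
        """Sidecar-schema DataFrame (one row per atom)."""
        return pd.DataFrame(
            {
                "serial": self.serials,
                "name": self.names,
                "element": self.elements,
                "residue_name": self.residue_names,
                "residue_id": self.residue_ids,
                "role": np.where(self.is_ligand, "LIGAND", "RECEPTOR"),
                "mass": self.masses,
                "charge": self.charges,
                "lj_rmin_half": self.lj_rmin_half,
                "lj_epsilon": self.lj_epsilon,
                "vdw_radius": self.vdw_radii,
            }
        )


@dataclass
class ComplexFrame:
    """One trajectory snapshot: a topology plus coordinates in Angstrom."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.topology), 3):
            raise StructureError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.topology)} topology atoms"
            )
        if self.frame_index < 0:
            raise StructureError("frame_index must be >= 0")


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing a single topology."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    system_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise StructureError("trajectory needs >= 1 frame of (n_atoms, 3) coordinates")
        if self.coords.shape[1] != len(self.topology):
            raise StructureError(
                f"frames have {self.coords.shape[1]} atoms, topology has {len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> ComplexFrame:
        return ComplexFrame(self.topology, self.coords[i], frame_index=i)

    def __iter__(self) -> Iterator[ComplexFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# Sidecar I/O


def read_topology_sidecar(path: str | Path) -> Topology:
    """Read a per-atom parameter table (CSV or JSON) into a :class:`Topology`.

    Required columns: ``serial, name, residue_name, residue_id, role, mass,
    charge, lj_rmin_half, lj_epsilon, vdw_radius``.  An optional ``element``
    column overrides name-based element inference.  Role values are restricted
    to ``RECEPTOR``/``LIGAND``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["atoms"] if isinstance(payload, dict) else payload)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise TopologyError(f"no atoms in sidecar {path}")
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise TopologyError(f"sidecar {path} is missing required column(s): {missing}")

    for col in ("mass", "charge", "lj_rmin_half", "lj_epsilon", "vdw_radius"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise TopologyError(
                f"sidecar {path}: non-numeric {col} value {df[col].iloc[row]!r} at row {row + 1}"
            )
        df[col] = numeric

    atoms = []
    for row_no, rec in enumerate(df.itertuples(index=False), start=1):
        role_text = str(rec.role).strip().upper()
        if role_text not in ("RECEPTOR", "LIGAND"):
            raise TopologyError(f"sidecar {path} row {row_no}: unknown role {rec.role!r}")
        name = str(rec.name).strip()
        element = (
            str(rec.element).strip().upper()
            if "element" in df.columns and not pd.isna(rec.element)
            else guess_element(name)
        )
        atoms.append(
            AtomRecord(
                serial=int(rec.serial),
                name=name,
                element=element,
                residue_name=str(rec.residue_name).strip(),
                residue_id=int(rec.residue_id),
                role=Role[role_text],
                mass=float(rec.mass),
                charge=float(rec.charge),
                lj_rmin_half=float(rec.lj_rmin_half),
                lj_epsilon=float(rec.lj_epsilon),
                vdw_radius=float(rec.vdw_radius),
            )
        )
    return Topology(atoms)


def write_topology_sidecar(topology: Topology, path: str | Path) -> None:
    topology.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PDB I/O


def _scan_model_atom_counts(path: Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (one implicit model if none)."""
    counts: list[int] = []
    current = 0
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                current = 0
            elif rec.startswith(("ATOM  ", "HETATM")):
                current += 1
    if not saw_model:
        counts = [current]
    elif current:  # trailing model without ENDMDL
        counts.append(current)
    return [c for c in counts if c > 0] or [0]


def read_pdb_models(path: str | Path, topology: str | Path | Topology) -> Trajectory:
    """Read a multi-model PDB plus its topology sidecar into a Trajectory.

    Every MODEL must contain exactly the sidecar's atoms; atoms are matched by
    serial number, falling back to ``(residue_id, atom name)`` when the serial
    sets disagree.  Coordinates are taken from ATOM/HETATM records in
    Angstrom.  If alternate locations are present only the first-listed
    location set (blank or ``A``) is kept.
    """
    import MDAnalysis as mda

    path = Path(path)
    topo = topology if isinstance(topology, Topology) else read_topology_sidecar(topology)

    counts = _scan_model_atom_counts(path)
    for i, c in enumerate(counts, start=1):
        if c != len(topo):
            raise StructureError(
                f"model {i} has {c} atoms while topology has {len(topo)}"
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    if hasattr(atoms, "altLocs"):
        alt = np.asarray(atoms.altLocs)
        if np.any(alt != ""):
            atoms = atoms[(alt == "") | (alt == "A")]

    if len(atoms) != len(topo):
        raise StructureError(
            f"structure has {len(atoms)} atoms after altloc filtering, "
            f"topology has {len(topo)}"
        )

    order = _match_order(atoms, topo, path)

    coords = np.empty((len(u.trajectory), len(topo), 3), dtype=float)
    for k, _ts in enumerate(u.trajectory):
        coords[k] = atoms.positions[order]
    return Trajectory(topo, coords, system_id=path.stem)


def _match_order(atoms, topo: Topology, path: Path) -> np.ndarray:
    """Permutation mapping topology order onto the structure's atom order."""
    pdb_serials = np.asarray(atoms.ids, dtype=np.int64)
    if set(pdb_serials.tolist()) == set(topo.serials.tolist()):
        lookup = {s: i for i, s in enumerate(pdb_serials.tolist())}
        return np.array([lookup[s] for s in topo.serials.tolist()], dtype=np.int64)
    keys = list(zip(np.asarray(atoms.resids).tolist(), [n.strip() for n in atoms.names]))
    lookup = {}
    for i, key in enumerate(keys):
        lookup.setdefault(key, i)
    order = np.empty(len(topo), dtype=np.int64)
    offenders = []
    for j, key in enumerate(zip(topo.residue_ids.tolist(), topo.names.tolist())):
        if key in lookup:
            order[j] = lookup[key]
        else:
            offenders.append(key)
    if offenders:
        raise StructureError(
            f"{path}: {len(offenders)} sidecar atoms not found in structure "
            f"(first 10 by (residue_id, name)): {offenders[:10]}"
        )
    return order


def write_pdb_models(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB (coordinates to 0.001 A)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    topo = traj.topology
    resid_keys = pd.unique(topo.residue_ids)
    resindex = np.searchsorted(resid_keys, topo.residue_ids)
    # residue_ids from pd.unique are in order of appearance; map explicitly
    key_to_idx = {rid: i for i, rid in enumerate(resid_keys.tolist())}
    resindex = np.array([key_to_idx[r] for r in topo.residue_ids.tolist()])
    resnames = [""] * len(resid_keys)
    for rid, rname in zip(topo.residue_ids.tolist(), topo.residue_names.tolist()):
        resnames[key_to_idx[rid]] = rname

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=len(topo),
            n_residues=len(resid_keys),
            atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", topo.names.tolist())
        u.add_TopologyAttr("elements", topo.elements.tolist())
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", [int(r) for r in resid_keys.tolist()])
        u.add_TopologyAttr("ids", [int(s) for s in topo.serials.tolist()])
        u.load_new(traj.coords.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=len(topo), multiframe=True) as writer:
            for _ts in u.trajectory:
                writer.write(u.atoms)
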