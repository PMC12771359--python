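"""Interface descriptors for protein-GAG complex frames.

Each trajectory frame is reduced to a fixed, named feature vector combining:

* formal charges of receptor and ligand (force-field partial-charge sums),
* counts of charged / hydrophobic / hydrophilic receptor residues within
  5 and 10 Angstrom of the ligand, with derived net-charge and polarity
  indices,
* ligand geometry (end-to-end distance, radius of gyration) and relative
  placement (centre-of-mass distance, principal-axis orientation angle),
* receptor-ligand heavy-atom contacts at short (3.5 A) and medium (5.0 A)
  cutoffs and directional hydrogen-bond counts (3.5 A donor-acceptor
  distance, 135 degree donor-H-acceptor angle),
* solvent-accessible surface areas of receptor, ligand and complex, and
* the electrostatic and van der Waals linear interaction energies.

A residue counts as "near the ligand" when *any* of its atoms lies within the
radius of *any* ligand atom (minimum atom-atom distance criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from gagbind import energetics
from gagbind.mol_io import ComplexFrame, Role, Trajectory

#: Canonical feature vector, in column order.
FEATURE_NAMES: tuple[str, ...] = (
    "prot_charge",
    "gag_charge",
    "n_pos_5A",
    "n_neg_5A",
    "net_charge_5A",
    "net_charge_10A",
    "eed_gag",
    "radgyr_gag",
    "com_distance",
    "orientation_angle",
    "n_phobic_5A",
    "n_philic_5A",
    "polarity_5A",
    "n_phobic_10A",
    "n_philic_10A",
    "polarity_10A",
    "n_contacts_short",
    "n_contacts_medium",
    "n_hbonds_gag_donor",
    "n_hbonds_gag_acceptor",
    "sasa_prot",
    "sasa_gag",
    "sasa_complex",
    "lie_elec",
    "lie_vdw",
)

#: The two energetic features toggled by the LIE-ablation experiments.
LIE_FEATURES: tuple[str, ...] = ("lie_elec", "lie_vdw")

#: Metadata columns carried alongside features in extracted tables.
METADATA_COLUMNS: tuple[str, ...] = (
    "system_id",
    "protein_id",
    "gag_type",
    "gag_length",
    "pose",
    "frame_index",
)

TARGET_COLUMN = "mmgbsa_kcal_mol"


@dataclass(frozen=True)
class DescriptorConfig:
    """Cutoffs, residue classes and feature selection for descriptor extraction."""

    near_radii: tuple[float, float] = (5.0, 10.0)
    contact_short: float = 3.5
    contact_medium: float = 5.0
    hbond_da_cutoff: float = 3.5
    hbond_angle_cutoff: float = 135.0  # degrees
    covalent_h_cutoff: float = 1.2     # bonded-H inference, Angstrom
    positive_residues: frozenset = frozenset({"LYS", "ARG", "HIS", "HIE"})
    negative_residues: frozenset = frozenset({"ASP", "GLU"})
    hydrophobic_residues: frozenset = frozenset(
        {"ALA", "VAL", "LEU", "ILE", "PHE", "TRP", "MET", "TYR"}
    )
    hydrophilic_residues: frozenset = frozenset(
        {"SER", "THR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS", "HIE"}
    )
    probe_radius: float = energetics.DEFAULT_PROBE_RADIUS
    sasa_points: int = energetics.DEFAULT_SPHERE_POINTS
    lie_cutoff: float = energetics.DEFAULT_LIE_CUTOFF
    feature_set: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.contact_short > self.contact_medium:
            raise ValueError("contact_short must be <= contact_medium")
        if any(r <= 0 for r in self.near_radii):
            raise ValueError("near radii must be strictly positive")
        if len(set(self.feature_set)) != len(self.feature_set):
            raise ValueError("feature IDs must be unique")
        unknown = set(self.feature_set) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature IDs: {sorted(unknown)}")

    def without_lie(self) -> "DescriptorConfig":
        return replace(
            self, feature_set=tuple(f for f in self.feature_set if f not in LIE_FEATURES)
        )


# ---------------------------------------------------------------------------
# Charge and residue-class descriptors


def formal_charge(frame: ComplexFrame, role: Role) -> tuple[float, int]:
    """Sum of partial charges over one role; returns (raw sum, rounded formal)."""
    mask = frame.topology.mask(role)
    if not mask.any():
        warnings.warn(f"no atoms with role {role.name}; charge reported as 0", stacklevel=2)
        return 0.0, 0
    raw = float(frame.topology.charges[mask].sum())
    return raw, int(np.rint(raw))


def residues_near_ligand(frame: ComplexFrame, radius: float) -> set[int]:
    """Receptor residue_ids with any atom within ``radius`` of any ligand atom."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    topo = frame.topology
    lig = topo.is_ligand
    if not lig.any() or lig.all():
        return set()
    tree = cKDTree(frame.coords[lig])
    rec_idx = np.flatnonzero(~lig)
    dist, _ = tree.query(frame.coords[rec_idx], k=1)
    near = dist <= radius
    return set(topo.residue_ids[rec_idx[near]].tolist())


def _count_classes(
    frame: ComplexFrame, radius: float, class_a: frozenset, class_b: frozenset
) -> tuple[int, int]:
    topo = frame.topology
    near = residues_near_ligand(frame, radius)
    names = {}
    for rid, rname, is_lig in zip(
        topo.residue_ids.tolist(), topo.residue_names.tolist(), topo.is_ligand.tolist()
    ):
        if not is_lig and rid in near:
            names[rid] = rname.upper()
    a = sum(1 for r in names.values() if r in class_a)
    b = sum(1 for r in names.values() if r in class_b)
    return a, b


def charged_counts(
    frame: ComplexFrame, radius: float, config: DescriptorConfig | None = None
) -> tuple[int, int, int]:
    """(n_positive, n_negative, net) charged receptor residues near the ligand."""
    config = config or DescriptorConfig()
    n_pos, n_neg = _count_classes(frame, radius, config.positive_residues, config.negative_residues)
    return n_pos, n_neg, n_pos - n_neg


def polarity_counts(
    frame: ComplexFrame, radius: float, config: DescriptorConfig | None = None
) -> tuple[int, int, int]:
    """(n_hydrophobic, n_hydrophilic, polarity = philic - phobic) near the ligand."""
    config = config or DescriptorConfig()
    n_phob, n_phil = _count_classes(
        frame, radius, config.hydrophobic_residues, config.hydrophilic_residues
    )
    return n_phob, n_phil, n_phil - n_phob


# ---------------------------------------------------------------------------
# Geometry


def end_to_end_distance(
    frame: ComplexFrame, anchors: tuple[int, int] | None = None
) -> float:
    """Distance between the ligand chain ends.

    Default anchors: the first ligand atom of the first ligand residue and the
    last ligand atom of the last ligand residue, in topology order.  Custom
    anchors are given as indices into the ligand atom list.
    """
    lig_idx = np.flatnonzero(frame.topology.is_ligand)
    if len(lig_idx) < 2:
        raise ValueError("end-to-end distance needs a ligand with >= 2 atoms")
    a, b = anchors if anchors is not None else (0, len(lig_idx) - 1)
    pa, pb = frame.coords[lig_idx[a]], frame.coords[lig_idx[b]]
    return float(np.linalg.norm(pa - pb))


def radius_of_gyration(frame: ComplexFrame) -> float:
    """Mass-weighted radius of gyration of the ligand about its centre of mass."""
    topo = frame.topology
    lig = topo.is_ligand
    m = topo.masses[lig]
    if not lig.any() or m.sum() <= 0:
        raise ValueError("ligand must have atoms with positive total mass")
    x = frame.coords[lig]
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def _center_of_mass(frame: ComplexFrame, mask: np.ndarray) -> np.ndarray:
    m = frame.topology.masses[mask]
    return (m[:, None] * frame.coords[mask]).sum(axis=0) / m.sum()


def com_distance(frame: ComplexFrame) -> float:
    """Distance between receptor and ligand mass-weighted centres."""
    lig = frame.topology.is_ligand
    if not lig.any() or lig.all():
        raise ValueError("frame must contain both receptor and ligand atoms")
    return float(np.linalg.norm(_center_of_mass(frame, ~lig) - _center_of_mass(frame, lig)))


def _principal_axis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray | None:
    """Largest-variance eigenvector of the mass-weighted coordinate covariance."""
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    d = coords - com
    cov = (masses[:, None] * d).T @ d / masses.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:  # all atoms coincident
        return None
    return evecs[:, -1]


def orientation_angle(frame: ComplexFrame) -> float:
    """Angle between receptor and ligand first principal axes, folded to [0, 90].

    Principal axes carry no intrinsic sign, so antiparallel axes fold to 0.
    Returns NaN when either group's geometry is degenerate (coincident atoms).
    """
    topo = frame.topology
    lig = topo.is_ligand
    if not lig.any() or lig.all():
        raise ValueError("frame must contain both receptor and ligand atoms")
    ax_r = _principal_axis(frame.coords[~lig], topo.masses[~lig])
    ax_l = _principal_axis(frame.coords[lig], topo.masses[lig])
    if ax_r is None or ax_l is None:
        return float("nan")
    cosang = np.clip(abs(float(ax_r @ ax_l)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Contacts and hydrogen bonds


def count_contacts(frame: ComplexFrame, cutoff: float) -> int:
    """Unique (receptor heavy atom, ligand heavy atom) pairs within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    topo = frame.topology
    heavy = ~topo.is_hydrogen
    rec = heavy & ~topo.is_ligand
    lig = heavy & topo.is_ligand
    if not rec.any() or not lig.any():
        return 0
    tree_r = cKDTree(frame.coords[rec])
    tree_l = cKDTree(frame.coords[lig])
    return int(tree_r.count_neighbors(tree_l, cutoff))


def _donors_with_hydrogens(
    frame: ComplexFrame, side_mask: np.ndarray, covalent_cutoff: float
) -> list[tuple[int, int]]:
    """(donor heavy atom, bonded hydrogen) index pairs within one role."""
    topo = frame.topology
    side_idx = np.flatnonzero(side_mask)
    heavies = side_idx[np.isin(topo.elements[side_idx], ("N", "O"))]
    hydrogens = side_idx[topo.is_hydrogen[side_idx]]
    if len(heavies) == 0 or len(hydrogens) == 0:
        return []
    tree_h = cKDTree(frame.coords[hydrogens])
    pairs = []
    for d in heavies:
        for hi in tree_h.query_ball_point(frame.coords[d], covalent_cutoff):
            pairs.append((int(d), int(hydrogens[hi])))
    return pairs


def count_hbonds(
    frame: ComplexFrame,
    ligand_is_donor: bool,
    config: DescriptorConfig | None = None,
) -> int:
    """Directional interface hydrogen-bond count.

    A bond is a (donor N/O, bonded H, acceptor N/O) triple across the
    interface with donor-acceptor distance <= 3.5 A and donor-H-acceptor
    angle >= 135 degrees.  Bonded hydrogens are inferred by a 1.2 A covalent
    cutoff (the sidecar carries no bond list).
    """
    config = config or DescriptorConfig()
    topo = frame.topology
    if not topo.is_hydrogen.any():
        warnings.warn("no hydrogens in frame; hydrogen-bond count is 0", stacklevel=2)
        return 0
    donor_side = topo.is_ligand if ligand_is_donor else ~topo.is_ligand
    acceptor_side = ~donor_side
    acceptors = np.flatnonzero(acceptor_side & np.isin(topo.elements, ("N", "O")))
    if len(acceptors) == 0:
        return 0
    donors = _donors_with_hydrogens(frame, donor_side, config.covalent_h_cutoff)
    if not donors:
        return 0
    tree_a = cKDTree(frame.coords[acceptors])
    # angle D-H-A >= cutoff  <=>  cos(D-H-A) <= cos(cutoff)
    max_cos = np.cos(np.radians(config.hbond_angle_cutoff))
    count = 0
    for d, h in donors:
        for ai in tree_a.query_ball_point(frame.coords[d], config.hbond_da_cutoff):
            a = int(acceptors[ai])
            v_hd = frame.coords[d] - frame.coords[h]
            v_ha = frame.coords[a] - frame.coords[h]
            denom = np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
            if denom == 0:
                continue
            if float(v_hd @ v_ha) / denom <= max_cos:
                count += 1
    return count


# ---------------------------------------------------------------------------
# Trajectory-level geometry


def rmsd_profile(
    trajectories: list[Trajectory], reference_frame: int = 0
) -> pd.DataFrame:
    """Mean +/- std (population) of ligand RMSD versus the initial conformation.

    For each trajectory, every frame's receptor atoms are least-squares
    superposed onto the reference frame's receptor before the ligand RMSD is
    measured without further fitting; profiles are then averaged across
    trajectories per frame index.  Trajectories of unequal length are
    truncated to the shortest with a warning.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    lengths = [t.n_frames for t in trajectories]
    n = min(lengths)
    if len(set(lengths)) > 1:
        warnings.warn(f"trajectories of unequal length; truncating to {n} frames", stacklevel=2)
    profiles = np.empty((len(trajectories), n))
    for ti, traj in enumerate(trajectories):
        topo = traj.topology
        rec, lig = ~topo.is_ligand, topo.is_ligand
        ref = traj.coords[reference_frame]
        ref_rec_c = ref[rec] - ref[rec].mean(axis=0)
        ref_lig = ref[lig] - ref[rec].mean(axis=0)
        for fi in range(n):
            mov = traj.coords[fi]
            shift = mov[rec].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_rec_c, mov[rec] - shift)
            lig_aligned = rot.apply(mov[lig] - shift)
            profiles[ti, fi] = float(
                np.sqrt(((lig_aligned - ref_lig) ** 2).sum(axis=1).mean())
            )
    return pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "rmsd_mean": profiles.mean(axis=0),
            "rmsd_std": profiles.std(axis=0),  # population std
        }
    )


# ---------------------------------------------------------------------------
# Assembly


def compute_feature_vector(
    frame: ComplexFrame, config: DescriptorConfig | None = None
) -> pd.Series:
    """All configured descriptors for one frame, as a named Series.

    Descriptors whose geometry is degenerate are reported as NaN; downstream
    table assembly drops (and logs) rows containing NaN rather than imputing.
    """
    config = config or DescriptorConfig()
    r5, r10 = config.near_radii
    values: dict[str, float] = {}

    prot_raw, _ = formal_charge(frame, Role.RECEPTOR)
    gag_raw, _ = formal_charge(frame, Role.LIGAND)
    values["prot_charge"] = prot_raw
    values["gag_charge"] = gag_raw

    n_pos, n_neg, net5 = charged_counts(frame, r5, config)
    values["n_pos_5A"], values["n_neg_5A"], values["net_charge_5A"] = n_pos, n_neg, net5
    values["net_charge_10A"] = charged_counts(frame, r10, config)[2]

    values["eed_gag"] = end_to_end_distance(frame)
    values["radgyr_gag"] = radius_of_gyration(frame)
    values["com_distance"] = com_distance(frame)
    values["orientation_angle"] = orientation_angle(frame)

    for radius, tag in ((r5, "5A"), (r10, "10A")):
        n_phob, n_phil, pol = polarity_counts(frame, radius, config)
        values[f"n_phobic_{tag}"] = n_phob
        values[f"n_philic_{tag}"] = n_phil
        values[f"polarity_{tag}"] = pol

    values["n_contacts_short"] = count_contacts(frame, config.contact_short)
    values["n_contacts_medium"] = count_contacts(frame, config.contact_medium)
    values["n_hbonds_gag_donor"] = count_hbonds(frame, True, config)
    values["n_hbonds_gag_acceptor"] = count_hbonds(frame, False, config)

    sp, sg, sc = energetics.sasa_triplet(frame, config.probe_radius, config.sasa_points)
    values["sasa_prot"], values["sasa_gag"], values["sasa_complex"] = sp, sg, sc

    lie = energetics.lie_energy(frame, config.lie_cutoff)
    values["lie_elec"], values["lie_vdw"] = lie.elec, lie.vdw

    return pd.Series({name: values[name] for name in config.feature_set}, dtype=float)


def extract_feature_table(
    traj: Trajectory,
    config: DescriptorConfig | None = None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """One descriptor row per frame, with metadata columns prepended."""
    config = config or DescriptorConfig()
    meta = {k: "" for k in METADATA_COLUMNS if k != "frame_index"}
    meta.update({"system_id": traj.system_id, **(traj.metadata or {}), **(metadata or {})})
    rows = []
    for frame in traj:
        vec = compute_feature_vector(frame, config)
        row = {k: meta.get(k, "") for k in METADATA_COLUMNS if k != "frame_index"}
        row["frame_index"] = frame.frame_index
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
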