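"""Independent brute-force descriptor oracle.

Re-implements every descriptor with the most literal possible algorithm --
explicit all-pairs distance scans, direct eigendecomposition, full-matrix
occlusion checks without spatial indexing -- sharing no code with the
production engine in :mod:`gagbind.descriptors` / :mod:`gagbind.energetics`.
The production path must agree with these values exactly for counts and to
1e-8 relative for continuous quantities on generated toy complexes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from gagbind.descriptors import DescriptorConfig
from gagbind.mol_io import ComplexFrame

_COULOMB = 332.0522


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return math.sqrt(
        (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2
    )


def _near_residues(frame: ComplexFrame, radius: float) -> set[int]:
    topo = frame.topology
    lig_idx = [i for i in range(len(topo)) if topo.is_ligand[i]]
    near = set()
    for i in range(len(topo)):
        if topo.is_ligand[i]:
            continue
        for j in lig_idx:
            if _dist(frame.coords[i], frame.coords[j]) <= radius:
                near.add(int(topo.residue_ids[i]))
                break
    return near


def _class_counts(frame: ComplexFrame, radius: float, classes: frozenset) -> int:
    topo = frame.topology
    near = _near_residues(frame, radius)
    count = 0
    for rid in sorted(near):
        names = {
            topo.residue_names[i]
            for i in range(len(topo))
            if topo.residue_ids[i] == rid and not topo.is_ligand[i]
        }
        if names and next(iter(names)).upper() in classes:
            count += 1
    return count


def _com(frame: ComplexFrame, ligand: bool) -> np.ndarray:
    topo = frame.topology
    total = np.zeros(3)
    mass = 0.0
    for i in range(len(topo)):
        if bool(topo.is_ligand[i]) == ligand:
            total += topo.masses[i] * frame.coords[i]
            mass += topo.masses[i]
    return total / mass


def _axis(frame: ComplexFrame, ligand: bool) -> np.ndarray | None:
    topo = frame.topology
    idx = [i for i in range(len(topo)) if bool(topo.is_ligand[i]) == ligand]
    com = _com(frame, ligand)
    cov = np.zeros((3, 3))
    mass = 0.0
    for i in idx:
        d = frame.coords[i] - com
        cov += topo.masses[i] * np.outer(d, d)
        mass += topo.masses[i]
    cov /= mass
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:
        return None
    return evecs[:, -1]


def _contacts(frame: ComplexFrame, cutoff: float) -> int:
    topo = frame.topology
    count = 0
    for i in range(len(topo)):
        if topo.is_ligand[i] or topo.elements[i] == "H":
            continue
        for j in range(len(topo)):
            if not topo.is_ligand[j] or topo.elements[j] == "H":
                continue
            if _dist(frame.coords[i], frame.coords[j]) <= cutoff:
                count += 1
    return count


def _hbonds(frame: ComplexFrame, ligand_is_donor: bool, config: DescriptorConfig) -> int:
    topo = frame.topology
    n = len(topo)
    donor_side = [
        i for i in range(n)
        if bool(topo.is_ligand[i]) == ligand_is_donor and topo.elements[i] in ("N", "O")
    ]
    hyd_side = [
        i for i in range(n)
        if bool(topo.is_ligand[i]) == ligand_is_donor and topo.elements[i] == "H"
    ]
    acceptors = [
        i for i in range(n)
        if bool(topo.is_ligand[i]) != ligand_is_donor and topo.elements[i] in ("N", "O")
    ]
    count = 0
    for d in donor_side:
        for h in hyd_side:
            if _dist(frame.coords[d], frame.coords[h]) > config.covalent_h_cutoff:
                continue
            for a in acceptors:
                if _dist(frame.coords[d], frame.coords[a]) > config.hbond_da_cutoff:
                    continue
                v1 = frame.coords[d] - frame.coords[h]
                v2 = frame.coords[a] - frame.coords[h]
                norm = math.sqrt((v1**2).sum()) * math.sqrt((v2**2).sum())
                if norm == 0:
                    continue
                angle = math.degrees(math.acos(max(-1.0, min(1.0, float(v1 @ v2) / norm))))
                if angle >= config.hbond_angle_cutoff:
                    count += 1
    return count


def _sasa(coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int) -> float:
    # golden-spiral lattice, re-derived here
    k = np.arange(n_points) + 0.5
    z = 1.0 - 2.0 * k / n_points
    phi = math.pi * (3.0 - math.sqrt(5.0)) * (k - 0.5)
    rho = np.sqrt(1.0 - z * z)
    lattice = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    total = 0.0
    for i in range(len(radii)):
        r = radii[i] + probe
        pts = coords[i] + r * lattice
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            rj = radii[j] + probe
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= rj * rj
        total += exposed.sum() / n_points * 4.0 * math.pi * r * r
    return total


def _lie(frame: ComplexFrame, cutoff: float) -> tuple[float, float]:
    topo = frame.topology
    elec = 0.0
    vdw = 0.0
    for i in range(len(topo)):
        if topo.is_ligand[i]:
            continue
        for j in range(len(topo)):
            if not topo.is_ligand[j]:
                continue
            r = _dist(frame.coords[i], frame.coords[j])
            if r > cutoff:
                continue
            elec += _COULOMB * topo.charges[i] * topo.charges[j] / r
            rmin = topo.lj_rmin_half[i] + topo.lj_rmin_half[j]
            eps = math.sqrt(topo.lj_epsilon[i] * topo.lj_epsilon[j])
            s6 = (rmin / r) ** 6
            vdw += eps * (s6 * s6 - 2.0 * s6)
    return elec, vdw


def oracle_descriptor_vector(
    frame: ComplexFrame, config: DescriptorConfig | None = None
) -> pd.Series:
    """Full descriptor vector by brute force, in canonical feature order."""
    config = config or DescriptorConfig()
    topo = frame.topology
    r5, r10 = config.near_radii
    v: dict[str, float] = {}

    v["prot_charge"] = sum(
        topo.charges[i] for i in range(len(topo)) if not topo.is_ligand[i]
    )
    v["gag_charge"] = sum(topo.charges[i] for i in range(len(topo)) if topo.is_ligand[i])

    n_pos5 = _class_counts(frame, r5, config.positive_residues)
    n_neg5 = _class_counts(frame, r5, config.negative_residues)
    v["n_pos_5A"], v["n_neg_5A"] = n_pos5, n_neg5
    v["net_charge_5A"] = n_pos5 - n_neg5
    v["net_charge_10A"] = _class_counts(frame, r10, config.positive_residues) - _class_counts(
        frame, r10, config.negative_residues
    )

    lig_idx = [i for i in range(len(topo)) if topo.is_ligand[i]]
    v["eed_gag"] = _dist(frame.coords[lig_idx[0]], frame.coords[lig_idx[-1]])

    com_l = _com(frame, True)
    msum = 0.0
    acc = 0.0
    for i in lig_idx:
        acc += topo.masses[i] * float(((frame.coords[i] - com_l) ** 2).sum())
        msum += topo.masses[i]
    v["radgyr_gag"] = math.sqrt(acc / msum)
    v["com_distance"] = _dist(_com(frame, False), com_l)

    ax_r, ax_l = _axis(frame, False), _axis(frame, True)
    if ax_r is None or ax_l is None:
        v["orientation_angle"] = float("nan")
    else:
        cosang = min(1.0, abs(float(ax_r @ ax_l)))
        v["orientation_angle"] = math.degrees(math.acos(cosang))

    for radius, tag in ((r5, "5A"), (r10, "10A")):
        phob = _class_counts(frame, radius, config.hydrophobic_residues)
        phil = _class_counts(frame, radius, config.hydrophilic_residues)
        v[f"n_phobic_{tag}"], v[f"n_philic_{tag}"] = phob, phil
        v[f"polarity_{tag}"] = phil - phob

    v["n_contacts_short"] = _contacts(frame, config.contact_short)
    v["n_contacts_medium"] = _contacts(frame, config.contact_medium)
    v["n_hbonds_gag_donor"] = _hbonds(frame, True, config)
    v["n_hbonds_gag_acceptor"] = _hbonds(frame, False, config)

    rec_mask = ~topo.is_ligand
    v["sasa_prot"] = _sasa(
        frame.coords[rec_mask], topo.vdw_radii[rec_mask], config.probe_radius, config.sasa_points
    )
    v["sasa_gag"] = _sasa(
        frame.coords[~rec_mask], topo.vdw_radii[~rec_mask], config.probe_radius, config.sasa_points
    )
    v["sasa_complex"] = _sasa(
        frame.coords, topo.vdw_radii, config.probe_radius, config.sasa_points
    )

    v["lie_elec"], v["lie_vdw"] = _lie(frame, config.lie_cutoff)
    return pd.Series({name: v[name] for name in config.feature_set}, dtype=float)
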