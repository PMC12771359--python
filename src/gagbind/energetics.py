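"""Energetic descriptors: linear interaction energies and Shrake-Rupley SASA.

The linear interaction energy (LIE) features are the raw pairwise
receptor-ligand Coulomb and Lennard-Jones sums at dielectric 1 -- no periodic
images, no switching functions, no exclusions (interface pairs are never
bonded).  The Lennard-Jones term uses the Rmin/epsilon convention of the
AMBER-family force fields with Lorentz-Berthelot-style combination: Rmin_ij =
Rmin_i/2 + Rmin_j/2 and eps_ij = sqrt(eps_i * eps_j).

SASA is computed with the Shrake-Rupley point-lattice method on a
deterministic golden-spiral sphere lattice, so results are bit-reproducible
for a fixed point count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from gagbind.mol_io import ComplexFrame

#: Coulomb conversion constant, kcal * Angstrom / (mol * e^2), dielectric 1.
COULOMB_CONSTANT = 332.0522

#: Water-probe radius in Angstrom.
DEFAULT_PROBE_RADIUS = 1.4

#: Sphere-lattice resolution for SASA.
DEFAULT_SPHERE_POINTS = 960

#: Pairwise distance below which geometry is treated as corrupt (Angstrom).
CLASH_DISTANCE = 0.1

#: Default receptor-ligand interaction cutoff for LIE sums (Angstrom).
DEFAULT_LIE_CUTOFF = 12.0


@dataclass(frozen=True)
class LIEResult:
    elec: float  # kcal/mol
    vdw: float   # kcal/mol
    n_pairs_evaluated: int
    cutoff: float  # Angstrom


@dataclass(frozen=True)
class SASAResult:
    per_atom: np.ndarray  # Angstrom^2
    total: float          # Angstrom^2
    probe_radius: float
    n_sphere_points: int


def lie_energy(frame: ComplexFrame, cutoff: float = DEFAULT_LIE_CUTOFF) -> LIEResult:
    """Receptor-ligand electrostatic and van der Waals interaction energies.

    Sums over all (receptor atom i, ligand atom j) pairs with r_ij <= cutoff:

        elec = sum k q_i q_j / r_ij                         (k = 332.0522)
        vdw  = sum eps_ij [(Rmin_ij/r_ij)^12 - 2 (Rmin_ij/r_ij)^6]

    Raises ``ValueError`` on any evaluated pair closer than 0.1 Angstrom
    (clashed or corrupt geometry).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    topo = frame.topology
    rec = ~topo.is_ligand
    lig = topo.is_ligand
    if not rec.any() or not lig.any():
        raise ValueError("frame must contain both receptor and ligand atoms")

    r = cdist(frame.coords[rec], frame.coords[lig])
    within = r <= cutoff
    n_pairs = int(within.sum())
    if n_pairs == 0:
        return LIEResult(0.0, 0.0, 0, cutoff)
    if (r[within] < CLASH_DISTANCE).any():
        i, j = np.unravel_index(np.argmin(np.where(within, r, np.inf)), r.shape)
        raise ValueError(
            f"receptor-ligand pair at {r[i, j]:.4f} A (< {CLASH_DISTANCE} A): "
            "clashed or corrupt geometry"
        )

    qq = np.outer(topo.charges[rec], topo.charges[lig])
    elec = COULOMB_CONSTANT * float((qq[within] / r[within]).sum())

    rmin = topo.lj_rmin_half[rec][:, None] + topo.lj_rmin_half[lig][None, :]
    eps = np.sqrt(np.outer(topo.lj_epsilon[rec], topo.lj_epsilon[lig]))
    ratio6 = (rmin[within] / r[within]) ** 6
    vdw = float((eps[within] * (ratio6**2 - 2.0 * ratio6)).sum())
    return LIEResult(elec, vdw, n_pairs, cutoff)


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    if n_points < 50:
        raise ValueError("n_points must be >= 50 for a usable lattice")
    k = np.arange(n_points, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> SASAResult:
    """Solvent-accessible surface area by the Shrake-Rupley rolling-probe method.

    For each atom, ``n_points`` lattice points are placed on the sphere of
    radius ``r_i + probe``; a point is accessible iff it lies outside every
    other atom's expanded sphere.  ``per_atom`` is the accessible fraction
    times the full expanded-sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii must have matching leading dimension")
    if (radii <= 0).any():
        raise ValueError("all radii must be positive")
    lattice = sphere_lattice(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.empty(len(radii), dtype=float)
    for i in range(len(radii)):
        pts = coords[i] + expanded[i] * lattice
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbors:
            nb = np.array(neighbors, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        per_atom[i] = accessible / n_points * 4.0 * np.pi * expanded[i] ** 2
    return SASAResult(per_atom, float(per_atom.sum()), probe, n_points)


def sasa_triplet(
    frame: ComplexFrame,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> tuple[float, float, float]:
    """SASA of the receptor alone, the ligand alone, and the full complex."""
    topo = frame.topology
    lig = topo.is_ligand
    prot = shrake_rupley(frame.coords[~lig], topo.vdw_radii[~lig], probe, n_points)
    gag = shrake_rupley(frame.coords[lig], topo.vdw_radii[lig], probe, n_points)
    both = shrake_rupley(frame.coords, topo.vdw_radii, probe, n_points)
    return prot.total, gag.total, both.total
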