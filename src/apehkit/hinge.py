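"""Hinge-rotation opening of a two-domain structure.

The open/closed transition of a two-domain protease is emulated by a purely
geometric move: all atoms sequence-C-terminal to a chosen backbone bond
(N-CA or CA-C) of a linker residue are rotated rigidly about that bond.  No
energetics are involved; steric clashes are counted, not resolved.  A
charge-based opening-propensity score (product of the two domain net
charges: like charges repel and favour opening) formalises the verbal
electrostatic argument and is reported as a heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .charge_profile import ChargeProfile
from .errors import ConfigurationError
from .site_environment import TriadSpec, sidechain_atoms
from .structures import DomainPartition, Structure

__all__ = [
    "HingeSpec",
    "OpeningMetrics",
    "Conformer",
    "rotate_about_bond",
    "opening_series",
    "opening_metrics",
    "clash_count",
    "opening_propensity_score",
]

_BOND_ATOMS = {"N-CA": ("N", "CA"), "CA-C": ("CA", "C")}


@dataclass(frozen=True)
class HingeSpec:
    """A backbone bond of a linker residue to rotate about."""

    residue: int
    bond: str = "N-CA"
    angles: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)

    def __post_init__(self) -> None:
        if self.bond not in _BOND_ATOMS:
            raise ValueError(f"bond must be one of {sorted(_BOND_ATOMS)}, got {self.bond!r}")
        if not all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")


@dataclass
class OpeningMetrics:
    centroid_distance: float          # between N-ter and C-ter region centroids, Angstrom
    min_interdomain_distance: float   # closest inter-domain atom pair, Angstrom
    exposure_count: int               # N-ter atoms within the shell of the triad (lower = more open)
    n_clashes: int


@dataclass
class Conformer:
    structure: Structure
    hinge: HingeSpec
    angle: float
    metrics: OpeningMetrics | None = None


def _moving_mask(structure: Structure, hinge: HingeSpec) -> list[tuple[int, int]]:
    """(residue index, atom index) pairs of atoms C-terminal to the hinge bond."""
    idx = None
    for i, res in enumerate(structure.residues):
        if res.number == hinge.residue and res.icode == "":
            idx = i
            break
    if idx is None:
        raise ConfigurationError(f"hinge residue {hinge.residue} not found")
    moving: list[tuple[int, int]] = []
    hinge_res = structure.residues[idx]
    if hinge.bond == "N-CA":
        fixed_names = {"N", "H"}
    else:  # CA-C: only the carbonyl moves within the hinge residue
        fixed_names = {a.name for a in hinge_res.atoms} - {"C", "O", "OXT"}
    for j, atom in enumerate(hinge_res.atoms):
        if atom.name not in fixed_names:
            moving.append((idx, j))
    for i in range(idx + 1, len(structure.residues)):
        for j in range(len(structure.residues[i].atoms)):
            moving.append((i, j))
    return moving


def rotate_about_bond(structure: Structure, hinge: HingeSpec, angle: float) -> Conformer:
    """Rotate everything C-terminal to the hinge bond rigidly by ``angle`` degrees.

    For an N-CA bond the moving set is the hinge residue from CA onward
    (side chain included) plus all later residues; for CA-C it is the
    hinge-residue carbonyl plus all later residues.  Atoms upstream of the
    bond are untouched; all intra-segment distances are preserved.
    """
    name_a, name_b = _BOND_ATOMS[hinge.bond]
    res = structure.residue(hinge.residue)
    if res is None:
        raise ConfigurationError(f"hinge residue {hinge.residue} not found")
    atom_a, atom_b = res.atom(name_a), res.atom(name_b)
    if atom_a is None or atom_b is None:
        raise ConfigurationError(
            f"hinge residue {res.label} lacks bond atoms {name_a}/{name_b}"
        )
    axis = atom_b.coords - atom_a.coords
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ConfigurationError("hinge bond atoms coincide")
    rot = Rotation.from_rotvec(np.radians(angle) * axis / norm)
    origin = atom_a.coords

    new = structure.copy()
    new.id = f"{structure.id}_rot{angle:g}"
    for i, j in _moving_mask(structure, hinge):
        atom = new.residues[i].atoms[j]
        atom.coords = origin + rot.apply(atom.coords - origin)
    return Conformer(new, hinge, float(angle))


def clash_count(conformer: Conformer, threshold: float = 2.0) -> int:
    """Atom pairs across the two rigid segments closer than ``threshold``.

    Pairs within the hinge residue itself (covalently tied through the
    rotated bond) are excluded.
    """
    if threshold <= 0:
        return 0
    structure, hinge = conformer.structure, conformer.hinge
    moving = set(_moving_mask(structure, hinge))
    coords, index = structure.atom_array()
    if coords.shape[0] == 0:
        return 0
    flat_moving = []
    pos = 0
    for i, res in enumerate(structure.residues):
        for j in range(len(res.atoms)):
            flat_moving.append((i, j) in moving)
            pos += 1
    flat_moving = np.array(flat_moving)
    hinge_res_idx = next(
        i for i, res in enumerate(structure.residues) if res.number == hinge.residue
    )
    res_of = np.repeat(
        np.arange(len(structure.residues)),
        [len(r.atoms) for r in structure.residues],
    )
    tree = cKDTree(coords)
    n = 0
    for ia, ib in tree.query_pairs(threshold):
        if flat_moving[ia] == flat_moving[ib]:
            continue
        if res_of[ia] == hinge_res_idx and res_of[ib] == hinge_res_idx:
            continue
        n += 1
    return n


def opening_metrics(
    conformer: Conformer,
    partition: DomainPartition,
    triad: TriadSpec,
    exposure_radius: float = 8.0,
    clash_threshold: float = 2.0,
) -> OpeningMetrics:
    """Openness descriptors of a conformer.

    Reports the N-ter/C-ter centroid separation, the closest inter-domain
    atom pair, the number of N-ter-domain atoms within ``exposure_radius``
    of any triad side-chain atom (a site-occlusion proxy: fewer atoms means
    a more exposed site), and the inter-segment clash count.
    """
    structure = conformer.structure
    groups: dict[str, list[np.ndarray]] = {"N-ter": [], "C-ter": []}
    for res in structure.residues:
        label = partition.classify(res.number)
        if label in groups:
            groups[label].extend(a.coords for a in res.atoms)
    for label, pts in groups.items():
        if not pts:
            raise ValueError(f"partition has no atoms in region {label}; need both domains")
    n_xyz = np.array(groups["N-ter"])
    c_xyz = np.array(groups["C-ter"])
    centroid_d = float(np.linalg.norm(n_xyz.mean(axis=0) - c_xyz.mean(axis=0)))
    min_d = float(cKDTree(n_xyz).query(c_xyz, k=1)[0].min())

    triad_xyz = []
    for number in triad.numbers:
        res = structure.residue(number)
        if res is None:
            raise ConfigurationError(f"triad residue {number} not found")
        triad_xyz.extend(a.coords for a in sidechain_atoms(res))
    if not triad_xyz:
        raise ConfigurationError("triad residues have no side-chain atoms")
    d_to_triad = cKDTree(np.array(triad_xyz)).query(n_xyz, k=1)[0]
    exposure = int(np.sum(d_to_triad <= exposure_radius))

    return OpeningMetrics(centroid_d, min_d, exposure, clash_count(conformer, clash_threshold))


def opening_series(
    structure: Structure,
    hinge: HingeSpec,
    angles: list[float] | None = None,
    partition: DomainPartition | None = None,
    triad: TriadSpec | None = None,
    exposure_radius: float = 8.0,
) -> list[Conformer]:
    """One rigid-rotation conformer per angle, with metrics when a partition
    and triad are supplied."""
    if angles is None:
        angles = list(hinge.angles)
    conformers = []
    for angle in angles:
        conf = rotate_about_bond(structure, hinge, angle)
        if partition is not None and triad is not None:
            conf.metrics = opening_metrics(conf, partition, triad, exposure_radius)
        conformers.append(conf)
    return conformers


def opening_propensity_score(
    profiles: list[ChargeProfile],
) -> list[tuple[str, int, tuple[int, int]]]:
    """Rank proteins by a charge-based opening propensity (heuristic).

    Score = (N-ter net) x (C-ter net).  A positive score means the two
    domains carry like net charges (electrostatic repulsion, open-prone); a
    negative score means opposite charges (attraction, closed-prone).
    Returns (protein_id, score, (n_net, c_net)) sorted ascending by score,
    ties broken by total net charge.
    """
    ranked = []
    for prof in profiles:
        try:
            n_net, c_net = prof.domain_nets
        except KeyError as exc:
            raise ValueError(f"profile {prof.protein_id} lacks a domain region: {exc}") from exc
        ranked.append((prof.protein_id, n_net * c_net, (n_net, c_net), prof.total_net))
    ranked.sort(key=lambda t: (t[1], t[3]))
    return [(pid, score, nets) for pid, score, nets, _ in ranked]
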