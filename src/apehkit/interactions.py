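"""Geometric detection of salt bridges and hydrogen bonds.

Salt bridges follow the classic charged-group distance criterion: a
residue pair counts as bridged when any acidic carboxylate oxygen
(Asp OD1/OD2, Glu OE1/OE2) lies within a cutoff (default 4.0 Angstrom) of
any basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2).
Histidine is counted as basic by default, consistent with sequence-level
charge tallies that count H with K and R.

Hydrogen bonds are detected on heavy atoms (homology models rarely carry
hydrogens): donor-acceptor distance <= 3.5 Angstrom by default, plus a
D-H...A angle test >= 90 degrees when an ideal backbone amide hydrogen can
be placed.  A stricter preset mirroring the classic HBplus defaults
(H...A <= 2.5 A, D...A <= 3.9 A, angle >= 90 deg) is available by name.

Both detectors report at residue-pair (salt bridges) or donor-acceptor-pair
(H-bonds) granularity and use a KD-tree for the neighbour search; tests
check them against a brute-force all-pairs oracle.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import ClassificationError
from .structures import DomainPartition, Residue, Structure

__all__ = [
    "ACIDIC_GROUP_ATOMS",
    "BASIC_GROUP_ATOMS",
    "SaltBridge",
    "HydrogenBond",
    "HBondCriteria",
    "HBOND_PRESETS",
    "find_salt_bridges",
    "find_hbonds",
    "classify_interdomain",
]

ACIDIC_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_GROUP_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

#: Heavy-atom hydrogen-bond donors and acceptors per residue type.  Backbone
#: N (donor, except proline) and O (acceptor) apply to every residue.
SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class SaltBridge:
    """One acidic/basic residue pair; the closest qualifying atom pair is kept."""

    res_a: tuple[int, str]  # (number, name3) of the acidic residue
    res_b: tuple[int, str]  # (number, name3) of the basic residue
    atom_a: str
    atom_b: str
    distance: float
    domain_class: str | None = None

    @property
    def residue_numbers(self) -> tuple[int, int]:
        return (self.res_a[0], self.res_b[0])


@dataclass(frozen=True)
class HydrogenBond:
    donor_res: tuple[int, str]
    acceptor_res: tuple[int, str]
    donor_atom: str
    acceptor_atom: str
    d_DA: float
    angle_DHA: float | None = None
    domain_class: str | None = None

    @property
    def residue_numbers(self) -> tuple[int, int]:
        return (self.donor_res[0], self.acceptor_res[0])


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds for hydrogen-bond detection."""

    max_da: float = 3.5          # donor...acceptor heavy-atom distance, Angstrom
    max_ha: float | None = None  # H...acceptor distance when H is placed
    min_dha_angle: float = 90.0  # D-H...A angle, degrees
    place_amide_h: bool = False  # place an ideal backbone amide H for the angle test

    def validate(self) -> None:
        if self.max_da <= 0:
            raise ValueError("max_da must be positive")


HBOND_PRESETS: dict[str, HBondCriteria] = {
    "heavy-atom": HBondCriteria(),
    "hbplus": HBondCriteria(max_da=3.9, max_ha=2.5, min_dha_angle=90.0, place_amide_h=True),
}


def _collect_atoms(
    structure: Structure,
    table: dict[str, tuple[str, ...]],
    warn_missing: bool = True,
) -> list[tuple[Residue, str, np.ndarray]]:
    out = []
    for res in structure.residues:
        names = table.get(res.name3.upper())
        if names is None:
            continue
        found = False
        for name in names:
            atom = res.atom(name)
            if atom is not None:
                out.append((res, name, atom.coords))
                found = True
        if not found and warn_missing:
            warnings.warn(f"{res.label}: side-chain atoms {names} missing; residue skipped",
                          stacklevel=3)
    return out


def find_salt_bridges(
    structure: Structure,
    cutoff: float = 4.0,
    include_his: bool = True,
) -> list[SaltBridge]:
    """Detect salt bridges at residue-pair granularity.

    A pair is bridged iff the minimum distance between any acidic
    carboxylate oxygen and any basic side-chain nitrogen is <= ``cutoff``.
    One record per residue pair (the closest atom pair), sorted by residue
    numbers.  Terminal amine/carboxylate charges are not considered.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    basic_table = dict(BASIC_GROUP_ATOMS)
    if not include_his:
        basic_table.pop("HIS")
    acidic = _collect_atoms(structure, ACIDIC_GROUP_ATOMS)
    basic = _collect_atoms(structure, basic_table)
    if not acidic or not basic:
        return []

    a_xyz = np.array([xyz for _, _, xyz in acidic])
    b_xyz = np.array([xyz for _, _, xyz in basic])
    tree = cKDTree(b_xyz)
    best: dict[tuple, SaltBridge] = {}
    for i, (res_a, name_a, xyz_a) in enumerate(acidic):
        for j in tree.query_ball_point(a_xyz[i], cutoff):
            res_b, name_b, xyz_b = basic[j]
            if res_b.key == res_a.key:
                continue
            d = float(np.linalg.norm(xyz_a - xyz_b))
            key = (res_a.key, res_b.key)
            if key not in best or d < best[key].distance:
                best[key] = SaltBridge(
                    (res_a.number, res_a.name3), (res_b.number, res_b.name3),
                    name_a, name_b, d,
                )
    return sorted(best.values(), key=lambda sb: sb.residue_numbers)


def _ideal_amide_h(structure: Structure) -> dict[tuple, np.ndarray]:
    """Ideal backbone amide H per residue: 1.0 A from N, opposite the
    bisector of the C(i-1)->N and CA->N directions."""
    out: dict[tuple, np.ndarray] = {}
    prev = None
    for res in structure.residues:
        n, ca = res.atom("N"), res.atom("CA")
        if prev is not None and n is not None and ca is not None:
            c_prev = prev.atom("C")
            if c_prev is not None and np.linalg.norm(n.coords - c_prev.coords) <= 2.5:
                u = n.coords - c_prev.coords
                v = n.coords - ca.coords
                u /= np.linalg.norm(u)
                v /= np.linalg.norm(v)
                bis = u + v
                norm = np.linalg.norm(bis)
                if norm > 1e-6:
                    out[res.key] = n.coords + bis / norm
        prev = res
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hbonds(
    structure: Structure,
    criteria: HBondCriteria | str = "heavy-atom",
) -> list[HydrogenBond]:
    """Detect hydrogen bonds between configured donors and acceptors.

    Each donor-acceptor atom pair is reported at most once.  Pairs within
    one residue are excluded, as are backbone-backbone pairs between
    sequence-adjacent residues (covalently constrained).  The angle test is
    applied only where an ideal backbone amide H can be placed; side-chain
    donors are accepted on distance alone.
    """
    if isinstance(criteria, str):
        criteria = HBOND_PRESETS[criteria]
    criteria.validate()

    donors: list[tuple[Residue, str, np.ndarray]] = []
    acceptors: list[tuple[Residue, str, np.ndarray]] = []
    for res in structure.residues:
        name3 = res.name3.upper()
        n = res.atom("N")
        if n is not None and name3 != "PRO":
            donors.append((res, "N", n.coords))
        o = res.atom("O")
        if o is not None:
            acceptors.append((res, "O", o.coords))
        oxt = res.atom("OXT")
        if oxt is not None:
            acceptors.append((res, "OXT", oxt.coords))
        for name in SIDECHAIN_DONORS.get(name3, ()):
            atom = res.atom(name)
            if atom is not None:
                donors.append((res, name, atom.coords))
        for name in SIDECHAIN_ACCEPTORS.get(name3, ()):
            atom = res.atom(name)
            if atom is not None:
                acceptors.append((res, name, atom.coords))
    if not donors or not acceptors:
        return []

    order = {res.key: i for i, res in enumerate(structure.residues)}
    amide_h = _ideal_amide_h(structure) if criteria.place_amide_h or criteria.min_dha_angle else {}

    d_xyz = np.array([xyz for _, _, xyz in donors])
    tree = cKDTree(np.array([xyz for _, _, xyz in acceptors]))
    bonds: list[HydrogenBond] = []
    for i, (dres, dname, dxyz) in enumerate(donors):
        for j in sorted(tree.query_ball_point(d_xyz[i], criteria.max_da)):
            ares, aname, axyz = acceptors[j]
            if ares.key == dres.key:
                continue
            backbone_pair = dname in ("N",) and aname in ("O", "OXT")
            if backbone_pair and abs(order[ares.key] - order[dres.key]) < 2:
                continue
            d_da = float(np.linalg.norm(dxyz - axyz))
            angle = None
            if dname == "N" and dres.key in amide_h:
                h = amide_h[dres.key]
                angle = _angle_deg(dxyz, h, axyz)
                if angle < criteria.min_dha_angle:
                    continue
                if criteria.max_ha is not None and np.linalg.norm(h - axyz) > criteria.max_ha:
                    continue
            bonds.append(
                HydrogenBond((dres.number, dres.name3), (ares.number, ares.name3),
                             dname, aname, d_da, angle)
            )
    bonds.sort(key=lambda hb: (hb.residue_numbers, hb.donor_atom, hb.acceptor_atom))
    return bonds


def classify_interdomain(
    interactions: list,
    partition: DomainPartition,
) -> tuple[Counter, list]:
    """Label each interaction intra-N, intra-C, inter or linker.

    ``inter`` means one residue in the N-ter region and the other in the
    C-ter region.  Any interaction touching the linker is classed
    ``linker`` and counted in neither intra nor inter tallies.  Residues
    outside every region raise :class:`ClassificationError`.
    """
    counts: Counter = Counter()
    annotated = []
    for item in interactions:
        num_a, num_b = item.residue_numbers
        lab_a = partition.classify(num_a)
        lab_b = partition.classify(num_b)
        missing = [n for n, lab in ((num_a, lab_a), (num_b, lab_b)) if lab is None]
        if missing:
            raise ClassificationError(
                f"residues {missing} not covered by partition {partition.protein_id}"
            )
        if "linker" in (lab_a, lab_b):
            cls = "linker"
        elif lab_a == lab_b:
            cls = "intra-N" if lab_a == "N-ter" else "intra-C"
        else:
            cls = "inter"
        counts[cls] += 1
        annotated.append(replace(item, domain_class=cls))
    return counts, annotated
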