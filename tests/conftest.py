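"""Shared fixtures: synthetic structures and independent brute-force oracles.

The oracles restate the geometric criteria with plain nested loops so they
stay independent of the package's KD-tree detection paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from apehkit import (
    Conformer,
    HingeSpec,
    PeptideSpec,
    ToyContact,
    ToyDesign,
    TriadSpec,
    make_peptide,
    make_two_domain_toy,
    rotate_about_bond,
)
from apehkit.structures import Atom, Residue, Structure

# --- independent criterion tables (restated, not imported) -----------------

ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"),
}


def brute_force_salt_bridges(structure, cutoff=4.0):
    """All-pairs reference: set of (acidic resnum, basic resnum, min distance)."""
    out = {}
    for ra in structure.residues:
        if ra.name3 not in ACIDIC:
            continue
        for rb in structure.residues:
            if rb.name3 not in BASIC or rb.key == ra.key:
                continue
            dists = [
                float(np.linalg.norm(aa.coords - ab.coords))
                for aa in ra.atoms if aa.name in ACIDIC[ra.name3]
                for ab in rb.atoms if ab.name in BASIC[rb.name3]
            ]
            if dists and min(dists) <= cutoff:
                out[(ra.number, rb.number)] = min(dists)
    return out


def brute_force_hbond_pairs(structure, max_da=3.5, min_angle=90.0):
    """All-pairs reference for the heavy-atom H-bond criterion.

    Returns the set of (donor resnum, donor atom, acceptor resnum,
    acceptor atom); mirrors the stated rules: same-residue pairs excluded,
    adjacent backbone-backbone pairs excluded, backbone-amide angle test
    where an ideal H can be placed.
    """
    residues = structure.residues
    order = {res.key: i for i, res in enumerate(residues)}

    # ideal amide H (same published construction: bisector of C(i-1)->N, CA->N)
    amide_h = {}
    for i in range(1, len(residues)):
        n, ca = residues[i].atom("N"), residues[i].atom("CA")
        c_prev = residues[i - 1].atom("C")
        if n is None or ca is None or c_prev is None:
            continue
        if np.linalg.norm(n.coords - c_prev.coords) > 2.5:
            continue
        u = n.coords - c_prev.coords
        v = n.coords - ca.coords
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        b = u + v
        if np.linalg.norm(b) > 1e-6:
            amide_h[residues[i].key] = n.coords + b / np.linalg.norm(b)

    def donors_of(res):
        out = []
        if res.name3 != "PRO" and res.atom("N") is not None:
            out.append("N")
        out.extend(n for n in DONORS.get(res.name3, ()) if res.atom(n) is not None)
        return out

    def acceptors_of(res):
        out = [n for n in ("O", "OXT") if res.atom(n) is not None]
        out.extend(n for n in ACCEPTORS.get(res.name3, ()) if res.atom(n) is not None)
        return out

    pairs = set()
    for dres in residues:
        for dname in donors_of(dres):
            dxyz = dres.atom(dname).coords
            for ares in residues:
                if ares.key == dres.key:
                    continue
                for aname in acceptors_of(ares):
                    if (dname == "N" and aname in ("O", "OXT")
                            and abs(order[ares.key] - order[dres.key]) < 2):
                        continue
                    axyz = ares.atom(aname).coords
                    if float(np.linalg.norm(dxyz - axyz)) > max_da:
                        continue
                    if dname == "N" and dres.key in amide_h:
                        h = amide_h[dres.key]
                        u, v = dxyz - h, axyz - h
                        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < min_angle:
                            continue
                    pairs.add((dres.number, dname, ares.number, aname))
    return pairs


# --- small structure builders ----------------------------------------------

def residue_from_atoms(chain, number, name3, atoms):
    """Residue from {atom name: xyz} pairs (serial numbers synthesised)."""
    res = Residue(chain, number, "", name3)
    for k, (name, xyz) in enumerate(atoms.items(), 1):
        res.atoms.append(Atom(number * 100 + k, name, name[0], np.asarray(xyz, float)))
    return res


def charged_pair_structure(distance, acid="GLU", base="LYS"):
    """Two residues whose charged-group atoms sit exactly ``distance`` apart."""
    atom_a = {"ASP": "OD1", "GLU": "OE1"}[acid]
    atom_b = {"LYS": "NZ", "ARG": "NH1", "HIS": "NE2"}[base]
    res1 = residue_from_atoms("A", 1, acid, {
        "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.2, 0), "O": (1.8, 2.3, 0),
        "CB": (2.0, -1.2, 0), atom_a: (3.0, -2.0, 0),
    })
    res2 = residue_from_atoms("A", 2, base, {
        "N": (10, 10, 10), "CA": (11.5, 10, 10), "C": (12.2, 11.2, 10),
        "O": (11.8, 12.3, 10), "CB": (12.0, 8.8, 10),
        atom_b: (3.0 + distance, -2.0, 0),
    })
    return Structure("pair", [res1, res2])


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def helix10():
    return make_peptide(PeptideSpec("A" * 10, id="helix10"))


@pytest.fixture(scope="session")
def bridged_toy():
    """Two-domain toy with two designed inter-domain salt bridges."""
    design = ToyDesign(contacts=[ToyContact("salt_bridge", 3.2),
                                 ToyContact("salt_bridge", 3.4)])
    return make_two_domain_toy(design, seed=11)


@pytest.fixture(scope="session")
def opening_scenario():
    """A compact two-domain toy pre-closed about its linker hinge.

    Rotating +20..+80 degrees about the hinge bond reopens it: the domain
    centroid separation rises strictly and the triad-occlusion count falls
    strictly (verified at fixture-design time).
    """
    design = ToyDesign(contacts=[], gap=0.0, linker_conformation="helix")
    structure, partition, _ = make_two_domain_toy(design, seed=1)
    hinge = HingeSpec(residue=18, bond="N-CA")
    closed = rotate_about_bond(structure, hinge, -160.0).structure
    triad = TriadSpec(ser=25, asp=27, his=29)
    return closed, partition, hinge, triad
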