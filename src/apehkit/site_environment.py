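"""Catalytic-triad environment: side-chain atoms near the Ser-Asp-His site.

For a serine protease of the prolyl-oligopeptidase family the triad sits at
the interface gated by the beta-propeller domain; the charge character of
the side chains crowding the triad (carboxylate oxygens vs basic nitrogens)
is a compact descriptor of the site's electrostatic environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .structures import Residue, Structure

__all__ = [
    "TriadSpec",
    "Neighbour",
    "SiteEnvironment",
    "triad_environment",
    "environment_charge_summary",
    "sidechain_atoms",
    "atom_charge_class",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

#: Charged side-chain atoms: carboxylate oxygens are negative, basic
#: side-chain nitrogens positive.
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_POSITIVE_ATOMS = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


def sidechain_atoms(res: Residue) -> list:
    """Side-chain atoms of a residue, CB-inclusive (glycine has none)."""
    return [a for a in res.atoms if a.name not in _BACKBONE and not a.name.startswith("H")]


def atom_charge_class(name3: str, atom_name: str) -> str:
    key = (name3.upper(), atom_name)
    if key in _NEGATIVE_ATOMS:
        return "negative"
    if key in _POSITIVE_ATOMS:
        return "positive"
    return "neutral"


@dataclass(frozen=True)
class TriadSpec:
    """Residue numbers of the catalytic Ser, Asp and His."""

    ser: int
    asp: int
    his: int

    @property
    def numbers(self) -> tuple[int, int, int]:
        return (self.ser, self.asp, self.his)


@dataclass(frozen=True)
class Neighbour:
    residue: tuple[int, str]      # (number, name3)
    atom: str
    closest_triad_atom: str       # "SER585:OG" style label
    distance: float
    charge_class: str


@dataclass
class SiteEnvironment:
    triad: TriadSpec
    cutoff: float
    neighbours: list[Neighbour]

    @property
    def n_negative_atoms(self) -> int:
        return sum(1 for n in self.neighbours if n.charge_class == "negative")

    @property
    def n_positive_atoms(self) -> int:
        return sum(1 for n in self.neighbours if n.charge_class == "positive")


def triad_environment(
    structure: Structure,
    triad: TriadSpec,
    cutoff: float = 3.0,
) -> SiteEnvironment:
    """Side-chain atoms of non-triad residues within ``cutoff`` of any triad
    side-chain atom.

    Each neighbouring atom is reported once with its minimum distance to the
    triad and the closest triad atom (ties broken by triad atom-name order).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    triad_atoms: list[tuple[str, np.ndarray]] = []
    for number in triad.numbers:
        res = structure.residue(number)
        if res is None:
            raise ConfigurationError(f"triad residue {number} not found in structure")
        sc = sidechain_atoms(res)
        if not sc:
            raise ConfigurationError(f"triad residue {res.label} has no side-chain atoms")
        for atom in sorted(sc, key=lambda a: a.name):
            triad_atoms.append((f"{res.label}:{atom.name}", atom.coords))

    triad_numbers = set(triad.numbers)
    neighbours: list[Neighbour] = []
    for res in structure.residues:
        if res.number in triad_numbers:
            continue
        for atom in sidechain_atoms(res):
            best_d, best_label = None, None
            for label, xyz in triad_atoms:
                d = float(np.linalg.norm(atom.coords - xyz))
                if best_d is None or d < best_d - 1e-12:
                    best_d, best_label = d, label
            if best_d is not None and best_d <= cutoff:
                neighbours.append(
                    Neighbour((res.number, res.name3), atom.name, best_label,
                              best_d, atom_charge_class(res.name3, atom.name))
                )
    neighbours.sort(key=lambda n: (n.residue[0], n.atom))
    return SiteEnvironment(triad, cutoff, neighbours)


def environment_charge_summary(env: SiteEnvironment) -> str:
    """Dominant charge character of the site environment."""
    if env.n_negative_atoms > env.n_positive_atoms:
        return "negative-dominated"
    if env.n_positive_atoms > env.n_negative_atoms:
        return "positive-dominated"
    return "balanced"
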