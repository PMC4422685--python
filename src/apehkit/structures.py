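"""Atomic structures, PDB I/O, dihedrals and Ramachandran summaries.

The in-memory model is deliberately small: an ordered list of residues,
each an ordered list of atoms with author numbering preserved.  Parsing and
writing of the PDB format are delegated to :mod:`gemmi`; everything the
package measures (distances, dihedrals, regions) is computed from this
container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .errors import FormatError, GeometryError, RangeError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Region",
    "DomainPartition",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "compute_dihedral",
    "backbone_dihedrals",
    "ramachandran_summary",
    "RamachandranSummary",
    "DEFAULT_RAMA_REGIONS",
    "THREE_TO_ONE",
]

#: Standard 20-amino-acid three-letter -> one-letter table.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    """A single atom record (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    """One residue, identified by (chain_id, number, icode) in author numbering."""

    chain_id: str
    number: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        return f"{self.name3}{self.number}{self.icode.strip()}"


@dataclass
class Structure:
    """An ordered collection of residues (typically a single protein chain)."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    source: str = "synthetic"

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atom_array(self) -> tuple[np.ndarray, list[tuple[Residue, Atom]]]:
        """All coordinates as an (n, 3) array plus parallel (residue, atom) index."""
        index = [(res, atom) for res in self.residues for atom in res.atoms]
        if not index:
            return np.empty((0, 3)), index
        coords = np.array([a.coords for _, a in index])
        return coords, index

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[
                Residue(
                    r.chain_id, r.number, r.icode, r.name3,
                    [Atom(a.serial, a.name, a.element, a.coords.copy(),
                          a.altloc, a.occupancy, a.bfactor) for a in r.atoms],
                )
                for r in self.residues
            ],
            source=self.source,
        )


@dataclass(frozen=True)
class Region:
    """An inclusive author-numbered residue range with a role label."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.label}: end {self.end} < start {self.start}")

    def __contains__(self, number: int) -> bool:
        return self.start <= number <= self.end


# Canonical region labels and accepted spellings on input.
_LABEL_ALIASES = {
    "n-ter": "N-ter", "nter": "N-ter", "n": "N-ter",
    "linker": "linker", "hinge": "linker",
    "c-ter": "C-ter", "cter": "C-ter", "c": "C-ter",
}


@dataclass
class DomainPartition:
    """Labelled residue regions of a two-domain protein (inclusive bounds).

    The canonical layout is an N-terminal domain, an optional ~10-residue
    linker, and a C-terminal domain.  Published domain tables often list
    only the two domains (e.g. 1-450 and 461-729), leaving the linker as
    the implicit gap; :meth:`from_bounds` reconstructs it.
    """

    protein_id: str
    regions: list[Region]

    def __post_init__(self) -> None:
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"partition {self.protein_id}: regions {a.label} and {b.label} overlap"
                )
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"partition {self.protein_id}: duplicate region labels")

    @classmethod
    def from_bounds(
        cls,
        protein_id: str,
        nter: tuple[int, int],
        cter: tuple[int, int],
        linker: tuple[int, int] | None = None,
    ) -> "DomainPartition":
        regions = [Region("N-ter", *nter), Region("C-ter", *cter)]
        if linker is None and cter[0] - nter[1] > 1:
            linker = (nter[1] + 1, cter[0] - 1)
        if linker is not None:
            regions.insert(1, Region("linker", *linker))
        return cls(protein_id, regions)

    @classmethod
    def from_string(cls, protein_id: str, text: str) -> "DomainPartition":
        """Parse ``"Nter:1-450,linker:451-460,Cter:461-729"``."""
        regions = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            try:
                label, span = part.split(":")
                lo, hi = span.split("-")
                canonical = _LABEL_ALIASES[label.strip().lower()]
                regions.append(Region(canonical, int(lo), int(hi)))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"cannot parse region {part!r}") from exc
        if not regions:
            raise ValueError("no regions given")
        return cls(protein_id, regions)

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"partition {self.protein_id} has no region {label!r}")

    def classify(self, residue_number: int) -> str | None:
        """Region label containing the residue, or None if uncovered."""
        for r in self.regions:
            if residue_number in r:
                return r.label
        return None

    @property
    def domain_labels(self) -> tuple[str, str]:
        return ("N-ter", "C-ter")


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _pick_chain(model: "gemmi.Model", chain: str | None) -> "gemmi.Chain":
    names = [ch.name for ch in model]
    if chain is not None:
        for ch in model:
            if ch.name == chain:
                return ch
        raise FormatError(f"chain {chain!r} not found (chains: {names})")
    if len(names) == 1:
        return model[0]
    for ch in model:
        if ch.name == "A":
            return ch
    raise FormatError(
        f"multi-chain structure with no chain 'A' (chains: {names}); pass chain= explicitly"
    )


def read_structure(
    path: str | Path,
    chain: str | None = None,
    include_hetatm: bool = False,
    keep_altloc: str = "A",
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Author residue numbering and insertion codes are preserved.  When
    alternate locations are present, the blank altloc and ``keep_altloc``
    are kept and all others dropped.  HETATM records and waters are
    excluded unless ``include_hetatm`` is set.  Only one chain is analysed:
    the single chain of a monomer, chain ``A`` otherwise, or an explicit
    ``chain=``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise FormatError(f"{path}: no ATOM records found")

    gch = _pick_chain(st[0], chain)
    residues: list[Residue] = []
    for gres in gch:
        if gres.het_flag == "H" and not include_hetatm:
            continue
        if gres.name in _WATER_NAMES:
            continue
        icode = gres.seqid.icode.strip()
        res = Residue(gch.name, gres.seqid.num, icode, gres.name)
        seen: set[str] = set()
        for ga in gres:
            alt = ga.altloc if ga.altloc not in ("\x00", "\0") else ""
            if alt not in ("", keep_altloc):
                continue
            if ga.name in seen:
                warnings.warn(
                    f"{path.name}: duplicate atom {ga.name} in {res.label}; keeping first",
                    stacklevel=2,
                )
                continue
            seen.add(ga.name)
            res.atoms.append(
                Atom(ga.serial, ga.name, ga.element.name,
                     np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                     alt, ga.occ, ga.b_iso)
            )
        if res.atoms:
            residues.append(res)
    if not residues:
        raise FormatError(f"{path}: no residues with atoms after filtering")
    return Structure(id=path.stem, residues=residues, source=str(path))


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a :class:`Structure` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = structure.id or "model"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in structure.residues:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id or "A")
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.name3
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        for atom in res.atoms:
            serial += 1
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element or atom.name[0])
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = atom.bfactor
            ga.serial = serial
            if atom.altloc:
                ga.altloc = atom.altloc
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def extract_sequence(
    source: "Structure | str",
    region: tuple[int, int] | None = None,
) -> str:
    """One-letter sequence of a structure or plain sequence string.

    For a :class:`Structure`, ``region`` selects author residue numbers
    (inclusive); unknown residue names map to ``X``.  For a plain string,
    ``region`` is a 1-based inclusive slice.
    """
    if isinstance(source, Structure):
        if region is None:
            return source.sequence
        lo, hi = region
        numbers = [r.number for r in source.residues]
        if not numbers or lo < min(numbers) or hi > max(numbers):
            raise RangeError(f"region {region} outside residue numbering")
        return "".join(r.one_letter for r in source.residues if lo <= r.number <= hi)
    seq = str(source)
    if region is None:
        return seq
    lo, hi = region
    if lo < 1 or hi > len(seq) or lo > hi:
        raise RangeError(f"region {region} outside sequence of length {len(seq)}")
    return seq[lo - 1 : hi]


# ---------------------------------------------------------------------------
# Dihedrals and Ramachandran QC
# ---------------------------------------------------------------------------

def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, range (-180, 180].

    Sign follows the IUPAC convention: atan2 of ``(n1 x n2) . b2_hat`` over
    ``n1 . n2`` where ``n1 = b1 x b2``, ``n2 = b2 x b3`` and ``b_i`` are the
    successive bond vectors.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("consecutive points coincide; dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear bond vectors; dihedral undefined")
    b2_hat = b2 / np.linalg.norm(b2)
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2_hat), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


_PEPTIDE_BOND_MAX = 2.5  # Angstrom; C(i)-N(i+1) beyond this breaks the chain


def _backbone(res: Residue) -> dict[str, np.ndarray] | None:
    out = {}
    for name in ("N", "CA", "C"):
        a = res.atom(name)
        if a is None:
            return None
        out[name] = a.coords
    return out


def backbone_dihedrals(structure: Structure) -> list[tuple[Residue, float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; None where undefined (termini, breaks)."""
    bbs = [(res, _backbone(res)) for res in structure.residues]
    out: list[tuple[Residue, float | None, float | None]] = []
    for i, (res, bb) in enumerate(bbs):
        phi = psi = None
        if bb is not None:
            prev = bbs[i - 1][1] if i > 0 else None
            nxt = bbs[i + 1][1] if i + 1 < len(bbs) else None
            if prev is not None and np.linalg.norm(bb["N"] - prev["C"]) <= _PEPTIDE_BOND_MAX:
                phi = compute_dihedral(prev["C"], bb["N"], bb["CA"], bb["C"])
            if nxt is not None and np.linalg.norm(nxt["N"] - bb["C"]) <= _PEPTIDE_BOND_MAX:
                psi = compute_dihedral(bb["N"], bb["CA"], bb["C"], nxt["N"])
        out.append((res, phi, psi))
    return out


#: Rectangle-union definition of core+allowed Ramachandran regions, as
#: (label, phi_min, phi_max, psi_min, psi_max), all inclusive.  This is a
#: deliberately simple, user-overridable stand-in for a contour-based map:
#: a broad beta/extended box, the right-handed alpha box, and the
#: left-handed alpha box.
DEFAULT_RAMA_REGIONS: tuple[tuple[str, float, float, float, float], ...] = (
    ("beta", -180.0, -40.0, 85.0, 180.0),
    ("beta-tail", -180.0, -40.0, -180.0, -160.0),
    ("alpha-R", -160.0, -40.0, -80.0, -5.0),
    ("bridge", -180.0, -40.0, -5.0, 85.0),
    ("alpha-L", 30.0, 90.0, -10.0, 80.0),
)


@dataclass
class RamachandranSummary:
    """Per-residue backbone dihedrals plus the core+allowed fraction."""

    per_residue: list[tuple[Residue, float | None, float | None]]
    fraction_allowed: float  # NaN when no complete (phi, psi) pair exists

    @property
    def n_classified(self) -> int:
        return sum(1 for _, phi, psi in self.per_residue if phi is not None and psi is not None)


def classify_rama(
    phi: float,
    psi: float,
    regions: Iterable[tuple[str, float, float, float, float]] = DEFAULT_RAMA_REGIONS,
) -> str | None:
    """Region label for a (phi, psi) pair, or None for disallowed."""
    for label, phi_lo, phi_hi, psi_lo, psi_hi in regions:
        if phi_lo <= phi <= phi_hi and psi_lo <= psi <= psi_hi:
            return label
    return None


def ramachandran_summary(
    structure: Structure,
    regions: Sequence[tuple[str, float, float, float, float]] = DEFAULT_RAMA_REGIONS,
) -> RamachandranSummary:
    """Backbone (phi, psi) per residue and the fraction in core+allowed regions.

    Terminal residues (and residues flanking chain breaks) have no complete
    (phi, psi) pair and are excluded from the fraction.  With fewer than
    three consecutive complete-backbone residues the summary is empty and a
    warning is issued.
    """
    per_res = backbone_dihedrals(structure)
    pairs = [(phi, psi) for _, phi, psi in per_res if phi is not None and psi is not None]
    if not pairs:
        warnings.warn("no complete (phi, psi) pairs; Ramachandran fraction undefined",
                      stacklevel=2)
        return RamachandranSummary(per_res, float("nan"))
    n_ok = sum(1 for phi, psi in pairs if classify_rama(phi, psi, regions) is not None)
    return RamachandranSummary(per_res, n_ok / len(pairs))
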