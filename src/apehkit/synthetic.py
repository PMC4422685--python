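"""Synthetic structures, sequences and Ct tables with known ground truth.

Everything the analysis modules measure can be exercised on data built
here: peptides constructed from ideal internal coordinates (so dihedrals
re-measure to their inputs), two-domain toys with designed inter-domain
contacts at exact distances, sequences with exact charge composition, and
qPCR Ct tables generated by inverting the Pfaffl relation from known fold
changes.  Every generator is deterministic under a fixed seed and returns
its ground truth alongside the data.

Side chains use a single idealised extended rotamer per residue type —
enough to carry the charged-group atoms the detectors look at, with no
claim of physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charge_profile import NEGATIVE_RESIDUES, POSITIVE_RESIDUES
from .errors import ConstructionError
from .expression import CtRecord, EfficiencyTable
from .structures import Atom, DomainPartition, ONE_TO_THREE, Residue, Structure

__all__ = [
    "PeptideSpec",
    "ToyContact",
    "ToyDesign",
    "ToyTruth",
    "make_peptide",
    "random_peptide",
    "make_two_domain_toy",
    "make_ct_table",
    "random_charged_sequence",
    "ct_records_to_csv",
    "HELIX_PHI_PSI",
    "EXTENDED_PHI_PSI",
]

# Ideal backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)

#: Extended pseudo-rotamer: side-chain atoms as (name, distance along the
#: CA->CB direction from CA, perpendicular offset), Angstrom.
_SIDECHAINS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "A": (),
    "G": (),
    "S": (("OG", 2.4, 0.0),),
    "C": (("SG", 2.8, 0.0),),
    "T": (("OG1", 2.4, 0.7), ("CG2", 2.5, -0.9)),
    "V": (("CG1", 2.5, 0.8), ("CG2", 2.5, -0.8)),
    "L": (("CG", 2.6, 0.0), ("CD1", 3.9, 0.8), ("CD2", 3.9, -0.8)),
    "I": (("CG1", 2.6, 0.6), ("CG2", 2.5, -0.9), ("CD1", 3.9, 0.6)),
    "M": (("CG", 2.6, 0.0), ("SD", 4.0, 0.0), ("CE", 5.4, 0.8)),
    "P": (("CG", 2.4, 0.8), ("CD", 1.9, 1.6)),
    "F": (("CG", 2.6, 0.0), ("CD1", 3.4, 1.2), ("CD2", 3.4, -1.2),
          ("CE1", 4.8, 1.2), ("CE2", 4.8, -1.2), ("CZ", 5.4, 0.0)),
    "Y": (("CG", 2.6, 0.0), ("CD1", 3.4, 1.2), ("CD2", 3.4, -1.2),
          ("CE1", 4.8, 1.2), ("CE2", 4.8, -1.2), ("CZ", 5.4, 0.0), ("OH", 6.8, 0.0)),
    "W": (("CG", 2.6, 0.0), ("CD1", 3.4, 1.1), ("CD2", 3.6, -0.9),
          ("NE1", 4.8, 1.0), ("CE2", 4.9, -0.2), ("CE3", 4.0, -2.2),
          ("CZ2", 6.2, -0.5), ("CZ3", 5.3, -2.6), ("CH2", 6.3, -1.8)),
    "D": (("CG", 2.6, 0.0), ("OD1", 3.3, 1.1), ("OD2", 3.3, -1.1)),
    "N": (("CG", 2.6, 0.0), ("OD1", 3.3, 1.1), ("ND2", 3.3, -1.1)),
    "E": (("CG", 2.6, 0.0), ("CD", 4.0, 0.0), ("OE1", 4.7, 1.1), ("OE2", 4.7, -1.1)),
    "Q": (("CG", 2.6, 0.0), ("CD", 4.0, 0.0), ("OE1", 4.7, 1.1), ("NE2", 4.7, -1.1)),
    "K": (("CG", 2.6, 0.0), ("CD", 4.0, 0.0), ("CE", 5.3, 0.0), ("NZ", 6.4, 0.0)),
    "R": (("CG", 2.6, 0.0), ("CD", 4.0, 0.0), ("NE", 5.3, 0.0), ("CZ", 6.3, 0.0),
          ("NH1", 7.0, 0.9), ("NH2", 7.0, -0.9)),
    "H": (("CG", 2.6, 0.0), ("ND1", 3.3, 1.2), ("CD2", 3.4, -1.1),
          ("CE1", 4.6, 1.1), ("NE2", 4.6, -0.5)),
}

_NEUTRAL_POOL = "ACFGILMNPQSTVWY"


@dataclass
class PeptideSpec:
    """Sequence plus per-residue backbone dihedrals for the ideal builder.

    ``phi``/``psi``/``omega`` may be scalars (applied to every residue) or
    per-residue sequences; omega defaults to 180 degrees (trans).
    """

    sequence: str
    phi: float | list[float] = HELIX_PHI_PSI[0]
    psi: float | list[float] = HELIX_PHI_PSI[1]
    omega: float | list[float] = 180.0
    start_number: int = 1
    chain_id: str = "A"
    id: str = "peptide"

    def per_residue(self, value, n) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("dihedrals must be finite")
        return arr


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees, IUPAC sign)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi, psi, omega) -> list[dict[str, np.ndarray]]:
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = bb[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        c_i = _place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        bb.append({"N": n_i, "CA": ca_i, "C": c_i})
    # Carbonyl oxygens: O anti to the next amide N (torsion psi + 180).
    for i, frame in enumerate(bb):
        frame["O"] = _place_atom(frame["N"], frame["CA"], frame["C"],
                                 BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    return bb


def _place_sidechain(aa: str, n, ca, c) -> list[tuple[str, np.ndarray]]:
    """CB plus the extended pseudo-rotamer for residue type ``aa``."""
    if aa == "G":
        return []
    u1 = n - ca
    u1 /= np.linalg.norm(u1)
    u2 = c - ca
    u2 /= np.linalg.norm(u2)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    out_of_plane = np.cross(u2, u1)
    out_of_plane /= np.linalg.norm(out_of_plane)
    cb_dir = 0.817 * bisector + 0.577 * out_of_plane
    cb_dir /= np.linalg.norm(cb_dir)
    cb = ca + 1.532 * cb_dir
    atoms = [("CB", cb)]
    perp = np.cross(cb_dir, out_of_plane)
    perp /= np.linalg.norm(perp)
    for name, along, offset in _SIDECHAINS[aa]:
        atoms.append((name, ca + along * cb_dir + offset * perp))
    return atoms


def make_peptide(spec: PeptideSpec) -> Structure:
    """Build a peptide from ideal internal coordinates.

    The backbone is constructed so that re-measured (phi, psi, omega) equal
    the requested values to numerical precision; side chains are placed in
    a single idealised rotamer carrying the charged-group atoms.
    """
    seq = spec.sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = [aa for aa in seq if aa not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid residue codes: {sorted(set(bad))}")
    n = len(seq)
    phi = spec.per_residue(spec.phi, n)
    psi = spec.per_residue(spec.psi, n)
    omega = spec.per_residue(spec.omega, n)

    backbone = _build_backbone(n, phi, psi, omega)
    residues = []
    serial = 0
    for i, aa in enumerate(seq):
        res = Residue(spec.chain_id, spec.start_number + i, "", ONE_TO_THREE[aa])
        frame = backbone[i]
        for name in ("N", "CA", "C", "O"):
            serial += 1
            res.atoms.append(Atom(serial, name, name[0], frame[name]))
        for name, xyz in _place_sidechain(aa, frame["N"], frame["CA"], frame["C"]):
            serial += 1
            res.atoms.append(Atom(serial, name, name[0], xyz))
        residues.append(res)
    return Structure(id=spec.id, residues=residues, source="synthetic")


def random_peptide(length: int, seed: int, compact: bool = True, id: str | None = None) -> Structure:
    """A seeded random-coil peptide over all 20 residue types.

    ``compact`` draws dihedrals from broad basins that keep the chain
    collapsed enough to produce plenty of atomic contacts — the regime the
    interaction detectors are stress-tested in.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(ONE_TO_THREE), size=length))
    if compact:
        phi = rng.uniform(-160, -40, size=length)
        psi = rng.uniform(-80, 60, size=length)
    else:
        phi = rng.uniform(-180, 180, size=length)
        psi = rng.uniform(-180, 180, size=length)
    spec = PeptideSpec(seq, phi=list(phi), psi=list(psi), id=id or f"random{seed}")
    return make_peptide(spec)


# ---------------------------------------------------------------------------
# Two-domain toys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyContact:
    """A designed inter-domain contact to be realised at an exact distance."""

    kind: str                 # "salt_bridge" (Glu...Lys) or "hbond" (Ser OG -> Glu OE1)
    target_distance: float    # Angstrom, between the closest qualifying atoms

    def __post_init__(self) -> None:
        if self.kind not in ("salt_bridge", "hbond"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        limit = 4.0 if self.kind == "salt_bridge" else 3.5
        if not (2.2 <= self.target_distance <= limit):
            raise ValueError(
                f"{self.kind} target {self.target_distance} outside the realisable "
                f"[2.2, {limit}] detection range"
            )


@dataclass
class ToyDesign:
    n_per_domain: int = 14
    linker_length: int = 10
    contacts: list[ToyContact] = field(default_factory=list)
    gap: float = 12.0   # rigid x-offset applied to the second domain, Angstrom
    #: "extended" keeps the domains well separated (contact design);
    #: "helix" gives a compact linker so the domains start adjacent — the
    #: closed-state regime used for hinge-opening studies.
    linker_conformation: str = "extended"


@dataclass
class ToyTruth:
    """Ground truth returned with a toy structure."""

    inter_salt_bridges: int
    inter_hbonds: int
    contacts: list[tuple[str, int, int, float]]  # (kind, res_a, res_b, distance)


def _verify_toy(structure: Structure, partition: DomainPartition,
                sb_cutoff: float = 4.0, hb_cutoff: float = 3.5, eps: float = 1e-9):
    """Generator-internal all-pairs feasibility check.

    Returns (inter salt-bridge residue pairs, inter donor->acceptor atom
    pairs) found by exhaustive scan over the atom groups a toy can contain.
    """
    acidic = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
    basic = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
    donor_names = {"LYS": ("NZ",), "SER": ("OG",)}
    acceptor_names = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"), "SER": ("OG",)}

    def label(res):
        return partition.classify(res.number)

    def is_inter(ra, rb):
        return {label(ra), label(rb)} == {"N-ter", "C-ter"}

    sb_pairs = set()
    hb_pairs = set()
    for ra in structure.residues:
        for rb in structure.residues:
            if ra.key == rb.key or not is_inter(ra, rb):
                continue
            if ra.name3 in acidic and rb.name3 in basic:
                d = min(
                    (float(np.linalg.norm(aa.coords - ab.coords))
                     for aa in ra.atoms if aa.name in acidic[ra.name3]
                     for ab in rb.atoms if ab.name in basic[rb.name3]),
                    default=np.inf,
                )
                if d <= sb_cutoff + eps:
                    sb_pairs.add((ra.number, rb.number))
            # hydrogen bonds at atom-pair granularity: side-chain donors in
            # one domain vs acceptors in the other, plus backbone N/O
            donors = [(rb, n) for n in donor_names.get(rb.name3, ())] + [(rb, "N")]
            acceptors = [(ra, n) for n in acceptor_names.get(ra.name3, ())] + [(ra, "O")]
            for dres, dname in donors:
                datom = dres.atom(dname)
                if datom is None:
                    continue
                for ares, aname in acceptors:
                    aatom = ares.atom(aname)
                    if aatom is None:
                        continue
                    if float(np.linalg.norm(datom.coords - aatom.coords)) <= hb_cutoff + eps:
                        hb_pairs.add((dres.number, dname, ares.number, aname))
    return sb_pairs, hb_pairs


def make_two_domain_toy(
    design: ToyDesign | None = None,
    seed: int = 0,
) -> tuple[Structure, DomainPartition, ToyTruth]:
    """A two-helix toy joined by an extended linker, with designed contacts.

    Domains are poly-alanine helices (the only charged/polar residues are
    the contact carriers), separated rigidly by ``design.gap`` so the only
    inter-domain interactions are the designed ones.  Each designed contact
    is realised by placing the two qualifying side-chain atoms on the line
    between the carrier residues at exactly the target distance (+/- 0.1 A
    verified).  Construction is deterministic given (design, seed).
    """
    if design is None:
        design = ToyDesign()
    n_dom, n_link = design.n_per_domain, design.linker_length
    if n_dom < 6:
        raise ConstructionError("domains need >= 6 residues")
    if len(design.contacts) > n_dom // 2 - 1:
        raise ConstructionError("too many contacts for the domain size")

    rng = np.random.default_rng(seed)
    # Carrier residues: acidic partner (Glu) in domain A, basic/donor partner
    # in domain B, spaced every second position starting at the 2nd residue.
    seq_a = list("A" * n_dom)
    seq_b = list("A" * n_dom)
    carriers = []
    for k, contact in enumerate(design.contacts):
        ia = 1 + 2 * k
        seq_a[ia] = "E"
        seq_b[ia] = "K" if contact.kind == "salt_bridge" else "S"
        carriers.append((contact, ia))

    sequence = "".join(seq_a) + "G" * n_link + "".join(seq_b)
    n_total = len(sequence)
    phi = [HELIX_PHI_PSI[0]] * n_total
    psi = [HELIX_PHI_PSI[1]] * n_total
    if design.linker_conformation == "extended":
        for i in range(n_dom, n_dom + n_link):
            phi[i], psi[i] = EXTENDED_PHI_PSI
    elif design.linker_conformation != "helix":
        raise ConstructionError(
            f"unknown linker_conformation {design.linker_conformation!r}"
        )
    structure = make_peptide(
        PeptideSpec(sequence, phi=phi, psi=psi, id=f"toy{seed}")
    )
    # Rigidly offset the second domain (and jitter direction slightly by seed)
    # so the domains face each other across a clean gap.
    shift = np.array([design.gap, 0.0, 0.0]) + rng.normal(0.0, 0.05, size=3)
    for res in structure.residues[n_dom + n_link:]:
        for atom in res.atoms:
            atom.coords = atom.coords + shift

    partition = DomainPartition.from_bounds(
        f"toy{seed}", (1, n_dom), (n_dom + n_link + 1, n_total)
    )

    # Realise each contact on the line between the carrier CB atoms.
    realized: list[tuple[str, int, int, float]] = []
    for contact, ia in carriers:
        res_a = structure.residues[ia]
        res_b = structure.residues[n_dom + n_link + ia]
        cb_a, cb_b = res_a.atom("CB").coords, res_b.atom("CB").coords
        direction = cb_b - cb_a
        direction /= np.linalg.norm(direction)
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(direction, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)

        # hydrogen-bond partners sit further out so the donor cannot also
        # reach the carrier's backbone oxygen
        anchor = cb_a + (2.0 if contact.kind == "salt_bridge" else 3.5) * direction
        res_a.atom("OE1").coords = anchor
        # OE2 sits behind and beside OE1 so only OE1 reaches the partner at
        # hydrogen-bond range; the pair still shares one carboxylate carbon.
        res_a.atom("OE2").coords = anchor - 1.0 * direction + 2.0 * perp
        res_a.atom("CD").coords = anchor - 0.8 * direction + 1.0 * perp
        res_a.atom("CG").coords = cb_a + 1.2 * direction + 0.6 * perp
        partner = anchor + contact.target_distance * direction
        if contact.kind == "salt_bridge":
            res_b.atom("NZ").coords = partner
            res_b.atom("CE").coords = partner + 1.5 * direction
            res_b.atom("CD").coords = partner + 2.9 * direction
            res_b.atom("CG").coords = cb_b - 1.3 * direction
            d = float(np.linalg.norm(res_a.atom("OE1").coords - res_b.atom("NZ").coords))
        else:
            res_b.atom("OG").coords = partner
            d = float(np.linalg.norm(res_a.atom("OE1").coords - res_b.atom("OG").coords))
        realized.append((contact.kind, res_a.number, res_b.number, d))

    # Verify the construction: designed distances exact, and exactly the
    # designed inter-domain contacts present (no accidental extras).
    for (kind, _, _, d), (contact, _) in zip(realized, carriers):
        if abs(d - contact.target_distance) > 0.1:
            raise ConstructionError(
                f"contact realised at {d:.3f} A, target {contact.target_distance} A"
            )
    n_sb_designed = sum(1 for c in design.contacts if c.kind == "salt_bridge")
    # A salt bridge between NZ and a carboxylate oxygen at H-bond range is
    # chemically also a hydrogen bond, so it counts in both tallies.
    n_hb_expected = sum(
        1 for c in design.contacts if c.kind == "hbond" or c.target_distance <= 3.5
    )
    sb_found, hb_found = _verify_toy(structure, partition)
    if len(sb_found) != n_sb_designed or len(hb_found) != n_hb_expected:
        raise ConstructionError(
            f"design infeasible: found {len(sb_found)} inter salt bridges "
            f"(designed {n_sb_designed}) and {len(hb_found)} inter H-bond atom "
            f"pairs (expected {n_hb_expected})"
        )
    truth = ToyTruth(n_sb_designed, n_hb_expected, realized)
    return structure, partition, truth


# ---------------------------------------------------------------------------
# Sequences and Ct tables
# ---------------------------------------------------------------------------

def random_charged_sequence(length: int, n_neg: int, n_pos: int, seed: int = 0) -> str:
    """A random sequence with exactly ``n_neg`` D/E and ``n_pos`` H/K/R residues."""
    if n_neg < 0 or n_pos < 0 or n_neg + n_pos > length:
        raise ValueError(f"counts ({n_neg}, {n_pos}) exceed length {length}")
    rng = np.random.default_rng(seed)
    letters = (
        list(rng.choice(sorted(NEGATIVE_RESIDUES), size=n_neg))
        + list(rng.choice(sorted(POSITIVE_RESIDUES), size=n_pos))
        + list(rng.choice(list(_NEUTRAL_POOL), size=length - n_neg - n_pos))
    )
    rng.shuffle(letters)
    return "".join(letters)


def make_ct_table(
    true_folds: dict[str, dict[str, float]],
    efficiencies: EfficiencyTable,
    reference_gene: str,
    control_tissue: str,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    base_ct: float = 24.0,
    reference_ct: float = 18.0,
) -> tuple[list[CtRecord], dict[str, dict[str, float]]]:
    """Generate Ct records whose Pfaffl folds equal ``true_folds``.

    ``true_folds[gene][tissue]`` is the intended expression fold of the gene
    in that tissue relative to ``control_tissue`` (the control's own fold is
    forced to 1).  Cts are obtained by inverting the Pfaffl relation with
    the reference gene held flat across tissues, then perturbed with
    Gaussian cycle noise of sd ``noise_sd``.  Returns the records and the
    truth mapping actually used.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    truth: dict[str, dict[str, float]] = {}
    tissues = sorted({t for folds in true_folds.values() for t in folds} | {control_tissue})
    records: list[CtRecord] = []

    for gene, folds in true_folds.items():
        for tissue, fold in folds.items():
            if not (fold > 0 and np.isfinite(fold)):
                raise ValueError(f"fold for {gene}/{tissue} must be positive, got {fold}")
        base = efficiencies.base(gene)
        truth[gene] = {}
        for tissue in tissues:
            fold = 1.0 if tissue == control_tissue else float(folds.get(tissue, 1.0))
            truth[gene][tissue] = fold
            # R = base ** (Ct_control - Ct_sample)  (reference flat, dCt_ref = 0)
            ct_clean = base_ct - np.log(fold) / np.log(base)
            for rep in range(1, n_replicates + 1):
                ct = ct_clean + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                records.append(CtRecord(f"{tissue}-{rep}", tissue, gene, float(ct), rep))
    for tissue in tissues:
        for rep in range(1, n_replicates + 1):
            ct = reference_ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            records.append(CtRecord(f"{tissue}-{rep}", tissue, reference_gene, float(ct), rep))
    return records, truth


def ct_records_to_csv(records: list[CtRecord], path) -> None:
    """Write Ct records as a deterministic CSV (sample, tissue, gene, Ct, replicate)."""
    import pandas as pd

    df = pd.DataFrame(
        [(r.sample, r.tissue, r.gene, r.ct, r.replicate) for r in records],
        columns=["sample", "tissue", "gene", "ct", "replicate"],
    )
    df.to_csv(path, index=False, float_format="%.6f")
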