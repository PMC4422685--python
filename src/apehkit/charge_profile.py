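"""Domain-resolved sequence charge statistics and molecular masses.

Charge bookkeeping follows the convention used in comparative tables for
two-domain APEH proteases: aspartate and glutamate count as negative,
histidine, lysine and arginine as positive (no pKa modelling), and the net
charge of a region is ``positives - negatives`` in elementary charge units.
Domain totals are taken over the N- and C-terminal regions only — the
linker is excluded, matching how such tables delimit their regions — unless
``include_linker`` is set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .errors import RangeError
from .structures import DomainPartition

__all__ = [
    "NEGATIVE_RESIDUES",
    "POSITIVE_RESIDUES",
    "residue_charge_class",
    "RegionCharge",
    "ChargeProfile",
    "region_charge_profile",
    "molecular_mass",
    "charge_table",
]

NEGATIVE_RESIDUES = frozenset("DE")
POSITIVE_RESIDUES = frozenset("HKR")
_VALID_CODES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def residue_charge_class(aa: str) -> str:
    """Charge class of a one-letter residue code: negative (D, E), positive
    (H, K, R) or neutral."""
    code = aa.upper()
    if len(code) != 1 or code not in _VALID_CODES:
        raise ValueError(f"invalid one-letter residue code: {aa!r}")
    if code in NEGATIVE_RESIDUES:
        return "negative"
    if code in POSITIVE_RESIDUES:
        return "positive"
    return "neutral"


@dataclass(frozen=True)
class RegionCharge:
    label: str
    n_negative: int
    n_positive: int

    @property
    def net(self) -> int:
        return self.n_positive - self.n_negative


@dataclass
class ChargeProfile:
    """Per-region charge counts plus the protein total over the two domains."""

    protein_id: str
    per_region: list[RegionCharge]
    total_net: int

    def region(self, label: str) -> RegionCharge:
        for rc in self.per_region:
            if rc.label == label:
                return rc
        raise KeyError(f"profile {self.protein_id} has no region {label!r}")

    @property
    def domain_nets(self) -> tuple[int, int]:
        """(N-ter net, C-ter net)."""
        return (self.region("N-ter").net, self.region("C-ter").net)


def _count(seq: str) -> tuple[int, int]:
    n_neg = sum(1 for aa in seq if aa.upper() in NEGATIVE_RESIDUES)
    n_pos = sum(1 for aa in seq if aa.upper() in POSITIVE_RESIDUES)
    return n_neg, n_pos


def region_charge_profile(
    sequence: str,
    partition: DomainPartition,
    include_linker: bool = False,
) -> ChargeProfile:
    """Charge counts per partition region and the protein total net charge.

    Region bounds are 1-based inclusive positions into ``sequence``.  The
    total is summed over the N-ter and C-ter regions; ``include_linker``
    adds any linker region to the total as well.
    """
    n = len(sequence)
    per_region = []
    total = 0
    for reg in partition.regions:
        if reg.start < 1 or reg.end > n:
            raise RangeError(
                f"region {reg.label} {reg.start}-{reg.end} exceeds sequence length {n}"
            )
        n_neg, n_pos = _count(sequence[reg.start - 1 : reg.end])
        rc = RegionCharge(reg.label, n_neg, n_pos)
        per_region.append(rc)
        if reg.label in ("N-ter", "C-ter") or include_linker:
            total += rc.net
    return ChargeProfile(partition.protein_id, per_region, total)


def molecular_mass(sequence: str) -> float:
    """Average molecular mass of the peptide in Da (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - (_VALID_CODES - {"X"})
    if bad:
        raise ValueError(f"cannot compute mass with unknown residues: {sorted(bad)}")
    return float(molecular_weight(seq, seq_type="protein"))


_ROWS = ("n_negative", "n_positive", "net", "total_net")


def charge_table(proteins: list[tuple[str, str, DomainPartition]]) -> pd.DataFrame:
    """Tabulate charge statistics for several proteins.

    ``proteins`` is a list of (protein_id, sequence, partition).  The result
    has one row per (protein, region) with the count columns plus the
    protein-level total net charge, mirroring the layout of published
    domain-charge tables.
    """
    records = []
    for protein_id, sequence, partition in proteins:
        prof = region_charge_profile(sequence, partition)
        for rc in prof.per_region:
            records.append(
                {
                    "protein": protein_id,
                    "region": rc.label,
                    "n_negative": rc.n_negative,
                    "n_positive": rc.n_positive,
                    "net": rc.net,
                    "total_net": prof.total_net,
                }
            )
    columns = ["protein", "region", "n_negative", "n_positive", "net", "total_net"]
    return pd.DataFrame.from_records(records, columns=columns)


def charge_table_json(table: pd.DataFrame) -> str:
    """JSON rendering of :func:`charge_table` output (records orient)."""
    return json.dumps(table.to_dict(orient="records"), indent=2)
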