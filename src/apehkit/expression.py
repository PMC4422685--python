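"""Efficiency-corrected relative qPCR expression (Pfaffl method).

The relative expression of a target gene versus a reference gene is

    R = (1 + e_target) ** dCt_target / (1 + e_ref) ** dCt_ref

where ``e`` is the fractional amplification efficiency of the primer pair
(e = 1 means perfect doubling per cycle, so the base 1 + e is the classic
Pfaffl E ~ 2) and ``dCt = Ct(control) - Ct(sample)`` for each gene.
Efficiencies quoted by qPCR instruments as fractions in (0, 1.2] are used
directly; replicate Ct values are averaged per (tissue, gene) before the
delta is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DataError

__all__ = [
    "EfficiencyTable",
    "CtRecord",
    "ExpressionResult",
    "pfaffl_ratio",
    "fold_table",
    "expression_ratio_column",
]

_E_MIN, _E_MAX = 0.0, 1.2


@dataclass(frozen=True)
class CtRecord:
    sample: str
    tissue: str
    gene: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"Ct must be positive and finite, got {self.ct}")


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    tissue: str
    fold: float      # R, relative to the control tissue
    dct_target: float
    dct_ref: float


class EfficiencyTable:
    """Per-primer-pair fractional amplification efficiencies.

    Keys are gene labels (optionally qualified by species); ``base(gene)``
    returns the amplification base 1 + e.
    """

    def __init__(self, efficiencies: dict[str, float]):
        for gene, e in efficiencies.items():
            if not (_E_MIN < e <= _E_MAX):
                raise ValueError(
                    f"efficiency for {gene!r} must be a fraction in ({_E_MIN}, {_E_MAX}], got {e}"
                )
        self._eff = dict(efficiencies)

    def __contains__(self, gene: str) -> bool:
        return gene in self._eff

    def efficiency(self, gene: str) -> float:
        try:
            return self._eff[gene]
        except KeyError:
            raise DataError(f"no efficiency for gene {gene!r}") from None

    def base(self, gene: str) -> float:
        return 1.0 + self.efficiency(gene)

    @classmethod
    def from_csv(cls, path) -> "EfficiencyTable":
        """Load a CSV with columns ``gene`` and ``efficiency``."""
        df = pd.read_csv(path)
        missing = {"gene", "efficiency"} - set(df.columns)
        if missing:
            raise DataError(f"efficiency CSV lacks columns {sorted(missing)}")
        return cls(dict(zip(df["gene"], df["efficiency"].astype(float))))

    def to_dict(self) -> dict[str, float]:
        return dict(self._eff)


def pfaffl_ratio(
    e_target: float,
    e_ref: float,
    dct_target: float,
    dct_ref: float,
) -> float:
    """Efficiency-corrected expression ratio R.

    ``dct`` values are Ct(control) - Ct(sample); efficiencies are fractions
    (0.95 means 95% amplification per cycle).
    """
    for name, v in (("e_target", e_target), ("e_ref", e_ref),
                    ("dct_target", dct_target), ("dct_ref", dct_ref)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if not (_E_MIN < e <= _E_MAX):
            raise ValueError(f"{name} must be in ({_E_MIN}, {_E_MAX}], got {e}")
    return (1.0 + e_target) ** dct_target / (1.0 + e_ref) ** dct_ref


def _mean_ct(records: list[CtRecord]) -> pd.Series:
    df = pd.DataFrame([(r.tissue, r.gene, r.ct) for r in records],
                      columns=["tissue", "gene", "ct"])
    return df.groupby(["tissue", "gene"])["ct"].mean()


def fold_table(
    ct_records: list[CtRecord],
    efficiencies: EfficiencyTable,
    reference_gene: str,
    control_tissue: str,
) -> pd.DataFrame:
    """Per-tissue Pfaffl folds for every target gene, relative to a control tissue.

    Replicate Cts are averaged per (tissue, gene) before the delta-Ct is
    formed.  The result has one row per (tissue, target gene) with columns
    ``fold``, ``dct_target`` and ``dct_ref``; the reference gene itself is
    not reported as a target.
    """
    if not ct_records:
        raise DataError("no Ct records")
    mean_ct = _mean_ct(ct_records)
    tissues = sorted({t for t, _ in mean_ct.index})
    genes = sorted({g for _, g in mean_ct.index})
    if reference_gene not in genes:
        raise DataError(f"reference gene {reference_gene!r} absent from Ct table")
    if control_tissue not in tissues:
        raise DataError(f"control tissue {control_tissue!r} absent from Ct table")

    e_ref = efficiencies.efficiency(reference_gene)
    rows = []
    for tissue in tissues:
        if (tissue, reference_gene) not in mean_ct.index:
            raise DataError(f"tissue {tissue!r} lacks reference-gene measurements")
        dct_ref = float(mean_ct[(control_tissue, reference_gene)]
                        - mean_ct[(tissue, reference_gene)])
        for gene in genes:
            if gene == reference_gene or (tissue, gene) not in mean_ct.index:
                continue
            if (control_tissue, gene) not in mean_ct.index:
                raise DataError(f"control tissue lacks measurements for gene {gene!r}")
            dct_t = float(mean_ct[(control_tissue, gene)] - mean_ct[(tissue, gene)])
            fold = pfaffl_ratio(efficiencies.efficiency(gene), e_ref, dct_t, dct_ref)
            rows.append({"tissue": tissue, "gene": gene, "fold": fold,
                         "dct_target": dct_t, "dct_ref": dct_ref})
    return pd.DataFrame(rows, columns=["tissue", "gene", "fold", "dct_target", "dct_ref"])


def expression_ratio_column(
    folds: pd.DataFrame,
    numerator_gene: str,
    denominator_gene: str,
) -> pd.DataFrame:
    """Per-tissue ratio of two genes' expression folds (e.g. apeh-2 / apeh-1)."""
    wide = folds.pivot(index="tissue", columns="gene", values="fold")
    for gene in (numerator_gene, denominator_gene):
        if gene not in wide.columns:
            raise DataError(f"gene {gene!r} absent from fold table")
    out = wide[[numerator_gene, denominator_gene]].copy()
    out["ratio"] = out[numerator_gene] / out[denominator_gene]
    return out.reset_index()
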