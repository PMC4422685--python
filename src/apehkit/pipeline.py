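"""End-to-end report orchestration.

``run_report`` validates a :class:`RunConfig` up front, then emits whatever
report sections its inputs support: the per-domain charge table (FASTA),
the interaction tables and inter-domain summary (PDB + partition), the
catalytic-site environment (PDB + triad), the hinge opening series (PDB +
hinge spec) and the expression fold/ratio tables (Ct CSV + efficiencies).
Outputs are machine-parseable TSV/JSON; given identical inputs and seed the
bundle is byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .charge_profile import charge_table
from .errors import ApehkitError
from .expression import EfficiencyTable, expression_ratio_column, fold_table
from .hinge import HingeSpec, opening_series
from .interactions import classify_interdomain, find_hbonds, find_salt_bridges
from .expression import CtRecord
from .site_environment import TriadSpec, environment_charge_summary, triad_environment
from .structures import DomainPartition, read_structure, write_structure

logger = logging.getLogger("apehkit")

__all__ = ["RunConfig", "ValidationError", "run_report"]


class ValidationError(ApehkitError):
    """Raised before any computation when a config is inconsistent."""


@dataclass
class RunConfig:
    outdir: Path
    fasta: Path | None = None
    partition: DomainPartition | None = None
    structure: Path | None = None
    triad: TriadSpec | None = None
    hinge: HingeSpec | None = None
    ct: Path | None = None
    efficiencies: Path | EfficiencyTable | None = None
    reference_gene: str | None = None
    control_tissue: str | None = None
    ratio_genes: tuple[str, str] | None = None
    salt_bridge_cutoff: float = 4.0
    hbond_criteria: str = "heavy-atom"
    site_cutoff: float = 3.0
    exposure_radius: float = 8.0
    clash_threshold: float = 2.0
    write_conformers: bool = False
    seed: int = 0

    def validate(self) -> None:
        for label, p in (("fasta", self.fasta), ("structure", self.structure),
                         ("ct", self.ct)):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{label} file does not exist: {p}")
        if isinstance(self.efficiencies, (str, Path)) and not Path(self.efficiencies).exists():
            raise ValidationError(f"efficiency file does not exist: {self.efficiencies}")
        for label, v in (("salt_bridge_cutoff", self.salt_bridge_cutoff),
                         ("site_cutoff", self.site_cutoff),
                         ("exposure_radius", self.exposure_radius)):
            if v <= 0:
                raise ValidationError(f"{label} must be positive, got {v}")
        if self.ct is not None:
            if self.efficiencies is None or not self.reference_gene or not self.control_tissue:
                raise ValidationError(
                    "expression section needs efficiencies, reference_gene and control_tissue"
                )
        if (self.fasta is not None or self.structure is not None) and self.partition is None:
            raise ValidationError("charge/interaction sections need a domain partition")


def _write(df: pd.DataFrame, outdir: Path, stem: str) -> None:
    df.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False, float_format="%.4f")
    (outdir / f"{stem}.json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=2, default=str) + "\n"
    )


def _read_ct_csv(path: Path) -> list[CtRecord]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    needed = {"tissue", "gene", "ct"}
    if not needed <= set(cols):
        raise ValidationError(f"Ct CSV must have columns {sorted(needed)}")
    return [
        CtRecord(
            str(row.get(cols.get("sample", ""), f"s{i}")),
            str(row[cols["tissue"]]), str(row[cols["gene"]]),
            float(row[cols["ct"]]),
            int(row[cols["replicate"]]) if "replicate" in cols else 1,
        )
        for i, row in df.iterrows()
    ]


def run_report(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every report section the config supports; return the tables.

    Sections whose inputs are absent are skipped with a log notice rather
    than failing the run.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []
    sections: dict[str, pd.DataFrame] = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.fasta is not None:
            records = list(SeqIO.parse(str(config.fasta), "fasta"))
            proteins = [(rec.id, str(rec.seq), config.partition) for rec in records]
            sections["charges"] = charge_table(proteins)
            _write(sections["charges"], outdir, "charges")
        else:
            logger.info("no FASTA input; charge section skipped")

        if config.structure is not None:
            structure = read_structure(config.structure)
            bridges = find_salt_bridges(structure, config.salt_bridge_cutoff)
            hbonds = find_hbonds(structure, config.hbond_criteria)
            sb_counts, bridges = classify_interdomain(bridges, config.partition)
            hb_counts, hbonds = classify_interdomain(hbonds, config.partition)
            rows = [
                {"type": "salt_bridge", "res_a": f"{b.res_a[1]}{b.res_a[0]}",
                 "res_b": f"{b.res_b[1]}{b.res_b[0]}", "atom_a": b.atom_a,
                 "atom_b": b.atom_b, "distance": round(b.distance, 3),
                 "class": b.domain_class}
                for b in bridges
            ] + [
                {"type": "hbond", "res_a": f"{h.donor_res[1]}{h.donor_res[0]}",
                 "res_b": f"{h.acceptor_res[1]}{h.acceptor_res[0]}",
                 "atom_a": h.donor_atom, "atom_b": h.acceptor_atom,
                 "distance": round(h.d_DA, 3), "class": h.domain_class}
                for h in hbonds
            ]
            sections["interactions"] = pd.DataFrame(
                rows, columns=["type", "res_a", "res_b", "atom_a", "atom_b",
                               "distance", "class"],
            )
            _write(sections["interactions"], outdir, "interactions")
            summary = {
                "total_salt_bridges": len(bridges),
                "inter_domain_salt_bridges": int(sb_counts.get("inter", 0)),
                "total_hbonds": len(hbonds),
                "inter_domain_hbonds": int(hb_counts.get("inter", 0)),
            }
            (outdir / "interaction_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )

            if config.triad is not None:
                env = triad_environment(structure, config.triad, config.site_cutoff)
                sections["site_environment"] = pd.DataFrame(
                    [{"residue": f"{n.residue[1]}{n.residue[0]}", "atom": n.atom,
                      "closest_triad_atom": n.closest_triad_atom,
                      "distance": round(n.distance, 3), "charge": n.charge_class}
                     for n in env.neighbours],
                    columns=["residue", "atom", "closest_triad_atom", "distance", "charge"],
                )
                _write(sections["site_environment"], outdir, "site_environment")
                (outdir / "site_summary.json").write_text(json.dumps({
                    "n_negative_atoms": env.n_negative_atoms,
                    "n_positive_atoms": env.n_positive_atoms,
                    "character": environment_charge_summary(env),
                }, indent=2) + "\n")

            if config.hinge is not None and config.triad is not None:
                conformers = opening_series(
                    structure, config.hinge, list(config.hinge.angles),
                    config.partition, config.triad, config.exposure_radius,
                )
                sections["hinge_metrics"] = pd.DataFrame(
                    [{"angle": c.angle,
                      "centroid_distance": round(c.metrics.centroid_distance, 3),
                      "min_interdomain_distance": round(c.metrics.min_interdomain_distance, 3),
                      "exposure_count": c.metrics.exposure_count,
                      "clashes": c.metrics.n_clashes}
                     for c in conformers],
                )
                _write(sections["hinge_metrics"], outdir, "hinge_metrics")
                if config.write_conformers:
                    for c in conformers:
                        write_structure(c.structure, outdir / f"conformer_{c.angle:g}.pdb")
        else:
            logger.info("no structure input; structural sections skipped")

        if config.ct is not None:
            eff = (config.efficiencies
                   if isinstance(config.efficiencies, EfficiencyTable)
                   else EfficiencyTable.from_csv(config.efficiencies))
            folds = fold_table(_read_ct_csv(Path(config.ct)), eff,
                               config.reference_gene, config.control_tissue)
            sections["expression"] = folds
            _write(folds, outdir, "expression")
            if config.ratio_genes is not None:
                ratios = expression_ratio_column(folds, *config.ratio_genes)
                sections["ratios"] = ratios
                _write(ratios, outdir, "ratios")
        else:
            logger.info("no Ct input; expression section skipped")

        run_warnings = [str(w.message) for w in caught]

    log = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "salt_bridge_cutoff": config.salt_bridge_cutoff,
            "hbond_criteria": config.hbond_criteria,
            "site_cutoff": config.site_cutoff,
            "exposure_radius": config.exposure_radius,
            "clash_threshold": config.clash_threshold,
        },
        "sections": sorted(sections),
        "warnings": run_warnings,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return sections
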