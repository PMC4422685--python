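"""Salt-bridge and hydrogen-bond detection with inter-domain classification.

Builds a two-domain toy structure with two designed inter-domain salt
bridges at exact distances, writes it as PDB, re-reads it, and shows that
the detectors recover exactly the designed contacts plus the regular
backbone hydrogen bonds of the helical domains.
"""

from pathlib import Path
from tempfile import mkdtemp

from apehkit import (
    ToyContact,
    ToyDesign,
    classify_interdomain,
    find_hbonds,
    find_salt_bridges,
    make_two_domain_toy,
    read_structure,
    write_structure,
)

design = ToyDesign(contacts=[ToyContact("salt_bridge", 3.2),
                             ToyContact("salt_bridge", 3.4)])
structure, partition, truth = make_two_domain_toy(design, seed=11)

pdb = Path(mkdtemp()) / "toy.pdb"
write_structure(structure, pdb)
structure = read_structure(pdb)  # full round trip through the PDB format

bridges = find_salt_bridges(structure, cutoff=4.0)
sb_counts, bridges = classify_interdomain(bridges, partition)
print(f"salt bridges found: {len(bridges)} (designed inter-domain: "
      f"{truth.inter_salt_bridges})")
for b in bridges:
    print(f"  {b.res_a[1]}{b.res_a[0]} {b.atom_a} ... "
          f"{b.res_b[1]}{b.res_b[0]} {b.atom_b}  {b.distance:.2f} A  [{b.domain_class}]")

hb_counts, _ = classify_interdomain(find_hbonds(structure), partition)
print("\nhydrogen bonds by class (helical domains contribute the intra counts):")
for cls in ("intra-N", "intra-C", "linker", "inter"):
    print(f"  {cls:8s} {hb_counts.get(cls, 0)}")
print("\na salt bridge at hydrogen-bond range counts in both tallies, so the")
print(f"inter H-bond count ({hb_counts.get('inter', 0)}) matches the designed "
      f"ground truth ({truth.inter_hbonds}).")
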