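"""Rigid hinge rotation: opening a two-domain structure about a linker bond.

The open/closed transition is emulated by rotating everything C-terminal to
one backbone bond (here N-CA of a linker residue) as a rigid body.  Starting
from a pre-closed pose, rotations of 20-80 degrees reopen the structure: the
domain centroid separation rises and the triad-occlusion count (N-terminal
domain atoms within a shell of the catalytic side chains) falls.
"""

from apehkit import (
    Conformer,
    HingeSpec,
    ToyDesign,
    TriadSpec,
    make_two_domain_toy,
    opening_metrics,
    opening_series,
    rotate_about_bond,
)

design = ToyDesign(contacts=[], gap=0.0, linker_conformation="helix")
structure, partition, _ = make_two_domain_toy(design, seed=1)
hinge = HingeSpec(residue=18, bond="N-CA")         # linker spans residues 15-24
triad = TriadSpec(ser=25, asp=27, his=29)          # catalytic site, C-ter domain

closed = rotate_about_bond(structure, hinge, -160.0).structure
m0 = opening_metrics(Conformer(closed, hinge, 0.0), partition, triad,
                     exposure_radius=18.0)
print("angle  centroid-dist  min-interdomain  occlusion  clashes")
print(f"{0.0:5.0f}  {m0.centroid_distance:13.2f}  {m0.min_interdomain_distance:15.2f}"
      f"  {m0.exposure_count:9d}  {m0.n_clashes:7d}")
for conf in opening_series(closed, hinge, [20, 40, 60, 80], partition, triad,
                           exposure_radius=18.0):
    m = conf.metrics
    print(f"{conf.angle:5.0f}  {m.centroid_distance:13.2f}"
          f"  {m.min_interdomain_distance:15.2f}  {m.exposure_count:9d}"
          f"  {m.n_clashes:7d}")
print("\ncentroid separation grows and occlusion falls monotonically: the")
print("rotation exposes the catalytic site, easing substrate access.")
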