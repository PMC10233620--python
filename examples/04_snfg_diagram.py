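"""Render an SNFG diagram with outlier highlighting.

Validates a core glycan whose 1,6-arm mannose has been twisted into an
unpopulated torsion region and whose 1,3-arm mannose sits in a 1S3
skew-boat, then writes the annotated SNFG diagram: an orange backing
behind the standout linkage, an orange backing behind the distorted ring.
"""

from pathlib import Path

from glycovalid import GlycanSpec, ResidueSpec, make_glycan, render_svg, validate_structure
from glycovalid.synthetic import make_database

db = make_database({
    "NAG-ASN": (-97.0, 178.5, 8.0, 1000),
    "NAG-1,4-NAG": (-80.0, -127.0, 8.0, 1000),
    "BMA-1,4-NAG": (-87.0, -133.0, 8.0, 1000),
    "MAN-1,3-BMA": (76.0, 121.0, 8.0, 1000),
    "MAN-1,6-BMA": (72.0, 168.0, 8.0, 1000),
}, seed=1)

structure = make_glycan(GlycanSpec(residues=[
    ResidueSpec("NAG", None, 0, phi=-97.0, psi=178.5),
    ResidueSpec("NAG", 0, 4, phi=-80.0, psi=-127.0),
    ResidueSpec("BMA", 1, 4, phi=-87.0, psi=-133.0),
    ResidueSpec("MAN", 2, 3, phi=76.0, psi=121.0, pucker=(0.55, 90.0, 210.0)),
    ResidueSpec("MAN", 2, 6, phi=-30.0, psi=60.0, omega=60.0),  # far from the cluster
]))

(report,) = validate_structure(structure, db)
svg = render_svg(report)
out = Path("snfg_example.svg")
out.write_text(svg)

print(f"global Z = {report.global_z:+.2f}, {report.n_flagged} flagged linkage(s), "
      f"{report.n_ring_issues} ring issue(s)")
print(f"orange linkage backings: {svg.count('linkage-backing-orange')}")
print(f"orange ring backings:    {svg.count('ring-backing-orange')}")
print(f"wrote {out}")

# GlcNAc is the blue square, mannoses are green circles; the 1,6 arm is
# drawn above the 1,3 arm.  Orange marks items worth inspecting; grey
# (not triggered here) marks linkage types with too little reference data.
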