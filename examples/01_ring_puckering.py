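"""Cremer-Pople puckering analysis of pyranose rings.

Builds three mannose residues -- a relaxed 4C1 chair, a 1S3 skew-boat and
one with an unphysically flat ring -- and runs the per-residue diagnostics
used for corpus curation.
"""

from glycovalid import cremer_pople, diagnose, find_ring_atoms, make_pyranose

for label, pucker in [
    ("ideal 4C1 chair", None),
    ("1S3 skew-boat", (0.55, 90.0, 210.0)),
    ("flattened ring", (0.20, 0.0, 0.0)),
]:
    residue = make_pyranose("MAN", pucker=pucker)
    params = cremer_pople([a.position for a in find_ring_atoms(residue)])
    result = diagnose(residue)
    conformer = result.conformer.code if result.conformer else "none"
    print(f"{label:16s}  Q = {params.Q:.3f} A  theta = {params.theta:6.1f}  "
          f"phi2 = {params.phi2:6.1f}  conformer = {conformer:4s}  -> {result.status}")

# Q is the total out-of-plane amplitude (0.55-0.6 A for a relaxed chair);
# theta ~ 0 is the low-energy 4C1 chair of D-pyranosides, theta ~ 90 the
# boat/skew-boat equator.  A ring that is not in its minimal-energy chair
# is reported high_energy and excluded from torsion harvesting; a ring
# with Q outside 0.4-0.8 A fails the amplitude check outright.
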