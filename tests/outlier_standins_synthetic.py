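"""Synthetic stand-ins for three published N-glycan outlier fragments.

These are NOT deposited coordinates: each structure is generated by the
package's own glycan builder with the torsion angles (and, for the
skew-boat case, the ring pucker) reported for the corresponding real
entries.  They exercise the measurement path -- bond perception, linkage
classification and phi/psi extraction -- on fragments with the same
topology and printed conformations as the real cases.
"""

from __future__ import annotations

from glycovalid import GlycanSpec, ResidueSpec, make_glycan

#: MAN-1,6-BMA linkage reported as a deposited-model outlier
#: (phi = -8.6, psi = -140.7) later corrected on re-refinement
#: (phi = 71.5, psi = 169.0).
MAN16BMA_OUTLIER = {"phi": -8.6, "psi": -140.7}
MAN16BMA_REREFINED = {"phi": 71.5, "psi": 169.0}

#: MAN-1,2-MAN linkage held in a rare conformation by electrostatics.
MAN12MAN_OUTLIER = {"phi": 82.9, "psi": -179.9}

#: MAN-1,3-BMA linkage distorted by a terminal mannose in a 1S3 skew-boat.
MAN13BMA_OUTLIER = {"phi": -3.0, "psi": 122.6}
SKEW_BOAT_PUCKER = (0.55, 90.0, 210.0)  # (Q, theta, phi2) of the 1S3 point


def man16bma_fragment(phi: float, psi: float):
    """BMA with a MAN attached 1->6 at the requested torsions (synthetic)."""
    spec = GlycanSpec(
        structure_id="man16bma-standin",
        asn_root=False,
        residues=[
            ResidueSpec("BMA", None, 0),
            ResidueSpec("MAN", 0, 6, phi=phi, psi=psi, omega=60.0),
        ],
    )
    return make_glycan(spec)


def man12man_fragment(phi: float, psi: float):
    """MAN-1,2-MAN disaccharide at the requested torsions (synthetic)."""
    spec = GlycanSpec(
        structure_id="man12man-standin",
        asn_root=False,
        residues=[
            ResidueSpec("MAN", None, 0),
            ResidueSpec("MAN", 0, 2, phi=phi, psi=psi),
        ],
    )
    return make_glycan(spec)


def man13bma_fragment(phi: float, psi: float, skew_boat: bool = True):
    """MAN-1,3-BMA disaccharide, terminal MAN in a 1S3 ring (synthetic)."""
    spec = GlycanSpec(
        structure_id="man13bma-standin",
        asn_root=False,
        residues=[
            ResidueSpec("BMA", None, 0),
            ResidueSpec("MAN", 0, 3, phi=phi, psi=psi,
                        pucker=SKEW_BOAT_PUCKER if skew_boat else None),
        ],
    )
    return make_glycan(spec)
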