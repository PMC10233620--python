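"""Dihedral geometry, per-linkage torsion extraction and circular statistics.

Glycosidic conformation is described by the torsion angles about the
glycosidic bond.  For a sugar-sugar 1->x linkage (x in 2, 3, 4)::

    phi = O5(d) - C1(d) - Ox(a) - Cx(a)
    psi = C1(d) - Ox(a) - Cx(a) - C(x-1)(a)

1->6 linkages have an extra rotatable bond and therefore a third angle::

    phi   = O5(d) - C1(d) - O6(a) - C6(a)
    psi   = C1(d) - O6(a) - C6(a) - C5(a)
    omega = O6(a) - C6(a) - C5(a) - O5(a)

For sialic acid (SIA) the anomeric centre is C2 and the ring oxygen is O6,
so C2(d)/O6(d) replace C1(d)/O5(d) in 2->6 linkages.  The protein-sugar
root linkage uses the asparagine side chain::

    phi = O5 - C1 - ND2 - CG      psi = C1 - ND2 - CG - CB

All angles follow the IUPAC sign convention (clockwise positive looking
from the second to the third atom) and are reported in (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import MONOSACCHARIDES
from .errors import UndefinedTorsionError

__all__ = [
    "TorsionRecord",
    "dihedral",
    "linkage_torsions",
    "wrap_angle",
    "circular_difference",
    "signed_circular_difference",
    "circular_mean_sd",
    "place_atom",
]

_COLLINEAR_TOL = 1e-10


def wrap_angle(x: float) -> float:
    """Map an angle in degrees to the principal range (-180, 180]."""
    y = math.fmod(x, 360.0)
    if y <= -180.0:
        y += 360.0
    elif y > 180.0:
        y -= 360.0
    return y


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Raises :class:`UndefinedTorsionError` when either bonded triple is
    collinear (the torsion plane is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL:
        raise UndefinedTorsionError("central bond p2-p3 has zero length")
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise UndefinedTorsionError("collinear atoms: torsion plane undefined")
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    x = float(np.dot(n1, n2))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given internal coordinates relative to chain A-B-C.

    Returns D with |D-C| = *bond*, angle D-C-B = *angle* degrees, and
    dihedral(D, C, B, A) = *torsion* degrees (the natural extension frame;
    standard NeRF construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def circular_difference(a: float, b: float) -> float:
    """Minimal absolute angular separation of two angles, in [0, 180]."""
    return abs(signed_circular_difference(a, b))


def signed_circular_difference(a: float, b: float) -> float:
    """Signed shortest rotation from *b* to *a*, in (-180, 180]."""
    return wrap_angle(a - b)


def circular_mean_sd(angles: Sequence[float]) -> tuple[float, float]:
    """Circular mean and standard deviation (degrees) of a sample of angles.

    The mean is the direction of the resultant vector; the SD is the
    standard ``sqrt(-2 ln R)`` mapping of the mean resultant length R.
    A zero resultant (e.g. perfectly uniform sample) leaves the mean
    undefined and raises ``ValueError``.
    """
    if len(angles) == 0:
        raise ValueError("circular mean of an empty sample is undefined")
    rad = np.radians(np.asarray(angles, dtype=float))
    s = np.mean(np.sin(rad))
    c = np.mean(np.cos(rad))
    r = math.hypot(s, c)
    if r < 1e-12:
        raise ValueError("zero resultant: circular mean undefined (uniform sample)")
    mean = wrap_angle(math.degrees(math.atan2(s, c)))
    sd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(r))))
    return mean, sd


def arithmetic_mean_sd(angles: Sequence[float]) -> tuple[float, float]:
    """Plain (linear) mean and population SD, for table comparability."""
    arr = np.asarray(angles, dtype=float)
    return float(arr.mean()), float(arr.std())


@dataclass
class TorsionRecord:
    """One phi/psi(/omega) measurement for a glycosidic linkage."""

    code: str
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float] = None
    source: tuple = field(default_factory=tuple)  # (structure id, donor (chain,seq), acceptor (chain,seq))
    resolution: Optional[float] = None
    warnings: tuple = ()

    @property
    def complete(self) -> bool:
        return self.phi is not None and self.psi is not None


def _atom_pos(residue, name: str):
    atom = residue.atoms.get(name)
    return None if atom is None else atom.position


def linkage_torsions(linkage, structure_id: str = "", resolution: Optional[float] = None) -> TorsionRecord:
    """Measure phi/psi(/omega) for one detected glycosidic linkage.

    Missing atoms yield a partial record carrying the computable angles
    plus a warning naming what was absent.
    """
    donor = linkage.donor
    acceptor = linkage.acceptor
    chem = MONOSACCHARIDES[donor.ccd_code]
    ring_o = chem.ring_oxygen          # "O5", or "O6" for sialic acid
    anomeric = chem.anomeric_carbon    # "C1", or "C2" for sialic acid

    warnings: list[str] = []
    phi = psi = omega = None

    d_o = _atom_pos(donor, ring_o)
    d_c = _atom_pos(donor, anomeric)

    if acceptor.ccd_code == "ASN":
        quad_phi = (d_o, d_c, _atom_pos(acceptor, "ND2"), _atom_pos(acceptor, "CG"))
        quad_psi = (d_c, _atom_pos(acceptor, "ND2"), _atom_pos(acceptor, "CG"),
                    _atom_pos(acceptor, "CB"))
        quad_omega = None
    else:
        x = linkage.acceptor_position
        ox = _atom_pos(acceptor, f"O{x}")
        cx = _atom_pos(acceptor, f"C{x}")
        quad_phi = (d_o, d_c, ox, cx)
        if x == 6:
            c5 = _atom_pos(acceptor, "C5")
            quad_psi = (d_c, ox, cx, c5)
            acc_ring_o = MONOSACCHARIDES[acceptor.ccd_code].ring_oxygen
            quad_omega = (ox, cx, c5, _atom_pos(acceptor, acc_ring_o))
        else:
            cprev = _atom_pos(acceptor, f"C{x - 1}")
            quad_psi = (d_c, ox, cx, cprev)
            quad_omega = None

    def measure(quad, label):
        if quad is None:
            return None
        if any(p is None for p in quad):
            warnings.append(f"missing atom for {label}")
            return None
        return dihedral(*quad)

    phi = measure(quad_phi, "phi")
    psi = measure(quad_psi, "psi")
    omega = measure(quad_omega, "omega")

    src = (
        structure_id,
        (donor.chain_id, donor.seq_num),
        (acceptor.chain_id, acceptor.seq_num),
    )
    return TorsionRecord(
        code=linkage.code, phi=phi, psi=psi, omega=omega,
        source=src, resolution=resolution, warnings=tuple(warnings),
    )
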