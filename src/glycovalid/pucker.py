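"""Cremer-Pople ring puckering and per-monosaccharide diagnostics.

A six-membered ring's out-of-plane geometry is captured by three puckering
coordinates: total amplitude Q (A) and two phase angles theta (polar,
0-180 deg) and phi2 (azimuthal, 0-360 deg) on the puckering sphere.  With
the ring cycle ordered ring-oxygen first (O5, C1, ..., C5 for
aldopyranoses), theta ~ 0 is the 4C1 chair expected for most D-pyranosides,
theta ~ 180 the 1C4 chair of L-pyranosides, and the theta ~ 90 equator
holds the boat / skew-boat (twist-boat) itinerary.  Conformers are named
by the nearest of the 38 canonical IUPAC reference points on the sphere.

The diagnostics combine three checks used for corpus curation: the
anomeric/absolute stereochemistry must match the residue's CCD code, the
puckering amplitude must be physically plausible, and the conformer must
be the minimal-energy chair for that sugar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import MONOSACCHARIDES
from .errors import GeometryError, IncompleteRingError, PlanarRingError

__all__ = [
    "PuckerParams",
    "ConformerName",
    "DiagnosticResult",
    "CANONICAL_CONFORMERS",
    "find_ring_atoms",
    "cremer_pople",
    "name_conformer",
    "check_stereochemistry",
    "diagnose",
]

#: Below this total amplitude (A) the phase angles are numerically
#: meaningless and the ring is reported as planar.
PLANARITY_FLOOR = 0.1
#: Physically plausible amplitude window for pyranose rings (A).
Q_MIN, Q_MAX = 0.4, 0.8

_THETA_H = math.degrees(math.atan(math.sqrt(6.0) / 2.0))   # half-chair band
_THETA_E = math.degrees(math.atan(math.sqrt(2.0)))          # envelope band


@dataclass(frozen=True)
class PuckerParams:
    Q: float
    theta: float      # degrees, [0, 180]
    phi2: float       # degrees, [0, 360)
    q2: float
    q3: float

    @property
    def planar(self) -> bool:
        return self.Q < PLANARITY_FLOOR


@dataclass(frozen=True)
class ConformerName:
    code: str
    family: str       # chair | boat | skew-boat | half-chair | envelope


@dataclass(frozen=True)
class _Canonical:
    theta: float
    phi2: float
    above: tuple      # ring-position indices displaced above the plane
    below: tuple
    letter: str       # C, B, S, H, E
    family: str


def _wheel() -> list[_Canonical]:
    pts = [
        _Canonical(0.0, 0.0, (4,), (1,), "C", "chair"),
        _Canonical(180.0, 0.0, (1,), (4,), "C", "chair"),
    ]
    # theta = 90 equator: boats at even multiples of 30 deg, skew-boats at odd
    equator = [
        (0, (0, 3), ()), (30, (3,), (1,)), (60, (), (1, 4)),
        (90, (5,), (1,)), (120, (2, 5), ()), (150, (2,), (0,)),
        (180, (), (0, 3)), (210, (1,), (3,)), (240, (1, 4), ()),
        (270, (1,), (5,)), (300, (), (2, 5)), (330, (0,), (2,)),
    ]
    for phi2, above, below in equator:
        if len(above) + len(below) == 2 and (len(above) == 2 or len(below) == 2):
            pts.append(_Canonical(90.0, float(phi2), above, below, "B", "boat"))
        else:
            pts.append(_Canonical(90.0, float(phi2), above, below, "S", "skew-boat"))
    north_h = [(30, 0, 1), (90, 2, 1), (150, 2, 3), (210, 4, 3), (270, 4, 5), (330, 0, 5)]
    south_h = [(30, 3, 4), (90, 5, 4), (150, 5, 0), (210, 1, 0), (270, 1, 2), (330, 3, 2)]
    for phi2, up, dn in north_h:
        pts.append(_Canonical(_THETA_H, float(phi2), (up,), (dn,), "H", "half-chair"))
    for phi2, up, dn in south_h:
        pts.append(_Canonical(180.0 - _THETA_H, float(phi2), (up,), (dn,), "H", "half-chair"))
    north_e = [(0, (0,), ()), (60, (), (1,)), (120, (2,), ()),
               (180, (), (3,)), (240, (4,), ()), (300, (), (5,))]
    south_e = [(0, (3,), ()), (60, (), (4,)), (120, (5,), ()),
               (180, (), (0,)), (240, (1,), ()), (300, (), (2,))]
    for phi2, above, below in north_e:
        pts.append(_Canonical(_THETA_E, float(phi2), above, below, "E", "envelope"))
    for phi2, above, below in south_e:
        pts.append(_Canonical(180.0 - _THETA_E, float(phi2), above, below, "E", "envelope"))
    return pts


CANONICAL_CONFORMERS: tuple = tuple(_wheel())

_DEFAULT_LABELS = ("O", "1", "2", "3", "4", "5")
_FAMILY_RANK = {"chair": 0, "boat": 1, "skew-boat": 2, "half-chair": 3, "envelope": 4}


def _label_sort_key(label: str):
    return (label == "O", label)  # digits ascending, ring oxygen last


def _format_name(c: _Canonical, labels: Sequence[str]) -> str:
    above = sorted((labels[i] for i in c.above), key=_label_sort_key)
    below = sorted((labels[i] for i in c.below), key=_label_sort_key)
    return "".join([",".join(above), c.letter, ",".join(below)])


def ring_labels(ring_atom_names: Sequence[str]) -> tuple:
    """Position labels for conformer naming: 'O5' -> 'O', 'C1' -> '1'."""
    return tuple("O" if n.startswith("O") else n[1:] for n in ring_atom_names)


def find_ring_atoms(residue):
    """Ordered ring cycle of a supported pyranoside (ring oxygen first)."""
    chem = MONOSACCHARIDES[residue.ccd_code]
    atoms = []
    missing = []
    for name in chem.ring_atoms:
        atom = residue.atoms.get(name)
        if atom is None:
            missing.append(name)
        else:
            atoms.append(atom)
    if missing:
        raise IncompleteRingError(missing, residue)
    return atoms


def cremer_pople(ring_positions) -> PuckerParams:
    """Puckering parameters from six ring positions in cycle order.

    Implements the original mean-plane construction: positions are
    centred, the plane normal comes from the two Fourier displacement
    vectors R' and R'', and the out-of-plane displacements z_j are
    decomposed into the (q2, phi2) and q3 amplitudes.
    """
    r = np.asarray([np.asarray(p, dtype=float) for p in ring_positions])
    if r.shape != (6, 3):
        raise GeometryError("exactly six 3-D positions required")
    r = r - r.mean(axis=0)
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate ring geometry: no mean plane")
    n /= norm
    z = r @ n
    q2c = math.sqrt(1.0 / 3.0) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2s = -math.sqrt(1.0 / 3.0) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q3 = math.sqrt(1.0 / 6.0) * float((z * ((-1.0) ** j)).sum())
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)
    theta = math.degrees(math.atan2(q2, q3))
    phi2 = math.degrees(math.atan2(q2s, q2c)) % 360.0 if q2 > 1e-12 else 0.0
    return PuckerParams(Q=Q, theta=theta, phi2=phi2, q2=q2, q3=q3)


def name_conformer(p: PuckerParams, labels: Sequence[str] = _DEFAULT_LABELS) -> ConformerName:
    """Nearest canonical conformer on the puckering sphere.

    Assignment is by great-circle distance to the 38 reference points;
    exact ties resolve toward the chair poles.  Planar rings (Q below the
    floor) have no conformer and raise :class:`PlanarRingError`.
    """
    if p.planar:
        raise PlanarRingError(f"Q = {p.Q:.3f} A is below the planarity floor")
    t = math.radians(p.theta)
    f = math.radians(p.phi2)
    best = None
    for c in CANONICAL_CONFORMERS:
        ct = math.radians(c.theta)
        cf = math.radians(c.phi2)
        cosd = math.cos(t) * math.cos(ct) + math.sin(t) * math.sin(ct) * math.cos(f - cf)
        d = math.acos(max(-1.0, min(1.0, cosd)))
        key = (round(d, 9), _FAMILY_RANK[c.family], c.theta, c.phi2)
        if best is None or key < best[0]:
            best = (key, c)
    c = best[1]
    return ConformerName(code=_format_name(c, labels), family=c.family)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _chirality_sign(center, a, b, c) -> int:
    vol = float(np.dot(np.cross(_unit(a - center), _unit(b - center)), _unit(c - center)))
    return 1 if vol > 0 else -1


def check_stereochemistry(residue, link_oxygen=None) -> str:
    """Compare modelled stereochemistry against the residue's CCD code.

    Returns ``"ok"``, ``"anomer_mismatch"``, ``"dl_mismatch"`` or
    ``"indeterminate"``.  The anomeric configuration is read from the
    signed volume of the substituents at the anomeric carbon; when the
    exocyclic anomeric oxygen has been replaced by a glycosidic bond, its
    position may be supplied via *link_oxygen*.  The absolute (D/L)
    configuration is checked at C5 via the C6 substituent.
    """
    chem = MONOSACCHARIDES[residue.ccd_code]
    ring = {name: residue.atoms.get(name) for name in chem.ring_atoms}
    if any(a is None for a in ring.values()):
        return "indeterminate"
    anomeric = ring[chem.anomeric_carbon].position
    ring_o = ring[chem.ring_oxygen].position
    next_c = ring[chem.ring_atoms[2]].position  # ring carbon after the anomeric one

    exo = residue.atoms.get(chem.anomeric_oxygen)
    exo_pos = exo.position if exo is not None else link_oxygen
    if exo_pos is None:
        return "indeterminate"

    # D/L first: a full mirror image flips both centres and is reported as
    # an absolute-configuration error rather than an anomer error.
    if chem.config_sign is not None:
        c5 = residue.atoms.get("C5")
        c4 = residue.atoms.get("C4")
        c6 = residue.atoms.get("C6")
        o5 = residue.atoms.get(chem.ring_oxygen)
        if all(a is not None for a in (c5, c4, c6, o5)):
            sign = _chirality_sign(c5.position, o5.position, c4.position, c6.position)
            if sign != chem.config_sign:
                return "dl_mismatch"

    if chem.anomeric_sign is not None:
        sign = _chirality_sign(anomeric, ring_o, next_c, exo_pos)
        if sign != chem.anomeric_sign:
            return "anomer_mismatch"
    return "ok"


@dataclass
class DiagnosticResult:
    """Per-monosaccharide curation verdict."""

    status: str                       # correct | high_energy | geometry_or_nomenclature_error
    reasons: list = field(default_factory=list)
    pucker: Optional[PuckerParams] = None
    conformer: Optional[ConformerName] = None
    stereo: Optional[str] = None

    @property
    def correct(self) -> bool:
        return self.status == "correct"


def diagnose(residue, link_oxygen=None, q_min: float = Q_MIN, q_max: float = Q_MAX) -> DiagnosticResult:
    """Run the full curation diagnostics on one pyranoside residue.

    ``correct`` requires: stereochemistry consistent with the CCD code, a
    puckering amplitude inside the physical window, and the ring in its
    minimal-energy chair.  A residue failing only the conformer check is
    ``high_energy``; any other failure is a geometry/nomenclature error.
    """
    reasons: list[str] = []
    try:
        ring = find_ring_atoms(residue)
    except IncompleteRingError as exc:
        return DiagnosticResult(status="geometry_or_nomenclature_error", reasons=[str(exc)])
    try:
        params = cremer_pople([a.position for a in ring])
    except GeometryError as exc:
        return DiagnosticResult(status="geometry_or_nomenclature_error", reasons=[str(exc)])

    chem = MONOSACCHARIDES[residue.ccd_code]
    stereo = check_stereochemistry(residue, link_oxygen=link_oxygen)
    if stereo in ("anomer_mismatch", "dl_mismatch"):
        reasons.append(f"stereochemistry: {stereo}")
    if not (q_min <= params.Q <= q_max):
        reasons.append(f"unphysical puckering amplitude Q = {params.Q:.3f} A")

    conformer = None
    conformer_ok = False
    if params.planar:
        reasons.append("planar ring: no conformer")
    else:
        conformer = name_conformer(params, labels=ring_labels(chem.ring_atoms))
        conformer_ok = conformer.code == chem.minimal_conformer
        if not conformer_ok:
            hint = f"non-minimal ring conformation {conformer.code} (expected {chem.minimal_conformer})"
            if not reasons:
                return DiagnosticResult(
                    status="high_energy", reasons=[hint],
                    pucker=params, conformer=conformer, stereo=stereo,
                )
            reasons.append(hint)

    status = "correct" if not reasons else "geometry_or_nomenclature_error"
    return DiagnosticResult(status=status, reasons=reasons, pucker=params,
                            conformer=conformer, stereo=stereo)
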