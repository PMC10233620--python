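"""Synthetic structures with known ground truth.

Every generator here is the documented inverse of a measurement operation:

* :func:`make_ring` realises exact Cremer-Pople coordinates (Q, theta,
  phi2), so ``cremer_pople(make_ring(...))`` is a round trip;
* :func:`make_glycan` positions full heavy-atom sugar residues so each
  linkage's phi/psi(/omega) equals a requested value, so
  ``linkage_torsions(detect_linkages(...))`` is a round trip;
* :func:`make_database` samples wrapped-normal torsion clusters into a
  binned database with a known generating mean.

Generated residues carry the ring, the exocyclic oxygens and enough
substituents for the stereochemistry and torsion checks; full CCD atom
inventories (and steric plausibility between residues) are not attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import MONOSACCHARIDES
from .database import TorsionDatabase, build_database
from .errors import SpecError
from .structures import AtomRecord, Residue, Structure
from .torsions import TorsionRecord, dihedral, place_atom, wrap_angle

__all__ = ["ResidueSpec", "GlycanSpec", "make_ring", "make_pyranose", "make_asn",
           "make_glycan", "make_database", "make_records", "mirror_structure"]

_TETRA_HALF = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356...: half tetrahedral
DEFAULT_Q = 0.55


def make_ring(Q: float, theta: float, phi2: float, bond_length: float = 1.52) -> np.ndarray:
    """Six ring positions realising exact puckering coordinates.

    The planar projection is a regular hexagon (side = *bond_length*)
    traversed clockwise seen from +z, so the mean-plane normal of the
    puckering analysis points along +z; out-of-plane displacements are the
    inverse Cremer-Pople Fourier sums for (Q, theta, phi2).
    """
    if not 0.0 <= Q <= 1.0:
        raise ValueError("Q must be in [0, 1] A for a pyranose ring")
    q2 = Q * math.sin(math.radians(theta))
    q3 = Q * math.cos(math.radians(theta))
    f = math.radians(phi2)
    pts = np.zeros((6, 3))
    for j in range(6):
        beta = -2.0 * math.pi * j / 6.0
        z = (
            math.sqrt(1.0 / 3.0) * q2 * math.cos(f + 4.0 * math.pi * j / 6.0)
            + math.sqrt(1.0 / 6.0) * q3 * ((-1.0) ** j)
        )
        pts[j] = (bond_length * math.cos(beta), bond_length * math.sin(beta), z)
    return pts


def _mean_plane_normal(ring: np.ndarray) -> np.ndarray:
    r = ring - ring.mean(axis=0)
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    return n / np.linalg.norm(n)


def _substituent_directions(ring: np.ndarray, idx: int):
    """The two free tetrahedral directions at ring position *idx*."""
    x = ring[idx]
    prev = ring[(idx - 1) % 6]
    nxt = ring[(idx + 1) % 6]
    a = (prev - x) / np.linalg.norm(prev - x)
    b = (nxt - x) / np.linalg.norm(nxt - x)
    u1 = -(a + b)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(a, b)
    u2 /= np.linalg.norm(u2)
    c, s = math.cos(math.radians(_TETRA_HALF)), math.sin(math.radians(_TETRA_HALF))
    return c * u1 + s * u2, c * u1 - s * u2


_BOND_BY_ELEMENT = {"O": 1.41, "N": 1.45, "C": 1.52}


def make_pyranose(code: str, pucker: Optional[tuple] = None,
                  chain_id: str = "A", seq_num: int = 1) -> Residue:
    """One full-heavy-atom monosaccharide residue in a local frame.

    Ring positions come from :func:`make_ring` (default: the sugar's
    minimal-energy chair at Q = 0.55 A); substituents are placed on the
    axial/equatorial tetrahedral slots recorded for the CCD code, which
    fixes the correct anomeric and absolute stereochemistry.
    """
    chem = MONOSACCHARIDES[code]
    if pucker is None:
        pucker = (DEFAULT_Q, chem.chair_theta, 0.0)
    ring = make_ring(*pucker)
    residue = Residue(ccd_code=code, chain_id=chain_id, seq_num=seq_num)
    for name, pos in zip(chem.ring_atoms, ring):
        residue.add_atom(AtomRecord(name=name, element=name[0], position=pos))

    # The ax/eq assignment of the dictionary refers to the sugar's
    # canonical chair.  A distorted ring must keep each stereocentre's
    # configuration, so on the target ring we pick the tetrahedral slot
    # whose local chirality sign matches the canonical-chair placement.
    canon = make_ring(DEFAULT_Q, chem.chair_theta, 0.0)
    canon_normal = _mean_plane_normal(canon)
    ring_index = {name: i for i, name in enumerate(chem.ring_atoms)}

    def _slot_sign(ring_pts, idx, direction) -> float:
        prev = ring_pts[(idx - 1) % 6] - ring_pts[idx]
        nxt = ring_pts[(idx + 1) % 6] - ring_pts[idx]
        return float(np.dot(np.cross(prev, nxt), direction))

    for name, parent, mode in chem.ring_substituents:
        idx = ring_index[parent]
        c1, c2 = _substituent_directions(canon, idx)
        axial, equatorial = (c1, c2) if abs(c1 @ canon_normal) >= abs(c2 @ canon_normal) else (c2, c1)
        ref_sign = _slot_sign(canon, idx, axial if mode == "ax" else equatorial)
        d1, d2 = _substituent_directions(ring, idx)
        direction = d1 if _slot_sign(ring, idx, d1) * ref_sign > 0 else d2
        bond = _BOND_BY_ELEMENT.get(name[0], 1.5)
        pos = ring[idx] + bond * direction
        residue.add_atom(AtomRecord(name=name, element=name[0], position=pos))

    for name, (a, b, c), bond, angle, torsion in chem.chain_atoms:
        pos = place_atom(
            residue.atoms[a].position, residue.atoms[b].position,
            residue.atoms[c].position, bond, angle, torsion,
        )
        residue.add_atom(AtomRecord(name=name, element=name[0], position=pos))
    return residue


def make_asn(chain_id: str = "A", seq_num: int = 1) -> Residue:
    """An asparagine residue with a full side chain, in a local frame."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.46, 0.0, 0.0])
    c = ca + 1.52 * np.array([math.cos(math.radians(69.0)), math.sin(math.radians(69.0)), 0.0])
    o = place_atom(n, ca, c, 1.23, 121.0, 0.0)
    cb = place_atom(c, n, ca, 1.53, 110.5, 122.0)
    cg = place_atom(n, ca, cb, 1.52, 113.0, -60.0)
    nd2 = place_atom(ca, cb, cg, 1.33, 116.5, -58.0)
    od1 = place_atom(ca, cb, cg, 1.23, 120.9, 122.0)
    residue = Residue(ccd_code="ASN", chain_id=chain_id, seq_num=seq_num)
    for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", o),
                      ("CB", cb), ("CG", cg), ("ND2", nd2), ("OD1", od1)):
        residue.add_atom(AtomRecord(name=name, element=name[0], position=pos))
    return residue


@dataclass
class ResidueSpec:
    """One sugar of a synthetic glycan.

    ``parent`` indexes an earlier entry of the spec (None attaches to the
    asparagine root, or places the sugar free-standing when the spec has
    no root).  ``acceptor_pos`` is x of the 1->x linkage nomenclature
    (ignored for the root attachment).  ``omega`` is honoured only for
    1->6 / 2->6 linkages; ``pucker`` is a (Q, theta, phi2) triple.
    """

    ccd: str
    parent: Optional[int] = None
    acceptor_pos: int = 0
    phi: float = -80.0
    psi: float = -130.0
    omega: Optional[float] = None
    pucker: Optional[tuple] = None


@dataclass
class GlycanSpec:
    residues: list
    asn_root: bool = True
    chain_id: str = "A"
    structure_id: str = "synthetic"
    resolution: Optional[float] = None

    @classmethod
    def from_dict(cls, doc: dict) -> "GlycanSpec":
        residues = [ResidueSpec(**r) for r in doc.get("residues", [])]
        meta = {k: v for k, v in doc.items() if k != "residues"}
        return cls(residues=residues, **meta)

    def to_dict(self) -> dict:
        return {
            "asn_root": self.asn_root,
            "chain_id": self.chain_id,
            "structure_id": self.structure_id,
            "resolution": self.resolution,
            "residues": [vars(r) for r in self.residues],
        }


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _align_rotation(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto unit vector w."""
    v = v / np.linalg.norm(v)
    w = w / np.linalg.norm(w)
    c = float(np.clip(v @ w, -1.0, 1.0))
    axis = np.cross(v, w)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular
        perp = np.cross(v, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(v, np.array([0.0, 1.0, 0.0]))
        return _rotation_about_axis(perp, 180.0)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + k + k @ k * ((1.0 - c) / (s * s))


def _transform_residue(residue: Residue, rot: np.ndarray, origin: np.ndarray, dest: np.ndarray):
    for atom in residue.atoms.values():
        atom.position = rot @ (atom.position - origin) + dest


def make_glycan(spec: GlycanSpec) -> Structure:
    """Build a Structure realising the spec's topology and torsions exactly.

    Each sugar is generated in a local frame, its anomeric carbon is placed
    by internal coordinates so psi is exact, and the residue is then spun
    about the glycosidic bond until phi matches.  Steric clashes are not
    relieved; the construction is purely geometric.
    """
    structure = Structure(id=spec.structure_id, resolution=spec.resolution)
    seq = 1
    root = None
    if spec.asn_root:
        root = make_asn(chain_id=spec.chain_id, seq_num=seq)
        structure.residues.append(root)
        seq += 1

    built: list[Residue] = []
    offset = 0.0
    for i, rs in enumerate(spec.residues):
        if rs.parent is not None and not (0 <= rs.parent < i):
            raise SpecError(f"residue {i}: parent index {rs.parent} is not an earlier residue")
        donor = make_pyranose(rs.ccd, pucker=rs.pucker, chain_id=spec.chain_id, seq_num=seq)
        seq += 1
        chem = MONOSACCHARIDES[rs.ccd]

        if rs.parent is None and root is None:
            # free-standing sugar: keep residues spatially separated
            for atom in donor.atoms.values():
                atom.position = atom.position + np.array([offset, 0.0, 0.0])
            offset += 20.0
            built.append(donor)
            structure.residues.append(donor)
            continue

        if rs.parent is None:
            acceptor = root
            link_atom = "ND2"
            psi_frame = ("CB", "CG", "ND2")
            phi_ref = "CG"
            bond = 1.44
            angle = 124.0
        else:
            acceptor = built[rs.parent]
            x = rs.acceptor_pos
            if x == 6:
                ring_o = MONOSACCHARIDES[acceptor.ccd_code].ring_oxygen
                omega = 60.0 if rs.omega is None else rs.omega
                acceptor.atoms["O6"].position = place_atom(
                    acceptor.atoms[ring_o].position,
                    acceptor.atoms["C5"].position,
                    acceptor.atoms["C6"].position,
                    1.43, 109.5, omega,
                )
                link_atom = "O6"
                psi_frame = ("C5", "C6", "O6")
                phi_ref = "C6"
            elif x in (2, 3, 4):
                link_atom = f"O{x}"
                psi_frame = (f"C{x - 1}", f"C{x}", f"O{x}")
                phi_ref = f"C{x}"
            else:
                raise SpecError(f"residue {i}: unsupported acceptor position {x}")
            if link_atom not in acceptor.atoms:
                raise SpecError(f"residue {i}: acceptor {acceptor.ccd_code} has no atom {link_atom}")
            bond = 1.41
            angle = 117.0

        a, b, c = (acceptor.atoms[n].position for n in psi_frame)
        c1_target = place_atom(a, b, c, bond, angle, rs.psi)
        link_pos = acceptor.atoms[link_atom].position

        c1_local = donor.atoms[chem.anomeric_carbon].position.copy()
        o1_local = donor.atoms[chem.anomeric_oxygen].position.copy()
        rot = _align_rotation(o1_local - c1_local, link_pos - c1_target)
        _transform_residue(donor, rot, c1_local, c1_target)
        del donor.atoms[chem.anomeric_oxygen]  # replaced by the glycosidic bond

        ring_o_pos = donor.atoms[chem.ring_oxygen].position
        phi_ref_pos = acceptor.atoms[phi_ref].position
        current = dihedral(ring_o_pos, c1_target, link_pos, phi_ref_pos)
        delta = wrap_angle(rs.phi - current)
        axis = link_pos - c1_target
        spin = _rotation_about_axis(axis, delta)
        _transform_residue(donor, spin, c1_target, c1_target)
        check = dihedral(donor.atoms[chem.ring_oxygen].position, c1_target,
                         link_pos, phi_ref_pos)
        if abs(wrap_angle(check - rs.phi)) > 1e-6:
            spin = _rotation_about_axis(axis, -2.0 * delta)
            _transform_residue(donor, spin, c1_target, c1_target)

        built.append(donor)
        structure.residues.append(donor)
    return structure


def mirror_structure(structure: Structure) -> Structure:
    """Mirror image (x -> -x): flips every stereocentre, for D/L tests."""
    out = Structure(id=structure.id + "-mirror", resolution=structure.resolution)
    for res in structure.residues:
        new = Residue(ccd_code=res.ccd_code, chain_id=res.chain_id, seq_num=res.seq_num)
        for atom in res.atoms.values():
            pos = atom.position.copy()
            pos[0] = -pos[0]
            new.add_atom(AtomRecord(name=atom.name, element=atom.element, position=pos,
                                    occupancy=atom.occupancy, altloc=atom.altloc))
        out.residues.append(new)
    return out


def make_records(clusters: dict, seed: int = 0,
                 resolution: Optional[float] = None) -> list:
    """Sample wrapped-normal torsion records per linkage code.

    ``clusters`` maps code -> (mean_phi, mean_psi, sigma, n).
    """
    rng = np.random.default_rng(seed)
    records = []
    for code in sorted(clusters):
        mean_phi, mean_psi, sigma, n = clusters[code]
        if sigma <= 0 or n <= 0:
            raise ValueError("cluster sigma and n must be positive")
        phis = rng.normal(mean_phi, sigma, size=n)
        psis = rng.normal(mean_psi, sigma, size=n)
        for phi, psi in zip(phis, psis):
            records.append(
                TorsionRecord(code=code, phi=wrap_angle(phi), psi=wrap_angle(psi),
                              resolution=resolution)
            )
    return records


def make_database(clusters: dict, seed: int = 0, min_obs: int = 50) -> TorsionDatabase:
    """Binned database from wrapped-normal clusters; deterministic per seed."""
    return build_database(make_records(clusters, seed=seed), min_obs=min_obs)
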