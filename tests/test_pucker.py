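"""Cremer-Pople puckering, conformer naming and ring diagnostics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from glycovalid import (
    check_stereochemistry,
    cremer_pople,
    diagnose,
    find_ring_atoms,
    make_pyranose,
    make_ring,
    name_conformer,
)
from glycovalid.errors import IncompleteRingError, PlanarRingError
from glycovalid.pucker import CANONICAL_CONFORMERS, _format_name, ring_labels
from glycovalid.synthetic import mirror_structure
from glycovalid.structures import Structure


def cp_brute_force(points):
    """Independent implementation of the 1975 puckering formulas.

    Plain-python re-derivation (loops, math module) used as the oracle
    for the vectorised implementation.
    """
    n = 6
    cx = [sum(p[k] for p in points) / n for k in range(3)]
    centred = [[p[k] - cx[k] for k in range(3)] for p in points]

    def scaled_sum(trig):
        out = [0.0, 0.0, 0.0]
        for j, p in enumerate(centred):
            w = trig(2.0 * math.pi * j / n)
            for k in range(3):
                out[k] += p[k] * w
        return out

    rp = scaled_sum(math.sin)
    rpp = scaled_sum(math.cos)
    normal = [
        rp[1] * rpp[2] - rp[2] * rpp[1],
        rp[2] * rpp[0] - rp[0] * rpp[2],
        rp[0] * rpp[1] - rp[1] * rpp[0],
    ]
    norm = math.sqrt(sum(c * c for c in normal))
    normal = [c / norm for c in normal]
    z = [sum(p[k] * normal[k] for k in range(3)) for p in centred]

    q2cos = math.sqrt(1.0 / 3.0) * sum(z[j] * math.cos(4 * math.pi * j / n) for j in range(n))
    q2sin = -math.sqrt(1.0 / 3.0) * sum(z[j] * math.sin(4 * math.pi * j / n) for j in range(n))
    q3 = math.sqrt(1.0 / 6.0) * sum(z[j] * (-1.0) ** j for j in range(n))
    q2 = math.hypot(q2cos, q2sin)
    Q = math.hypot(q2, q3)
    theta = math.degrees(math.atan2(q2, q3))
    phi2 = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    return Q, theta, phi2


class TestCremerPople:
    def test_planar_hexagon_has_zero_amplitude(self):
        ring = make_ring(0.0, 0.0, 0.0)
        p = cremer_pople(ring)
        assert p.Q == pytest.approx(0.0, abs=1e-12)
        assert p.planar

    def test_alternating_displacement_chair_closed_form(self):
        # z_j = (-1)^j * z0 is a pure q3 deformation: Q = sqrt(6) z0, theta = 0
        z0 = 0.25
        ring = []
        for j in range(6):
            beta = -2.0 * math.pi * j / 6.0
            ring.append((1.5 * math.cos(beta), 1.5 * math.sin(beta), z0 * (-1.0) ** j))
        p = cremer_pople(ring)
        assert p.Q == pytest.approx(math.sqrt(6) * z0, abs=1e-9)
        assert p.q2 == pytest.approx(0.0, abs=1e-9)
        assert p.theta == pytest.approx(0.0, abs=1e-9)
        bf = cp_brute_force(ring)
        assert bf[0] == pytest.approx(p.Q, abs=1e-12)
        assert bf[1] == pytest.approx(p.theta, abs=1e-9)

    def test_matches_brute_force_oracle_on_random_rings(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ring = make_ring(rng.uniform(0.2, 0.8), rng.uniform(1, 179), rng.uniform(0, 360))
            ring = ring + rng.normal(0, 0.03, size=ring.shape)  # break perfect symmetry
            p = cremer_pople(ring)
            Q, theta, phi2 = cp_brute_force([tuple(r) for r in ring])
            assert p.Q == pytest.approx(Q, abs=1e-10)
            assert p.theta == pytest.approx(theta, abs=1e-8)
            assert abs((p.phi2 - phi2 + 180) % 360 - 180) < 1e-8

    def test_round_trip_recovers_requested_coordinates(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            Q = rng.uniform(0.05, 0.9)
            theta = rng.uniform(0.5, 179.5)
            phi2 = rng.uniform(0.0, 360.0)
            p = cremer_pople(make_ring(Q, theta, phi2))
            assert p.Q == pytest.approx(Q, abs=1e-6)
            assert p.theta == pytest.approx(theta, abs=1e-6)
            assert abs((p.phi2 - phi2 + 180) % 360 - 180) < 1e-6

    def test_amplitude_invariant_under_rototranslation(self):
        rng = np.random.default_rng(3)
        ring = make_ring(0.55, 35.0, 140.0)
        ref = cremer_pople(ring)
        for _ in range(20):
            # random rotation via QR of a Gaussian matrix
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = ring @ q.T + rng.normal(0, 50, size=3)
            p = cremer_pople(moved)
            assert p.Q == pytest.approx(ref.Q, abs=1e-9)
            assert p.theta == pytest.approx(ref.theta, abs=1e-6)

    def test_cyclic_reorigin_shifts_phase_predictably(self):
        # advancing the ring origin by one atom adds 120 deg to phi2 and
        # mirrors theta through the equator
        ring = make_ring(0.6, 70.0, 25.0)
        ref = cremer_pople(ring)
        rolled = np.roll(ring, -1, axis=0)
        p = cremer_pople(rolled)
        assert p.Q == pytest.approx(ref.Q, abs=1e-9)
        assert p.theta == pytest.approx(180.0 - ref.theta, abs=1e-6)
        assert abs((p.phi2 - (ref.phi2 + 120.0) + 180) % 360 - 180) < 1e-6
        bf = cp_brute_force([tuple(r) for r in rolled])
        assert p.theta == pytest.approx(bf[1], abs=1e-8)


class TestConformerNaming:
    def test_chair_poles(self):
        assert name_conformer(cremer_pople(make_ring(0.55, 0.5, 123.0))).code == "4C1"
        assert name_conformer(cremer_pople(make_ring(0.55, 179.2, 10.0))).code == "1C4"

    @pytest.mark.parametrize(
        "phi2,code",
        [(30, "3S1"), (90, "5S1"), (150, "2SO"), (210, "1S3"), (270, "1S5"), (330, "OS2")],
    )
    def test_equatorial_skew_boats(self, phi2, code):
        name = name_conformer(cremer_pople(make_ring(0.55, 90.0, phi2)))
        assert name.code == code
        assert name.family == "skew-boat"

    def test_all_canonical_points_reproduce_their_names(self):
        labels = ("O", "1", "2", "3", "4", "5")
        assert len(CANONICAL_CONFORMERS) == 38
        for canon in CANONICAL_CONFORMERS:
            p = cremer_pople(make_ring(0.55, canon.theta, canon.phi2))
            assert name_conformer(p).code == _format_name(canon, labels)

    def test_sialic_acid_labels_give_its_chair_name(self):
        labels = ring_labels(("O6", "C2", "C3", "C4", "C5", "C6"))
        p = cremer_pople(make_ring(0.55, 180.0, 0.0))
        assert name_conformer(p, labels=labels).code == "2C5"

    def test_planar_ring_has_no_conformer(self):
        with pytest.raises(PlanarRingError):
            name_conformer(cremer_pople(make_ring(0.05, 90.0, 0.0)))


class TestRingAtoms:
    def test_complete_nag_ring_order(self):
        residue = make_pyranose("NAG")
        assert [a.name for a in find_ring_atoms(residue)] == ["O5", "C1", "C2", "C3", "C4", "C5"]

    def test_missing_atom_is_named(self):
        residue = make_pyranose("NAG")
        del residue.atoms["C4"]
        with pytest.raises(IncompleteRingError, match="C4"):
            find_ring_atoms(residue)

    def test_sialic_acid_ring_order(self):
        residue = make_pyranose("SIA")
        assert [a.name for a in find_ring_atoms(residue)] == ["O6", "C2", "C3", "C4", "C5", "C6"]


class TestStereochemistry:
    def test_ideal_sugars_pass(self):
        for code in ("NAG", "BMA", "MAN", "GAL", "FUC", "SIA"):
            assert check_stereochemistry(make_pyranose(code)) == "ok"

    def test_alpha_coordinates_labelled_beta_mismatch(self):
        residue = make_pyranose("MAN")
        residue.ccd_code = "BMA"  # same geometry, wrong anomer code
        assert check_stereochemistry(residue) == "anomer_mismatch"

    def test_mirror_image_is_dl_mismatch(self):
        structure = Structure(id="m", residues=[make_pyranose("MAN")])
        mirrored = mirror_structure(structure).residues[0]
        assert check_stereochemistry(mirrored) == "dl_mismatch"

    def test_missing_anomeric_substituent_is_indeterminate(self):
        residue = make_pyranose("MAN")
        del residue.atoms["O1"]
        assert check_stereochemistry(residue) == "indeterminate"


class TestDiagnose:
    def test_ideal_chairs_are_correct(self):
        for code in ("NAG", "MAN", "FUC"):
            result = diagnose(make_pyranose(code))
            assert result.status == "correct"
            assert result.reasons == []

    def test_skew_boat_is_high_energy(self):
        residue = make_pyranose("MAN", pucker=(0.55, 90.0, 210.0))
        result = diagnose(residue)
        assert result.status == "high_energy"
        assert result.conformer.code == "1S3"

    def test_wrong_anomer_label_is_nomenclature_error(self):
        residue = make_pyranose("MAN")
        residue.ccd_code = "BMA"
        assert diagnose(residue).status == "geometry_or_nomenclature_error"

    def test_unphysical_amplitude_is_flagged(self):
        residue = make_pyranose("MAN", pucker=(0.95, 0.0, 0.0))
        result = diagnose(residue)
        assert result.status == "geometry_or_nomenclature_error"
        assert any("amplitude" in r for r in result.reasons)

    def test_incomplete_ring_reports_reason(self):
        residue = make_pyranose("NAG")
        del residue.atoms["C3"]
        result = diagnose(residue)
        assert result.status == "geometry_or_nomenclature_error"
        assert any("C3" in r for r in result.reasons)
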