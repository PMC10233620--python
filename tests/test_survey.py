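"""Curation filters, corpus harvesting, summary tables and Welch tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from glycovalid import (
    CurationPolicy,
    GlycanSpec,
    ResidueSpec,
    RsccTable,
    TorsionRecord,
    compare_corpora,
    curate,
    harvest_corpus,
    make_glycan,
    resolution_binned_table,
    welch_t_test,
    write_structure,
)
from glycovalid.errors import InsufficientSampleError
from glycovalid.pucker import DiagnosticResult
from glycovalid.synthetic import make_records
from glycovalid.torsions import circular_difference


def rec(code, phi, psi, sid="toy", donor=("A", 2), acceptor=("A", 3), resolution=None):
    return TorsionRecord(code=code, phi=phi, psi=psi,
                         source=(sid, donor, acceptor), resolution=resolution)


def diag(status="correct"):
    return DiagnosticResult(status=status, reasons=[] if status == "correct" else ["x"])


class TestCurate:
    def make_toy(self):
        """Five records: two RSCC failures, one high-energy ring, two clean."""
        records = [
            rec("NAG-1,4-NAG", -80, -130, donor=("A", 2), acceptor=("A", 3)),   # clean
            rec("BMA-1,4-NAG", -85, -133, donor=("A", 4), acceptor=("A", 2)),   # clean
            rec("MAN-1,3-BMA", 76, 121, donor=("A", 5), acceptor=("A", 4)),     # donor rscc 0.75
            rec("MAN-1,6-BMA", 72, 168, donor=("A", 6), acceptor=("A", 4)),     # donor rscc 0.75
            rec("MAN-1,2-MAN", 78, 132, donor=("A", 7), acceptor=("A", 5)),     # high-energy ring
        ]
        rscc = RsccTable()
        for seq in (2, 3, 4):
            rscc.set("toy", "A", seq, 0.95)
        rscc.set("toy", "A", 5, 0.95)
        rscc.set("toy", "A", 6, 0.75)
        rscc.set("toy", "A", 7, 0.95)
        diagnostics = {("A", s): diag() for s in (2, 3, 4, 5, 6)}
        diagnostics[("A", 7)] = diag("high_energy")
        # record 3's donor fails RSCC via a second table entry
        rscc.set("toy", "A", 5, 0.75)
        return records, diagnostics, rscc

    def test_toy_corpus_keeps_exactly_two(self):
        records, diagnostics, rscc = self.make_toy()
        kept, rejected = curate(records, diagnostics, rscc, CurationPolicy())
        assert len(kept) == 2
        assert {r.code for r in kept} == {"NAG-1,4-NAG", "BMA-1,4-NAG"}
        reasons = {r.code: reason for r, reason in rejected}
        assert reasons["MAN-1,3-BMA"] == "low_rscc"
        assert reasons["MAN-1,6-BMA"] == "low_rscc"
        assert reasons["MAN-1,2-MAN"] == "high_energy_ring"

    def test_rscc_exactly_at_threshold_is_rejected(self):
        rscc = RsccTable()
        rscc.set("toy", "A", 2, 0.80)
        rscc.set("toy", "A", 3, 0.95)
        kept, rejected = curate(
            [rec("NAG-1,4-NAG", -80, -130)], {("A", 2): diag(), ("A", 3): diag()},
            rscc, CurationPolicy(),
        )
        assert kept == []
        assert rejected[0][1] == "low_rscc"

    def test_missing_rscc_policy(self):
        records = [rec("NAG-1,4-NAG", -80, -130)]
        diagnostics = {("A", 2): diag(), ("A", 3): diag()}
        kept, rejected = curate(records, diagnostics, RsccTable(), CurationPolicy())
        assert rejected[0][1] == "missing_rscc"
        relaxed = CurationPolicy(missing_rscc_rejects=False)
        kept, rejected = curate(records, diagnostics, RsccTable(), relaxed)
        assert len(kept) == 1

    def test_empty_input(self):
        assert curate([], {}, RsccTable(), CurationPolicy()) == ([], [])

    def test_idempotent(self):
        records, diagnostics, rscc = self.make_toy()
        kept, _ = curate(records, diagnostics, rscc, CurationPolicy())
        again, rejected = curate(kept, diagnostics, rscc, CurationPolicy())
        assert again == kept
        assert rejected == []


class TestHarvestCorpus:
    def write_corpus(self, tmp_path, n=3, high_energy_in=None):
        paths = []
        for k in range(n):
            spec = GlycanSpec(
                structure_id=f"syn{k}",
                residues=[
                    ResidueSpec("NAG", None, 0, phi=-97, psi=178),
                    ResidueSpec("NAG", 0, 4, phi=-80, psi=-130),
                    ResidueSpec("BMA", 1, 4, phi=-87, psi=-133),
                    ResidueSpec("MAN", 2, 3, phi=76, psi=121,
                                pucker=(0.55, 90.0, 210.0) if k == high_energy_in else None),
                ],
            )
            path = tmp_path / f"syn{k}.pdb"
            write_structure(make_glycan(spec), path)
            paths.append(path)
        return paths

    def test_clean_corpus_counts(self, tmp_path):
        paths = self.write_corpus(tmp_path)
        policy = CurationPolicy(missing_rscc_rejects=False)
        records, rejected, skipped = harvest_corpus(paths, None, policy)
        assert len(records) == 12      # 3 structures x 4 linkages
        assert rejected == []
        assert skipped == []

    def test_corrupt_file_is_skipped(self, tmp_path):
        paths = self.write_corpus(tmp_path, n=2)
        bad = tmp_path / "broken.pdb"
        bad.write_bytes(b"\x00\x01 not a coordinate file")
        policy = CurationPolicy(missing_rscc_rejects=False)
        records, _, skipped = harvest_corpus(paths + [bad], None, policy)
        assert len(records) == 8
        assert len(skipped) == 1 and "broken.pdb" in skipped[0][0]

    def test_high_energy_ring_excludes_its_linkages(self, tmp_path):
        paths = self.write_corpus(tmp_path, n=3, high_energy_in=1)
        policy = CurationPolicy(missing_rscc_rejects=False)
        records, rejected, _ = harvest_corpus(paths, None, policy)
        # the skew-boat MAN is donor of one linkage: 12 - 1 kept
        assert len(records) == 11
        assert len(rejected) == 1
        assert rejected[0][0].code == "MAN-1,3-BMA"
        assert rejected[0][1] == "high_energy_ring"


class TestResolutionTable:
    def test_one_record_per_shell(self):
        records = [rec("NAG-1,4-NAG", -80, -130, resolution=r) for r in (1.2, 2.0, 3.5)]
        table = resolution_binned_table(records)
        rows = table[table.code == "NAG-1,4-NAG"]
        by_bin = dict(zip(rows.resolution_bin, rows.n))
        assert by_bin == {"x < 1.50": 1, "1.50 < x < 3.00": 1, "x > 3.00": 1, "All": 3}

    def test_single_shell_only(self):
        records = [rec("NAG-1,4-NAG", -80, -130, resolution=2.0)] * 4
        table = resolution_binned_table(records)
        assert set(table.resolution_bin) == {"1.50 < x < 3.00", "All"}
        assert table[table.resolution_bin == "All"].n.iloc[0] == 4

    def test_all_row_mean_recovery(self):
        records = make_records({"NAG-1,4-NAG": (-80.0, -130.0, 14.0, 500)}, seed=31)
        table = resolution_binned_table(records)
        row = table[table.resolution_bin == "All"].iloc[0]
        bound = 2 * 14.0 / math.sqrt(500)
        assert circular_difference(row.phi_mean, -80.0) < bound
        assert circular_difference(row.psi_mean, -130.0) < bound


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_five_element_samples(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        # independent textbook evaluation of Welch's statistic
        ma, mb = sum(a) / 5, sum(b) / 5
        va = sum((x - ma) ** 2 for x in a) / 4
        vb = sum((x - mb) ** 2 for x in b) / 4
        se2 = va / 5 + vb / 5
        t_ref = (ma - mb) / math.sqrt(se2)
        df = se2 ** 2 / ((va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4)
        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        t, p = welch_t_test(a, b)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_wrap_straddling_samples_are_unwrapped(self):
        a = [179.0, 178.0, -179.0]
        b = [170.0, 171.0, 169.0]
        # brute force: unwrap a's -179 to +181, then ordinary Welch
        ua = [179.0, 178.0, 181.0]
        t_ref, p_ref = stats.ttest_ind(ua, b, equal_var=False)
        t, p = welch_t_test(a, b)
        assert t == pytest.approx(float(t_ref), abs=1e-9)
        assert p == pytest.approx(float(p_ref), abs=1e-9)
        # the naive test would see a's mean near 59 degrees and explode
        assert abs(t) < 20

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            welch_t_test([1.0], [1.0, 2.0])


class TestCompareCorpora:
    def test_identical_corpora_not_significant(self):
        records = make_records({"NAG-1,4-NAG": (-80.0, -130.0, 10.0, 100)}, seed=1)
        table = compare_corpora(records, list(records))
        assert len(table) == 2
        assert np.allclose(table.p.to_numpy(float), 1.0)
        assert not table.significant.any()

    def test_shifted_mean_is_detected(self):
        a = make_records({"MAN-1,3-BMA": (-80.0, 120.0, 10.0, 200)}, seed=2)
        b = make_records({"MAN-1,3-BMA": (-60.0, 120.0, 10.0, 200)}, seed=3)
        table = compare_corpora(a, b)
        phi_row = table[table.angle == "phi"].iloc[0]
        assert phi_row.significant
        assert phi_row.p < 1e-6

    def test_scarce_code_is_omitted_with_note(self):
        a = make_records({"SIA-2,6-GAL": (-60.0, 100.0, 10.0, 10)}, seed=4)
        b = make_records({"SIA-2,6-GAL": (-60.0, 100.0, 10.0, 10)}, seed=5)
        table = compare_corpora(a, b)
        assert (table.note == "insufficient data").all()
        assert table.t.isna().all()

    def test_same_distribution_means_within_one_sd(self):
        clusters = {
            "NAG-1,4-NAG": (-80.0, -130.0, 14.0, 300),
            "MAN-1,6-BMA": (72.0, 168.0, 25.0, 300),
            "MAN-1,6-MAN": (68.0, -173.0, 20.0, 300),   # psi straddles the wrap
        }
        a = make_records(clusters, seed=6)
        b = make_records(clusters, seed=7)
        table = compare_corpora(a, b)
        tested = table[table.note == ""]
        assert len(tested) == 6
        for _, row in tested.iterrows():
            assert circular_difference(row.mean_a, row.mean_b) < row.sd_a
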