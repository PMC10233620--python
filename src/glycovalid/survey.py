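"""Corpus curation, torsion harvesting and two-corpus comparison.

The curation policy mirrors the database-building protocol: a torsion
record survives only if *both* monosaccharides of the linkage have a
real-space correlation coefficient strictly above the threshold (default
0.80) and pass the ring diagnostics (correct stereochemistry, physical
puckering amplitude, minimal-energy chair).  Summary tables report
circular mean +/- SD of phi and psi per linkage type and resolution shell,
and two harvested corpora can be compared with Welch t-tests computed on
angles unwrapped about the pooled circular mean (a naive t-test breaks for
distributions straddling +/-180 degrees, e.g. the alpha-1,6 mannobiose
psi cluster near -173 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientSampleError
from .graph import build_trees, detect_linkages
from .pucker import diagnose
from .structures import RsccTable, Structure, extract_glyco_residues, read_structure
from .torsions import (
    TorsionRecord,
    arithmetic_mean_sd,
    circular_mean_sd,
    linkage_torsions,
    signed_circular_difference,
)

__all__ = [
    "CurationPolicy",
    "curate",
    "harvest_structure",
    "harvest_corpus",
    "resolution_binned_table",
    "welch_t_test",
    "compare_corpora",
]

SIGNIFICANCE_LEVEL = 0.05  # two-sided, no multiple-testing correction


@dataclass
class CurationPolicy:
    rscc_min: float = 0.80
    require_diagnostic_correct: bool = True
    resolution_bins: tuple = (1.50, 3.00)
    min_obs: int = 50
    bond_cutoff: float = 1.7
    missing_rscc_rejects: bool = True

    def __post_init__(self):
        if not -1.0 <= self.rscc_min <= 1.0:
            raise ValueError("rscc_min must lie in [-1, 1]")
        if list(self.resolution_bins) != sorted(self.resolution_bins):
            raise ValueError("resolution bin breakpoints must increase")


def _residue_passes(structure_id, res_key, diagnostics, rscc, policy):
    """First failing reason for one monosaccharide, or None if it passes."""
    chain_id, seq_num = res_key
    if rscc is not None or policy.missing_rscc_rejects:
        value = None if rscc is None else rscc.get(structure_id, chain_id, seq_num)
        if value is None:
            if policy.missing_rscc_rejects:
                return "missing_rscc"
        elif not value > policy.rscc_min:   # strict: exactly rscc_min is rejected
            return "low_rscc"
    if policy.require_diagnostic_correct:
        diag = diagnostics.get((chain_id, seq_num))
        if diag is None:
            return None  # non-sugar end (the asparagine root) is not gated
        if diag.status == "high_energy":
            return "high_energy_ring"
        if not diag.correct:
            return "diagnostic_error"
    return None


def curate(records: Iterable[TorsionRecord], diagnostics: dict,
           rscc: Optional[RsccTable], policy: CurationPolicy):
    """Filter torsion records through the RSCC and ring-diagnostic gates.

    *diagnostics* maps (chain, seqnum) -> DiagnosticResult for the sugar
    residues of the records' structure.  Both ends of a linkage must pass;
    each rejection carries its first failing reason.  Returns
    ``(kept, rejected)`` with rejected as (record, reason) pairs.
    """
    kept, rejected = [], []
    for rec in records:
        sid = rec.source[0] if rec.source else ""
        reason = None
        for end in (1, 2):
            if rec.source and len(rec.source) > end:
                reason = _residue_passes(sid, rec.source[end], diagnostics, rscc, policy)
                if reason is not None:
                    break
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def harvest_structure(structure: Structure, rscc: Optional[RsccTable],
                      policy: CurationPolicy):
    """Parse one structure into curated torsion records."""
    sugars, asn_roots = extract_glyco_residues(structure)
    linkages = detect_linkages(structure, cutoff=policy.bond_cutoff)
    trees, _ = build_trees(linkages, asn_roots, sugars=sugars)

    link_oxygen_of = {}
    for link in linkages:
        atom = link.acceptor.atoms.get(link.acceptor_atom)
        if atom is not None:
            link_oxygen_of[link.donor.key] = atom.position

    diagnostics = {
        (r.chain_id, r.seq_num): diagnose(r, link_oxygen=link_oxygen_of.get(r.key))
        for r in sugars
    }
    records = [
        linkage_torsions(link, structure.id, structure.resolution)
        for tree in trees
        for link in tree.edges
    ]
    return curate(records, diagnostics, rscc, policy)


def harvest_corpus(paths: Iterable, rscc: Optional[RsccTable],
                   policy: Optional[CurationPolicy] = None):
    """Harvest curated torsion records across many coordinate files.

    Per-structure failures are logged and skipped, never fatal.  Returns
    ``(records, rejected, skipped)`` where skipped lists (path, message)
    for unreadable files.
    """
    policy = policy or CurationPolicy()
    records, rejected, skipped = [], [], []
    for path in sorted(Path(p) for p in paths):
        try:
            structure = read_structure(path)
        except Exception as exc:  # any unreadable file is skipped, not fatal
            skipped.append((str(path), str(exc)))
            continue
        kept, rej = harvest_structure(structure, rscc, policy)
        records.extend(kept)
        rejected.extend(rej)
    return records, rejected, skipped


def _bin_labels(breakpoints) -> list:
    labels = [f"x < {breakpoints[0]:.2f}"]
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        labels.append(f"{lo:.2f} < x < {hi:.2f}")
    labels.append(f"x > {breakpoints[-1]:.2f}")
    return labels


def _resolution_label(resolution, breakpoints) -> Optional[str]:
    if resolution is None:
        return None
    labels = _bin_labels(breakpoints)
    for i, bp in enumerate(breakpoints):
        if resolution < bp:
            return labels[i]
    return labels[-1]


def resolution_binned_table(records: Iterable[TorsionRecord],
                            policy: Optional[CurationPolicy] = None,
                            circular: bool = True) -> pd.DataFrame:
    """Mean +/- SD of phi and psi per (linkage code, resolution shell).

    Rows: one per populated shell per code plus an 'All' row.  Records
    without a resolution contribute to 'All' only.  Statistics are
    circular by default; set ``circular=False`` for plain arithmetic
    moments.
    """
    policy = policy or CurationPolicy()
    stat = circular_mean_sd if circular else arithmetic_mean_sd
    groups: dict[tuple, list] = {}
    for rec in records:
        if not rec.complete:
            continue
        label = _resolution_label(rec.resolution, policy.resolution_bins)
        if label is not None:
            groups.setdefault((rec.code, label), []).append(rec)
        groups.setdefault((rec.code, "All"), []).append(rec)

    order = _bin_labels(policy.resolution_bins) + ["All"]
    rows = []
    for (code, label) in sorted(groups, key=lambda k: (k[0], order.index(k[1]))):
        recs = groups[(code, label)]
        phi_mean, phi_sd = stat([r.phi for r in recs])
        psi_mean, psi_sd = stat([r.psi for r in recs])
        rows.append(
            {
                "code": code, "resolution_bin": label,
                "phi_mean": phi_mean, "phi_sd": phi_sd,
                "psi_mean": psi_mean, "psi_sd": psi_sd,
                "n": len(recs),
            }
        )
    return pd.DataFrame(rows)


def _unwrap_about(angles, center) -> np.ndarray:
    return np.array([center + signed_circular_difference(a, center) for a in angles])


def welch_t_test(a, b) -> tuple:
    """Welch's unequal-variance two-sided t-test on two angle samples.

    Both samples are unwrapped about their pooled circular mean before
    testing, so clusters straddling the +/-180 wrap are handled correctly.
    Identical samples give (0, 1).
    """
    a = list(a)
    b = list(b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientSampleError("Welch t-test needs at least two values per sample")
    pooled_mean, _ = circular_mean_sd(list(a) + list(b))
    ua = _unwrap_about(a, pooled_mean)
    ub = _unwrap_about(b, pooled_mean)
    if np.var(ua) == 0 and np.var(ub) == 0:
        return (0.0, 1.0) if np.isclose(ua.mean(), ub.mean()) else (math.inf, 0.0)
    t, p = stats.ttest_ind(ua, ub, equal_var=False)
    return float(t), float(p)


def compare_corpora(records_a: Iterable[TorsionRecord],
                    records_b: Iterable[TorsionRecord],
                    policy: Optional[CurationPolicy] = None) -> pd.DataFrame:
    """Per-(code, angle) Welch comparison of two harvested corpora.

    One row per linkage code and torsion angle with the circular means and
    SDs of each corpus, the Welch t and p, and a significance verdict at
    p <= 0.05 (two-sided, uncorrected).  Codes below the policy's min_obs
    in either corpus are listed with a note instead of a test.
    """
    policy = policy or CurationPolicy()
    by_code_a: dict[str, list] = {}
    by_code_b: dict[str, list] = {}
    for rec in records_a:
        if rec.complete:
            by_code_a.setdefault(rec.code, []).append(rec)
    for rec in records_b:
        if rec.complete:
            by_code_b.setdefault(rec.code, []).append(rec)

    rows = []
    for code in sorted(set(by_code_a) | set(by_code_b)):
        ra = by_code_a.get(code, [])
        rb = by_code_b.get(code, [])
        for angle in ("phi", "psi"):
            va = [getattr(r, angle) for r in ra]
            vb = [getattr(r, angle) for r in rb]
            if len(va) < policy.min_obs or len(vb) < policy.min_obs:
                rows.append(
                    {
                        "code": code, "angle": angle,
                        "mean_a": None, "sd_a": None, "mean_b": None, "sd_b": None,
                        "n_a": len(va), "n_b": len(vb),
                        "t": None, "p": None, "significant": None,
                        "note": "insufficient data",
                    }
                )
                continue
            mean_a, sd_a = circular_mean_sd(va)
            mean_b, sd_b = circular_mean_sd(vb)
            t, p = welch_t_test(va, vb)
            rows.append(
                {
                    "code": code, "angle": angle,
                    "mean_a": mean_a, "sd_a": sd_a, "mean_b": mean_b, "sd_b": sd_b,
                    "n_a": len(va), "n_b": len(vb),
                    "t": t, "p": p,
                    "significant": bool(p <= SIGNIFICANCE_LEVEL),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
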