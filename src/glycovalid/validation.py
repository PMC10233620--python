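"""Linkage Z-scores, glycan-level aggregation and reporting.

A linkage's conformational normality is scored against the binned torsion
database as

    z = (c - <c>) / sigma<c>

where c is the count in the 2 x 2 degree (phi, psi) bin the measured
torsions fall into, and <c> / sigma<c> are the mean and standard deviation
of counts over all bins for that linkage type.  Positive scores mean the
conformation is well represented in the reference corpus; negative scores
mean it is rare.  Any linkage with z strictly below -1 is flagged as a
standout worth inspecting (orange); linkage types with fewer than the
minimum number of database observations are reported as insufficient-data
(grey) rather than scored.

Per glycan, the global Z-score is the plain average of the available
linkage Z-scores, and an optional quality Z-score standardises that global
score against a reference set of global scores from trusted structures.
Interpretation bands: global Z below -2 may indicate serious problems;
above +2 (especially at low resolution) possible torsion over-restraining.
A flag never proves a modelling error -- it marks the linkage as worth
inspecting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .database import TorsionDatabase
from .errors import DegenerateDatabaseError, DegenerateReferenceError
from .graph import build_trees, detect_linkages
from .pucker import DiagnosticResult, diagnose
from .structures import Structure, extract_glyco_residues
from .torsions import TorsionRecord, linkage_torsions

__all__ = [
    "OUTLIER_THRESHOLD",
    "ZScoreResult",
    "ReferenceSet",
    "GlycanReport",
    "linkage_zscore",
    "global_zscore",
    "quality_zscore",
    "validate_structure",
]

#: z strictly below this value marks a standout linkage.
OUTLIER_THRESHOLD = -1.0
#: |global Z| beyond this band warrants attention either way.
WARNING_BAND = 2.0


@dataclass(frozen=True)
class ZScoreResult:
    code: str
    z: Optional[float]
    status: str                 # "validated" | "insufficient_data"
    flagged: bool = False

    @property
    def validated(self) -> bool:
        return self.status == "validated"


def linkage_zscore(rec: TorsionRecord, db: TorsionDatabase,
                   outlier_threshold: float = OUTLIER_THRESHOLD) -> ZScoreResult:
    """Score one measured linkage against the database.

    Linkage types below the database's min_obs (or absent, or with an
    incomplete phi/psi measurement) come back as insufficient-data with no
    score.  Flagging uses a strict inequality: z equal to the threshold is
    not flagged.
    """
    if not rec.complete or not db.validated(rec.code):
        return ZScoreResult(code=rec.code, z=None, status="insufficient_data")
    lg = db.grid_for(rec.code)
    sd = lg.sd_count
    if sd == 0:
        raise DegenerateDatabaseError(
            f"zero count spread for {rec.code}: Z-score undefined"
        )
    z = (lg.count_at(rec.phi, rec.psi) - lg.mean_count) / sd
    return ZScoreResult(code=rec.code, z=float(z), status="validated",
                        flagged=bool(z < outlier_threshold))


def global_zscore(results) -> Optional[float]:
    """Arithmetic mean of the validated linkage Z-scores; None if none."""
    zs = [r.z for r in results if r.validated]
    if not zs:
        return None
    return float(np.mean(zs))


class ReferenceSet:
    """Distribution of global Z-scores from a trusted reference corpus."""

    def __init__(self, global_z_values):
        self.values = [float(v) for v in global_z_values]
        if len(self.values) < 2:
            raise ValueError("a reference set needs at least two global Z values")
        self.mean = float(np.mean(self.values))
        self.sd = float(np.std(self.values, ddof=1))

    @classmethod
    def from_json(cls, path) -> "ReferenceSet":
        doc = json.loads(open(path).read())
        values = doc["global_z"] if isinstance(doc, dict) else doc
        return cls(values)


def quality_zscore(global_z: float, ref: ReferenceSet) -> float:
    """Standardise a glycan's global Z against the reference distribution."""
    if ref.sd == 0:
        raise DegenerateReferenceError("reference set has zero spread")
    return (global_z - ref.mean) / ref.sd


def _interpret(global_z: Optional[float]) -> str:
    if global_z is None:
        return "no validated linkages"
    if global_z < -WARNING_BAND:
        return "global Z < -2: may indicate serious problems"
    if global_z > WARNING_BAND:
        return "global Z > 2: may indicate over-restrained torsions"
    return "within the expected range"


@dataclass
class GlycanReport:
    """Everything the validation pipeline knows about one N-glycan."""

    tree: object
    linkage_results: list = field(default_factory=list)   # (TorsionRecord, ZScoreResult)
    ring_diagnostics: list = field(default_factory=list)  # (Residue, DiagnosticResult)
    global_z: Optional[float] = None
    quality_z: Optional[float] = None
    interpretation: str = ""

    @property
    def n_flagged(self) -> int:
        return sum(1 for _, z in self.linkage_results if z.flagged)

    @property
    def n_insufficient(self) -> int:
        return sum(1 for _, z in self.linkage_results if not z.validated)

    @property
    def n_ring_issues(self) -> int:
        return sum(1 for _, d in self.ring_diagnostics if not d.correct)

    def to_dict(self) -> dict:
        return {
            "root": f"{self.tree.root.chain_id}{self.tree.root.seq_num}",
            "global_z": self.global_z,
            "quality_z": self.quality_z,
            "interpretation": self.interpretation,
            "n_flagged": self.n_flagged,
            "n_insufficient": self.n_insufficient,
            "linkages": [
                {
                    "code": rec.code,
                    "donor": list(rec.source[1]) if rec.source else None,
                    "acceptor": list(rec.source[2]) if rec.source else None,
                    "phi": rec.phi,
                    "psi": rec.psi,
                    "omega": rec.omega,
                    "z": z.z,
                    "status": z.status,
                    "flagged": z.flagged,
                }
                for rec, z in self.linkage_results
            ],
            "rings": [
                {
                    "residue": f"{r.ccd_code} {r.chain_id}{r.seq_num}",
                    "status": d.status,
                    "conformer": d.conformer.code if d.conformer else None,
                    "Q": d.pucker.Q if d.pucker else None,
                    "reasons": list(d.reasons),
                }
                for r, d in self.ring_diagnostics
            ],
        }

    def to_rows(self) -> list:
        """One row per linkage, for TSV export."""
        rows = []
        for rec, z in self.linkage_results:
            rows.append(
                {
                    "root": f"{self.tree.root.chain_id}{self.tree.root.seq_num}",
                    "code": rec.code,
                    "phi": rec.phi,
                    "psi": rec.psi,
                    "omega": rec.omega,
                    "z": z.z,
                    "status": z.status,
                    "flagged": z.flagged,
                }
            )
        return rows


def validate_structure(structure: Structure, db: TorsionDatabase,
                       ref: Optional[ReferenceSet] = None,
                       outlier_threshold: float = OUTLIER_THRESHOLD,
                       bond_cutoff: Optional[float] = None) -> list:
    """Score every N-glycan in a structure; one report per glycan tree."""
    sugars, asn_roots = extract_glyco_residues(structure)
    kwargs = {} if bond_cutoff is None else {"cutoff": bond_cutoff}
    linkages = detect_linkages(structure, **kwargs)
    trees, _orphans = build_trees(linkages, asn_roots, sugars=sugars)

    link_oxygen_of = {}
    for link in linkages:
        acc_atom = link.acceptor.atoms.get(link.acceptor_atom)
        if acc_atom is not None:
            link_oxygen_of[link.donor.key] = acc_atom.position

    reports = []
    for tree in trees:
        report = GlycanReport(tree=tree)
        for residue in tree.nodes:
            d = diagnose(residue, link_oxygen=link_oxygen_of.get(residue.key))
            report.ring_diagnostics.append((residue, d))
        for link in tree.edges:
            rec = linkage_torsions(link, structure.id, structure.resolution)
            z = linkage_zscore(rec, db, outlier_threshold=outlier_threshold)
            report.linkage_results.append((rec, z))
        report.global_z = global_zscore([z for _, z in report.linkage_results])
        if ref is not None and report.global_z is not None:
            report.quality_z = quality_zscore(report.global_z, ref)
        report.interpretation = _interpret(report.global_z)
        reports.append(report)
    return reports
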