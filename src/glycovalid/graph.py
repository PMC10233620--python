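"""Glycosidic bond perception and N-glycan tree assembly.

Connectivity is perceived geometrically: a linkage is emitted for every
(donor anomeric carbon, acceptor exocyclic oxygen or asparagine ND2) pair
within a covalent cutoff (default 1.7 A, generous relative to the ~1.4 A
glycosidic bond but well short of van-der-Waals contacts).  Each anomeric
carbon bonds at most one acceptor; when several candidates fall inside the
cutoff the nearest wins and the ambiguity is logged.

Trees are rooted at asparagine residues; sugar clusters with no path to an
ASN are reported as orphans and are never validated as N-glycans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .chem import MONOSACCHARIDES, SUPPORTED_LINKAGE_CODES
from .errors import MalformedGlycanError
from .structures import Residue, Structure, extract_glyco_residues

__all__ = ["GlycosidicLinkage", "GlycanTree", "detect_linkages", "build_trees", "classify_linkage"]

logger = logging.getLogger(__name__)

DEFAULT_BOND_CUTOFF = 1.7

#: candidate acceptor oxygens on a sugar (the ring oxygen and the
#: acceptor's own anomeric oxygen never accept a glycosidic bond)
_ACCEPTOR_OXYGENS = ("O2", "O3", "O4", "O6")


@dataclass
class GlycosidicLinkage:
    donor: Residue
    acceptor: Residue
    donor_anomeric_atom: str
    acceptor_atom: str
    acceptor_position: int      # x of the 1->x nomenclature; 0 for ASN
    code: str = ""
    distance: float = 0.0

    @property
    def supported(self) -> bool:
        return self.code in SUPPORTED_LINKAGE_CODES

    def __post_init__(self):
        if not self.code:
            self.code = classify_linkage(self)


def classify_linkage(linkage: GlycosidicLinkage) -> str:
    """Taxonomy code '<DONOR>-<dpos>,<apos>-<ACCEPTOR>' ('NAG-ASN' at the root)."""
    donor = linkage.donor.ccd_code
    if linkage.acceptor.ccd_code == "ASN":
        return f"{donor}-ASN"
    dpos = MONOSACCHARIDES[donor].anomeric_position
    return f"{donor}-{dpos},{linkage.acceptor_position}-{linkage.acceptor.ccd_code}"


def _acceptor_candidates(residue: Residue):
    if residue.ccd_code == "ASN":
        atom = residue.atoms.get("ND2")
        if atom is not None:
            yield "ND2", 0, atom
        return
    chem = MONOSACCHARIDES[residue.ccd_code]
    for name in _ACCEPTOR_OXYGENS:
        if name in (chem.ring_oxygen, chem.anomeric_oxygen):
            continue
        atom = residue.atoms.get(name)
        if atom is not None:
            yield name, int(name[1:]), atom


def detect_linkages(structure: Structure, cutoff: float = DEFAULT_BOND_CUTOFF) -> list:
    """Perceive glycosidic bonds from geometry alone.

    Returns one linkage per donor anomeric carbon with an acceptor atom
    inside the cutoff (nearest candidate wins).
    """
    sugars, asn_roots = extract_glyco_residues(structure)
    acceptors = sugars + asn_roots
    linkages = []
    for donor in sugars:
        chem = MONOSACCHARIDES[donor.ccd_code]
        anomeric = donor.atoms.get(chem.anomeric_carbon)
        if anomeric is None:
            continue
        hits = []
        for acc in acceptors:
            if acc is donor:
                continue
            for name, pos, atom in _acceptor_candidates(acc):
                d = float(np.linalg.norm(atom.position - anomeric.position))
                if d <= cutoff:
                    hits.append((d, acc, name, pos))
        if not hits:
            continue
        hits.sort(key=lambda h: h[0])
        if len(hits) > 1:
            logger.warning(
                "ambiguous glycosidic bond for %s %s%d: %d candidates within %.2f A",
                donor.ccd_code, donor.chain_id, donor.seq_num, len(hits), cutoff,
            )
        d, acc, name, pos = hits[0]
        linkages.append(
            GlycosidicLinkage(
                donor=donor, acceptor=acc,
                donor_anomeric_atom=chem.anomeric_carbon,
                acceptor_atom=name, acceptor_position=pos, distance=d,
            )
        )
    return linkages


@dataclass
class GlycanTree:
    """One N-glycan: sugars hanging off an asparagine root."""

    root: Residue
    nodes: list = field(default_factory=list)       # sugar residues, BFS order
    edges: list = field(default_factory=list)       # GlycosidicLinkage, BFS order

    def children(self, residue: Residue) -> list:
        return [e.donor for e in self.edges if e.acceptor is residue]

    def parent_edge(self, residue: Residue) -> Optional[GlycosidicLinkage]:
        for e in self.edges:
            if e.donor is residue:
                return e
        return None

    def to_dict(self) -> dict:
        return {
            "root": {"chain": self.root.chain_id, "seqnum": self.root.seq_num, "ccd": "ASN"},
            "nodes": [
                {"chain": r.chain_id, "seqnum": r.seq_num, "ccd": r.ccd_code}
                for r in self.nodes
            ],
            "edges": [
                {
                    "donor": [e.donor.chain_id, e.donor.seq_num],
                    "acceptor": [e.acceptor.chain_id, e.acceptor.seq_num],
                    "code": e.code,
                }
                for e in self.edges
            ],
        }


def build_trees(linkages: list, asn_roots: list, sugars: Optional[list] = None):
    """Assemble rooted glycan trees from perceived linkages.

    Returns ``(trees, orphans)`` where orphans are sugars with no path to
    any asparagine (pass *sugars* to have completely unlinked residues
    reported too).  A connectivity cycle raises
    :class:`MalformedGlycanError` naming the residues involved.
    """
    g = nx.DiGraph()
    for link in linkages:
        g.add_edge(link.donor.key, link.acceptor.key, linkage=link)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        residues = " -> ".join(f"{u[2]} {u[0]}{u[1]}" for u, v in cycle)
        raise MalformedGlycanError(f"glycosidic connectivity contains a cycle: {residues}")

    trees = []
    attached: set = set()
    for asn in asn_roots:
        if asn.key not in g:
            continue
        tree = GlycanTree(root=asn)
        frontier = [asn]
        while frontier:
            current = frontier.pop(0)
            incoming = sorted(
                (g.edges[u, current.key]["linkage"] for u in g.predecessors(current.key)),
                key=lambda l: (l.donor.chain_id, l.donor.seq_num),
            )
            for link in incoming:
                tree.nodes.append(link.donor)
                tree.edges.append(link)
                attached.add(link.donor.key)
                frontier.append(link.donor)
        if tree.nodes:
            trees.append(tree)

    donors = {l.donor.key: l.donor for l in linkages}
    acceptors = {l.acceptor.key: l.acceptor for l in linkages if l.acceptor.ccd_code != "ASN"}
    orphan_map = {**acceptors, **donors}
    if sugars is not None:
        orphan_map.update({r.key: r for r in sugars})
    orphans = [r for key, r in sorted(orphan_map.items()) if key not in attached]
    return trees, orphans
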