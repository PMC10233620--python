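"""Minimal structural data model and coordinate/table I/O.

Coordinates are read with gemmi (PDB and mmCIF/PDBx); only the first model
is kept, hydrogens are dropped, and alternate locations are resolved to the
highest-occupancy conformer (ties broken toward the lexicographically first
altloc).  Per-residue real-space correlation coefficients (RSCC) are
consumed from a 4-column TSV rather than computed from maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd

from .chem import SUGAR_CODES
from .errors import FormatError, ParseError, ValidationInputError

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "RsccTable",
    "read_structure",
    "write_structure",
    "extract_glyco_residues",
    "load_rscc_table",
    "masked_correlation",
]


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}")


@dataclass
class Residue:
    ccd_code: str
    chain_id: str
    seq_num: int
    atoms: dict = field(default_factory=dict)  # name -> AtomRecord

    @property
    def is_sugar(self) -> bool:
        return self.ccd_code in SUGAR_CODES

    @property
    def is_asn(self) -> bool:
        return self.ccd_code == "ASN" and "ND2" in self.atoms

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.ccd_code)

    def add_atom(self, atom: AtomRecord) -> None:
        self.atoms[atom.name] = atom

    def __repr__(self) -> str:
        return f"<Residue {self.ccd_code} {self.chain_id}{self.seq_num} ({len(self.atoms)} atoms)>"


@dataclass
class Structure:
    id: str
    residues: list = field(default_factory=list)
    resolution: Optional[float] = None

    def find(self, chain_id: str, seq_num: int) -> Optional[Residue]:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_num == seq_num:
                return r
        return None


def _resolve_altlocs(raw_atoms) -> list:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, list] = {}
    for atom in raw_atoms:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        kept.append(group[0])
    return kept


def read_structure(path, format: str = "auto") -> Structure:
    """Load the first model of a PDB or mmCIF file into a Structure.

    Hydrogens and waters are ignored; altlocs are resolved by occupancy.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise FormatError(f"unsupported format {format!r} (expected pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    st.setup_entities()

    structure = Structure(id=st.name.lower() or path.stem)
    if st.resolution and st.resolution > 0:
        structure.resolution = float(st.resolution)

    model = st[0]  # first model only
    for chain in model:
        for res in chain:
            if res.name == "HOH":
                continue
            raw = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                raw.append(
                    AtomRecord(
                        name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(1.0, max(0.0, atom.occ)),
                        altloc=atom.altloc if atom.altloc else "",
                    )
                )
            if not raw:
                continue
            residue = Residue(ccd_code=res.name, chain_id=chain.name, seq_num=res.seqid.num)
            for atom in _resolve_altlocs(raw):
                residue.add_atom(atom)
            structure.residues.append(residue)
    if not structure.residues:
        raise ParseError(f"{path} contains no atom records")
    return structure


def write_structure(structure: Structure, path, format: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF (by extension when format='auto')."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = structure.id
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        chain = chains.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.ccd_code
        gres.seqid = gemmi.SeqId(res.seq_num, " ")
        gres.het_flag = "A" if res.ccd_code == "ASN" else "H"
        for atom in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = atom.occupancy
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise FormatError(f"unsupported format {format!r}")


def extract_glyco_residues(structure: Structure):
    """Split out the residues relevant to N-glycosylation.

    Returns ``(sugars, asn_roots)``: residues whose CCD code is in the
    supported sugar dictionary, and asparagines carrying a side-chain ND2.
    """
    sugars = [r for r in structure.residues if r.is_sugar]
    asn_roots = [r for r in structure.residues if r.is_asn]
    return sugars, asn_roots


class RsccTable:
    """Mapping (structure id, chain, seqnum) -> RSCC value in [-1, 1]."""

    def __init__(self, values: Optional[dict] = None):
        self._values = dict(values or {})

    def get(self, structure_id: str, chain_id: str, seq_num: int) -> Optional[float]:
        return self._values.get((structure_id.lower(), chain_id, int(seq_num)))

    def set(self, structure_id: str, chain_id: str, seq_num: int, rscc: float) -> None:
        if not -1.0 <= rscc <= 1.0:
            raise ValidationInputError(f"RSCC {rscc} outside [-1, 1]")
        self._values[(structure_id.lower(), chain_id, int(seq_num))] = float(rscc)

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, key) -> bool:
        sid, chain, seq = key
        return (sid.lower(), chain, int(seq)) in self._values


def load_rscc_table(path) -> RsccTable:
    """Read per-residue RSCC values from a headered 4-column TSV.

    Expected columns: structure_id, chain, seqnum, rscc.  Rows with a
    non-numeric RSCC are rejected; values outside [-1, 1] raise a
    validation error naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chain": str})
    except pd.errors.EmptyDataError:
        return RsccTable()
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read RSCC table {path}: {exc}") from exc
    required = {"structure_id", "chain", "seqnum", "rscc"}
    if not required.issubset(df.columns):
        raise ParseError(f"RSCC table {path} lacks columns {sorted(required - set(df.columns))}")
    table = RsccTable()
    for idx, row in df.iterrows():
        rscc = pd.to_numeric(pd.Series([row["rscc"]]), errors="coerce").iloc[0]
        if pd.isna(rscc):
            continue  # non-numeric rows are rejected silently
        if not -1.0 <= rscc <= 1.0:
            raise ValidationInputError(f"row {idx + 2}: RSCC {rscc} outside [-1, 1]")
        table.set(str(row["structure_id"]), str(row["chain"]), int(row["seqnum"]), float(rscc))
    return table


def masked_correlation(a, b, mask=None) -> float:
    """Pearson correlation of two arrays under an optional boolean mask.

    Generic helper mirroring how real-space correlations are computed from
    gridded values; RSCC values for curation are consumed from tables, not
    computed here.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        a, b = a[m], b[m]
    if a.size < 2:
        raise ValueError("need at least two samples for a correlation")
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(a @ b) / denom
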