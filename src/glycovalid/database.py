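"""The 2-degree-binned glycosidic torsion database.

Torsion observations for each linkage type are accumulated on a 180 x 180
count grid over (phi, psi) in [-180, 180) with 2-degree spacing (32 400
bins).  The grid's mean count <c_l> and standard deviation sigma<c_l> normalise
the per-bin counts into the linkage Z-score used downstream.  A linkage type is only
considered validated once it has at least ``min_obs`` observations
(default 50); scarcer linkages are reported as insufficient-data.

Raw (phi, psi, omega) records are retained alongside the grid so that
summary statistics can be recomputed exactly, and the whole database
round-trips through a JSON schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import DegenerateDatabaseError, MissingCodeError, ParseError, SchemaError
from .torsions import TorsionRecord, circular_mean_sd

__all__ = [
    "GRID_SIZE",
    "N_BINS",
    "bin_index",
    "LinkageGrid",
    "TorsionDatabase",
    "build_database",
    "merge_databases",
    "summarize_linkage",
    "save_database",
    "load_database",
]

BIN_SPACING = 2.0
GRID_SIZE = 180
N_BINS = GRID_SIZE * GRID_SIZE
SCHEMA_VERSION = 1
DEFAULT_MIN_OBS = 50


def _wrap_half_open(x: float) -> float:
    """Map an angle to [-180, 180)."""
    return (float(x) + 180.0) % 360.0 - 180.0


def bin_index(phi: float, psi: float) -> tuple[int, int]:
    """Half-open 2-degree bin of a (phi, psi) pair: indices in [0, 180)^2."""
    i = int(math.floor((_wrap_half_open(phi) + 180.0) / BIN_SPACING))
    j = int(math.floor((_wrap_half_open(psi) + 180.0) / BIN_SPACING))
    return min(i, GRID_SIZE - 1), min(j, GRID_SIZE - 1)


class LinkageGrid:
    """Count grid plus retained raw records for one linkage type.

    The normalising statistics ``mean_count`` and ``sd_count`` are taken
    over the occupied bins by default.  Including the empty bins is
    available (``include_empty_bins=True``) but collapses the dynamic
    range of negative scores: an unobserved conformation could then never
    fall much below zero, let alone past the -1 standout threshold,
    because the grid is overwhelmingly empty at realistic sample sizes.
    """

    def __init__(self, code: str, include_empty_bins: bool = False):
        self.code = code
        self.include_empty_bins = include_empty_bins
        self.grid = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.int64)
        self.records: list[tuple] = []  # (phi, psi, omega or None)

    def add(self, phi: float, psi: float, omega: Optional[float] = None) -> None:
        i, j = bin_index(phi, psi)
        self.grid[i, j] += 1
        self.records.append((float(phi), float(psi), None if omega is None else float(omega)))

    @property
    def n_obs(self) -> int:
        return int(self.grid.sum())

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.grid))

    def _population(self) -> np.ndarray:
        if self.include_empty_bins:
            return self.grid.ravel()
        return self.grid[self.grid > 0]

    @property
    def mean_count(self) -> float:
        pop = self._population()
        return float(pop.mean()) if pop.size else 0.0

    @property
    def sd_count(self) -> float:
        # population SD: the bins are treated as the complete population
        pop = self._population()
        return float(pop.std()) if pop.size else 0.0

    def count_at(self, phi: float, psi: float) -> int:
        i, j = bin_index(phi, psi)
        return int(self.grid[i, j])


class TorsionDatabase:
    def __init__(self, min_obs: int = DEFAULT_MIN_OBS, include_empty_bins: bool = False):
        self.min_obs = int(min_obs)
        self.include_empty_bins = bool(include_empty_bins)
        self.linkages: dict[str, LinkageGrid] = {}

    def __contains__(self, code: str) -> bool:
        return code in self.linkages

    def __len__(self) -> int:
        return len(self.linkages)

    def grid_for(self, code: str) -> LinkageGrid:
        if code not in self.linkages:
            raise MissingCodeError(f"no torsion data for linkage code {code!r}")
        return self.linkages[code]

    def validated(self, code: str) -> bool:
        return code in self.linkages and self.linkages[code].n_obs >= self.min_obs

    def add_record(self, rec: TorsionRecord) -> bool:
        """Accumulate one record; incomplete (phi or psi missing) are skipped."""
        if not rec.complete:
            return False
        lg = self.linkages.get(rec.code)
        if lg is None:
            lg = self.linkages[rec.code] = LinkageGrid(rec.code, self.include_empty_bins)
        lg.add(rec.phi, rec.psi, rec.omega)
        return True


def build_database(records: Iterable[TorsionRecord], min_obs: int = DEFAULT_MIN_OBS,
                   include_empty_bins: bool = False) -> TorsionDatabase:
    db = TorsionDatabase(min_obs=min_obs, include_empty_bins=include_empty_bins)
    for rec in records:
        db.add_record(rec)
    return db


def merge_databases(a: TorsionDatabase, b: TorsionDatabase) -> TorsionDatabase:
    """Union of two databases: grids add, statistics are recomputed."""
    if a.min_obs != b.min_obs:
        raise ValueError("cannot merge databases with different min_obs")
    out = TorsionDatabase(min_obs=a.min_obs, include_empty_bins=a.include_empty_bins)
    for src in (a, b):
        for code, lg in src.linkages.items():
            dest = out.linkages.get(code)
            if dest is None:
                dest = out.linkages[code] = LinkageGrid(code, out.include_empty_bins)
            dest.grid += lg.grid
            dest.records.extend(lg.records)
    return out


@dataclass(frozen=True)
class LinkageSummary:
    code: str
    n_obs: int
    phi_mean: float
    phi_sd: float
    psi_mean: float
    psi_sd: float
    modal_bin: tuple          # (i, j): the single hottest grid cell
    modal_bin_center: tuple   # (phi, psi) degrees of that cell
    mode_estimate: tuple      # robust per-angle mode (degrees), see below


def _marginal_mode(marginal: np.ndarray) -> float:
    """Bin-centre of the 3-bin (6 degree) windowed marginal maximum.

    A single 2-degree cell of a sparse 2-D histogram holds only a handful
    of counts, so its argmax is a noisy location estimate; summing each
    bin with its circular neighbours before taking the maximum is the
    standard stabilisation.
    """
    windowed = marginal + np.roll(marginal, 1) + np.roll(marginal, -1)
    return -180.0 + BIN_SPACING * (int(windowed.argmax()) + 0.5)


def summarize_linkage(db: TorsionDatabase, code: str) -> LinkageSummary:
    """Circular mean +/- SD of phi and psi plus modal-conformation estimates."""
    lg = db.grid_for(code)
    if lg.n_obs == 0:
        raise MissingCodeError(f"linkage {code!r} has no observations")
    phis = [r[0] for r in lg.records]
    psis = [r[1] for r in lg.records]
    phi_mean, phi_sd = circular_mean_sd(phis)
    psi_mean, psi_sd = circular_mean_sd(psis)
    i, j = np.unravel_index(int(lg.grid.argmax()), lg.grid.shape)
    center = (-180.0 + BIN_SPACING * (i + 0.5), -180.0 + BIN_SPACING * (j + 0.5))
    mode = (_marginal_mode(lg.grid.sum(axis=1)), _marginal_mode(lg.grid.sum(axis=0)))
    return LinkageSummary(
        code=code, n_obs=lg.n_obs,
        phi_mean=phi_mean, phi_sd=phi_sd, psi_mean=psi_mean, psi_sd=psi_sd,
        modal_bin=(int(i), int(j)), modal_bin_center=center, mode_estimate=mode,
    )


def save_database(db: TorsionDatabase, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "bin_spacing_deg": BIN_SPACING,
        "min_obs": db.min_obs,
        "include_empty_bins": db.include_empty_bins,
        "linkages": {},
    }
    for code in sorted(db.linkages):
        lg = db.linkages[code]
        idx = np.nonzero(lg.grid)
        sparse = {f"{int(i)},{int(j)}": int(lg.grid[i, j]) for i, j in zip(*idx)}
        doc["linkages"][code] = {
            "n_obs": lg.n_obs,
            "grid": sparse,
            "records": [list(r) for r in lg.records],
            "mean_count": lg.mean_count,
            "sd_count": lg.sd_count,
            "validated": db.validated(code),
        }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_database(path) -> TorsionDatabase:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ParseError(f"cannot read torsion database {path}: {exc}") from exc
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"database schema version {doc.get('schema_version')!r} "
            f"is incompatible with {SCHEMA_VERSION}"
        )
    db = TorsionDatabase(min_obs=int(doc["min_obs"]),
                         include_empty_bins=bool(doc.get("include_empty_bins", False)))
    for code, entry in doc["linkages"].items():
        lg = LinkageGrid(code, db.include_empty_bins)
        for key, count in entry["grid"].items():
            i, j = (int(v) for v in key.split(","))
            lg.grid[i, j] = int(count)
        lg.records = [
            (float(r[0]), float(r[1]), None if r[2] is None else float(r[2]))
            for r in entry["records"]
        ]
        if lg.n_obs != int(entry["n_obs"]):
            raise ParseError(f"inconsistent grid for {code}: stored n_obs != sum of counts")
        db.linkages[code] = lg
    return db
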