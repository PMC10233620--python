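"""Built-in monosaccharide dictionary.

One entry per supported Chemical Component Dictionary (CCD) code, covering
the sugars that occur in the validated N-glycan linkage set: GlcNAc (NAG),
beta/alpha-D-mannose (BMA/MAN), L-fucose (FUC), D-galactose (GAL) and
sialic acid (SIA).  Each entry records the ring cycle in the order used by
the puckering analysis (ring oxygen first), the anomeric centre, the
expected anomeric and absolute configuration, the minimal-energy chair and
the SNFG glyph, plus the substituent layout used by the synthetic-structure
generator.

The chirality sign fields encode the expected sign of the signed volume

    det[ u(ring O), u(next ring C), u(exocyclic O) ]

of unit bond vectors at the anomeric carbon (``anomeric_sign``) and, at the
configurational carbon C5, of ``det[u(O5), u(C4), u(C6)]``
(``config_sign``).  These are conformation-robust fingerprints of the
alpha/beta and D/L assignments and are what the stereochemistry diagnostics
compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["SugarChem", "MONOSACCHARIDES", "SUGAR_CODES", "SUPPORTED_LINKAGE_CODES"]


@dataclass(frozen=True)
class SugarChem:
    code: str
    full_name: str
    ring_atoms: tuple            # CP order, ring oxygen first
    anomeric_carbon: str
    anomeric_position: int       # 1, or 2 for sialic acid
    anomeric_oxygen: str         # exocyclic oxygen replaced by the glycosidic bond
    anomer: str                  # "alpha" | "beta"
    dl: Optional[str]            # "D" | "L" | None (not checked)
    chair_theta: float           # canonical chair pole on the CP sphere (deg)
    minimal_conformer: str
    snfg_shape: str
    snfg_color: str
    # generator layout: ring substituents as (name, ring parent, "ax"|"eq")
    ring_substituents: tuple = ()
    # generator layout: chain atoms as (name, (A, B, C), bond, angle, torsion)
    chain_atoms: tuple = ()
    anomeric_sign: Optional[int] = None
    config_sign: Optional[int] = None

    @property
    def ring_oxygen(self) -> str:
        return self.ring_atoms[0]


# SNFG v3 palette (white/blue/green/yellow/red/purple subset used here).
_BLUE = "#0072BC"
_GREEN = "#00A651"
_YELLOW = "#FFD400"
_RED = "#ED1C24"
_PURPLE = "#A54399"

_HEX_RING = ("O5", "C1", "C2", "C3", "C4", "C5")
_O6 = ("O6", ("O5", "C5", "C6"), 1.43, 109.5, 60.0)

MONOSACCHARIDES: dict[str, SugarChem] = {
    "NAG": SugarChem(
        code="NAG", full_name="N-acetyl-beta-D-glucosamine",
        ring_atoms=_HEX_RING, anomeric_carbon="C1", anomeric_position=1,
        anomeric_oxygen="O1", anomer="beta", dl="D", chair_theta=0.0,
        minimal_conformer="4C1", snfg_shape="square", snfg_color=_BLUE,
        ring_substituents=(
            ("O1", "C1", "eq"), ("N2", "C2", "eq"), ("O3", "C3", "eq"),
            ("O4", "C4", "eq"), ("C6", "C5", "eq"),
        ),
        chain_atoms=(
            _O6,
            ("C7", ("C3", "C2", "N2"), 1.33, 122.0, 150.0),
            ("O7", ("C2", "N2", "C7"), 1.23, 122.0, 0.0),
        ),
        anomeric_sign=+1, config_sign=-1,
    ),
    "BMA": SugarChem(
        code="BMA", full_name="beta-D-mannose",
        ring_atoms=_HEX_RING, anomeric_carbon="C1", anomeric_position=1,
        anomeric_oxygen="O1", anomer="beta", dl="D", chair_theta=0.0,
        minimal_conformer="4C1", snfg_shape="circle", snfg_color=_GREEN,
        ring_substituents=(
            ("O1", "C1", "eq"), ("O2", "C2", "ax"), ("O3", "C3", "eq"),
            ("O4", "C4", "eq"), ("C6", "C5", "eq"),
        ),
        chain_atoms=(_O6,),
        anomeric_sign=+1, config_sign=-1,
    ),
    "MAN": SugarChem(
        code="MAN", full_name="alpha-D-mannose",
        ring_atoms=_HEX_RING, anomeric_carbon="C1", anomeric_position=1,
        anomeric_oxygen="O1", anomer="alpha", dl="D", chair_theta=0.0,
        minimal_conformer="4C1", snfg_shape="circle", snfg_color=_GREEN,
        ring_substituents=(
            ("O1", "C1", "ax"), ("O2", "C2", "ax"), ("O3", "C3", "eq"),
            ("O4", "C4", "eq"), ("C6", "C5", "eq"),
        ),
        chain_atoms=(_O6,),
        anomeric_sign=-1, config_sign=-1,
    ),
    "GAL": SugarChem(
        code="GAL", full_name="beta-D-galactose",
        ring_atoms=_HEX_RING, anomeric_carbon="C1", anomeric_position=1,
        anomeric_oxygen="O1", anomer="beta", dl="D", chair_theta=0.0,
        minimal_conformer="4C1", snfg_shape="circle", snfg_color=_YELLOW,
        ring_substituents=(
            ("O1", "C1", "eq"), ("O2", "C2", "eq"), ("O3", "C3", "eq"),
            ("O4", "C4", "ax"), ("C6", "C5", "eq"),
        ),
        chain_atoms=(_O6,),
        anomeric_sign=+1, config_sign=-1,
    ),
    "FUC": SugarChem(
        code="FUC", full_name="alpha-L-fucose",
        ring_atoms=_HEX_RING, anomeric_carbon="C1", anomeric_position=1,
        anomeric_oxygen="O1", anomer="alpha", dl="L", chair_theta=180.0,
        minimal_conformer="1C4", snfg_shape="triangle", snfg_color=_RED,
        # axial/equatorial labels refer to the canonical 1C4 chair of the
        # L-sugar (mirror image of alpha-D-galactose minus O6).
        ring_substituents=(
            ("O1", "C1", "ax"), ("O2", "C2", "eq"), ("O3", "C3", "eq"),
            ("O4", "C4", "ax"), ("C6", "C5", "eq"),
        ),
        chain_atoms=(),
        anomeric_sign=+1, config_sign=+1,
    ),
    "SIA": SugarChem(
        code="SIA", full_name="alpha-N-acetylneuraminic acid",
        ring_atoms=("O6", "C2", "C3", "C4", "C5", "C6"),
        anomeric_carbon="C2", anomeric_position=2,
        anomeric_oxygen="O2", anomer="alpha", dl=None, chair_theta=180.0,
        minimal_conformer="2C5", snfg_shape="diamond", snfg_color=_PURPLE,
        ring_substituents=(
            ("O2", "C2", "ax"), ("C1", "C2", "eq"), ("O4", "C4", "eq"),
        ),
        chain_atoms=(),
        anomeric_sign=+1, config_sign=None,
    ),
}

SUGAR_CODES = frozenset(MONOSACCHARIDES)

#: Validated linkage taxonomy: every code with enough survey data to score.
SUPPORTED_LINKAGE_CODES = frozenset(
    {
        "NAG-ASN",
        "NAG-1,4-NAG",
        "BMA-1,4-NAG",
        "MAN-1,3-BMA",
        "MAN-1,6-BMA",
        "MAN-1,2-MAN",
        "MAN-1,3-MAN",
        "MAN-1,6-MAN",
        "FUC-1,3-NAG",
        "FUC-1,6-NAG",
        "NAG-1,2-MAN",
        "GAL-1,4-NAG",
        "SIA-2,6-GAL",
    }
)
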