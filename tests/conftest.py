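"""Shared fixtures: synthetic glycans, concentrated databases, corpora."""

from __future__ import annotations

import numpy as np
import pytest

from glycovalid import (
    CurationPolicy,
    GlycanSpec,
    ResidueSpec,
    build_database,
    make_glycan,
)
from glycovalid.synthetic import make_database


@pytest.fixture
def pentasaccharide_spec() -> GlycanSpec:
    """ASN <- NAG <- NAG <- BMA (<- MAN-1,3, <- MAN-1,6): the common core."""
    return GlycanSpec(
        structure_id="core5",
        residues=[
            ResidueSpec("NAG", None, 0, phi=-97.0, psi=178.0),
            ResidueSpec("NAG", 0, 4, phi=-80.0, psi=-130.0),
            ResidueSpec("BMA", 1, 4, phi=-87.0, psi=-133.0),
            ResidueSpec("MAN", 2, 3, phi=76.0, psi=121.0),
            ResidueSpec("MAN", 2, 6, phi=72.0, psi=168.0, omega=60.0),
        ],
    )


@pytest.fixture
def pentasaccharide(pentasaccharide_spec):
    return make_glycan(pentasaccharide_spec)


#: generating cluster (mean phi, mean psi, sigma, n) per linkage type,
#: centred on the survey's modal conformations
CORE_CLUSTERS = {
    "NAG-ASN": (-97.0, 178.0, 8.0, 1000),
    "NAG-1,4-NAG": (-80.0, -130.0, 8.0, 1000),
    "BMA-1,4-NAG": (-87.0, -133.0, 8.0, 1000),
    "MAN-1,3-BMA": (76.0, 121.0, 8.0, 1000),
    "MAN-1,6-BMA": (72.0, 168.0, 8.0, 1000),
    "MAN-1,2-MAN": (78.0, 132.0, 8.0, 1000),
}


@pytest.fixture(scope="session")
def concentrated_db():
    """Database with tight clusters at the core-glycan modal torsions."""
    return make_database(CORE_CLUSTERS, seed=20210801)
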