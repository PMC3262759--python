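import numpy as np
import pytest

from tfdnabench.synthetic_fixtures import (
    build_bdna,
    build_peptide,
    place_with_contacts,
)

DNA16 = "ACGTACGTACGTACGT"
PEP18 = "NQSDNQSDNQSDNQSDNQ"


@pytest.fixture(scope="session")
def duplex16():
    return build_bdna(DNA16)


@pytest.fixture(scope="session")
def helix18():
    return build_peptide(PEP18, "helix")


@pytest.fixture(scope="session")
def complex_k5(duplex16, helix18):
    """Single peptide engineered to exactly 5 sidechain-base contacts."""
    return place_with_contacts(helix18, duplex16, k=5, seed=2)


@pytest.fixture(scope="session")
def homodimer_complex(duplex16):
    """Two identical peptides on opposite faces, 6 + 6 engineered contacts."""
    comp = place_with_contacts(build_peptide(PEP18, "helix", chain_id="A"),
                               duplex16, k=6, seed=5)
    comp = place_with_contacts(build_peptide(PEP18, "helix", chain_id="B"),
                               comp, k=6, seed=6, azimuth=np.pi)
    return comp
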