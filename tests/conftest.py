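import pytest

from pairdia import make_pair


@pytest.fixture(scope="session")
def l858r_pair():
    """2+ light/heavy pair of the kinase-domain point-mutant peptide."""
    return make_pair("ITDFGRAK", 2)


@pytest.fixture(scope="session")
def elre_pair():
    """2+ light/heavy pair of the exon-19-region wild-type peptide."""
    return make_pair("ELREATSPK", 2)
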