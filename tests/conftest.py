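import logging

import pytest

import reesfel as rf

# the optimizer logs a clip warning per candidate; keep test output readable
logging.getLogger("reesfel").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg():
    return rf.ModelConfig()


@pytest.fixture(scope="session")
def p38_ligand():
    """Fitted AG1478 photophysics in the p38α kinase complex."""
    return rf.P38A_LIGAND


@pytest.fixture(scope="session")
def aph_ligand():
    """Fitted AG1478 photophysics in the APH complex."""
    return rf.APH_LIGAND


@pytest.fixture(scope="session")
def p38_fel():
    return rf.P38A_FEL


@pytest.fixture(scope="session")
def aph_fel():
    return rf.APH_FEL


@pytest.fixture(scope="session")
def fig_ligand():
    """Simulation-family ligand (slightly different rounding than the
    fitted case-study values)."""
    return rf.LigandPhotophysics(x_ct=0.89, dg_ctgs0=3.346, dg_ctgsn=3.223)


@pytest.fixture(scope="session")
def fixtures():
    """Reconstructed noiseless case-study datasets."""
    return rf.make_reference_fixtures()


@pytest.fixture(scope="session")
def p38_sigmoid(fixtures):
    data, _, _ = fixtures["p38a"]
    return rf.fit_sigmoid(data)


@pytest.fixture(scope="session")
def aph_sigmoid(fixtures):
    data, _, _ = fixtures["aph"]
    return rf.fit_sigmoid(data)
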