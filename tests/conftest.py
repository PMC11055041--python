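import pytest

from toxforge import gen_molecules, load_paper_tables


@pytest.fixture(scope="session")
def molecule_set():
    """30 deterministic, valid, whitelist-compliant molecules."""
    return gen_molecules(30, seed=11)


@pytest.fixture(scope="session")
def paper_tables():
    return load_paper_tables()
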