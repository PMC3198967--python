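import pytest

from ychap import load_table2


@pytest.fixture(scope="session")
def table2():
    """The packaged 10-haplotype, 87-male composite haplotype table."""
    return load_table2()


@pytest.fixture()
def table2_text():
    """Raw text of the packaged fixture, for parser round-trip tests."""
    from importlib import resources

    return (resources.files("ychap.data") / "table2.tsv").read_text()
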