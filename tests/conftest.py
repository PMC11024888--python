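import pytest

from gslprof.structures import (
    AcylChain,
    LongChainBase,
    assemble_structure,
    build_database,
    default_headgroup_catalog,
    enumerate_ceramides,
)


@pytest.fixture(scope="session")
def catalog():
    """Default headgroup catalog keyed by name."""
    return {hg.name: hg for hg in default_headgroup_catalog()}


@pytest.fixture(scope="session")
def make_structure(catalog):
    """Assemble a structure from (headgroup name, LCB name, acyl name)."""

    def _make(head: str, lcb: str, acyl: str):
        return assemble_structure(
            catalog[head], LongChainBase.parse(lcb), AcylChain.parse(acyl)
        )

    return _make


@pytest.fixture(scope="session")
def default_db(catalog):
    """The full default search-space database (18 headgroups x 325 ceramides)."""
    return build_database(list(catalog.values()), enumerate_ceramides())
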