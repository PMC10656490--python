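import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    """The shipped registry: 20 canonical residues + 12 stock mAAs."""
    from pepsol.registry import default_registry

    return default_registry()


@pytest.fixture(scope="session")
def scales():
    from pepsol.registry import default_scales

    return default_scales()


@pytest.fixture(scope="session")
def calibrators():
    from pepsol.registry import default_calibrators

    return default_calibrators()


@pytest.fixture(scope="session")
def pka_table():
    from pepsol.chem import load_pka_table

    return tuple(load_pka_table())


@pytest.fixture(scope="session")
def fixture_peptides():
    """The 37 shipped validation peptides as (header, ParsedPeptide)."""
    from pepsol.parser import load_fixture_peptides

    return load_fixture_peptides()


@pytest.fixture(scope="session")
def descriptor_rows():
    from pepsol.registry import canonical_descriptor_rows

    return canonical_descriptor_rows()
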