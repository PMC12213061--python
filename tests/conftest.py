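import pytest

from mockforge.strain_registry import StrainRecord, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def ecoli(registry):
    return registry["NBRC 3301"]


@pytest.fixture(scope="session")
def ldelbrueckii(registry):
    return registry["NBRC 3202"]


@pytest.fixture
def toy_record():
    return StrainRecord(
        name="Toyus exampli",
        strain_id="TOY 1",
        genome_size_bp=1_000_000,
        gc_fraction=0.5,
        rrs_copies=1,
    )
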