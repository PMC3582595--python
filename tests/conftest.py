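import pytest

from cnvmir.network import CnvAnnotation, RegulatoryNetwork
from cnvmir.synthetic import SyntheticConfig, generate_bundle, write_bundle


@pytest.fixture
def toy_network() -> RegulatoryNetwork:
    """m1 -> {g1, g2}, m2 -> {g2}: one exclusive and one mixed gene under cnv={m1}."""
    return RegulatoryNetwork(
        families={"m1", "m2"},
        genes={"g1", "g2"},
        edges={("m1", "g1"), ("m1", "g2"), ("m2", "g2")},
    )


@pytest.fixture
def toy_cnv() -> CnvAnnotation:
    return CnvAnnotation(cnv_families={"m1"})


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale synthetic world shared across tests (seed 7)."""
    return generate_bundle(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    """The same world written to disk in the formats the readers consume."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(default_bundle, outdir)
    return paths
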