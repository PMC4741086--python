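import pytest

from divadj import build_adjusted, estimate_singletons, load_virome


@pytest.fixture(scope="session")
def swine():
    """Pooled contig-spectrum counts of seven swine fecal viromes."""
    return load_virome("swine_feces")


@pytest.fixture(scope="session")
def reclaimed():
    """Pooled contig-spectrum counts of four reclaimed-water viromes."""
    return load_virome("reclaimed_water")


@pytest.fixture(scope="session")
def swine_adj(swine):
    return build_adjusted(swine, estimate_singletons(swine).f1_hat)


@pytest.fixture(scope="session")
def reclaimed_adj(reclaimed):
    return build_adjusted(reclaimed, estimate_singletons(reclaimed).f1_hat)
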