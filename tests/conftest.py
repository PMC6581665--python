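import pytest

from karyoinfer import load_reference_karyotypes, match_homologs


@pytest.fixture(scope="session")
def reference_profiles():
    """The packaged published summaries: n5 (5 chromosomes) and n6 (6)."""
    return load_reference_karyotypes()


@pytest.fixture(scope="session")
def n5(reference_profiles):
    return reference_profiles["n5"]


@pytest.fixture(scope="session")
def n6(reference_profiles):
    return reference_profiles["n6"]


@pytest.fixture(scope="session")
def reference_matching(n5, n6):
    return match_homologs(n5, n6, threshold=3.0)
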