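import warnings

import pytest

import aromakey as ak

warnings.filterwarnings(
    "ignore", message="class .* has fewer than 2 observations")


@pytest.fixture(scope="session")
def fixture_data():
    """The deterministic study-shaped bundle and its planted truth."""
    return ak.paper_fixture()


@pytest.fixture(scope="session")
def fixture_bundle(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_truth(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fixture_result(fixture_bundle):
    """Full pipeline output on the deterministic bundle (computed once)."""
    return ak.run_pipeline(fixture_bundle)


@pytest.fixture
def tiny_library():
    return [
        ak.CompoundLibraryEntry("guaiacol", "phenol", ref_ri=1860.0,
                                odor_threshold=1.1,
                                odor_descriptor="smoky, woody"),
        ak.CompoundLibraryEntry("2,3-butanedione", "ketone", ref_ri=980.0,
                                odor_threshold=1.4,
                                odor_descriptor="strong butter, yoghurt"),
        ak.CompoundLibraryEntry("1-octen-3-ol", "alcohol", ref_ri=1450.0,
                                odor_threshold=6.7,
                                odor_descriptor="mushroom"),
        ak.CompoundLibraryEntry("mystery", "other", ref_ri=1200.0,
                                odor_threshold=None, odor_descriptor=""),
    ]


@pytest.fixture
def simple_ladder():
    return ak.AlkaneLadder(entries=tuple(
        (n, 5.0 + 3.0 * (n - 7)) for n in range(7, 21)))
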