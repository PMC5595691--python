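import pytest
from hypothesis import settings

from agerank.conservation import AlignedFamily

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from agerank.fixtures import generate_fixtures
from agerank.grantham import AminoAcidSimilarityMatrix


@pytest.fixture(scope="session")
def matrix() -> AminoAcidSimilarityMatrix:
    return AminoAcidSimilarityMatrix.load()


@pytest.fixture()
def toy_family() -> AlignedFamily:
    """Five-member family; reference carries one internal gap."""
    return AlignedFamily(
        family_id="FAMTOY",
        ref_id="REF",
        aligned_seqs={
            "REF": "AC-DEFGHIK",
            "WORM1": "ACLDEFGHIK",
            "WORM2": "ACLDE-GHIK",
            "FLY1": "ACLDEYGHIK",
            "MOUSE1": "ACLDEFGHIK",
        },
        species_of={
            "REF": "hsapiens",
            "WORM1": "celegans",
            "WORM2": "celegans",
            "FLY1": "dmelanogaster",
            "MOUSE1": "mmusculus",
        },
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One small synthetic input set shared by IO/pipeline tests."""
    out = tmp_path_factory.mktemp("fixtures") / "run"
    raw = generate_fixtures(out, seed=7, n_families=5, n_compounds=20)
    return out, raw
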