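import pytest

from setsig.genesets import GeneSet, GeneSetLibrary
from setsig.synthetic_data import PlantedDesign


@pytest.fixture
def tiny_library():
    return GeneSetLibrary(
        name="tiny",
        sets=[
            GeneSet.from_symbols("S1", ["A", "B", "C"]),
            GeneSet.from_symbols("S2", ["C", "D"]),
            GeneSet.from_symbols("S3", ["E", "F", "G", "H"]),
        ],
    )


@pytest.fixture
def small_design():
    """Scaled-down planted design used across module tests."""
    return PlantedDesign(
        universe_size=2000,
        disease_set_size=200,
        test_set_size=300,
        planted_overlap=80,
        n_regulators=20,
        targets_per_regulator=100,
        shared_regulators=3,
        seed=11,
    )
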