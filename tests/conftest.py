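import pytest

from stereobind import (
    SyntheticLibraryConfig,
    generate_library,
    standardize_molecule,
)

# the two penicillamine enantiomers: a classic single-stereocentre pair
PENICILLAMINE_S = "CC(C)(S)[C@@H](N)C(=O)O"
PENICILLAMINE_R = "CC(C)(S)[C@H](N)C(=O)O"


@pytest.fixture(scope="session")
def penicillamine_records():
    return (
        standardize_molecule("pen_S", PENICILLAMINE_S),
        standardize_molecule("pen_R", PENICILLAMINE_R),
    )


@pytest.fixture(scope="session")
def small_library():
    """A mixed library: 1-3 stereocentres, some undefined entries."""
    cfg = SyntheticLibraryConfig(
        n_families=40,
        stereocenters_per_family=(1, 3),
        isomers_per_family=(2, 3),
        stereo_sensitivity=0.05,
        undefined_fraction=0.15,
        seed=7,
    )
    return generate_library(cfg)


@pytest.fixture(scope="session")
def single_center_library():
    """Enantiomer-pair-only library: the 1-(1-p)^T closed form is exact here."""
    cfg = SyntheticLibraryConfig(
        n_families=150,
        stereocenters_per_family=(1, 1),
        isomers_per_family=(2, 2),
        stereo_sensitivity=0.05,
        undefined_fraction=0.0,
        seed=11,
    )
    return generate_library(cfg)
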