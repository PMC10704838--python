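import numpy as np
import pytest

from capimorph.io import RunConfig
from capimorph.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small two-group cohort for fast pipeline/round-trip tests."""
    return CohortSpec(
        group_names=("A", "B"),
        group_sizes=(2, 2),
        cf_true=(1.6, 1.4),
        mcsfa_true=(3000.0, 2800.0),
        type2b_atrophy_factor=(1.0, 0.5),
        type2b_atrophy_fraction=(0.0, 0.5),
        cbm_mean=(300.0, 340.0),
        cbm_sd=(40.0, 40.0),
        cells_per_10hpf_mean={"CD68": (30.0, 50.0), "CD169": (15.0, 35.0)},
        capillaries_per_sample_range=(5, 8),
        seed=11,
        fibers_per_scene=60,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_config(tiny_spec) -> RunConfig:
    cfg = RunConfig(seed=11, cohort=tiny_spec, fov_size_um=120.0, n_fov=4)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def study_cohort():
    """Three-group cohort at reduced scene size, study-like design."""
    spec = CohortSpec(seed=5, fibers_per_scene=120, group_sizes=(3, 3, 4))
    return spec, generate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
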