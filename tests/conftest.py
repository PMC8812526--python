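import numpy as np
import pytest

from wmhresample import (
    LesionVolumeModel,
    PhantomParams,
    generate_cohort,
    generate_subject,
)


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    """Small, fast phantom geometry used across the suite."""
    return PhantomParams(
        grid_shape=(24, 24, 24),
        voxel_dims=(2.0, 2.0, 2.0),
        n_paired=4,
        n_external=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return generate_cohort(tiny_params, LesionVolumeModel())


@pytest.fixture(scope="session")
def tiny_subject(tiny_params):
    """One deterministic subject with a 1 ml lesion."""
    return generate_subject(
        tiny_params, 1.0, "sub-xxxx", "BL", np.random.default_rng(5)
    )
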