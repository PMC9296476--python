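import pytest

from hdacscope.core import KineticParams, martinostat_frame_schedule
from hdacscope.synthetic_data import (
    PhantomSpec,
    RegionSpec,
    make_phantom,
    simulate_reference_tac,
)


@pytest.fixture(scope="session")
def schedule():
    return martinostat_frame_schedule()


@pytest.fixture(scope="session")
def ref_tac(schedule):
    """Bi-exponential reference curve: fast wash-in, slow washout."""
    return simulate_reference_tac(schedule, A1=50.0, lambda1_per_s=4e-4, lambda2_per_s=0.02)


@pytest.fixture(scope="session")
def three_region_spec():
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        voxel_size_mm=2.0,
        regions=(
            RegionSpec(1, (2, 2, 2), (6, 6, 6), "target"),
            RegionSpec(2, (14, 14, 14), (6, 6, 6), "reference_white_matter"),
            RegionSpec(3, (2, 14, 14), (6, 6, 6), "target"),
        ),
    )


@pytest.fixture(scope="session")
def three_region_map(three_region_spec):
    return make_phantom(three_region_spec)


@pytest.fixture(scope="session")
def kinetic_truth():
    """Per-label SRTM parameters used in roundtrip phantoms."""
    return {1: KineticParams(0.8, 0.10, 0.5), 3: KineticParams(1.2, 0.12, 0.3)}
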