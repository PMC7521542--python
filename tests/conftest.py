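import numpy as np
import pytest

from sgrnet import BoldTimeSeries, standardize
from sgrnet.simulate import make_cohort


@pytest.fixture
def toy_ts() -> BoldTimeSeries:
    """4 volumes x 3 ROIs; column 2 is exactly 2x column 1."""
    return BoldTimeSeries(
        data=np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 1.0], [3.0, 6.0, 1.0], [4.0, 8.0, 0.0]]),
        subject_id="toy",
    )


@pytest.fixture
def std_ts() -> BoldTimeSeries:
    """Standardized random 30 x 6 series (fixed seed)."""
    rng = np.random.default_rng(0)
    return standardize(BoldTimeSeries(rng.standard_normal((30, 6)), subject_id="rand"))


@pytest.fixture(scope="session")
def null_cohort():
    """Two-group cohort with no planted effect (both groups share the truth).

    Uses the generator's standard conditions (20 ROIs in 4 modules, 150
    volumes) so edge features have realistic dimensionality."""
    return make_cohort(
        n_per_group=10, n_rois=20, n_modules=4, t_volumes=150,
        n_planted=0, effect_size=0.0, seed=21,
    )
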