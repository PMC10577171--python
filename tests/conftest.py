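import numpy as np
import pytest

from radioseg import CohortMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_cohort(fc, sf2, sample_prefix="S", marker_prefix="M"):
    fc = np.asarray(fc, dtype=float)
    n, m = fc.shape
    return CohortMatrix(
        sample_ids=tuple(f"{sample_prefix}{i}" for i in range(n)),
        marker_ids=tuple(f"{marker_prefix}{j}" for j in range(m)),
        fc=fc,
        sf2=np.asarray(sf2, dtype=float),
    )


@pytest.fixture
def toy_cohort():
    """Six samples, three markers; marker M0 tracks SF2 exactly."""
    sf2 = np.array([0.15, 0.22, 0.28, 0.33, 0.40, 0.46])
    fc = np.column_stack([
        sf2,
        -sf2,
        np.array([0.1, -0.2, 0.05, 0.3, -0.1, 0.0]),
    ])
    return make_cohort(fc, sf2)


@pytest.fixture
def linear_cohort(rng):
    """60 samples: sf2 = 0.3 + 0.25*FC(M0) + noise; 9 null markers."""
    n = 60
    x = rng.normal(0.0, 0.2, n)
    noise = rng.normal(0.0, 0.01, n)
    sf2 = 0.3 + 0.25 * x + noise
    fc = np.column_stack([x] + [rng.normal(0.0, 0.2, n) for _ in range(9)])
    return make_cohort(fc, sf2)
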