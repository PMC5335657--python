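import numpy as np
import pytest

from longisel import FeatureMatrix, SimulationSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_feature_matrix(values: np.ndarray) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    s, f = values.shape
    return FeatureMatrix(
        values,
        subject_ids=[f"sub{i:03d}" for i in range(s)],
        feature_names=[f"roi{j:03d}" for j in range(f)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Quick cohort reused by pipeline tests: S=50, F=30, T=3, C=2."""
    return generate(
        SimulationSpec(
            n_subjects=50,
            n_features=30,
            support_size=5,
            n_timepoints=3,
            noise_sd=0.5,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default-dimension cohort (S=200, F=93, T=4, C=2)."""
    return generate(SimulationSpec(seed=11))
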