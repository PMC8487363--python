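import numpy as np
import pytest

from gradoffset import CohortSpec, LongitudinalDataset, generate_cohort


def make_spec(
    n_progressor=25,
    n_stable=25,
    n_markers=3,
    dt=0.5,
    slope_progressor=-0.05,
    slope_stable=-0.01,
    coupling=None,
    subject_slope_sd=0.1,
    noise_sd=0.0,
    baseline=(0.8, 1.0),
    seed=0,
):
    """Unit-scale cohort spec with zero coupling unless given."""
    N = n_markers
    if coupling is None:
        coupling = np.zeros((N, N))
    return CohortSpec(
        n_progressor=n_progressor,
        n_stable=n_stable,
        n_markers=N,
        dt=dt,
        slope_progressor=slope_progressor,
        slope_stable=slope_stable,
        coupling_matrix=np.asarray(coupling, float),
        subject_slope_sd=subject_slope_sd,
        noise_sd=noise_sd,
        baseline_ranges=np.column_stack([np.full(N, baseline[0]), np.full(N, baseline[1])]),
        seed=seed,
    )


@pytest.fixture
def spec_factory():
    return make_spec


@pytest.fixture
def mu3():
    """A fixed well-conditioned 3x3 coupling matrix."""
    return np.random.default_rng(7).uniform(-0.3, 0.3, (3, 3))


@pytest.fixture
def coupled_noiseless(mu3):
    """Noiseless cohort whose second-interval offsets are exactly mu3-coupled."""
    spec = make_spec(coupling=mu3, subject_slope_sd=0.1, noise_sd=0.0, seed=11)
    return generate_cohort(spec), spec


def dataset_from_values(values, labels, dt=0.5):
    """Hand-built dataset: values is (n_subjects, n_markers, n_visits)."""
    values = np.asarray(values, float)
    n, N = values.shape[:2]
    return LongitudinalDataset(
        subject_ids=tuple(f"s{i}" for i in range(n)),
        labels=np.asarray(labels, int),
        values=values,
        dt=dt,
        marker_ids=tuple(f"m{j}" for j in range(N)),
    )


@pytest.fixture
def tiny_dataset():
    return dataset_from_values
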