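import numpy as np
import pytest

from lungtau.phantom import (
    PhantomSpec,
    generate_parameter_fields,
    render_sequence,
)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(24, 24, 24), n_phases=13, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_parameter_fields(small_spec)


@pytest.fixture(scope="session")
def small_seq(small_truth, small_spec):
    return render_sequence(small_truth, small_spec)


@pytest.fixture(scope="session")
def small_noiseless_seq(small_truth, small_spec):
    spec0 = PhantomSpec(grid_shape=(24, 24, 24), n_phases=13, seed=42, noise_sigma_hu=0.0)
    return render_sequence(small_truth, spec0)


@pytest.fixture(scope="session")
def small_grid(small_spec):
    return small_spec.phase_grid(end_insp_index=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
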