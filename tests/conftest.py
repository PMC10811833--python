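import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctinpaint import (
    NetworkSpec,
    PhantomSpec,
    TrainConfig,
    apply_mask,
    generate_dataset,
    make_truncation_mask,
    train,
)

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    from ctinpaint.phantom import generate_phantom

    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def small_spec():
    """64x64 phantom spec on the same 384 mm field of view."""
    return PhantomSpec(grid_size=64, pixel_spacing=6.0)


@pytest.fixture(scope="session")
def smoke_run(small_spec):
    """One scaled-down adversarial training run shared by the training and
    ranking checks: 64x64 grid, quarter-width channels, 64 training + 8
    held-out phantoms, 60 epochs, fixed seed."""
    n_train, n_test = 64, 8
    data = generate_dataset(small_spec, n_train + n_test, seed=123)
    mask = make_truncation_mask(64, 18, 18)
    train_set = [(s.to_normalized01(), mask) for s, _ in data[:n_train]]
    state = train(train_set, NetworkSpec(base_channels=0.25),
                  TrainConfig(epochs=60, seed=7))
    return {
        "state": state,
        "mask": mask,
        "train": data[:n_train],
        "test": data[n_train:],
    }
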