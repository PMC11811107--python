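import numpy as np
import pytest

import wingmorph as wm


@pytest.fixture(scope="session")
def base_template():
    return wm.builtin_template("base_wing")


@pytest.fixture(scope="session")
def widened_template():
    return wm.builtin_template("widened_cell")


@pytest.fixture(scope="session")
def two_group_dataset(base_template, widened_template):
    """A/B dataset at the between-species scale (n = 23 + 24, sigma 0.03)."""
    spec = wm.SyntheticSpec(
        templates={"A": base_template, "B": widened_template},
        n_per_group={"A": 23, "B": 24},
        noise_sigma=0.03,
        seed=424242,
    )
    return wm.simulate_labeled(spec)


@pytest.fixture(scope="session")
def aligned_two_group(two_group_dataset):
    return wm.gpa(two_group_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_shape(rng, k=7):
    """A non-degenerate random landmark configuration."""
    while True:
        shape = rng.normal(size=(k, 2))
        centered = shape - shape.mean(axis=0)
        if np.sqrt((centered**2).sum()) > 0.5:
            return shape
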