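import numpy as np
import pytest

import tcifollow as tf


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced cohort (6 subjects, 2+2 trials) reused by analysis tests."""
    pop = tf.PopulationSpec(n_subjects=6, trials_per_condition=2, master_seed=11)
    return tf.simulate_experiment(pop)


@pytest.fixture(scope="session")
def default_experiment():
    """One full-size default cohort (18 subjects, 4+4 trials)."""
    return tf.simulate_experiment(tf.PopulationSpec(master_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
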