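import numpy as np
import pytest

import lethaldose as ld


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the default two-strain shoulder design."""
    return ld.simulate_dataset(ld.default_config(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    return ld.fit_penalized_nb(default_dataset)


@pytest.fixture(scope="session")
def default_boot(default_dataset, default_fit):
    return ld.parametric_bootstrap(
        default_dataset, default_fit, levels=(0.5, 0.1), n_boot=60, seed=2024
    )


@pytest.fixture(scope="session")
def flat_dataset():
    """Counts identical at every dose: no dose effect at all."""
    import pandas as pd

    rows = []
    for strain in ("A", "B"):
        for exp in ("e1", "e2"):
            for dose in (0.0, 1.0, 5.0, 10.0, 20.0, 40.0):
                rows.append((strain, exp, dose, 50.0))
    frame = pd.DataFrame(rows, columns=["strain", "experiment", "dose", "count"])
    return ld.ToleranceDataset(frame, dose_unit="min", stress_name="none")


@pytest.fixture(scope="session")
def flat_fit(flat_dataset):
    return ld.fit_penalized_nb(flat_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
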