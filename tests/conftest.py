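import numpy as np
import pytest

from dnrs import SweepConfig, canonical_network, generate_sweep, run_sweep_detection


@pytest.fixture()
def small_matrix():
    from dnrs import ExpressionMatrix

    return ExpressionMatrix(
        ["G1", "G2", "G3"],
        np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.5, 1.5, 2.5, 0.5]]),
        "t0",
    )


@pytest.fixture(scope="session")
def canonical_spec():
    return canonical_network()


@pytest.fixture(scope="session")
def single_trial_sweep(canonical_spec):
    """One seeded stochastic sweep of the 18-node fixture (100 cells/stage)."""
    series, ppi, truth = generate_sweep(
        canonical_spec, SweepConfig(n_trials=1, n_cells_per_stage=100, seed=7)
    )
    return series, ppi, truth


@pytest.fixture(scope="session")
def averaged_sweep():
    """Trial-averaged pipeline run at validation scale: 10 trials x 100 cells."""
    return run_sweep_detection(
        cfg=SweepConfig(n_trials=10, n_cells_per_stage=100, seed=1)
    )
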