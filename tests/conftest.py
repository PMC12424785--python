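import numpy as np
import pytest

from fishsleep import GeneratorConfig, generate_cohort
from fishsleep.pipeline import fit_cohort
from fishsleep.types import HMMParameters

# canonical wild-type-like generating model (ascending rates: S2, S1, W1, W2)
WT_RATES = np.array([0.02, 1.14, 3.82, 7.53])
WT_STICKY_T = np.array(
    [
        [0.90, 0.06, 0.03, 0.01],
        [0.08, 0.78, 0.07, 0.07],
        [0.09, 0.09, 0.72, 0.10],
        [0.01, 0.04, 0.15, 0.80],
    ]
)


@pytest.fixture(scope="session")
def wt_params() -> HMMParameters:
    return HMMParameters(
        initial_probs=np.full(4, 0.25),
        transition_matrix=WT_STICKY_T,
        rates=WT_RATES,
    )


@pytest.fixture(scope="session")
def wt_cohort():
    """Small baseline cohort with ground-truth states (no fitting needed)."""
    return generate_cohort(GeneratorConfig(n_animals=8, seed=11))


@pytest.fixture(scope="session")
def fitted_wt_cohort(wt_cohort):
    """Per-animal 4-state fits of the baseline cohort (reduced restarts)."""
    fits, seqs = fit_cohort(wt_cohort.traces, K=4, n_restarts=5, seed=202)
    return wt_cohort, fits, seqs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_params(rng: np.random.Generator, K: int) -> HMMParameters:
    T = np.stack([rng.dirichlet(np.ones(K)) for _ in range(K)])
    return HMMParameters(
        initial_probs=rng.dirichlet(np.ones(K)),
        transition_matrix=T,
        rates=rng.uniform(0.1, 8.0, K),
    )
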