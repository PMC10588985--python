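import numpy as np
import pytest

from phasecoh.model import (
    ExperimentLayout,
    ModelParams,
    PriorConfig,
    simulate_dataset,
)
from phasecoh.inference import sample_posterior


def logit(s):
    return np.log(s) - np.log1p(-s)


def recovery_params(layout: ExperimentLayout, condition_R, seed,
                    sigma=0.2) -> ModelParams:
    """Hierarchically plausible parameters with known condition-level R."""
    rng = np.random.default_rng(seed)
    P, C, E = layout.n_participants, layout.n_conditions, layout.n_electrodes
    angles = rng.uniform(-np.pi, np.pi, (P, C, E))
    return ModelParams(
        alpha=logit(1.0 - np.asarray(condition_R, dtype=float)),
        beta=rng.standard_normal((P, C)) * sigma,
        delta=rng.standard_normal((C, E)) * sigma,
        mu_xy=np.stack([np.cos(angles), np.sin(angles)], axis=-1),
        sigma_beta=np.full(C, sigma), corr_beta=np.eye(C),
        sigma_delta=np.full(C, sigma), nu=30.0)


@pytest.fixture(scope="session")
def standard_layout():
    return ExperimentLayout(8, 2, 8, 20, condition_labels=("strong", "weak"))


@pytest.fixture(scope="session")
def standard_dataset(standard_layout):
    """Strong-signal two-condition fixture: true R = {0.4, 0.1}."""
    params = recovery_params(standard_layout, [0.4, 0.1], seed=7)
    return simulate_dataset(params, standard_layout, seed=11, frequency=1.5625)


@pytest.fixture(scope="session")
def standard_fit(standard_dataset):
    """One shared posterior fit of the standard fixture (reused across tests
    to keep the suite fast)."""
    return sample_posterior(standard_dataset, PriorConfig(), chains=2,
                            iterations=1200, seed=3, target_accept=0.85)
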