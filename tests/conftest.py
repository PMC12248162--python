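"""Shared fixtures: synthetic datasets and the expensive fitted models.

The replicate fits and bootstrap fits are session-scoped because several
test modules interrogate the same fitted models (parameter recovery,
monotonicity, likelihood ascent, fit quality).
"""

from __future__ import annotations

import numpy as np
import pytest

from mavecal.calibration import estimate_prior
from mavecal.dataio import build_sample_set
from mavecal.mixture import SampleSet, fit
from mavecal.synthetic import GeneratorConfig, generate

#: study conditions for the recovery experiments: the generator defaults
#: (components at -3/0, w_P=0.9, w_B=0.05, implied prior 0.1, 2000/sample)
N_RECOVERY_REPLICATES = 20
RECOVERY_RESTARTS = 10


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate(default_config)


@pytest.fixture(scope="session")
def default_samples(default_dataset) -> SampleSet:
    dataset, _ = default_dataset
    return build_sample_set(dataset)


@pytest.fixture(scope="session")
def recovery_fits():
    """20 replicate (truth, samples, fit) triples under the default generator."""
    out = []
    for rep in range(N_RECOVERY_REPLICATES):
        config = GeneratorConfig(seed=1000 + rep)
        dataset, truth = generate(config)
        samples = build_sample_set(dataset)
        model = fit(samples, n_restarts=RECOVERY_RESTARTS, seed=rep)
        out.append((truth, samples, model))
    return out


@pytest.fixture(scope="session")
def bootstrap_fits(default_samples):
    """50 stratified-bootstrap refits of the default dataset (reduced restarts)."""
    labeled = dict(default_samples.items())
    fits = []
    for i in range(50):
        rng = np.random.default_rng(5000 + i)
        boot = SampleSet(
            scores_plp=labeled["P"][rng.integers(0, labeled["P"].size, labeled["P"].size)],
            scores_blb=labeled["B"][rng.integers(0, labeled["B"].size, labeled["B"].size)],
            scores_ref=labeled["G"][rng.integers(0, labeled["G"].size, labeled["G"].size)],
            scores_syn=labeled["S"][rng.integers(0, labeled["S"].size, labeled["S"].size)],
        )
        fits.append((boot, fit(boot, n_restarts=RECOVERY_RESTARTS, seed=i)))
    return fits


@pytest.fixture(scope="session")
def recovery_priors(recovery_fits):
    return np.array([estimate_prior(model).value for _, _, model in recovery_fits])
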