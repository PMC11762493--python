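"""Shared fixtures: the reference synthetic cohort and its trained models.

The fixture cohort is the package's standard test bed: four severity-1
archetypes, 30 instances each, T = 100 (120 x 600 tensor), seed 0, with
per-feature z-scoring before the network.  Heavy artefacts (pretrained and
jointly trained models) are session-scoped so many tests share one run.
"""

import numpy as np
import pytest

from dtcgait import (
    build_tensor,
    make_archetypes,
    sample_cohort,
    standardize_tensor,
)
from dtcgait.temporal_autoencoder import TAE, TAEConfig, mse_loss, pretrain
from dtcgait.temporal_clustering import DTCConfig, train

#: joint-training epochs used for fixture-cohort runs (loss plateaus well
#: before this at N = 120; the config default remains 600)
FIXTURE_EPOCHS = 120


@pytest.fixture(scope="session")
def fixture_cohort():
    specs = make_archetypes(4, severity=1.0, seed=0)
    return sample_cohort(specs, n_per_cluster=30, T=100, seed=0)


@pytest.fixture(scope="session")
def fixture_tensor(fixture_cohort):
    return standardize_tensor(build_tensor(fixture_cohort.instances))


@pytest.fixture(scope="session")
def pretrained(fixture_tensor):
    cfg = TAEConfig(seed=0)
    untrained = TAE(cfg, fixture_tensor.matrix.shape[1])
    _, xhat = untrained.forward(fixture_tensor.matrix)
    init_loss = mse_loss(fixture_tensor.matrix, xhat.data)
    model, history = pretrain(fixture_tensor, cfg)
    return {"model": model, "history": history, "init_loss": init_loss,
            "config": cfg}


@pytest.fixture(scope="session")
def trained_k4(fixture_tensor, pretrained):
    model = TAE(pretrained["config"], fixture_tensor.matrix.shape[1])
    model.load_state_dict(pretrained["model"].state_dict())
    contract_log = []

    def watch(epoch, Q, P):
        contract_log.append(
            (
                float(np.abs(Q.sum(axis=1) - 1).max()),
                float(np.abs(P.sum(axis=1) - 1).max()),
                float(Q.min()),
            )
        )

    result = train(
        fixture_tensor,
        model,
        DTCConfig(K=4, epochs=FIXTURE_EPOCHS, seed=0),
        epoch_callback=watch,
    )
    return {"result": result, "contract_log": contract_log}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
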