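"""Shared fixtures: small cohorts and a quickly trained model.

Session scope keeps expensive simulation/training out of individual
tests; everything is fully seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from cgvae import CohortParams, ModelConfig, simulate_cohort, prepare_graphs
from cgvae.training import make_splits, train_model


SMALL_PARAMS = CohortParams(n_subjects=40, n_timepoints=150, seed=202)


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects with the default planted effects; cheap to simulate."""
    records, sex_mask, fi_mask = simulate_cohort(SMALL_PARAMS)
    return records, sex_mask, fi_mask


@pytest.fixture(scope="session")
def study_cohort():
    """Default-size cohort (600 subjects, planted effects 0.6 on 30 edges)."""
    records, sex_mask, fi_mask = simulate_cohort(CohortParams(seed=11))
    return records, sex_mask, fi_mask


@pytest.fixture(scope="session")
def small_graphs(small_cohort):
    records, _, _ = small_cohort
    return prepare_graphs(records, "sex", 0.1)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(
        encoder_type="gatv2", encoder_hidden=16, encoder_layers=2, heads=2,
        decoder_hidden=16, decoder_layers=2, latent_dim=8, dropout=0.1,
    )


@pytest.fixture(scope="session")
def tiny_trained(small_cohort, tiny_config):
    """A small model trained for a few epochs on the 40-subject cohort."""
    records, _, _ = small_cohort
    plan = make_splits([r.subject_id for r in records], test_frac=0.2,
                       n_splits=1, val_frac=0.15, seed=5)
    by_id = {r.subject_id: r for r in records}
    tr_ids, va_ids = plan.splits[0]
    tr = prepare_graphs([by_id[i] for i in tr_ids], "sex", 0.1)
    va = prepare_graphs([by_id[i] for i in va_ids], "sex", 0.1)
    te = prepare_graphs([by_id[i] for i in plan.test_ids], "sex", 0.1)
    model, history = train_model(tr, va, tiny_config, epochs=4,
                                 batch_size=8, seed=5)
    return {
        "model": model,
        "history": history,
        "plan": plan,
        "train": tr,
        "val": va,
        "test": te,
        "test_records": [by_id[i] for i in plan.test_ids],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
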