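"""Shared fixtures: small synthetic datasets reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from leida_eeg import phase, states, synth

RECOVERY_SEED = 11  # fixed once for the planted-state recovery fixtures


@pytest.fixture(scope="session")
def recovery_dataset() -> synth.SyntheticDataset:
    """12 subjects, 8 channels, 3 planted states at default noise."""
    cfg = synth.SyntheticConfig(
        n_subjects=12,
        n_channels=8,
        n_samples=8000,
        n_states=3,
        seed=RECOVERY_SEED,
    )
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_analysis(recovery_dataset):
    """Eigenvector series, pooled matrix, and k=3 model for the recovery set."""
    ds = recovery_dataset
    eigs, dpls, truths = [], [], {}
    n_edge = int(round(ds.config.sampling_rate / ds.config.carrier_freq))
    for ep in ds.epochs:
        eig, dpl = phase.epoch_to_eigenvectors(
            ep, carrier_freq=ds.config.carrier_freq, decimation=25
        )
        eigs.append(eig)
        dpls.append(dpl)
        planted = ds.true_state_sequence[(ep.subject_id, ep.condition)]
        truths[(ep.subject_id, ep.condition)] = planted[n_edge:-n_edge][dpl.time_index]
    pool = states.pool_eigenvectors(eigs)
    model = states.cluster_eigenvectors(pool, k=3, n_init=10, seed=0)
    return {
        "dataset": ds,
        "eigs": eigs,
        "dpls": dpls,
        "truths": truths,
        "pool": pool,
        "model": model,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def pooled_truth(analysis) -> np.ndarray:
    """Planted labels in the same row order as the pooled eigenvectors."""
    order = sorted(analysis["eigs"], key=lambda e: (e.subject_id, e.condition))
    return np.concatenate(
        [analysis["truths"][(e.subject_id, e.condition)] for e in order]
    )
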