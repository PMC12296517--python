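import numpy as np
import pytest

import plvnet


@pytest.fixture(scope="session")
def tiny_config() -> plvnet.CohortConfig:
    """A 2+2-subject, 5-trials-per-side cohort configuration."""
    return plvnet.CohortConfig(n_per_group=2, n_trials_per_side=5, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return plvnet.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_connectivity(tiny_cohort):
    """Full-epoch theta connectivity of the first simulated subject."""
    epochs, _ = tiny_cohort[0]
    return plvnet.subject_connectivity(epochs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def make_connectivity(rplv, labels=None, t0=0.0, dt=5.0):
    """Build a Connectivity carrying a prescribed pairwise rPLV field.

    ``rplv`` is n_pairs x n_samples over the unordered pairs (i < j,
    row-major) of ``labels`` (default: the 31 ROI electrodes).
    """
    from plvnet.connectivity import Connectivity

    rplv = np.asarray(rplv, float)
    labels = tuple(labels) if labels is not None else plvnet.DEFAULT_ROI_MAP.electrodes
    n_ch = len(labels)
    iu = np.triu_indices(n_ch, k=1)
    pairs = np.column_stack(iu)
    assert rplv.shape[0] == len(pairs)
    n_samp = rplv.shape[1]
    freqs = np.array([4.0, 5.0, 6.0, 7.0])
    return Connectivity(
        pairs=pairs,
        plv=np.zeros((len(pairs), n_samp, freqs.size)),
        baseline=np.full((len(pairs), freqs.size), 0.5),
        rplv=rplv,
        usable=np.ones(len(pairs), bool),
        freqs=freqs,
        times=t0 + np.arange(n_samp) * dt,
        channel_labels=labels,
        baseline_window=(-3700.0, -3200.0),
    )
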