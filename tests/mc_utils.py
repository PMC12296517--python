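"""Shared helpers for Monte-Carlo recovery experiments in the test suite.

The recovery checks run scaled-down cohorts: the study's subject count
(20 per group) but 10 trials per response side, with PLV computed only on
the baseline and post-stimulus analysis windows.
"""

from __future__ import annotations

import numpy as np

import plvnet
from plvnet.config import BASELINE_WINDOW, S1_WINDOW, S2_WINDOW, window_mask
from plvnet.connectivity import subject_connectivity
from plvnet.graphs import summarize_graph
from plvnet.roi import mean_network_rplv

MC_TRIALS_PER_SIDE = 10


def analysis_sample_mask(config: plvnet.CohortConfig) -> np.ndarray:
    times = config.time_axis
    return (
        window_mask(times, BASELINE_WINDOW)
        | window_mask(times, S1_WINDOW)
        | window_mask(times, S2_WINDOW)
    )


def cohort_window_metrics(config: plvnet.CohortConfig) -> dict[str, np.ndarray]:
    """Per-subject post-stimulus metrics for one simulated cohort.

    Returns arrays over subjects: group label, network-average rPLV and
    binary global efficiency after S1, efficiency after S2, mean filtered
    reaction time, and the 21-dimensional post-S1/post-S2 feature vectors.
    """
    mask = analysis_sample_mask(config)
    cohort = plvnet.generate_cohort(config)
    group, rplv_s1, eglob_s1, eglob_s2, mean_rt = [], [], [], [], []
    feats_s1, feats_s2 = [], []
    for epochs, behavior in cohort:
        conn = subject_connectivity(epochs, sample_mask=mask)
        group.append(epochs.group)
        rplv_s1.append(mean_network_rplv(conn, S1_WINDOW))
        eglob_s1.append(summarize_graph(conn, window=S1_WINDOW).e_glob)
        eglob_s2.append(summarize_graph(conn, window=S2_WINDOW).e_glob)
        for store, win in ((feats_s1, S1_WINDOW), (feats_s2, S2_WINDOW)):
            am = plvnet.area_adjacency(conn, window=win, subject_id=epochs.subject_id)
            store.append(am.feature_vector)
        rt = behavior.trials["rt_ms"].to_numpy(float)
        ok = np.isfinite(rt) & (rt > 150.0) & (rt < 1500.0)
        mean_rt.append(float(rt[ok].mean()))
    return {
        "group": np.array(group),
        "rplv_s1": np.array(rplv_s1),
        "eglob_s1": np.array(eglob_s1),
        "eglob_s2": np.array(eglob_s2),
        "mean_rt": np.array(mean_rt),
        "feats_s1": np.array(feats_s1),
        "feats_s2": np.array(feats_s2),
    }


def mc_config(seed: int, deficit: float, **kw) -> plvnet.CohortConfig:
    return plvnet.CohortConfig(
        n_per_group=20,
        n_trials_per_side=MC_TRIALS_PER_SIDE,
        seed=seed,
        group_deficit_s1=deficit,
        **kw,
    )
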