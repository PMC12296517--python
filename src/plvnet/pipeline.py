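"""End-to-end study orchestration on a cohort of epoch sets.

``run_study`` chains the full analysis — per-subject rPLV connectivity,
area networks, graph metrics, multivariate group comparison, and the
statistical layer — and returns a single result object with tidy tables.
Individual stages remain importable for piecemeal use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_ROI_MAP,
    S1_WINDOW,
    S2_WINDOW,
    THETA_FREQS,
    CohortConfig,
    RoiMap,
)
from .connectivity import Connectivity, subject_connectivity
from .graphs import summarize_graph
from .multivariate import (
    ClassificationResult,
    GroupNetworkTimecourse,
    NetworkPca,
    euclidean_timecourse,
    lda_cv_classify,
    network_pca,
)
from .roi import area_feature_timecourse, mean_network_rplv
from .config import window_mask
from .simulate import BehavioralRecord, EpochSet, generate_cohort
from .stats import (
    GroupComparison,
    RegressionResult,
    behavioral_summary,
    efficiency_rt_regression,
    fdr_adjust,
    mann_whitney_compare,
)

__all__ = ["SubjectNetworks", "StudyResult", "analyze_subject", "run_study"]

_WINDOWS = {"s1": S1_WINDOW, "s2": S2_WINDOW}


@dataclass
class SubjectNetworks:
    """Everything the group-level stages need from one subject."""

    subject_id: str
    group: str
    feature_timecourse: np.ndarray  # samples x 21
    times: np.ndarray
    mean_rplv: dict[str, float]  # window name -> network-average rPLV
    e_glob: dict[str, float]
    clustering: dict[str, float]
    features: dict[str, np.ndarray]  # window name -> 21-vector


def analyze_subject(
    epochs: EpochSet,
    roi: RoiMap = DEFAULT_ROI_MAP,
    freqs=THETA_FREQS,
    n_cycles: float = 5.0,
    graph_mode: str = "binary",
    windows: dict[str, tuple[float, float]] | None = None,
) -> SubjectNetworks:
    """Connectivity, area features, and graph metrics for one subject."""
    windows = dict(_WINDOWS if windows is None else windows)
    conn: Connectivity = subject_connectivity(epochs, freqs=freqs, n_cycles=n_cycles)
    feats_t = area_feature_timecourse(conn, roi)
    mean_rplv, e_glob, clustering, features = {}, {}, {}, {}
    for name, win in windows.items():
        mean_rplv[name] = mean_network_rplv(conn, win)
        gs = summarize_graph(conn, roi, win, mode=graph_mode, subject_id=epochs.subject_id)
        e_glob[name] = gs.e_glob
        clustering[name] = gs.clustering
        mask = window_mask(conn.times, win)
        features[name] = feats_t[mask].mean(axis=0)
    return SubjectNetworks(
        subject_id=epochs.subject_id,
        group=epochs.group,
        feature_timecourse=feats_t,
        times=conn.times,
        mean_rplv=mean_rplv,
        e_glob=e_glob,
        clustering=clustering,
        features=features,
    )


@dataclass
class StudyResult:
    """Aggregated outputs of a full synthetic-cohort analysis."""

    subject_table: pd.DataFrame
    area_table: pd.DataFrame
    behavior_table: pd.DataFrame
    contrasts: dict[str, GroupComparison]
    distance: GroupNetworkTimecourse
    pca: NetworkPca
    classification: dict[str, ClassificationResult] = field(default_factory=dict)
    regressions: dict[str, RegressionResult] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Study summary", "=============", ""]
        for name, c in self.contrasts.items():
            g1, g2 = list(c.median)
            lines.append(
                f"{name}: {g1} Mdn={c.median[g1]:.3f} IQR={c.iqr[g1]:.3f} | "
                f"{g2} Mdn={c.median[g2]:.3f} IQR={c.iqr[g2]:.3f} | "
                f"U={c.u:.1f} Z={c.z:.2f} p={c.p:.4f} r={c.r:.2f}"
                + (f" p_fdr={c.p_fdr:.4f}" if c.p_fdr is not None else "")
            )
        if self.classification:
            lines.append("")
            for name, res in self.classification.items():
                lines.append(f"LDA {name}: mean accuracy {100 * res.mean_accuracy:.1f}%")
        if self.regressions:
            lines.append("")
            for name, r in self.regressions.items():
                lines.append(
                    f"OLS {name}: slope={r.slope:.1f} R2={r.r_squared:.3f} "
                    f"F({r.df[0]},{r.df[1]})={r.f_stat:.2f} p={r.p:.4f}"
                    + (f" p_fdr={r.p_fdr:.4f}" if r.p_fdr is not None else "")
                )
        return "\n".join(lines)


def run_study(
    cohort: list[tuple[EpochSet, BehavioralRecord]] | None = None,
    config: CohortConfig | None = None,
    seed: int | None = None,
    roi: RoiMap = DEFAULT_ROI_MAP,
    freqs=THETA_FREQS,
    n_cycles: float = 5.0,
    graph_mode: str = "binary",
    classify: bool = True,
    n_folds: int = 100,
    k_features: int = 10,
) -> StudyResult:
    """Run the full pipeline on a cohort (simulated if not supplied).

    Group contrasts (network-average rPLV, global efficiency, clustering;
    post-S1 and post-S2 windows) are FDR-adjusted as one family.  The
    efficiency–RT regressions are fit per group and window and FDR-adjusted
    as their own family.  Classification (unshuffled and shuffled
    surrogate) runs per window on the 21-feature subject vectors.
    """
    if cohort is None:
        config = config or CohortConfig()
        cohort = generate_cohort(config, seed=seed)
    seed = 0 if seed is None else seed

    rows, behav_rows, area_rows = [], [], []
    nets: list[SubjectNetworks] = []
    cells = [
        (roi.area_names[a], roi.area_names[b])
        for a in range(roi.n_areas)
        for b in range(a, roi.n_areas)
    ]
    for epochs, behavior in cohort:
        sn = analyze_subject(epochs, roi, freqs, n_cycles, graph_mode)
        nets.append(sn)
        perf = behavioral_summary(behavior)
        rt_all = behavior.trials["rt_ms"].to_numpy(float)
        ok = np.isfinite(rt_all) & (rt_all > 150.0) & (rt_all < 1500.0)
        mean_rt = float(rt_all[ok].mean()) if ok.any() else np.nan
        for wname in sn.mean_rplv:
            rows.append(
                {
                    "subject": sn.subject_id,
                    "group": sn.group,
                    "window": wname,
                    "mean_rplv": sn.mean_rplv[wname],
                    "e_glob": sn.e_glob[wname],
                    "clustering": sn.clustering[wname],
                    "mean_rt": mean_rt,
                    "accuracy_pct": perf.accuracy_pct,
                    "anticipatory": perf.anticipatory_count,
                }
            )
        for wname, feats in sn.features.items():
            for (ai, aj), val in zip(cells, feats):
                area_rows.append(
                    {
                        "subject": sn.subject_id,
                        "group": sn.group,
                        "window": wname,
                        "area_i": ai,
                        "area_j": aj,
                        "rplv": float(val),
                    }
                )
        behav_rows.append(
            {
                "subject": perf.subject_id,
                "group": behavior.group,
                "median_rt_left": perf.median_rt["left"],
                "median_rt_right": perf.median_rt["right"],
                "accuracy_pct": perf.accuracy_pct,
                "anticipatory": perf.anticipatory_count,
            }
        )
    table = pd.DataFrame(rows)
    behavior_table = pd.DataFrame(behav_rows)

    groups = ("TS", "CO")
    contrasts: dict[str, GroupComparison] = {}
    for metric in ("mean_rplv", "e_glob", "clustering"):
        for wname in _WINDOWS:
            sel = table[table["window"] == wname]
            a = sel.loc[sel["group"] == groups[0], metric].to_numpy()
            b = sel.loc[sel["group"] == groups[1], metric].to_numpy()
            contrasts[f"{metric}_{wname}"] = mann_whitney_compare(a, b, groups)
    adj = fdr_adjust([c.p for c in contrasts.values()])
    for c, q in zip(contrasts.values(), adj):
        c.p_fdr = float(q)

    feats_by_group = {
        g: np.stack([sn.feature_timecourse for sn in nets if sn.group == g])
        for g in groups
    }
    distance = euclidean_timecourse(feats_by_group, nets[0].times)
    pca = network_pca({g: feats_by_group[g].mean(axis=0) for g in groups})

    classification: dict[str, ClassificationResult] = {}
    if classify:
        y = np.array([sn.group for sn in nets])
        for wname in _WINDOWS:
            X = np.stack([sn.features[wname] for sn in nets])
            classification[wname] = lda_cv_classify(
                X, y, n_folds=n_folds, k_features=k_features, seed=seed
            )
            classification[f"{wname}_shuffled"] = lda_cv_classify(
                X, y, n_folds=n_folds, k_features=k_features, shuffle=True, seed=seed
            )

    regressions: dict[str, RegressionResult] = {}
    for g in groups:
        for wname in _WINDOWS:
            sel = table[(table["group"] == g) & (table["window"] == wname)]
            for outcome in ("mean_rt", "accuracy_pct", "anticipatory"):
                key = f"{g}_{wname}_{outcome}"
                regressions[key] = efficiency_rt_regression(
                    sel["e_glob"].to_numpy(), sel[outcome].to_numpy()
                )
    adj = fdr_adjust([r.p for r in regressions.values()])
    for r, q in zip(regressions.values(), adj):
        r.p_fdr = float(q)

    return StudyResult(
        subject_table=table,
        area_table=pd.DataFrame(area_rows),
        behavior_table=behavior_table,
        contrasts=contrasts,
        distance=distance,
        pca=pca,
        classification=classification,
        regressions=regressions,
    )
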