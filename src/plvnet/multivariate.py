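"""Group-level multivariate comparison of network timecourses.

Three complementary views of group separation in the 21-dimensional area
feature space: the time-resolved Euclidean distance between group-mean
networks, d(t) = ||A_TS(t) − A_CO(t)||₂, with within-group dispersion;
PCA of the standardized concatenated group-average networks; and a
100-fold cross-validated LDA classification of subjects with a
shuffled-label surrogate control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import f_classif

from .roi import features_to_matrix

__all__ = [
    "GroupNetworkTimecourse",
    "NetworkPca",
    "ClassificationResult",
    "euclidean_timecourse",
    "network_pca",
    "lda_cv_classify",
]


@dataclass
class GroupNetworkTimecourse:
    """Euclidean separation of group-mean networks over time."""

    times: np.ndarray
    mean_a: np.ndarray  # samples x n_features, first group's mean network
    mean_b: np.ndarray
    d: np.ndarray  # samples, ||mean_a - mean_b||_2
    var_within: dict[str, np.ndarray]  # group -> per-sample variance of
    # each subject's distance to the group-mean network
    groups: tuple[str, str] = ("TS", "CO")


@dataclass
class NetworkPca:
    """PCA of standardized, concatenated group-average network vectors."""

    explained_ratio: np.ndarray
    components: np.ndarray  # n_components x n_features (standardized space)
    scores: dict[str, np.ndarray]  # group -> samples x n_components
    kept_features: np.ndarray  # indices of features with nonzero variance
    mean_: np.ndarray
    scale_: np.ndarray

    def component_matrix(self, k: int = 0, n_areas: int = 6) -> np.ndarray:
        """Eigenvector ``k`` reshaped to the symmetric area adjacency."""
        full = np.zeros(n_areas * (n_areas + 1) // 2)
        full[self.kept_features] = self.components[k]
        return features_to_matrix(full, n_areas)


@dataclass
class ClassificationResult:
    """Cross-validated LDA accuracies (one entry per fold)."""

    fold_accuracies: np.ndarray
    selected_features: list[np.ndarray]
    shuffled: bool
    seed: int
    test_subjects: list[tuple] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


def euclidean_timecourse(
    features_by_group: dict[str, np.ndarray], times: np.ndarray
) -> GroupNetworkTimecourse:
    """Time-resolved distance between group-mean networks.

    ``features_by_group`` maps each of the two group labels to an array
    ``subjects x samples x n_features``.  ``d(t)`` is the Euclidean norm of
    the difference of the group means; the within-group series is the
    variance, across subjects, of each subject's Euclidean distance to the
    group-mean vector at that sample.
    """
    if len(features_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, fa), (gb, fb) = features_by_group.items()
    fa, fb = np.asarray(fa, float), np.asarray(fb, float)
    if fa.shape[2] != fb.shape[2] or fa.shape[1] != fb.shape[1]:
        raise ValueError("feature arrays must share samples and feature length")
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    mean_a = fa.mean(axis=0)
    mean_b = fb.mean(axis=0)
    d = np.linalg.norm(mean_a - mean_b, axis=1)
    var_within = {}
    for g, f, m in ((ga, fa, mean_a), (gb, fb, mean_b)):
        dist = np.linalg.norm(f - m[None], axis=2)  # subjects x samples
        var_within[g] = dist.var(axis=0, ddof=1)
    return GroupNetworkTimecourse(
        times=np.asarray(times), mean_a=mean_a, mean_b=mean_b, d=d,
        var_within=var_within, groups=(ga, gb),
    )


def network_pca(
    mean_by_group: dict[str, np.ndarray], n_components: int | None = None
) -> NetworkPca:
    """PCA of the concatenated group-average network timecourses.

    The group-mean feature vectors (``samples x n_features`` per group) are
    stacked across groups, mean-centered and scaled to unit variance using
    the pooled concatenated data, and decomposed; per-sample component
    scores are reported separately per group.  Zero-variance features
    cannot be scaled and are dropped with a warning.
    """
    groups = list(mean_by_group)
    mats = [np.asarray(mean_by_group[g], float) for g in groups]
    X = np.vstack(mats)
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    mean_ = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance feature(s) from PCA",
            RuntimeWarning,
            stacklevel=2,
        )
    Z = (X[:, kept] - mean_[kept]) / sd[kept]
    pca = PCA(n_components=n_components)
    pca.fit(Z)
    scores = {}
    for g, m in zip(groups, mats):
        zg = (m[:, kept] - mean_[kept]) / sd[kept]
        scores[g] = pca.transform(zg)
    return NetworkPca(
        explained_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        scores=scores,
        kept_features=kept,
        mean_=mean_,
        scale_=sd,
    )


def lda_cv_classify(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 100,
    k_features: int = 10,
    shuffle: bool = False,
    seed: int = 0,
) -> ClassificationResult:
    """Cross-validated LDA of subjects from connectivity feature vectors.

    Each of ``n_folds`` folds holds out one randomly chosen subject per
    class (two test subjects, keeping chance at exactly 50%).  The training
    set is z-scored by its own mean/SD, the ``k_features`` features with the
    highest one-way ANOVA F on the training data are selected (ties broken
    toward the lower feature index), and a linear discriminant
    (least-squares solver with a 1e-6 shrinkage ridge) is fit and scored on
    the held-out pair.  With ``shuffle=True`` the training labels are
    permuted within each fold (surrogate control; expected accuracy ~50%).
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be subjects x n_features matching labels")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if k_features > X.shape[1]:
        raise ValueError("k_features exceeds the number of features")
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    root = np.random.SeedSequence(seed)
    fold_seeds = root.spawn(n_folds)

    accs = np.empty(n_folds)
    selected: list[np.ndarray] = []
    held_out: list[tuple] = []
    for k in range(n_folds):
        rng = np.random.default_rng(fold_seeds[k])
        test_idx = np.array([rng.choice(ids) for ids in idx_by_class])
        train_mask = np.ones(X.shape[0], bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        Xte, yte = X[test_idx], y[test_idx]
        if shuffle:
            ytr = rng.permutation(ytr)
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Ztr = (Xtr - mu) / sd
        Zte = (Xte - mu) / sd
        with np.errstate(divide="ignore", invalid="ignore"):
            F, _ = f_classif(Ztr, ytr)
        F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
        order = np.argsort(-F, kind="stable")[:k_features]
        sel = np.sort(order)
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Ztr[:, sel], ytr)
        accs[k] = float(np.mean(clf.predict(Zte[:, sel]) == yte))
        selected.append(sel)
        held_out.append(tuple(test_idx))
    return ClassificationResult(
        fold_accuracies=accs,
        selected_features=selected,
        shuffled=shuffle,
        seed=seed,
        test_subjects=held_out,
    )
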