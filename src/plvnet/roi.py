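"""Area-level network construction from pairwise rPLV.

Channel-pair connectivity is aggregated into a symmetric 6x6 area
adjacency: diagonal cells average all unordered electrode pairs within an
area, off-diagonal cells average all cross-area electrode pairs.  The 21
unique entries (6 diagonal + 15 upper triangle), enumerated row-major over
the upper triangle including the diagonal, form the feature vector used by
the multivariate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_ROI_MAP, RoiMap, window_mask
from .connectivity import Connectivity

__all__ = [
    "AreaMatrix",
    "feature_index_pairs",
    "matrix_to_features",
    "features_to_matrix",
    "pair_cell_index",
    "area_feature_timecourse",
    "area_adjacency",
    "subwindows",
    "mean_network_rplv",
]


def feature_index_pairs(n_areas: int = 6) -> list[tuple[int, int]]:
    """Fixed enumeration of the unique cells: row-major upper triangle incl. diagonal."""
    return [(a, b) for a in range(n_areas) for b in range(a, n_areas)]


def matrix_to_features(matrix: np.ndarray) -> np.ndarray:
    """Extract the unique entries of a symmetric area matrix (length 21 for 6 areas)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(m.shape[0])
    return m[iu]


def features_to_matrix(features: np.ndarray, n_areas: int = 6) -> np.ndarray:
    """Inverse of :func:`matrix_to_features` (lossless round trip)."""
    feats = np.asarray(features, dtype=float)
    if feats.size != n_areas * (n_areas + 1) // 2:
        raise ValueError("feature vector length does not match n_areas")
    out = np.zeros((n_areas, n_areas))
    iu = np.triu_indices(n_areas)
    out[iu] = feats
    out.T[iu] = feats
    return out


@dataclass
class AreaMatrix:
    """Symmetric area-level adjacency for one subject and time window."""

    subject_id: str
    window: tuple[float, float]
    matrix: np.ndarray
    area_names: tuple[str, ...]

    @property
    def feature_vector(self) -> np.ndarray:
        return matrix_to_features(self.matrix)


def pair_cell_index(
    pairs: np.ndarray, channel_labels, roi: RoiMap
) -> tuple[np.ndarray, np.ndarray]:
    """Map each channel pair to its area cell.

    Returns ``(cell_ids, counts)``: for every pair the flat index of its
    cell in the feature enumeration, and the number of electrode pairs per
    cell.  Raises if a channel label is not in the ROI map.
    """
    cells = feature_index_pairs(roi.n_areas)
    cell_of = {c: k for k, c in enumerate(cells)}
    area_idx = np.array([roi.area_index(channel_labels[i]) for i in range(len(channel_labels))])
    ai = area_idx[pairs[:, 0]]
    aj = area_idx[pairs[:, 1]]
    lo, hi = np.minimum(ai, aj), np.maximum(ai, aj)
    cell_ids = np.array([cell_of[(a, b)] for a, b in zip(lo, hi)])
    counts = np.bincount(cell_ids, minlength=len(cells))
    if np.any(counts == 0):
        bad = [cells[k] for k in np.flatnonzero(counts == 0)]
        raise ValueError(f"area cell(s) with no electrode pairs: {bad}")
    return cell_ids, counts


def area_feature_timecourse(conn: Connectivity, roi: RoiMap = DEFAULT_ROI_MAP) -> np.ndarray:
    """Per-sample area feature vectors, shape ``samples x 21``.

    Each sample's pairwise rPLV field is averaged into the 21 unique area
    cells.  Pure pair-averaging: time-averaging a window of this timecourse
    equals building the windowed :func:`area_adjacency` directly.
    """
    sub = [conn.channel_labels.index(lab) for lab in roi.electrodes]
    sub_set = set(sub)
    keep = np.array(
        [k for k, (i, j) in enumerate(conn.pairs) if i in sub_set and j in sub_set]
    )
    pairs = conn.pairs[keep]
    cell_ids, counts = pair_cell_index(pairs, conn.channel_labels, roi)
    rplv = conn.rplv[keep]  # pairs x samples
    if np.isnan(rplv).any():
        raise ValueError("unusable pairs present; cannot aggregate areas")
    n_cells = counts.size
    sums = np.zeros((n_cells, rplv.shape[1]))
    np.add.at(sums, cell_ids, rplv)
    return (sums / counts[:, None]).T


def area_adjacency(
    conn: Connectivity,
    roi: RoiMap = DEFAULT_ROI_MAP,
    window: tuple[float, float] = (0.0, 500.0),
    subject_id: str = "",
) -> AreaMatrix:
    """Windowed 6x6 area adjacency: time-average rPLV, then pair-average per cell."""
    mask = window_mask(conn.times, window)
    feats_t = area_feature_timecourse(conn, roi)
    feats = feats_t[mask].mean(axis=0)
    return AreaMatrix(
        subject_id=subject_id,
        window=tuple(window),
        matrix=features_to_matrix(feats, roi.n_areas),
        area_names=roi.area_names,
    )


def subwindows(window: tuple[float, float], n: int) -> list[tuple[float, float]]:
    """Split a half-open ms window into ``n`` contiguous equal subwindows."""
    start, end = window
    length = end - start
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(length / n - round(length / n)) > 1e-9:
        raise ValueError(f"window length {length} not divisible into {n} parts")
    step = length / n
    return [(start + k * step, start + (k + 1) * step) for k in range(n)]


def mean_network_rplv(conn: Connectivity, window: tuple[float, float]) -> float:
    """Average rPLV over all channel pairs and all samples in the window."""
    mask = window_mask(conn.times, window)
    vals = conn.rplv[:, mask]
    if np.isnan(vals).any():
        raise ValueError("unusable pairs present in network average")
    return float(vals.mean())
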