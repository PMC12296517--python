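"""Study configuration: ROI montage, analysis windows, and cohort parameters.

The defaults encode the cued reaction-time (CNV) study design this package
analyses: epochs sampled at 200 Hz spanning −3.7 s to +3.0 s around the
imperative stimulus (S2), with the warning stimulus (S1) at −3.2 s, theta-band
(4–7 Hz) connectivity over 31 electrodes grouped into six sensorimotor areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RoiMap",
    "DEFAULT_ROI_MAP",
    "CohortConfig",
    "BASELINE_WINDOW",
    "S1_WINDOW",
    "S2_WINDOW",
    "THETA_FREQS",
    "ALPHA_FREQS",
    "n_epoch_samples",
    "epoch_time_axis",
    "window_mask",
]

#: Pre-stimulus baseline used to normalise PLV into rPLV, ms relative to S2.
BASELINE_WINDOW: tuple[float, float] = (-3700.0, -3200.0)
#: Cue-processing window: 500 ms following the warning stimulus S1.
S1_WINDOW: tuple[float, float] = (-3200.0, -2700.0)
#: Motor preparation/execution window: 500 ms following the imperative stimulus S2.
S2_WINDOW: tuple[float, float] = (0.0, 500.0)

#: Theta band analysed at 1-Hz increments.
THETA_FREQS: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0)
#: Alpha band for the frequency-specificity control analysis.
ALPHA_FREQS: tuple[float, ...] = (8.0, 9.0, 10.0, 11.0, 12.0, 13.0)


class RoiMap:
    """Ordered mapping from cortical areas to their 10-10 electrode labels.

    Areas are disjoint; the default montage defines six areas over 31
    electrodes (DLPFC, SMA/PMA, M1, S1, PPC, POC).
    """

    def __init__(self, areas: Mapping[str, Sequence[str]]):
        self.areas: dict[str, tuple[str, ...]] = {
            name: tuple(labels) for name, labels in areas.items()
        }
        seen: dict[str, str] = {}
        for area, labels in self.areas.items():
            if len(labels) < 2:
                raise ValueError(f"area {area!r} needs >=2 electrodes")
            for lab in labels:
                if lab in seen:
                    raise ValueError(f"electrode {lab!r} in both {seen[lab]!r} and {area!r}")
                seen[lab] = area
        self._area_of = seen

    @property
    def area_names(self) -> tuple[str, ...]:
        return tuple(self.areas)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def electrodes(self) -> tuple[str, ...]:
        """All electrode labels in area order."""
        return tuple(lab for labels in self.areas.values() for lab in labels)

    def area_of(self, label: str) -> str:
        return self._area_of[label]

    def area_index(self, label: str) -> int:
        return self.area_names.index(self._area_of[label])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RoiMap) and self.areas == other.areas

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{a}: {len(e)}" for a, e in self.areas.items())
        return f"RoiMap({inner})"


#: The six-area, 31-electrode montage used throughout the analysis.
DEFAULT_ROI_MAP = RoiMap(
    {
        "DLPFC": ("F5", "F1", "AF3", "AF4", "F2", "F6"),
        "SMA/PMA": ("FC4", "FC2", "FCz", "FC1", "FC3"),
        "M1": ("C5", "C1", "Cz", "C4", "C6"),
        "S1": ("CP3", "CP1", "CPz", "CP2", "CP4"),
        "PPC": ("P3", "P1", "Pz", "P2", "P4"),
        "POC": ("PO1", "PO2", "O1", "Oz", "O2"),
    }
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic two-group cohort.

    The generator produces epoched oscillatory recordings whose pairwise
    phase coupling is controlled by a von-Mises concentration profile:
    ``kappa_base`` everywhere, rising by ``kappa_event`` for
    ``stim_window_ms`` after each stimulus.  The patient group ("TS")
    carries a fractional post-S1 coupling deficit ``group_deficit_s1``.
    Per-subject heterogeneity enters as a multiplicative scale on the
    post-S2 coupling increment, to which reaction times are linearly tied.

    Parameters
    ----------
    n_per_group : subjects per group (TS and CO).
    n_trials_per_side : trials for each response side (left/right).
    fs : sampling rate, Hz.
    epoch_span : epoch start/end in ms relative to S2.
    s1_latency : onset of the warning stimulus S1, ms relative to S2.
    stim_window_ms : duration of elevated coupling after each stimulus, ms.
    kappa_base, kappa_event : baseline and event-added von-Mises
        concentrations of the pairwise phase jitter (dimensionless).
    group_deficit_s1 : fractional reduction of ``kappa_event`` after S1
        for the TS group, in [0, 1].
    noise_exponent : spectral slope of the 1/f background noise.
    snr : oscillation-to-noise RMS amplitude ratio; ``None`` disables noise.
    subject_scale_range : uniform range of the per-subject post-S2
        coupling scale.
    rt_intercept, rt_slope, rt_sigma : linear reaction-time model, ms;
        RT = intercept + slope * subject_scale + N(0, sigma) per trial.
    anticipatory_rate : probability a trial's press lands between S1 and S2.
    accuracy_rate : probability a non-anticipatory press is correct.
    seed : root seed for all randomness.
    """

    n_per_group: int = 20
    n_trials_per_side: int = 50
    fs: float = 200.0
    epoch_span: tuple[float, float] = (-3700.0, 3000.0)
    s1_latency: float = -3200.0
    stim_window_ms: float = 500.0
    roi_map: RoiMap = field(default_factory=lambda: DEFAULT_ROI_MAP)
    kappa_base: float = 0.15
    kappa_event: float = 1.0
    group_deficit_s1: float = 0.5
    noise_exponent: float = 1.0
    snr: float | None = 0.7
    subject_scale_range: tuple[float, float] = (0.6, 1.4)
    rt_intercept: float = 430.0
    rt_slope: float = -100.0
    rt_sigma: float = 120.0
    anticipatory_rate: float = 0.08
    accuracy_rate: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_trials_per_side < 1:
            raise ValueError("n_trials_per_side must be >= 1")
        if self.fs <= 2 * max(THETA_FREQS):
            raise ValueError("fs must exceed twice the highest analysis frequency")
        lo, hi = self.epoch_span
        if not (lo < hi):
            raise ValueError("epoch_span must be increasing")
        if not (lo <= BASELINE_WINDOW[0] and BASELINE_WINDOW[1] <= hi):
            raise ValueError("epoch_span must cover the baseline window")
        if self.kappa_base < 0 or self.kappa_event < 0:
            raise ValueError("kappa values must be >= 0")
        if not (0.0 <= self.group_deficit_s1 <= 1.0):
            raise ValueError("group_deficit_s1 must lie in [0, 1]")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noise-free)")

    def with_(self, **kw) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    @property
    def n_samples(self) -> int:
        return n_epoch_samples(self.epoch_span, self.fs)

    @property
    def time_axis(self) -> np.ndarray:
        return epoch_time_axis(self.epoch_span, self.fs)


def n_epoch_samples(span: tuple[float, float], fs: float) -> int:
    """Number of samples in an epoch spanning ``span`` ms at ``fs`` Hz.

    Inclusive of both endpoints: a 6700-ms epoch at 200 Hz has 1341 samples.
    """
    return int(round((span[1] - span[0]) / 1000.0 * fs)) + 1


def epoch_time_axis(span: tuple[float, float], fs: float) -> np.ndarray:
    """Sample times in ms relative to S2, uniformly spaced at 1000/fs."""
    n = n_epoch_samples(span, fs)
    return span[0] + np.arange(n) * (1000.0 / fs)


def window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples in the half-open window [start, end) ms.

    Half-open intervals keep adjacent subwindows disjoint, so the five
    100-ms subwindows of a 500-ms window partition it exactly.
    """
    start, end = window
    if not start < end:
        raise ValueError("window must be increasing")
    mask = (times >= start) & (times < end)
    if not mask.any():
        raise ValueError(f"window {window} selects no samples")
    return mask
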