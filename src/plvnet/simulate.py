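"""Synthetic two-group cohort of phase-coupled oscillatory epochs.

The generative model is a hierarchy of von-Mises phase jitter around a
shared latent theta oscillator.  Each trial draws a carrier frequency
uniformly in the analysis band and a random starting phase; each cortical
area's oscillator jitters around that carrier, and each electrode jitters
around its area's oscillator.  The jitter concentration follows a
deterministic event profile: ``kappa_base`` at rest, rising by
``kappa_event`` for 500 ms after the warning (S1) and imperative (S2)
stimuli.  Because the phase difference of two electrodes is a sum of
independent von-Mises terms, its across-trial phase-locking value is a
known monotone function of the concentration, which gives every downstream
stage a controllable ground truth.

Group structure: the "TS" group's post-S1 concentration increment is
reduced by the fraction ``group_deficit_s1``.  Subject structure: each
subject carries a multiplicative scale on the post-S2 increment, and
reaction times are a linear function of that scale plus Gaussian noise —
so post-S2 network efficiency and reaction time are coupled by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortConfig, epoch_time_axis

__all__ = [
    "EpochSet",
    "BehavioralRecord",
    "coupling_profile",
    "generate_epoch_set",
    "generate_cohort",
]


@dataclass
class EpochSet:
    """One subject's epoched multichannel recording.

    ``data`` is channels x samples x trials (float32, arbitrary µV-scale
    units); ``time_ms`` is the sample axis in ms relative to S2.
    """

    subject_id: str
    group: str
    data: np.ndarray
    time_ms: np.ndarray
    channel_labels: tuple[str, ...]
    fs: float
    trial_table: pd.DataFrame
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_ch, n_samp, n_tr = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel_labels does not match data")
        if n_samp != len(self.time_ms):
            raise ValueError("time_ms does not match data")
        if n_tr != len(self.trial_table):
            raise ValueError("trial_table does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        """A view-like copy restricted to the given trial indices."""
        return EpochSet(
            self.subject_id,
            self.group,
            self.data[:, :, idx],
            self.time_ms,
            self.channel_labels,
            self.fs,
            self.trial_table.iloc[np.asarray(idx)].reset_index(drop=True),
            dict(self.info),
        )


@dataclass
class BehavioralRecord:
    """Per-trial button-press log for one subject.

    ``trials`` columns: trial, side, rt_ms (NaN when no timed press),
    anticipatory (press between S1 and S2), correct.
    """

    subject_id: str
    group: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        rt = self.trials["rt_ms"].to_numpy(float)
        if np.any(rt[np.isfinite(rt)] < 0):
            raise ValueError("reaction times must be >= 0")


def coupling_profile(
    t: float | np.ndarray, group: str, config: CohortConfig
) -> float | np.ndarray:
    """Von-Mises concentration of the pairwise phase jitter at time ``t``.

    ``t`` is in ms relative to S2.  Outside the two post-stimulus windows
    the concentration is ``kappa_base``; within 500 ms of S1 it is
    ``kappa_base + kappa_event * (1 - group_deficit_s1)`` for the TS group
    (undiminished for CO); within 500 ms of S2 both groups receive the
    full increment.

    Raises ``ValueError`` for any ``t`` outside the epoch span.
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = config.epoch_span
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise ValueError(f"t outside epoch span {config.epoch_span}")
    deficit = config.group_deficit_s1 if group == "TS" else 0.0
    s1 = config.s1_latency
    w = config.stim_window_ms
    kappa = np.full(t_arr.shape, config.kappa_base)
    in_s1 = (t_arr >= s1) & (t_arr < s1 + w)
    in_s2 = (t_arr >= 0.0) & (t_arr < w)
    kappa[in_s1] += config.kappa_event * (1.0 - deficit)
    kappa[in_s2] += config.kappa_event
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(kappa)
    return kappa


def _von_mises(rng: np.random.Generator, kappa: np.ndarray, size: tuple) -> np.ndarray:
    """Zero-mean von-Mises angles; kappa may broadcast; inf means no jitter."""
    kap = np.broadcast_to(kappa, size).copy()
    inf = ~np.isfinite(kap)
    kap[inf] = 1.0
    out = rng.vonmises(0.0, kap, size=size)
    out[inf] = 0.0
    return out


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, exponent: float, fs: float
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with amplitude ~ f**(-exponent/2), unit RMS."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= scale
    noise = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return noise / rms


def generate_epoch_set(
    subject_id: str,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    coupling_scale: float = 1.0,
    trial_table: pd.DataFrame | None = None,
) -> EpochSet:
    """Simulate one subject's epoched recording.

    Per trial, a carrier frequency is drawn uniformly in the theta band and
    all electrodes oscillate at that frequency with hierarchical von-Mises
    phase jitter (area level and electrode level) whose concentration
    follows :func:`coupling_profile`; 1/f background noise is added at the
    configured SNR.  ``coupling_scale`` multiplies the post-S2
    concentration increment (the subject's "injected" post-S2 coupling).

    Deterministic given ``rng``'s state.
    """
    roi = config.roi_map
    labels = roi.electrodes
    if group not in ("TS", "CO"):
        raise ValueError("group must be 'TS' or 'CO'")
    times = epoch_time_axis(config.epoch_span, config.fs)
    n_samp = times.size
    n_ch = len(labels)
    area_idx = np.array([roi.area_index(lab) for lab in labels])
    n_areas = roi.n_areas

    if trial_table is None:
        n_tr = 2 * config.n_trials_per_side
        side = np.array(["left", "right"])[np.arange(n_tr) % 2]
        trial_table = pd.DataFrame(
            {"trial": np.arange(n_tr), "side": side, "valid": True}
        )
    n_tr = len(trial_table)

    # Event-modulated jitter concentration; the post-S2 increment carries the
    # subject's coupling scale.
    kappa_t = np.asarray(coupling_profile(times, group, config), dtype=float)
    if coupling_scale != 1.0:
        in_s2 = (times >= 0.0) & (times < config.stim_window_ms)
        kappa_t[in_s2] = config.kappa_base + coupling_scale * (
            kappa_t[in_s2] - config.kappa_base
        )

    t_sec = (times - times[0]) / 1000.0
    f_n = rng.uniform(4.0, 7.0, size=n_tr)
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=n_tr)
    carrier = 2.0 * np.pi * f_n[:, None] * t_sec[None, :] + phi0[:, None]
    area_jit = _von_mises(rng, kappa_t, (n_tr, n_areas, n_samp))
    elec_jit = _von_mises(rng, kappa_t, (n_tr, n_ch, n_samp))
    phase = carrier[:, None, :] + area_jit[:, area_idx, :] + elec_jit
    data = np.cos(phase).astype(np.float32).transpose(1, 2, 0)
    data = np.ascontiguousarray(data)

    if config.snr is not None and np.isfinite(config.snr):
        osc_rms = 1.0 / np.sqrt(2.0)
        noise = _one_over_f_noise(
            rng, (n_tr, n_ch), n_samp, config.noise_exponent, config.fs
        )
        data += (osc_rms / config.snr) * noise.transpose(1, 2, 0).astype(np.float32)

    return EpochSet(
        subject_id=subject_id,
        group=group,
        data=data,
        time_ms=times,
        channel_labels=labels,
        fs=config.fs,
        trial_table=trial_table,
        info={"coupling_scale": float(coupling_scale)},
    )


def _behavior_for_subject(
    subject_id: str,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    coupling_scale: float,
) -> BehavioralRecord:
    n_tr = 2 * config.n_trials_per_side
    side = np.array(["left", "right"])[np.arange(n_tr) % 2]
    anticipatory = rng.random(n_tr) < config.anticipatory_rate
    correct = (~anticipatory) & (rng.random(n_tr) < config.accuracy_rate)
    mean_rt = config.rt_intercept + config.rt_slope * coupling_scale
    rt = mean_rt + rng.normal(0.0, config.rt_sigma, size=n_tr)
    rt = np.clip(rt, 1.0, None)
    rt[anticipatory] = np.nan
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_tr),
            "side": side,
            "rt_ms": rt,
            "anticipatory": anticipatory,
            "correct": correct,
        }
    )
    return BehavioralRecord(subject_id=subject_id, group=group, trials=trials)


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> list[tuple[EpochSet, BehavioralRecord]]:
    """Simulate the full two-group cohort.

    Returns ``2 * n_per_group`` subjects (TS first), each with
    ``2 * n_trials_per_side`` trials.  All randomness descends from a single
    root seed through per-subject spawned streams, so cohorts are
    bit-reproducible and subjects are independent.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_subjects = 2 * config.n_per_group
    streams = root.spawn(n_subjects)
    cohort: list[tuple[EpochSet, BehavioralRecord]] = []
    k = 0
    for group in ("TS", "CO"):
        for j in range(config.n_per_group):
            rng = np.random.default_rng(streams[k])
            k += 1
            subject_id = f"{group}{j + 1:02d}"
            scale = rng.uniform(*config.subject_scale_range)
            behavior = _behavior_for_subject(subject_id, group, config, rng, scale)
            valid = (
                behavior.trials["correct"]
                & ~behavior.trials["anticipatory"]
                & (behavior.trials["rt_ms"] > 150.0)
                & (behavior.trials["rt_ms"] < 1500.0)
            ).to_numpy()
            trial_table = pd.DataFrame(
                {
                    "trial": behavior.trials["trial"],
                    "side": behavior.trials["side"],
                    "valid": valid,
                }
            )
            epochs = generate_epoch_set(
                subject_id, group, config, rng, coupling_scale=scale,
                trial_table=trial_table,
            )
            cohort.append((epochs, behavior))
    return cohort
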