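"""Time-frequency phase extraction and phase-locking connectivity.

The pipeline is: Morlet wavelet transform (wavelets built with
``mne.time_frequency.morlet``, convolved in one batched FFT pass) →
instantaneous phase per channel/sample/trial/frequency → across-trial
phase-locking value per channel pair → baseline-normalised relative PLV
(rPLV), averaged over the band's 1-Hz bins.

PLV for channels i, j at time t over N trials is the modulus of the
trial-mean unit phasor of their phase difference::

    PLV_ij(t) = | (1/N) * sum_n exp(-i (phi_i(t,n) - phi_j(t,n))) |

rPLV normalises each frequency bin to its own mean PLV over the
pre-stimulus baseline window b̄: rPLV(t) = (PLV(t) - b̄) / b̄.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import morlet as _mne_morlet
from scipy import fft as _sfft

from .config import BASELINE_WINDOW, THETA_FREQS, window_mask
from .simulate import EpochSet

__all__ = [
    "PhaseTensor",
    "PairConnectivity",
    "Connectivity",
    "morlet_phase",
    "plv_timecourse",
    "pairwise_plv",
    "relative_plv",
    "subject_connectivity",
]

#: Baseline PLV below this floor makes a pair's rPLV numerically meaningless.
BASELINE_EPS = 1e-6
#: Amplitude floor below which phase estimates are flagged invalid.
AMPLITUDE_EPS = 1e-10


@dataclass
class PhaseTensor:
    """Instantaneous phase/amplitude of one subject's epochs.

    Arrays are channels x samples x trials x frequencies.  ``valid_mask``
    is False where the amplitude is numerically negligible or where the
    sample lies within half the wavelet support of an epoch edge (the
    zero-padded convolution is unreliable there).
    """

    phase: np.ndarray
    amplitude: np.ndarray
    freqs: np.ndarray
    valid_mask: np.ndarray
    times: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class PairConnectivity:
    """Connectivity of one unordered channel pair (i < j)."""

    pair: tuple[int, int]
    labels: tuple[str, str]
    plv: np.ndarray  # samples x frequencies, in [0, 1]
    baseline_mean: np.ndarray  # per-frequency baseline PLV b̄
    rplv: np.ndarray  # samples, band-averaged
    usable: bool


@dataclass
class Connectivity:
    """All-pairs PLV/rPLV for one subject (dense storage).

    ``pairs`` enumerates the unordered channel pairs (i < j) in row-major
    order; ``plv`` is pairs x samples x frequencies, ``rplv`` is pairs x
    samples (band-averaged).  Pairs whose baseline PLV fell below the
    numeric floor are flagged unusable and carry NaN rPLV.
    """

    pairs: np.ndarray  # n_pairs x 2 channel indices
    plv: np.ndarray
    baseline: np.ndarray  # n_pairs x n_freqs
    rplv: np.ndarray
    usable: np.ndarray  # n_pairs bool
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    baseline_window: tuple[float, float]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair(self, i: int, j: int) -> PairConnectivity:
        """Extract one pair's connectivity (order-insensitive)."""
        if i == j:
            raise ValueError("self-pairs are undefined")
        a, b = (i, j) if i < j else (j, i)
        idx = np.flatnonzero((self.pairs[:, 0] == a) & (self.pairs[:, 1] == b))
        if idx.size == 0:
            raise KeyError((i, j))
        k = int(idx[0])
        return PairConnectivity(
            pair=(a, b),
            labels=(self.channel_labels[a], self.channel_labels[b]),
            plv=self.plv[k],
            baseline_mean=self.baseline[k],
            rplv=self.rplv[k],
            usable=bool(self.usable[k]),
        )


def _wavelets(fs: float, freqs: np.ndarray, n_cycles: float) -> list[np.ndarray]:
    return _mne_morlet(fs, freqs, n_cycles=n_cycles, zero_mean=True)


def morlet_phase(
    epochs: EpochSet,
    freqs=THETA_FREQS,
    n_cycles: float = 5.0,
    dtype=np.complex64,
) -> PhaseTensor:
    """Morlet wavelet phase/amplitude decomposition of an epoch set.

    Complex Morlet wavelets (``n_cycles`` cycles, zero-mean) are convolved
    with every channel x trial signal in a single batched FFT; phase is the
    argument and amplitude the modulus of the analytic coefficient.  Samples
    within half a wavelet's support of either epoch edge, or with amplitude
    below the numeric floor, are flagged invalid in ``valid_mask``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if not np.all(np.diff(freqs) > 0):
        raise ValueError("freqs must be strictly increasing")
    if epochs.fs <= 2 * freqs.max():
        raise ValueError("sampling rate too low for requested frequencies")
    n_ch, n_samp, n_tr = epochs.data.shape
    real_dtype = np.float32 if dtype == np.complex64 else np.float64

    Ws = _wavelets(epochs.fs, freqs, n_cycles)
    max_w = max(len(w) for w in Ws)
    if max_w > n_samp:
        raise ValueError("epoch shorter than the widest wavelet")
    nfft = _sfft.next_fast_len(n_samp + max_w - 1)

    # channels*trials batched convolution, same-mode centering
    x = np.ascontiguousarray(
        epochs.data.transpose(0, 2, 1).reshape(n_ch * n_tr, n_samp)
    ).astype(real_dtype)
    Xf = _sfft.fft(x, nfft, axis=-1)

    phase = np.empty((n_ch, n_samp, n_tr, freqs.size), dtype=real_dtype)
    amplitude = np.empty_like(phase)
    valid = np.ones((n_ch, n_samp, n_tr, freqs.size), dtype=bool)
    for fi, w in enumerate(Ws):
        Wf = _sfft.fft(w.astype(np.complex128), nfft)
        full = _sfft.ifft(Xf * Wf.astype(Xf.dtype), axis=-1)
        start = (len(w) - 1) // 2
        tf = full[:, start : start + n_samp].reshape(n_ch, n_tr, n_samp)
        tf = tf.transpose(0, 2, 1)  # ch, samp, trial
        amp = np.abs(tf)
        amplitude[..., fi] = amp
        with np.errstate(invalid="ignore"):
            ph = np.angle(tf)
        low = amp < AMPLITUDE_EPS
        ph[low] = 0.0
        phase[..., fi] = ph
        half = len(w) // 2
        valid[:, :half, :, fi] = False
        if half > 0:
            valid[:, n_samp - half :, :, fi] = False
        valid[..., fi] &= ~low

    return PhaseTensor(
        phase=phase,
        amplitude=amplitude,
        freqs=freqs,
        valid_mask=valid,
        times=epochs.time_ms,
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
    )


def plv_timecourse(phases_i: np.ndarray, phases_j: np.ndarray) -> np.ndarray:
    """Phase-locking value over trials for one channel pair.

    ``phases_i``/``phases_j`` are ``samples x trials`` (or
    ``samples x trials x frequencies``) phase arrays in radians.  Returns
    PLV per sample (per frequency), in [0, 1]; symmetric in (i, j).
    """
    phases_i = np.asarray(phases_i, dtype=float)
    phases_j = np.asarray(phases_j, dtype=float)
    if phases_i.shape != phases_j.shape:
        raise ValueError("phase arrays must have identical shapes")
    if phases_i.ndim not in (2, 3):
        raise ValueError("expected samples x trials [x frequencies]")
    n_trials = phases_i.shape[1]
    if n_trials < 2:
        raise ValueError("PLV needs at least 2 trials")
    dphi = phases_i - phases_j
    return np.abs(np.mean(np.exp(-1j * dphi), axis=1))


def pairwise_plv(
    tensor: PhaseTensor,
    dtype=np.complex64,
    sample_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PLV for every unordered channel pair.

    Returns ``(pairs, plv)`` where ``pairs`` is n_pairs x 2 (i < j,
    row-major) and ``plv`` is n_pairs x samples x frequencies.  Uses a
    trial-contracted Hermitian product; accumulation dtype is configurable
    (single precision by default — the error is orders of magnitude below
    across-trial sampling noise).  ``sample_mask`` restricts the
    computation to a subset of samples.
    """
    ph = tensor.phase
    if sample_mask is not None:
        ph = ph[:, np.asarray(sample_mask)]
    n_ch, n_samp, n_tr, n_fr = ph.shape
    if n_tr < 2:
        raise ValueError("PLV needs at least 2 trials")
    iu = np.triu_indices(n_ch, k=1)
    pairs = np.column_stack(iu)
    real_dtype = np.float32 if dtype == np.complex64 else np.float64
    u = np.empty(ph.shape, dtype=dtype)
    u.real = np.cos(ph, dtype=real_dtype)
    u.imag = np.sin(ph, dtype=real_dtype)
    plv = np.empty((len(iu[0]), n_samp, n_fr), dtype=real_dtype)
    for fi in range(n_fr):
        uf = u[..., fi]  # ch, samp, trial
        cross = np.einsum("cst,dst->scd", uf, uf.conj(), optimize=True)
        plv[:, :, fi] = np.abs(cross[:, iu[0], iu[1]]).T / n_tr
    np.clip(plv, 0.0, 1.0, out=plv)
    return pairs, plv


def relative_plv(
    plv: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    eps: float = BASELINE_EPS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-normalised, band-averaged relative PLV.

    For each frequency bin, ``rPLV(t) = (PLV(t) - b̄) / b̄`` with ``b̄``
    the mean PLV over the baseline window; the per-bin rPLV is then
    averaged across the band.  Pairs whose ``b̄`` falls below ``eps`` in
    any bin are flagged unusable (rPLV set to NaN) and reported via a
    warning rather than silently divided.

    Accepts ``plv`` of shape ``samples x freqs`` (one pair) or
    ``pairs x samples x freqs``; returns ``(rplv, baseline, usable)`` with
    the pair axis preserved (or absent for a single pair).
    """
    arr = np.asarray(plv, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    mask = window_mask(np.asarray(times), baseline_window)
    baseline = arr[:, mask, :].mean(axis=1)  # pairs x freqs
    usable = np.all(baseline >= eps, axis=1)
    if not usable.all():
        warnings.warn(
            f"{np.count_nonzero(~usable)} pair(s) with baseline PLV below "
            f"{eps:g} excluded from rPLV",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(baseline >= eps, baseline, 1.0)
    rplv = ((arr - safe[:, None, :]) / safe[:, None, :]).mean(axis=2)
    rplv[~usable] = np.nan
    if single:
        return rplv[0], baseline[0], usable[0]
    return rplv, baseline, usable


def subject_connectivity(
    epochs: EpochSet,
    freqs=THETA_FREQS,
    n_cycles: float = 5.0,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    valid_only: bool = True,
    average_sides: bool = True,
    dtype=np.complex64,
    sample_mask: np.ndarray | None = None,
) -> Connectivity:
    """Full per-subject connectivity: Morlet phase → PLV → band rPLV.

    rPLV is computed separately for the left- and right-response conditions
    and then averaged (``average_sides``), mirroring the aggregation used
    before all group statistics; set ``average_sides=False`` to pool trials
    instead.  ``valid_only`` restricts to trials marked valid in the epoch
    set's trial table.  ``sample_mask`` restricts PLV computation to a
    subset of samples (the wavelet transform still sees the full epoch);
    the returned ``times`` axis is subset accordingly.
    """
    table = epochs.trial_table
    keep = table["valid"].to_numpy(bool) if (valid_only and "valid" in table) else np.ones(len(table), bool)
    out_times = epochs.time_ms if sample_mask is None else epochs.time_ms[sample_mask]

    def _one(trial_idx: np.ndarray):
        sub = epochs.select_trials(trial_idx)
        tensor = morlet_phase(sub, freqs=freqs, n_cycles=n_cycles, dtype=dtype)
        return pairwise_plv(tensor, dtype=dtype, sample_mask=sample_mask)

    if average_sides and "side" in table:
        sides = table["side"].to_numpy()
        rplvs, plvs, baselines, usables = [], [], [], []
        pairs = None
        for side in ("left", "right"):
            idx = np.flatnonzero(keep & (sides == side))
            if idx.size < 2:
                continue
            pairs, plv = _one(idx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r, b, u = relative_plv(plv, out_times, baseline_window)
            rplvs.append(r)
            plvs.append(plv)
            baselines.append(b)
            usables.append(u)
        if pairs is None:
            raise ValueError("no condition with >=2 usable trials")
        rplv = np.nanmean(np.stack(rplvs), axis=0)
        plv = np.mean(np.stack(plvs), axis=0)
        baseline = np.mean(np.stack(baselines), axis=0)
        usable = np.any(np.stack(usables), axis=0)
        rplv[~usable] = np.nan
    else:
        idx = np.flatnonzero(keep)
        pairs, plv = _one(idx)
        rplv, baseline, usable = relative_plv(plv, out_times, baseline_window)

    return Connectivity(
        pairs=pairs,
        plv=plv,
        baseline=baseline,
        rplv=rplv,
        usable=usable,
        freqs=np.asarray(freqs, dtype=float),
        times=out_times,
        channel_labels=epochs.channel_labels,
        baseline_window=baseline_window,
    )
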