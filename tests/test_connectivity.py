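"""Morlet phase extraction, PLV, and baseline-normalised rPLV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from mne.time_frequency import tfr_array_morlet

import plvnet
from plvnet.config import ALPHA_FREQS, BASELINE_WINDOW
from plvnet.connectivity import morlet_phase, pairwise_plv, plv_timecourse, relative_plv
from plvnet.simulate import EpochSet


def _epochs_from_array(data: np.ndarray, fs: float = 200.0) -> EpochSet:
    n_ch, n_samp, n_tr = data.shape
    t0 = -3700.0
    return EpochSet(
        subject_id="toy",
        group="CO",
        data=data.astype(np.float32),
        time_ms=t0 + np.arange(n_samp) * 1000.0 / fs,
        channel_labels=tuple(f"ch{i}" for i in range(n_ch)),
        fs=fs,
        trial_table=pd.DataFrame(
            {"trial": np.arange(n_tr), "side": ["left"] * n_tr, "valid": True}
        ),
    )


class TestMorletPhase:
    def test_pure_tone_phase_slope(self):
        """The unwrapped phase of a 5 Hz tone advances at 2*pi*5 rad/s."""
        fs = 200.0
        t = np.arange(1341) / fs
        sig = np.sin(2 * np.pi * 5.0 * t)
        data = np.tile(sig, (2, 2, 1)).transpose(0, 2, 1)
        tensor = morlet_phase(_epochs_from_array(data), freqs=(4.0, 5.0, 6.0, 7.0))
        fi = 1  # 5 Hz bin
        valid = tensor.valid_mask[0, :, 0, fi]
        ph = np.unwrap(tensor.phase[0, valid, 0, fi])
        slope = np.polyfit(np.arange(ph.size) / fs, ph, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 5.0, rel=0.01)

    def test_pure_tone_amplitude_peaks_at_own_bin(self):
        fs = 200.0
        t = np.arange(1341) / fs
        sig = np.sin(2 * np.pi * 5.0 * t)
        data = sig[None, :, None]
        tensor = morlet_phase(_epochs_from_array(data), freqs=(4.0, 5.0, 6.0, 7.0))
        valid = tensor.valid_mask[0, :, 0, :].all(axis=1)
        amp = tensor.amplitude[0, valid, 0, :]
        assert np.all(amp[:, 1] > amp[:, 3])

    def test_zero_signal_flagged_invalid(self):
        data = np.zeros((1, 1341, 2))
        tensor = morlet_phase(_epochs_from_array(data))
        assert not tensor.valid_mask.any()
        assert np.isfinite(tensor.phase).all()
        assert np.all(tensor.amplitude < 1e-9)

    def test_matches_mne_reference_transform(self, tiny_cohort):
        """Batched convolution equals mne's tfr_array_morlet coefficients."""
        epochs, _ = tiny_cohort[0]
        sub = epochs.select_trials(np.arange(3))
        tensor = morlet_phase(sub, dtype=np.complex128)
        ref = tfr_array_morlet(
            sub.data.transpose(2, 0, 1).astype(float),
            sub.fs,
            tensor.freqs,
            n_cycles=5.0,
            output="complex",
            verbose=False,
        )  # trials x channels x freqs x samples
        mine = tensor.amplitude * np.exp(1j * tensor.phase)
        ref_arr = np.transpose(ref, (1, 3, 0, 2))
        assert np.allclose(mine, ref_arr, atol=1e-6 * np.abs(ref).max())

    def test_alpha_band_runs_config_only(self, tiny_cohort):
        epochs, _ = tiny_cohort[0]
        conn = plvnet.subject_connectivity(epochs, freqs=ALPHA_FREQS)
        assert conn.plv.shape[2] == len(ALPHA_FREQS)
        assert np.isfinite(conn.rplv[conn.usable]).all()

    def test_low_sampling_rate_rejected(self):
        data = np.zeros((1, 400, 2))
        with pytest.raises(ValueError):
            morlet_phase(_epochs_from_array(data, fs=10.0))


class TestPlv:
    def test_constant_phase_offset_gives_unit_plv(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-np.pi, np.pi, size=(30, 8))
        plv = plv_timecourse(base, base + np.pi / 3)
        assert np.allclose(plv, 1.0, atol=1e-12)

    def test_antipodal_phase_differences_cancel(self):
        n_samp, n_tr = 10, 6
        ph_i = np.zeros((n_samp, n_tr))
        ph_j = np.where(np.arange(n_tr) % 2 == 0, 0.0, np.pi)[None, :] * np.ones(
            (n_samp, 1)
        )
        assert np.allclose(plv_timecourse(ph_i, ph_j), 0.0, atol=1e-12)

    def test_uniform_phases_match_rayleigh_expectation(self):
        """E[PLV] under independence is sqrt(pi)/(2 sqrt(N)) ~ 0.089 at N=100."""
        rng = np.random.default_rng(42)
        n_rep, n_tr = 1000, 100
        dphi = rng.uniform(-np.pi, np.pi, size=(n_rep, n_tr))
        plv = plv_timecourse(dphi, np.zeros_like(dphi))
        assert plv.mean() == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(n_tr)), abs=0.02)

    def test_brute_force_equivalence_small(self):
        """PLV equals the direct per-sample complex-sum oracle to 1e-12."""
        rng = np.random.default_rng(7)
        for n_tr in (2, 3, 4):
            pi_ = rng.uniform(-np.pi, np.pi, size=(20, n_tr))
            pj_ = rng.uniform(-np.pi, np.pi, size=(20, n_tr))
            plv = plv_timecourse(pi_, pj_)
            oracle = np.empty(20)
            for s in range(20):
                acc = 0.0 + 0.0j
                for n in range(n_tr):
                    acc += np.exp(-1j * (pi_[s, n] - pj_[s, n]))
                oracle[s] = abs(acc) / n_tr
            assert np.allclose(plv, oracle, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(1, 12))
    def test_symmetry_and_bounds(self, seed, n_tr, n_samp):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, size=(n_samp, n_tr))
        b = rng.uniform(-np.pi, np.pi, size=(n_samp, n_tr))
        pab = plv_timecourse(a, b)
        pba = plv_timecourse(b, a)
        assert np.array_equal(pab, pba)
        assert np.all((pab >= 0) & (pab <= 1))

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            plv_timecourse(np.zeros((5, 3)), np.zeros((5, 4)))
        with pytest.raises(ValueError):
            plv_timecourse(np.zeros((5, 1)), np.zeros((5, 1)))

    def test_pairwise_matches_single_pair_route(self, tiny_cohort):
        epochs, _ = tiny_cohort[0]
        sub = epochs.select_trials(np.arange(4))
        tensor = morlet_phase(sub)
        pairs, plv = pairwise_plv(tensor)
        k = 12
        i, j = pairs[k]
        direct = plv_timecourse(tensor.phase[i].astype(float), tensor.phase[j].astype(float))
        assert np.allclose(plv[k], direct, atol=1e-5)


class TestRelativePlv:
    def _times(self, n=300):
        return -3700.0 + np.arange(n) * 5.0

    def test_self_normalisation_is_zero(self):
        times = self._times()
        plv = np.full((1, times.size, 4), 0.37)
        rplv, baseline, usable = relative_plv(plv, times)
        assert np.allclose(rplv, 0.0, atol=1e-12)
        assert np.allclose(baseline, 0.37)
        assert usable.all()

    def test_doubling_gives_one(self):
        times = self._times()
        plv = np.full((times.size, 4), 0.25)
        plv[250, :] = 0.5
        rplv, _, _ = relative_plv(plv, times)
        assert rplv[250] == pytest.approx(1.0)

    def test_baseline_mean_zero_identity(self, rng):
        """Time-mean of rPLV over the baseline window is 0 by construction."""
        times = self._times()
        plv = rng.uniform(0.05, 0.95, size=(10, times.size, 4))
        rplv, _, usable = relative_plv(plv, times)
        in_base = (times >= BASELINE_WINDOW[0]) & (times < BASELINE_WINDOW[1])
        assert np.allclose(rplv[:, in_base].mean(axis=1), 0.0, atol=1e-12)

    def test_rplv_lower_bound(self, rng):
        times = self._times()
        plv = rng.uniform(0.0, 1.0, size=(5, times.size, 4))
        rplv, _, usable = relative_plv(plv, times)
        assert np.all(rplv[usable] >= -1.0 - 1e-12)

    def test_tiny_baseline_flags_pair_unusable(self):
        times = self._times()
        plv = np.full((2, times.size, 4), 0.3)
        plv[1, :100, :] = 0.0  # baseline samples
        with pytest.warns(RuntimeWarning, match="baseline"):
            rplv, _, usable = relative_plv(plv, times)
        assert usable[0] and not usable[1]
        assert np.isnan(rplv[1]).all()
        assert np.isfinite(rplv[0]).all()


class TestSubjectConnectivity:
    def test_shapes_and_bounds(self, tiny_connectivity):
        conn = tiny_connectivity
        assert conn.pairs.shape == (465, 2)
        assert conn.plv.shape == (465, 1341, 4)
        assert np.all((conn.plv >= 0) & (conn.plv <= 1))
        assert conn.rplv.shape == (465, 1341)

    def test_pair_accessor_symmetric(self, tiny_connectivity):
        a = tiny_connectivity.pair(3, 17)
        b = tiny_connectivity.pair(17, 3)
        assert a.pair == b.pair == (3, 17)
        assert np.array_equal(a.plv, b.plv)
        with pytest.raises(ValueError):
            tiny_connectivity.pair(4, 4)

    def test_sample_mask_restriction_matches_full(self, tiny_cohort):
        epochs, _ = tiny_cohort[0]
        full = plvnet.subject_connectivity(epochs)
        mask = plvnet.window_mask(epochs.time_ms, BASELINE_WINDOW) | plvnet.window_mask(
            epochs.time_ms, (0.0, 500.0)
        )
        sub = plvnet.subject_connectivity(epochs, sample_mask=mask)
        assert np.allclose(sub.plv, full.plv[:, mask], atol=1e-6)
        assert np.allclose(sub.rplv, full.rplv[:, mask], atol=1e-5, equal_nan=True)
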