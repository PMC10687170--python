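"""Spectral chain: notch filter, Morlet CWT, windowing, log-z, epoching."""

import numpy as np
import pytest

from motorstates.spectral import (
    default_freqs,
    epoch_lock,
    morlet_cwt,
    normalize_log_z,
    notch_filter,
    unnormalize_log_z,
    window_average,
)

FS = 600.0


@pytest.fixture(scope="module")
def time_axis():
    return np.arange(0.0, 20.0, 1.0 / FS)


def _steady(x):
    n = len(x)
    return x[n // 4 : -n // 4]


def test_notch_kills_60hz_keeps_neighbors(time_axis):
    x60 = np.sin(2 * np.pi * 60.0 * time_axis)
    y = notch_filter(x60, FS)
    assert np.sqrt(np.mean(_steady(y) ** 2)) <= 0.01 * np.sqrt(np.mean(_steady(x60) ** 2))
    x10 = np.sin(2 * np.pi * 10.0 * time_axis)
    y10 = notch_filter(x10, FS)
    ratio = np.sqrt(np.mean(_steady(y10) ** 2)) / np.sqrt(np.mean(_steady(x10) ** 2))
    assert ratio == pytest.approx(1.0, abs=0.01)
    # passband within 0.5 dB at 50 and 70 Hz
    for f in (50.0, 70.0):
        xf = np.sin(2 * np.pi * f * time_axis)
        yf = notch_filter(xf, FS)
        db = 20 * np.log10(np.sqrt(np.mean(_steady(yf) ** 2)) / np.sqrt(np.mean(_steady(xf) ** 2)))
        assert abs(db) < 0.5


def test_notch_harmonics_and_degenerate_inputs(time_axis):
    x120 = np.sin(2 * np.pi * 120.0 * time_axis)
    y = notch_filter(x120, FS)
    assert np.sqrt(np.mean(_steady(y) ** 2)) < 0.02
    assert np.all(notch_filter(np.zeros(4000), FS) == 0.0)
    with pytest.raises(ValueError):
        notch_filter(np.zeros(100), 100.0)


def test_cwt_peak_within_one_bin_of_tone(time_axis):
    freqs = default_freqs(1.0, 200.0, 12)
    for tone in (4.0, 10.0, 40.0):
        power = morlet_cwt(np.sin(2 * np.pi * tone * time_axis), FS, freqs)
        peak = int(power.mean(axis=0).argmax())
        true = int(np.argmin(np.abs(freqs - tone)))
        assert abs(peak - true) <= 1


def test_cwt_power_scales_quadratically(time_axis):
    freqs = default_freqs(2.0, 100.0, 6)
    x = np.sin(2 * np.pi * 15.0 * time_axis)
    p1 = morlet_cwt(x, FS, freqs)
    p2 = morlet_cwt(2.0 * x, FS, freqs)
    core = slice(2000, -2000)
    np.testing.assert_allclose(p2[core], 4.0 * p1[core], rtol=1e-9)


def test_cwt_rejects_out_of_range_freqs(time_axis):
    with pytest.raises(ValueError):
        morlet_cwt(time_axis, FS, np.array([0.5, 400.0]))


def test_window_average_matches_bruteforce_and_labels():
    rng = np.random.default_rng(0)
    power = rng.random((1000, 3))
    binned, times = window_average(power, sample_rate=100.0, window=0.1, step=0.05)
    win, hop = 10, 5
    expect = np.stack([power[k * hop : k * hop + win].mean(axis=0) for k in range(len(times))])
    np.testing.assert_allclose(binned, expect, atol=1e-12)
    # labels mark window END times
    assert times[0] == pytest.approx(0.1)
    assert times[1] == pytest.approx(0.15)
    const, _ = window_average(np.full((200, 2), 3.7), 100.0)
    np.testing.assert_allclose(const, 3.7)


def test_window_average_step_impulse_spans_two_bins():
    power = np.zeros((40, 1))
    power[12] = 1.0  # single-sample impulse at 0.12 s (100 Hz sampling)
    binned, times = window_average(power, 100.0, window=0.1, step=0.05)
    hit = np.where(binned[:, 0] > 0)[0]
    assert len(hit) == 2  # 100 ms window / 50 ms step -> exactly 2 bins see it
    np.testing.assert_allclose(binned[hit, 0], 0.1)


def test_normalize_log_z_moments_scale_invariance_roundtrip():
    rng = np.random.default_rng(1)
    p = rng.lognormal(0.0, 1.0, size=(500, 4))
    z, stats = normalize_log_z(p)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)
    z_scaled, _ = normalize_log_z(7.3 * p)  # multiplicative scale drops out
    np.testing.assert_allclose(z, z_scaled, atol=1e-10)
    np.testing.assert_allclose(unnormalize_log_z(z, stats), np.log(p), atol=1e-10)


def test_epoch_lock_alignment_and_injection_recovery():
    rng = np.random.default_rng(2)
    fs, n_trials = 200.0, 8
    trial_len = 1.5
    n = int(n_trials * trial_len * fs)
    sig = rng.standard_normal(n)
    onsets = np.arange(n_trials) * trial_len
    for on in onsets:  # burst 0.2-0.4 s after each onset
        i0, i1 = int((on + 0.2) * fs), int((on + 0.4) * fs)
        sig[i0:i1] += 4.0 * np.sin(2 * np.pi * 25.0 * np.arange(i1 - i0) / fs)
    freqs = default_freqs(4.0, 60.0, 8)
    power = morlet_cwt(sig, fs, freqs)
    binned, times = window_average(power, fs)
    z, _ = normalize_log_z(binned)
    locked = epoch_lock(z, times, onsets, epoch="Go Cue", window=(0.0, 1.0), freqs=freqs)
    assert locked.power_z.shape[0] == n_trials  # aligns with the trial table
    fbin = np.argmin(np.abs(freqs - 25.0))
    prof = locked.power_z[:, :, fbin].mean(axis=0)
    inside = prof[(locked.times > 0.2) & (locked.times < 0.45)].mean()
    outside = prof[(locked.times > 0.6)].mean()
    assert inside > outside + 1.0  # elevation localized to the injected window

    single = epoch_lock(z, times, onsets, epoch="Go Cue", window=(0.0, 0.0), freqs=freqs)
    assert single.power_z.shape[1] == 1  # degenerate window -> one bin
    with pytest.raises(ValueError):
        epoch_lock(z, times, np.array([50.0]), epoch="Go Cue", window=(0.0, 1.0))
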