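"""Spectral preprocessing of LFP: notch, Morlet CWT, binning, log-z, epoching.

The chain mirrors standard intracranial practice: (1) zero-phase notch
filtering of 60 Hz line noise and its harmonics, with the -1 dB bandwidth set
to 3 Hz; (2) a complex Morlet continuous wavelet transform (center radian
frequency w0 = 6) on a logarithmic frequency axis covering 1-200 Hz;
(3) averaging instantaneous power into overlapping 100 ms windows every
50 ms, each bin labeled with the *end* time of its window; (4) per-frequency
z-scoring of natural-log power over the entire recording, which equalizes
the 1/f power gradient across bins; (5) extraction of trial-locked windows
around epoch onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.signal import filtfilt, iirnotch

#: Morlet center radian frequency.
OMEGA0 = 6.0

#: pywt complex-Morlet wavelet matching psi(t) = pi^-1/4 exp(i*w0*t) exp(-t^2/2).
_WAVELET = f"cmor2.0-{OMEGA0 / (2 * np.pi):.12f}"

#: Canonical frequency bands (Hz), lower edge inclusive.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "low gamma": (30.0, 60.0),
    "high gamma": (60.0, 100.0),
    "hyper gamma": (100.0, 200.0),
}


def default_freqs(
    fmin: float = 1.0, fmax: float = 200.0, bins_per_octave: int = 12
) -> np.ndarray:
    """Logarithmically spaced frequency axis, ``bins_per_octave`` bins/octave.

    12 bins/octave makes the one-octave cluster-size filter exactly 13 bin
    centers wide.
    """
    n = int(np.floor(np.log2(fmax / fmin) * bins_per_octave)) + 1
    return fmin * 2.0 ** (np.arange(n) / bins_per_octave)


def notch_filter(
    signal: np.ndarray,
    sample_rate: float,
    base_freq: float = 60.0,
    bw_1db: float = 3.0,
) -> np.ndarray:
    """Zero-phase notch at ``base_freq`` and harmonics below Nyquist.

    The filter is specified by its bandwidth at the -1 dB point;
    scipy's ``iirnotch`` takes the -3 dB bandwidth, so convert using the
    second-order notch magnitude response: ``bw3 = bw1 / sqrt(g^2/(1-g^2))``
    with ``g^2 = 10^(-0.1)``.
    """
    if sample_rate <= 2 * base_freq:
        raise ValueError(f"sample_rate {sample_rate} too low to notch {base_freq} Hz")
    g2 = 10.0 ** (-0.1)
    bw_3db = bw_1db / np.sqrt(g2 / (1.0 - g2))
    out = np.asarray(signal, dtype=float)
    nyq = sample_rate / 2.0
    k = 1
    while k * base_freq < nyq:
        f0 = k * base_freq
        b, a = iirnotch(f0, Q=f0 / bw_3db, fs=sample_rate)
        out = filtfilt(b, a, out)
        k += 1
    return out


def morlet_cwt(
    signal: np.ndarray, sample_rate: float, freqs: np.ndarray
) -> np.ndarray:
    """Instantaneous power (time x frequency) from a complex Morlet CWT.

    Power is the squared modulus of the wavelet coefficients.  Edge effects
    (reflection-free FFT convolution) extend roughly one wavelet width —
    about ``w0 / (pi * f)`` seconds — into each end at frequency ``f``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= sample_rate / 2):
        raise ValueError("frequencies must lie in (0, Nyquist)")
    scales = pywt.frequency2scale(_WAVELET, freqs / sample_rate)
    coef, _ = pywt.cwt(
        np.asarray(signal, dtype=float),
        scales,
        _WAVELET,
        sampling_period=1.0 / sample_rate,
        method="fft",
    )
    return np.abs(coef.T) ** 2  # (n_samples, n_freqs)


def window_average(
    power: np.ndarray,
    sample_rate: float,
    window: float = 0.100,
    step: float = 0.050,
) -> tuple[np.ndarray, np.ndarray]:
    """Average power in overlapping windows; labels mark each window's end.

    Returns ``(binned, times)`` with ``binned`` of shape (n_bins, n_freqs)
    and ``times[k]`` the end time in seconds of bin ``k``.
    """
    power = np.asarray(power, dtype=float)
    win = int(round(window * sample_rate))
    hop = int(round(step * sample_rate))
    if win < 1 or hop < 1:
        raise ValueError("window shorter than one sample")
    n = power.shape[0]
    n_bins = (n - win) // hop + 1
    if n_bins < 1:
        raise ValueError("signal shorter than one window")
    csum = np.vstack([np.zeros((1, power.shape[1])), np.cumsum(power, axis=0)])
    starts = np.arange(n_bins) * hop
    binned = (csum[starts + win] - csum[starts]) / win
    times = (starts + win) / sample_rate
    return binned, times


def normalize_log_z(binned: np.ndarray) -> tuple[np.ndarray, dict]:
    """Per-frequency z-score of natural-log power over the whole session.

    Non-positive power bins are floored at the smallest positive normal
    float before the log (degenerate inputs only).  Returns the z-scored
    array and the per-frequency ``{"mean", "sd"}`` stats for reuse.
    """
    binned = np.asarray(binned, dtype=float)
    floored = np.maximum(binned, np.finfo(float).tiny)
    logp = np.log(floored)
    mean = logp.mean(axis=0)
    sd = logp.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (logp - mean) / sd_safe
    return z, {"mean": mean, "sd": sd}


def unnormalize_log_z(z: np.ndarray, stats: dict) -> np.ndarray:
    """Invert :func:`normalize_log_z` back to natural-log power."""
    sd_safe = np.where(stats["sd"] > 0, stats["sd"], 1.0)
    return z * sd_safe + stats["mean"]


@dataclass
class SpectrogramSet:
    """Epoch-locked normalized spectrograms for one channel.

    ``power_z`` has shape (n_trials, n_times, n_freqs); ``times`` are window
    end-labels in seconds relative to the epoch onset.
    """

    channel_id: str
    epoch: str
    freqs: np.ndarray
    times: np.ndarray
    power_z: np.ndarray
    session_stats: dict | None = None


def epoch_lock(
    power_z: np.ndarray,
    times: np.ndarray,
    onsets_s: np.ndarray,
    epoch: str,
    window: tuple = (0.0, 0.5),
    channel_id: str = "",
    freqs: np.ndarray | None = None,
    session_stats: dict | None = None,
) -> SpectrogramSet:
    """Cut trial-locked windows out of a session-long binned spectrogram.

    ``onsets_s`` holds one epoch-onset time per trial.  Each trial's slice
    covers the bins whose labels fall in ``onset + window``; all trials use
    the same bin count (taken from the first trial) so the output stacks.
    """
    times = np.asarray(times)
    onsets = np.asarray(onsets_s, dtype=float)
    step = times[1] - times[0] if len(times) > 1 else 1.0
    i0s = np.searchsorted(times, onsets + window[0] - 1e-9)
    n_bins = int(np.floor((window[1] - window[0]) / step)) + 1
    if np.any(i0s + n_bins > len(times)) or np.any(i0s < 0):
        raise ValueError("epoch window extends outside the recording")
    trials = np.stack([power_z[i0 : i0 + n_bins] for i0 in i0s])
    rel_times = times[i0s[0] : i0s[0] + n_bins] - onsets[0]
    return SpectrogramSet(
        channel_id=channel_id,
        epoch=epoch,
        freqs=freqs if freqs is not None else np.array([]),
        times=rel_times,
        power_z=trials,
        session_stats=session_stats,
    )


def preprocess_channel(
    signal: np.ndarray,
    sample_rate: float,
    freqs: np.ndarray | None = None,
    window: float = 0.100,
    step: float = 0.050,
    notch: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Full single-channel chain: notch -> CWT power -> binning -> log-z.

    Returns ``(power_z, times, freqs, session_stats)``.
    """
    freqs = default_freqs(fmax=min(200.0, 0.95 * sample_rate / 2)) if freqs is None else freqs
    x = notch_filter(signal, sample_rate) if notch else np.asarray(signal, float)
    power = morlet_cwt(x, sample_rate, freqs)
    binned, times = window_average(power, sample_rate, window=window, step=step)
    z, stats = normalize_log_z(binned)
    return z, times, np.asarray(freqs, float), stats
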