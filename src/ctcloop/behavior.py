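"""Whisker-behavior analysis: bout detection, event statistics, band power.

A self-initiated whisking bout counts as a movement onset only if the
movement lasts at least 200 ms and is preceded by at least 400 ms without
any movement.  Resting windows are 200 ms segments centred in quiescent
stretches of at least 400 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .analysis import phase_relation

__all__ = [
    "EpochSet", "detect_movement_onsets", "whisker_lfp_phase",
    "bout_rate_change", "movement_band_power", "morlet_cwt_power",
    "downsample",
]


@dataclass
class EpochSet:
    """Movement-onset derived analysis windows (all times in ms)."""

    onsets: np.ndarray
    pre_windows: np.ndarray   # (n, 2): [onset-200, onset)
    move_windows: np.ndarray  # (n, 2): [onset, onset+200)
    rest_windows: np.ndarray  # (m, 2): 200 ms centred in quiescence >=400 ms

    def __len__(self):
        return len(self.onsets)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    m = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(int)))
    return m.reshape(-1, 2)


def detect_movement_onsets(whisker, fs: float = 1000.0,
                           speed_threshold: float = 50.0,
                           smooth_ms: float = 10.0,
                           hysteresis_ms: float = 25.0,
                           min_duration_ms: float = 200.0,
                           min_quiescence_ms: float = 400.0) -> EpochSet:
    """Detect qualifying whisking-bout onsets from a whisker-angle trace.

    Movement is where the absolute angular speed of the ``smooth_ms``
    moving-average trace exceeds ``speed_threshold`` (deg/s); gaps shorter
    than ``hysteresis_ms`` are closed.  Onsets require >= 200 ms of
    movement with no movement in the preceding 400 ms.

    ``fs`` must be the uniform whisker sampling rate (1 kHz nominal).
    """
    w = np.asarray(whisker, dtype=float)
    if w.ndim != 1:
        raise ValueError("whisker trace must be one-dimensional")
    k = max(1, int(round(smooth_ms * fs / 1000.0)))
    kernel = np.ones(k) / k
    smooth = np.convolve(w, kernel, mode="same")
    # slope over the smoothing scale (central difference across +-k
    # samples): per-sample gradients of a noisy 1 kHz trace would cross
    # any realistic threshold constantly
    slope = np.zeros_like(smooth)
    slope[k:-k] = (smooth[2 * k:] - smooth[:-2 * k]) * fs / (2.0 * k)
    speed = np.abs(slope)  # deg/s
    moving = speed > speed_threshold
    # close sub-hysteresis gaps
    gap = int(round(hysteresis_ms * fs / 1000.0))
    for start, stop in _runs(~moving):
        if stop - start < gap and start > 0 and stop < len(moving):
            moving[start:stop] = True
    min_dur = int(round(min_duration_ms * fs / 1000.0))
    min_qui = int(round(min_quiescence_ms * fs / 1000.0))
    onsets = []
    for start, stop in _runs(moving):
        if stop - start < min_dur:
            continue
        if start < min_qui or moving[start - min_qui:start].any():
            continue
        # the +-k slope window anticipates the bout by ~k samples
        onsets.append(start + k)
    onsets_ms = np.array(onsets, dtype=float) * 1000.0 / fs
    win = 200.0
    pre = np.column_stack([onsets_ms - win, onsets_ms]) if onsets else \
        np.empty((0, 2))
    mov = np.column_stack([onsets_ms, onsets_ms + win]) if onsets else \
        np.empty((0, 2))
    rests = []
    for start, stop in _runs(~moving):
        if stop - start >= min_qui:
            mid = (start + stop) / 2.0 * 1000.0 / fs
            rests.append((mid - win / 2.0, mid + win / 2.0))
    return EpochSet(onsets=onsets_ms, pre_windows=pre, move_windows=mov,
                    rest_windows=np.array(rests) if rests else
                    np.empty((0, 2)))


def downsample(x, fs_in: float, fs_out: float = 1000.0) -> np.ndarray:
    """Anti-aliased decimation (8th-order Chebyshev low-pass, zero phase)."""
    q = int(round(fs_in / fs_out))
    if q <= 1:
        return np.asarray(x, dtype=float)
    return sps.decimate(np.asarray(x, dtype=float), q, n=8, ftype="iir",
                        zero_phase=True)


def whisker_lfp_phase(whisker, lfp, fs: float, onsets_ms,
                      window_ms=(20.0, 170.0), max_lag_ms: float = 100.0):
    """Phase relation between an LFP channel and the whisker angle.

    Computed per movement onset in the window of the biggest movement
    (+20..+170 ms after onset) with the LFP as the *first* correlation
    argument: a negative phase relation means LFP changes precede the
    whisker movement.  Returns ``(mean_lag_ms, per_onset_lags)``; onsets
    whose windows are degenerate or out of range are skipped.
    """
    w = np.asarray(whisker, dtype=float)
    l = np.asarray(lfp, dtype=float)
    if w.shape != l.shape:
        raise ValueError("whisker and LFP must share the 1 kHz grid")
    a = int(round(window_ms[0] * fs / 1000.0))
    b = int(round(window_ms[1] * fs / 1000.0))
    lags = []
    for onset in np.atleast_1d(onsets_ms):
        i0 = int(round(onset * fs / 1000.0)) + a
        i1 = int(round(onset * fs / 1000.0)) + b
        if i0 < 0 or i1 > len(w):
            continue
        res = phase_relation(l[i0:i1], w[i0:i1], fs, max_lag_ms=max_lag_ms)
        if res.valid:
            lags.append(res.phase_relation)
    lags = np.array(lags)
    return (float(lags.mean()) if lags.size else np.nan), lags


def bout_rate_change(bout_starts, stim_onsets, window_ms: float = 200.0):
    """Mean bout-initiation rate before (-200..0) and during (0..+200 ms)
    stimulation, from a peristimulus time histogram of bout-start events.

    Returns ``(rate_before_hz, rate_after_hz)``.
    """
    bouts = np.asarray(bout_starts, dtype=float)
    stims = np.atleast_1d(np.asarray(stim_onsets, dtype=float))
    if stims.size == 0:
        raise ValueError("need at least one stimulus")
    rel = bouts[None, :] - stims[:, None]
    n_before = np.sum((rel >= -window_ms) & (rel < 0))
    n_after = np.sum((rel >= 0) & (rel < window_ms))
    denom = stims.size * window_ms / 1000.0  # seconds of PSTH window
    return n_before / denom, n_after / denom


def morlet_cwt_power(x, fs: float, freqs=None, omega0: float = 6.0):
    """Power scalogram |CWT|^2 with an analytic Morlet wavelet.

    ``freqs`` defaults to 48 geometrically spaced frequencies over
    1-30 Hz.  Returns ``(freqs, power (n_freqs, n_samples))``.
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = np.geomspace(1.0, 30.0, 48)
    power = np.empty((len(freqs), len(x)))
    for i, f in enumerate(freqs):
        s = omega0 / (2.0 * np.pi * f)  # wavelet scale in seconds
        half = int(np.ceil(4.0 * s * fs))
        t = np.arange(-half, half + 1) / fs
        psi = (np.pi ** -0.25) * np.exp(1j * omega0 * t / s) * \
            np.exp(-0.5 * (t / s) ** 2) / np.sqrt(s * fs)
        w = sps.fftconvolve(x, np.conj(psi[::-1]), mode="same")
        power[i] = np.abs(w) ** 2
    return np.asarray(freqs), power


def movement_band_power(whisker, fs: float, stim_onsets_ms,
                        band=(3.0, 10.0), window_ms: float = 500.0,
                        freqs=None):
    """Mean wavelet power of the whisker trace in a frequency band,
    in the 500 ms before versus after each stimulus onset, averaged over
    stimuli.  Stimuli whose windows fall outside the trace are dropped;
    an error is raised if none qualify.

    Returns ``(power_before, power_after)``.
    """
    w = np.asarray(whisker, dtype=float)
    stims = np.atleast_1d(np.asarray(stim_onsets_ms, dtype=float))
    half = int(round(window_ms * fs / 1000.0))
    keep = [s for s in stims
            if int(s * fs / 1000.0) - half >= 0
            and int(s * fs / 1000.0) + half <= len(w)]
    if not keep:
        raise ValueError("no stimulus with a full +/-500 ms window")
    f, power = morlet_cwt_power(w, fs, freqs=freqs)
    in_band = (f >= band[0]) & (f <= band[1])
    before, after = [], []
    for s in keep:
        i = int(round(s * fs / 1000.0))
        before.append(power[in_band, i - half:i].mean())
        after.append(power[in_band, i:i + half].mean())
    return float(np.mean(before)), float(np.mean(after))
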