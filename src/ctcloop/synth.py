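"""Surrogate experimental recordings with known ground truth.

Real recordings of head-fixed mice (whisker angle at 1 kHz, 16+16 cortical
and 12 cerebellar LFP channels at 25 kHz, Purkinje-cell spike trains) are
not redistributable; this module generates statistically matched surrogates
in which every injected dependency -- pairwise lags, bout times, rate
modulations -- is recorded as ground truth, so the analysis chain can be
validated by round trip.

The surrogate LFP does not attempt biophysical realism: each area has a
latent pink-noise (1/f) source band-limited to 1-80 Hz (the band the LFP
analyses use); real per-channel spectra would differ in detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .analysis import SpikeTrain

__all__ = [
    "SyntheticRecording", "RecordingTruth",
    "gen_whisker", "gen_lagged_lfp", "gen_spike_trains", "gen_stim_times",
    "make_recording",
]

#: inter-stimulus gaps of the optogenetic pulse trains, ms
STIM_INTERVALS_MS = (500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0)


@dataclass
class RecordingTruth:
    """Everything injected into a surrogate recording."""

    bout_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_lags_ms: dict = field(default_factory=dict)
    modulation: dict = field(default_factory=dict)
    shared_fraction: float | None = None
    snr: float | None = None


@dataclass
class SyntheticRecording:
    """A surrogate experiment: behaviour, LFP, spikes, events, truth."""

    whisker: np.ndarray | None = None
    whisker_fs: float = 1000.0
    lfp: dict = field(default_factory=dict)     # area -> (n_chan, n) array
    lfp_fs: float = 25000.0
    spikes: list = field(default_factory=list)  # SpikeTrain
    stim_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    truth: RecordingTruth = field(default_factory=RecordingTruth)
    seed: object = None


# --------------------------------------------------------------------------
# whisker traces
# --------------------------------------------------------------------------

def gen_whisker(T_ms: float, fs: float = 1000.0, bout_rate_hz: float = 0.3,
                bout_dur_range_ms=(250.0, 700.0),
                whisk_freq_range_hz=(6.0, 12.0), amplitude_deg: float = 15.0,
                noise_sd_deg: float = 0.5, min_gap_ms: float = 500.0,
                seed=0):
    """Whisker-angle trace: quiescence with noise, interleaved whisking
    bouts (sinusoid with frequency jitter and a raised-cosine envelope).

    Bout onsets follow a Poisson process thinned so that consecutive bouts
    are separated by at least ``min_gap_ms`` of quiescence (default 500 ms,
    comfortably above the 400 ms pre-onset quiescence criterion).

    Returns ``(trace, true_bout_starts_ms)``.
    """
    if T_ms <= 0:
        raise ValueError("T must be positive")
    if bout_rate_hz * bout_dur_range_ms[1] / 1000.0 >= 1.0:
        raise ValueError("bout rate x max duration >= 1: bouts would overlap")
    rng = np.random.default_rng(seed)
    n = int(round(T_ms * fs / 1000.0))
    trace = rng.normal(0.0, noise_sd_deg, size=n)
    t_ms = 0.0
    bouts = []
    while True:
        gap = rng.exponential(1000.0 / bout_rate_hz) if bout_rate_hz > 0 \
            else np.inf
        t_ms += max(gap, min_gap_ms)
        dur = rng.uniform(*bout_dur_range_ms)
        if t_ms + dur >= T_ms:
            break
        i0 = int(round(t_ms * fs / 1000.0))
        i1 = int(round((t_ms + dur) * fs / 1000.0))
        tt = np.arange(i1 - i0) / fs  # seconds
        freq = rng.uniform(*whisk_freq_range_hz)
        # slow frequency jitter within the bout
        jitter = 1.0 + 0.1 * np.sin(2.0 * np.pi * rng.uniform(0.5, 1.5) * tt
                                    + rng.uniform(0, 2 * np.pi))
        phase = 2.0 * np.pi * np.cumsum(freq * jitter) / fs
        envelope = 0.5 * (1.0 - np.cos(
            2.0 * np.pi * np.minimum(tt / 0.06, 0.5)))
        envelope = np.minimum(envelope, 0.5 * (1.0 - np.cos(
            2.0 * np.pi * np.minimum((tt[-1] - tt) / 0.06, 0.5))))
        trace[i0:i1] += amplitude_deg * envelope * np.sin(phase)
        bouts.append(t_ms)
        t_ms += dur
    return trace, np.array(bouts)


# --------------------------------------------------------------------------
# lagged multichannel LFP
# --------------------------------------------------------------------------

def _pink_bandlimited(n: int, fs: float, band=(1.0, 80.0), rng=None):
    """Unit-variance pink (1/f) noise band-passed to ``band``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    inside = (f >= band[0]) & (f <= band[1])
    shaping[inside] = 1.0 / np.sqrt(f[inside])
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _delay(x: np.ndarray, shift_samples: int) -> np.ndarray:
    """Shift right (delay) by ``shift_samples`` (negative = advance)."""
    return np.roll(x, shift_samples)


def gen_lagged_lfp(T_ms: float, fs: float = 25000.0,
                   n_channels={"M1": 16, "S1": 16, "CB": 12},
                   lags_ms={"M1": -5.0, "S1": -5.0},
                   post_lags_ms=None, onset_ms=None,
                   shared_fraction: float = 0.8, snr: float = 2.0,
                   crossfade_ms: float = 20.0, seed=0):
    """Multichannel surrogate LFP with controlled inter-area lags.

    A single latent band-limited (1-80 Hz) pink-noise source drives the
    cerebellar (CB) channels; each cerebral area is a delayed/advanced copy
    whose lag equals the *target phase relation* under the pipeline's sign
    convention: ``lags_ms['M1'] = -5`` makes the M1 source precede CB such
    that the measured M1-CB phase relation is -5 ms.

    Per channel, a fraction ``shared_fraction`` of the variance comes from
    the (lagged) area source and the rest from private pink noise, plus
    white measurement noise at power ``1/snr``.

    If ``post_lags_ms`` and ``onset_ms`` are given, the cerebral lag
    switches from ``lags_ms`` to ``post_lags_ms`` at the onset, crossfading
    over ``crossfade_ms`` to avoid splice artefacts (emulating the
    pre-movement/movement lag flip).

    Returns ``(lfp: dict area -> (n_chan, n) array, truth: RecordingTruth)``.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    for name, lag in lags_ms.items():
        if abs(lag) > 100.0:
            raise ValueError("lags must be within +/-100 ms")
    rng = np.random.default_rng(seed)
    n = int(round(T_ms * fs / 1000.0))
    master = _pink_bandlimited(n, fs, rng=rng)

    def area_source(area):
        if area == "CB":
            return master
        lag = lags_ms.get(area, 0.0)
        # cerebral copy earlier in time by -lag (phase relation = lag)
        pre = _delay(master, int(round(lag * fs / 1000.0)))
        if post_lags_ms is None or onset_ms is None:
            return pre
        post = _delay(master,
                      int(round(post_lags_ms.get(area, 0.0) * fs / 1000.0)))
        i_on = int(round(onset_ms * fs / 1000.0))
        w = np.zeros(n)
        ramp = int(round(crossfade_ms * fs / 1000.0))
        w[i_on:i_on + ramp] = np.linspace(0, 1, ramp, endpoint=False)
        w[i_on + ramp:] = 1.0
        return (1.0 - w) * pre + w * post

    lfp = {}
    for area, k in n_channels.items():
        src = area_source(area)
        chans = np.empty((k, n))
        for c in range(k):
            private = _pink_bandlimited(n, fs, rng=rng)
            sig = np.sqrt(shared_fraction) * src + \
                np.sqrt(1.0 - shared_fraction) * private
            meas = rng.normal(0.0, np.sqrt(1.0 / snr), size=n)
            chans[c] = sig + meas
        lfp[area] = chans
    truth = RecordingTruth(
        pair_lags_ms={("pre", a): lags_ms.get(a, 0.0)
                      for a in n_channels if a != "CB"} |
                     ({("post", a): post_lags_ms.get(a, 0.0)
                       for a in n_channels if a != "CB"}
                      if post_lags_ms else {}),
        shared_fraction=shared_fraction, snr=snr)
    return lfp, truth


# --------------------------------------------------------------------------
# spike trains
# --------------------------------------------------------------------------

def _thinned_poisson(rate_hz: np.ndarray, fs: float, dead_time_ms: float,
                     rng, forbidden=None):
    """Inhomogeneous Poisson spikes by thinning, with absolute dead time
    and optional forbidden windows ``[(t0, t1), ...]`` in ms."""
    n = rate_hz.size
    p = rate_hz / fs  # per-sample spike probability
    hits = np.flatnonzero(rng.random(n) < p)
    times = hits * 1000.0 / fs + rng.uniform(0, 1000.0 / fs, size=hits.size)
    times.sort()
    out = []
    last = -np.inf
    for t in times:
        if t - last < dead_time_ms:
            continue
        if forbidden is not None and forbidden(t):
            continue
        out.append(t)
        last = t
    return np.array(out)


def gen_spike_trains(T_ms: float, base_rate_hz: float = 60.0,
                     cs_rate_hz: float = 1.0, kind: str = "simple",
                     driver=None, driver_fs: float = 1000.0,
                     modulation_gain: float = 0.0,
                     modulation_lag_ms: float = 0.0,
                     ss_refractory_ms: float = 3.0,
                     cs_pause_ms: float = 8.0, seed=0):
    """Generate Purkinje-cell (or cortical) spike trains.

    PC simple spikes (default 60 Hz) are an inhomogeneous Poisson process
    with a 3 ms dead time; complex spikes (default 1 Hz) are an independent
    Poisson train, and simple spikes pause for at least 8 ms after each
    complex spike.  An optional ``driver`` signal modulates the
    simple-spike rate: ``rate(t) = base * (1 + gain * z(t - lag))`` with
    ``z`` the standardised driver, clipped at zero.

    Returns a list of :class:`SpikeTrain`: ``[simple, complex]`` for PC
    trains (``kind='simple'``), ``[cortical_unit]`` otherwise.
    """
    if base_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    if base_rate_hz * ss_refractory_ms / 1000.0 >= 1.0:
        raise ValueError("rate x refractory >= 1: unrealizable train")
    rng = np.random.default_rng(seed)
    n = int(round(T_ms * driver_fs / 1000.0))
    rate = np.full(n, float(base_rate_hz))
    if driver is not None and modulation_gain != 0.0:
        z = np.asarray(driver, dtype=float)
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        shift = int(round(modulation_lag_ms * driver_fs / 1000.0))
        z = np.roll(z, shift)
        m = min(n, z.size)
        rate[:m] = np.maximum(base_rate_hz * (1.0 + modulation_gain * z[:m]),
                              0.0)
    if kind != "simple":
        times = _thinned_poisson(rate, driver_fs, ss_refractory_ms, rng)
        return [SpikeTrain(times=times, kind="cortical_unit")]
    cs_times = _thinned_poisson(np.full(n, float(cs_rate_hz)), driver_fs,
                                3.0 * cs_pause_ms, rng)

    def in_pause(t):
        i = np.searchsorted(cs_times, t)
        return i > 0 and t - cs_times[i - 1] < cs_pause_ms

    ss_times = _thinned_poisson(rate, driver_fs, ss_refractory_ms, rng,
                                forbidden=in_pause)
    return [SpikeTrain(times=ss_times, kind="simple"),
            SpikeTrain(times=cs_times, kind="complex")]


# --------------------------------------------------------------------------
# stimulus trains
# --------------------------------------------------------------------------

def gen_stim_times(n: int, intervals_ms=STIM_INTERVALS_MS, seed=0,
                   t0_ms: float = 0.0) -> np.ndarray:
    """Optogenetic stimulus onsets: cumulative sums of gaps drawn uniformly
    from the allowed interval set (default 0.5-3.5 s in 0.5 s steps, in
    random sequence)."""
    if n < 1:
        raise ValueError("need n >= 1 stimuli")
    intervals = np.asarray(intervals_ms, dtype=float)
    if intervals.size == 0:
        raise ValueError("empty interval set")
    rng = np.random.default_rng(seed)
    gaps = rng.choice(intervals, size=n)
    return t0_ms + np.cumsum(gaps)


# --------------------------------------------------------------------------
# full recordings
# --------------------------------------------------------------------------

def make_recording(T_ms: float = 60_000.0, lfp_fs: float = 25000.0,
                   pre_lag_ms: float = -5.0, post_lag_ms: float = 5.0,
                   shared_fraction: float = 0.8, snr: float = 2.0,
                   bout_rate_hz: float = 0.3, n_stim: int = 0,
                   seed=0) -> SyntheticRecording:
    """Assemble a full surrogate recording (paper-default geometry:
    16 M1 + 16 S1 + 12 cerebellar channels, 1 kHz whisker trace, PC
    simple/complex spikes modulated by the whisker trace).

    The cerebral-vs-cerebellar lag flips from ``pre_lag_ms`` to
    ``post_lag_ms`` at the first true bout onset (or never, if no bout).
    """
    ss = np.random.SeedSequence(seed)
    s_wh, s_lfp, s_spk, s_stim = ss.spawn(4)
    whisker, bouts = gen_whisker(T_ms, bout_rate_hz=bout_rate_hz, seed=s_wh)
    onset = float(bouts[0]) if bouts.size else None
    lfp, truth = gen_lagged_lfp(
        T_ms, fs=lfp_fs,
        lags_ms={"M1": pre_lag_ms, "S1": pre_lag_ms},
        post_lags_ms=({"M1": post_lag_ms, "S1": post_lag_ms}
                      if onset is not None else None),
        onset_ms=onset, shared_fraction=shared_fraction, snr=snr,
        seed=s_lfp)
    spikes = gen_spike_trains(T_ms, driver=whisker,
                              modulation_gain=0.3, modulation_lag_ms=10.0,
                              seed=s_spk)
    stims = gen_stim_times(n_stim, seed=s_stim) if n_stim else np.empty(0)
    truth.bout_times_ms = bouts
    truth.modulation = {"ss_gain": 0.3, "ss_lag_ms": 10.0}
    return SyntheticRecording(whisker=whisker, lfp=lfp, lfp_fs=lfp_fs,
                              spikes=spikes, stim_times_ms=stims,
                              truth=truth, seed=seed)
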