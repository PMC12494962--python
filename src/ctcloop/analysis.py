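"""Continuous-signal and spike-train analysis chain.

These operations are applied identically to modeled rate traces and to
(synthetic) recordings: cross-correlogram phase relations with shuffle
nulls, peak counting, mutual information, spike-density functions,
trial-by-trial correlation matrices, and stimulus-evoked LFP responses.

Sign convention (fixed throughout): the first signal of a pair is the
*cerebral* one.  A negative phase relation means the cerebral signal
precedes the cerebellar one; if ``x(t) = y(t + d)`` with ``d > 0`` (the
cerebral copy is earlier in time), the phase relation is ``-d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CrossCorrelogram", "PhaseRelationResult", "SpikeTrain",
    "cross_correlogram", "phase_relation", "shuffle_zscore",
    "count_cc_peaks", "mutual_information", "spike_density",
    "trial_corr_matrix", "asymmetry_index", "lfp_response", "LfpResponse",
]


# --------------------------------------------------------------------------
# cross-correlograms and phase relations
# --------------------------------------------------------------------------

@dataclass
class CrossCorrelogram:
    """Cross-correlogram over lags in ms; positive lag = cerebellar leads."""

    lags: np.ndarray
    values: np.ndarray
    normalized: bool

    @property
    def fs(self) -> float:
        return 1000.0 / (self.lags[1] - self.lags[0])


@dataclass
class PhaseRelationResult:
    """Peak of a cross-correlogram and its signed lag ("phase relation")."""

    peak_value: float
    phase_relation: float
    zscore: float | None = None
    valid: bool = True
    tie_flag: bool = False
    ccg: CrossCorrelogram | None = None

    @property
    def significant(self) -> bool | None:
        if self.zscore is None:
            return None
        return self.zscore > 2.0


def _xcorr_matrix(X: np.ndarray, Y: np.ndarray, max_lag: int,
                  normalized: bool = True):
    """Batched cross-correlation ``R[m] = sum_n x[n+m] y[n]`` for lag
    ``m`` in ``[-max_lag, max_lag]``; rows are independent pairs.

    Returns ``(values (k, 2L+1), norm (k,))`` where ``norm`` is the
    normalisation ``n * sd_x * sd_y`` (zero where degenerate) and values
    are already demeaned/normalised when requested.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError("signal pairs must have equal shapes")
    n = X.shape[1]
    L = int(max_lag)
    if L >= n:
        raise ValueError("max lag must be shorter than the window")
    if normalized:
        X = X - X.mean(axis=1, keepdims=True)
        Y = Y - Y.mean(axis=1, keepdims=True)
    # R(m) = sum_n x[n+m] y[n]  ==  (x * reversed(y))[n-1+m]
    full = sps.fftconvolve(X, Y[:, ::-1], mode="full", axes=1)
    mid = n - 1
    vals = full[:, mid - L:mid + L + 1]
    if normalized:
        norm = n * X.std(axis=1) * Y.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(norm[:, None] > 0, vals / norm[:, None], np.nan)
    else:
        norm = np.ones(X.shape[0])
    return vals, norm


def cross_correlogram(x, y, fs: float, max_lag_ms: float = 100.0,
                      normalized: bool = True) -> CrossCorrelogram:
    """Cross-correlogram of one signal pair (x cerebral, y cerebellar)."""
    L = int(round(max_lag_ms * fs / 1000.0))
    vals, _ = _xcorr_matrix(np.asarray(x)[None, :], np.asarray(y)[None, :],
                            L, normalized)
    lags = np.arange(-L, L + 1) * 1000.0 / fs
    return CrossCorrelogram(lags=lags, values=vals[0], normalized=normalized)


def _peak_with_ties(values: np.ndarray, L: int):
    """Index of the maximum; equal-height ties resolved toward the smallest
    |lag|, a +/- tie toward the negative lag (flagged)."""
    vmax = np.nanmax(values)
    cand = np.flatnonzero(values >= vmax - 1e-12 * max(1.0, abs(vmax)))
    lags = cand - L
    order = np.lexsort((lags, np.abs(lags)))  # smallest |lag|, then negative
    pick = cand[order[0]]
    tie = len(cand) > 1 and np.abs(lags[order[0]]) == np.abs(
        lags[order[1 % len(order)]]) if len(cand) > 1 else False
    return pick, bool(tie)


def phase_relation(x, y, fs: float, max_lag_ms: float = 100.0,
                   normalized: bool = True,
                   return_ccg: bool = False) -> PhaseRelationResult:
    """Peak amplitude and signed peak lag of the cross-correlogram.

    Parameters
    ----------
    x, y : array_like
        Equal-length windows; ``x`` is the cerebral signal, ``y`` the
        cerebellar one.
    fs : float
        Sampling rate, Hz.
    max_lag_ms : float
        Lag range searched (default +/-100 ms).
    normalized : bool
        Demean within the window and scale to correlation-coefficient
        units.

    Returns
    -------
    PhaseRelationResult
        ``valid=False`` (NaN peak/phase) when either window has zero
        variance.
    """
    L = int(round(max_lag_ms * fs / 1000.0))
    vals, norm = _xcorr_matrix(np.asarray(x)[None, :],
                               np.asarray(y)[None, :], L, normalized)
    ccg = None
    if return_ccg:
        ccg = CrossCorrelogram(lags=np.arange(-L, L + 1) * 1000.0 / fs,
                               values=vals[0], normalized=normalized)
    if normalized and norm[0] <= 0:
        return PhaseRelationResult(np.nan, np.nan, valid=False, ccg=ccg)
    pick, tie = _peak_with_ties(vals[0], L)
    return PhaseRelationResult(peak_value=float(vals[0][pick]),
                               phase_relation=(pick - L) * 1000.0 / fs,
                               tie_flag=tie, ccg=ccg)


def _batch_peaks(X, Y, L):
    """Max of the normalised ccg per row pair (NaN on degenerate rows)."""
    vals, norm = _xcorr_matrix(X, Y, L, normalized=True)
    with np.errstate(invalid="ignore"):
        return np.nanmax(vals, axis=1)


def shuffle_zscore(x, y, fs: float, window_start: int, window_len: int,
                   n_shuffles: int = 100, max_lag_ms: float = 100.0,
                   rng=None) -> float:
    """Shuffle-null Z-score of the peak correlation of one window.

    The observed peak is the cross-correlogram maximum of the windows
    ``[window_start, window_start + window_len)`` of ``x`` and ``y``
    (samples).  The null draws ``n_shuffles`` pairs of windows of the same
    length at independent random start points of the two full recordings;
    ``Z = (observed - mean(null)) / SD(null)``.  A correlation is
    conventionally called significant when ``Z > 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if window_len > n or window_start + window_len > n:
        raise ValueError("window outside the recording")
    if n - window_len < n_shuffles:
        raise ValueError("recording too short to place the shuffle windows")
    L = int(round(max_lag_ms * fs / 1000.0))
    obs = _batch_peaks(x[None, window_start:window_start + window_len],
                       y[None, window_start:window_start + window_len], L)[0]
    sx = rng.integers(0, n - window_len + 1, size=n_shuffles)
    sy = rng.integers(0, n - window_len + 1, size=n_shuffles)
    take = np.arange(window_len)
    null = _batch_peaks(x[sx[:, None] + take], y[sy[:, None] + take], L)
    m, s = np.nanmean(null), np.nanstd(null)
    if not s > 0:
        raise ValueError("degenerate shuffle null (zero SD)")
    return float((obs - m) / s)


def count_cc_peaks(ccg: CrossCorrelogram, min_width_ms: float = 20.0,
                   min_prominence: float = 0.01,
                   min_distance_ms: float = 20.0) -> int:
    """Count local maxima of a cross-correlogram.

    Peaks must be at least ``min_width_ms`` wide (at half prominence),
    ``min_prominence`` prominent (topographic definition) and separated by
    ``min_distance_ms``.  The defaults reproduce width/prominence/distance
    of 500 samples / 0.01 / 500 samples on a 25 kHz lag grid.
    """
    fs = ccg.fs
    w = min_width_ms * fs / 1000.0
    d = max(1, int(round(min_distance_ms * fs / 1000.0)))
    peaks, _ = sps.find_peaks(ccg.values, prominence=min_prominence,
                              width=w, distance=d, rel_height=0.5)
    return int(len(peaks))


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------

def _equal_occupancy_codes(v: np.ndarray, k: int) -> np.ndarray:
    """Quantile-bin a continuous variable into ``k`` codes."""
    edges = np.quantile(v, np.linspace(0, 1, k + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def _plugin_mi(a_codes: np.ndarray, b_codes: np.ndarray) -> float:
    joint = np.zeros((a_codes.max() + 1, b_codes.max() + 1))
    np.add.at(joint, (a_codes, b_codes), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def mutual_information(a, b, mode: str = "cont_cont") -> float:
    """Plug-in (histogram) mutual information in bits.

    ``mode`` selects the treatment of the inputs: ``cont_cont`` quantile-
    bins both with ``ceil(n**(1/3))`` equal-occupancy bins per variable,
    ``disc_cont`` bins only the second, ``disc_disc`` uses the raw values
    as categories.  Inputs are expected already aligned and resampled to a
    common rate (1 kHz in the recording pipeline; spike trains as binary
    vectors).

    The estimate is non-negative and for discrete inputs satisfies
    ``MI(a, a) = H(a)`` exactly.  No bias correction is applied: for
    independent continuous inputs the estimate approaches
    ``(k-1)^2 / (2 n ln 2)`` bits rather than zero, about 0.015 bits at
    ``n = 1e5``.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    n = a.size
    k = max(2, int(np.ceil(n ** (1.0 / 3.0))))
    if mode == "cont_cont":
        ac = _equal_occupancy_codes(a.astype(float), k)
        bc = _equal_occupancy_codes(b.astype(float), k)
    elif mode == "disc_cont":
        _, ac = np.unique(a, return_inverse=True)
        bc = _equal_occupancy_codes(b.astype(float), k)
    elif mode == "disc_disc":
        _, ac = np.unique(a, return_inverse=True)
        _, bc = np.unique(b, return_inverse=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return max(0.0, _plugin_mi(ac, bc))


# --------------------------------------------------------------------------
# spike trains and spike densities
# --------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """A sorted spike-time sequence (ms).

    ``kind`` is one of ``simple``, ``complex``, ``cortical_unit``.  PC
    simple-spike trains obey a 3 ms minimal inter-spike interval; simple
    spikes pause for at least 8 ms after each complex spike.
    """

    times: np.ndarray
    kind: str = "cortical_unit"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return self.times.size


def spike_density(train, kernel_sd: float = 8.0, bin_ms: float = 1.0,
                  t_start: float | None = None, t_stop: float | None = None):
    """Spike-density function: 1 ms binned counts convolved with a
    Gaussian kernel (SD 8 ms), kernel normalised to unit area.

    Returns ``(times, sdf)`` with rate in spikes/ms; the integral of the
    SDF over time equals the spike count (up to kernel mass lost outside
    an explicitly requested ``[t_start, t_stop)`` range).  Without explicit
    limits the grid pads the spike span by 6 kernel SDs so the integral is
    conserved to ~1e-9.
    """
    times = train.times if isinstance(train, SpikeTrain) else \
        np.asarray(train, dtype=float)
    pad = 6.0 * kernel_sd
    if t_start is None:
        t_start = (times.min() if times.size else 0.0) - pad
    if t_stop is None:
        t_stop = (times.max() if times.size else 0.0) + pad + bin_ms
    n_bins = max(1, int(np.ceil((t_stop - t_start) / bin_ms)))
    edges = t_start + bin_ms * np.arange(n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    half = int(np.ceil(6.0 * kernel_sd / bin_ms))
    kt = np.arange(-half, half + 1) * bin_ms
    kern = np.exp(-0.5 * (kt / kernel_sd) ** 2)
    kern /= kern.sum() * bin_ms
    sdf = sps.fftconvolve(counts.astype(float), kern, mode="same")
    centers = edges[:-1] + bin_ms / 2.0
    return centers, np.maximum(sdf, 0.0)


def trial_corr_matrix(sdf_a: np.ndarray, sdf_b: np.ndarray,
                      bin_ms: float = 10.0, sample_ms: float = 1.0):
    """Trial-by-trial correlation matrix between two units.

    ``sdf_a``/``sdf_b`` are per-trial spike-density arrays of shape
    ``(n_trials, n_samples)`` aligned on movement onset and spanning
    -400..+400 ms (so 80 bins of 10 ms by default; the data are *not*
    baseline-aligned).  Entry ``(i, j)`` is the Pearson r across trials
    between A's activity in bin i and B's in bin j.  Bins with zero
    variance across trials yield NaN (flagged, excluded downstream).
    """
    A = np.asarray(sdf_a, dtype=float)
    B = np.asarray(sdf_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("trial arrays must have equal shapes")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    step = int(round(bin_ms / sample_ms))
    n_bins = A.shape[1] // step
    Ab = A[:, :n_bins * step].reshape(A.shape[0], n_bins, step).mean(axis=2)
    Bb = B[:, :n_bins * step].reshape(B.shape[0], n_bins, step).mean(axis=2)
    Ab = Ab - Ab.mean(axis=0)
    Bb = Bb - Bb.mean(axis=0)
    sa = Ab.std(axis=0)
    sb = Bb.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ab.T @ Bb) / A.shape[0] / np.outer(sa, sb)
    r[:, sb <= 0] = np.nan
    r[sa <= 0, :] = np.nan
    return r


def asymmetry_index(r_matrix: np.ndarray, epoch: str = "pre",
                    n_bins_total: int = 80) -> float:
    """Directionality index of an epoch submatrix of the trial-correlation
    matrix: mean below-diagonal r minus mean above-diagonal r (diagonal
    excluded).  ``epoch='pre'`` uses bins covering -200..0 ms, ``'move'``
    0..+200 ms of the -400..+400 ms span.
    """
    r = np.asarray(r_matrix, dtype=float)
    q = n_bins_total // 4
    if epoch == "pre":
        sub = r[q:2 * q, q:2 * q]
    elif epoch in ("move", "movement"):
        sub = r[2 * q:3 * q, 2 * q:3 * q]
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    below = sub[np.tril_indices_from(sub, k=-1)]
    above = sub[np.triu_indices_from(sub, k=1)]
    return float(np.nanmean(below) - np.nanmean(above))


# --------------------------------------------------------------------------
# stimulus-evoked LFP responses
# --------------------------------------------------------------------------

@dataclass
class LfpResponse:
    onset_ms: float | None
    peak: float
    significant: bool


def _lowpass_diff(trace: np.ndarray, fs: float, cutoff: float = 80.0):
    """Zero-phase 4th-order Butterworth low-pass then first difference."""
    ny = fs / 2.0
    if cutoff < ny:
        b, a = sps.butter(4, cutoff / ny)
        trace = sps.filtfilt(b, a, trace)
    return np.gradient(trace) * fs / 1000.0  # per-ms slope


def lfp_response(stim_traces: np.ndarray, baseline_traces: np.ndarray,
                 fs: float, stim_index: int,
                 search_ms: float = 100.0) -> LfpResponse:
    """Onset and peak of the stimulus-evoked LFP deflection.

    ``stim_traces`` (n_stim, n_samples) are stimulus-aligned segments with
    the stimulus at sample ``stim_index``; ``baseline_traces`` are
    equally-shaped segments from non-stimulation periods.  The mean trace
    is low-pass filtered at 80 Hz and differentiated; the response onset
    is the first post-stimulus crossing of the baseline mean +/- 2 SD of
    the identically processed baseline.  The peak is the furthest
    deviation of the filtered mean from its pre-stimulus mean within the
    search window (signed).  Significance gates onset reporting only.
    """
    stim_traces = np.atleast_2d(np.asarray(stim_traces, dtype=float))
    baseline_traces = np.atleast_2d(np.asarray(baseline_traces, dtype=float))
    mean = stim_traces.mean(axis=0)
    dmean = _lowpass_diff(mean, fs)
    dbase = _lowpass_diff(baseline_traces.mean(axis=0), fs)
    mu, sd = dbase.mean(), dbase.std()
    if not sd > 0:
        raise ValueError("degenerate baseline (zero SD)")
    n_search = int(round(search_ms * fs / 1000.0))
    seg = dmean[stim_index:stim_index + n_search]
    crossing = np.flatnonzero(np.abs(seg - mu) > 2.0 * sd)
    onset = float(crossing[0] * 1000.0 / fs) if crossing.size else None
    # peak: furthest deviation of the filtered mean from the pre-stimulus mean
    ny = fs / 2.0
    b, a = sps.butter(4, min(80.0 / ny, 0.99))
    fmean = sps.filtfilt(b, a, mean)
    pre_mean = fmean[:stim_index].mean()
    resp = fmean[stim_index:stim_index + n_search] - pre_mean
    peak = float(resp[np.argmax(np.abs(resp))])
    return LfpResponse(onset_ms=onset, peak=peak,
                       significant=crossing.size > 0)
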