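"""Beat detectors.

Each detector maps a (usually preprocessed) :class:`WaveSignal` to a
:class:`PeakTrain`. The registry keys the implementations by the codenames
used throughout the evaluation harness; external detectors can be plugged
in with :func:`register_detector`.

The central method is the sliding-window maximum detector
(``nabian2018``): a point is a beat iff it is the highest sample of the
window centered on it. The simplified variant is exactly that rule; the
full variant additionally rejects low-amplitude peaks against a running
mean of accepted amplitudes and interpolates peaks into abnormally long
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .signals import PeakTrain, WaveSignal

__all__ = [
    "DetectorConfig",
    "detect_nabian",
    "detect_pan_tompkins",
    "detect_hamilton",
    "detect_elgendi",
    "detect_gradient",
    "promac_combine",
    "list_detectors",
    "get_detector",
    "register_detector",
]


@dataclass
class DetectorConfig:
    """Tunable constants shared by the detector registry."""

    method: str = "nabian2018"
    window_ms: float = 400.0
    refractory_ms: float = 200.0
    amplitude_fraction: float = 0.4
    gap_factor: float = 1.5
    promac_sigma_ms: float = 10.0
    promac_threshold: float = 0.33

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be > 0")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be >= 0")
        if not 0 < self.promac_threshold <= 1:
            raise ValueError("promac_threshold must be in (0, 1]")


def _check_signal(sig: WaveSignal, min_duration_s: float = 0.0) -> np.ndarray:
    x = np.asarray(sig.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if min_duration_s and sig.duration_s < min_duration_s:
        raise ValueError(
            f"signal too short ({sig.duration_s:.2f} s < {min_duration_s} s)"
        )
    return x


# ---------------------------------------------------------------------------
# sliding-window maximum detector
# ---------------------------------------------------------------------------

def _window_max_peaks(x: np.ndarray, half: int) -> np.ndarray:
    """Indices i with x[i] the maximum of the full centered window
    [i-half, i+half]; ties resolve to the earliest sample of a plateau.

    Vectorised as: strictly greater than everything in the trailing
    half-window, at least as great as everything in the leading one.
    Edge indices whose window is incomplete never qualify.
    """
    n = x.size
    if 2 * half + 1 > n:
        raise ValueError("window longer than signal")
    h = half
    # trailing[i] = max(x[i-h+1 .. i]); origin shifts the h-wide window so
    # its last element sits at i (ndimage: positive origin moves the window
    # towards earlier samples)
    origin = h - 1 - h // 2
    trailing = maximum_filter1d(x, size=h, mode="constant", cval=-np.inf,
                                origin=origin)
    left = np.concatenate(([-np.inf], trailing[:-1]))  # max over [i-h, i-1]
    # leading_from[i] = max(x[i .. i+h-1]) via the trailing max of the
    # reversed signal (keeps origin inside scipy's legal range for even h)
    trailing_rev = maximum_filter1d(x[::-1], size=h, mode="constant",
                                    cval=-np.inf, origin=origin)
    leading_from = trailing_rev[::-1]
    right = np.concatenate((leading_from[1:], [-np.inf]))  # max over [i+1, i+h]
    mask = (x > left) & (x >= right)
    mask[:h] = False
    mask[n - h:] = False
    return np.flatnonzero(mask)


def _nabian_postprocess(
    x: np.ndarray,
    peaks: np.ndarray,
    fs: float,
    amplitude_fraction: float,
    gap_factor: float,
) -> np.ndarray:
    """Full-variant post-detection: amplitude restriction then gap filling."""
    accepted: List[int] = []
    running_mean = 0.0
    for idx in peaks:
        amp = x[idx]
        if accepted and amp < amplitude_fraction * running_mean:
            continue
        accepted.append(int(idx))
        running_mean += (amp - running_mean) / len(accepted)
    if len(accepted) < 3:
        return np.asarray(accepted, dtype=np.int64)
    intervals = np.diff(accepted)
    median_iv = float(np.median(intervals))
    out: List[int] = [accepted[0]]
    for prev, nxt in zip(accepted[:-1], accepted[1:]):
        if nxt - prev > gap_factor * median_iv:
            out.append(int((prev + nxt) // 2))  # interpolated missing beat
        out.append(nxt)
    return np.asarray(sorted(set(out)), dtype=np.int64)


def detect_nabian(
    sig: WaveSignal,
    window_ms: float = 400.0,
    simplified: bool = True,
    amplitude_fraction: float = 0.4,
    gap_factor: float = 1.5,
) -> PeakTrain:
    """Sliding-window maximum beat detector.

    A sliding window of ``window_ms`` moves one sample at a time; the
    highest point of the window is a beat when it lies at the window
    center. ``simplified=False`` adds the original post-detection:
    amplitude restriction against ``amplitude_fraction`` times the running
    mean of accepted peak amplitudes, and interpolation of a peak at the
    midpoint of any gap exceeding ``gap_factor`` times the median accepted
    interval.
    """
    x = _check_signal(sig)
    w = int(round(window_ms * sig.fs / 1000.0))
    if w < 3:
        raise ValueError(f"window of {window_ms} ms is under 3 samples at fs={sig.fs}")
    half = w // 2
    peaks = _window_max_peaks(x, half)
    if not simplified:
        peaks = _nabian_postprocess(x, peaks, sig.fs, amplitude_fraction, gap_factor)
    return PeakTrain(peaks, sig.fs)


def nabian_bruteforce(sig: WaveSignal, window_ms: float = 400.0) -> PeakTrain:
    """Literal per-index oracle for the simplified sliding-window rule.

    Tests every index against the max of its full centered window; kept
    deliberately free of the incremental tricks of :func:`detect_nabian`
    so the two can cross-check each other.
    """
    x = _check_signal(sig)
    w = int(round(window_ms * sig.fs / 1000.0))
    if w < 3:
        raise ValueError("window under 3 samples")
    half = w // 2
    if 2 * half + 1 > x.size:
        raise ValueError("window longer than signal")
    windows = np.lib.stride_tricks.sliding_window_view(x, 2 * half + 1)
    centers = x[half : x.size - half]
    wmax = windows.max(axis=1)
    # earliest sample of a tied plateau: strictly greater than all before it
    lmax = windows[:, :half].max(axis=1)
    peaks = np.flatnonzero((centers == wmax) & (centers > lmax)) + half
    return PeakTrain(peaks, sig.fs)


# ---------------------------------------------------------------------------
# derivative/energy detectors
# ---------------------------------------------------------------------------

def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Interior strict local maxima (plateau -> earliest sample)."""
    if x.size < 3:
        return np.empty(0, dtype=np.int64)
    prev = x[:-2]
    cur = x[1:-1]
    nxt = x[2:]
    return np.flatnonzero((cur > prev) & (cur >= nxt)) + 1


def _snap_to_signal_peak(x: np.ndarray, idx: int, radius: int) -> int:
    lo = max(idx - radius, 0)
    hi = min(idx + radius + 1, x.size)
    return lo + int(np.argmax(x[lo:hi]))


def detect_pan_tompkins(sig: WaveSignal) -> PeakTrain:
    """Derivative-squaring-integration detector with adaptive dual thresholds.

    Differentiation, squaring and 150 ms moving-window integration produce
    an energy envelope; signal and noise levels adapt per candidate peak,
    with a 200 ms refractory period and a search-back pass when no beat is
    found within 1.66x the running average interval. Detected positions are
    snapped to the local maximum of the input signal within +-75 ms.
    """
    if sig.fs < 100:
        raise ValueError("detect_pan_tompkins requires fs >= 100 Hz")
    x = _check_signal(sig, min_duration_s=2.0)
    fs = sig.fs
    deriv = np.gradient(x)
    energy = deriv * deriv
    mwi = uniform_filter1d(energy, size=max(int(round(0.150 * fs)), 1))

    cand = _local_maxima(mwi)
    cand = cand[mwi[cand] > 0]
    if cand.size == 0:
        return PeakTrain(np.empty(0, dtype=np.int64), fs)

    init = mwi[: int(2 * fs)]
    spki = float(init.max()) * 0.25
    npki = float(init.mean()) * 0.5
    refractory = int(round(0.200 * fs))
    snap = int(round(0.075 * fs))

    accepted: List[int] = []
    rejected: List[int] = []
    rr_history: List[int] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        idx = int(idx)
        if accepted and idx - accepted[-1] < refractory:
            continue
        amp = mwi[idx]
        if amp > threshold():
            # search-back: long gap since previous beat -> recover the best
            # rejected candidate inside it at half threshold
            if accepted and len(rr_history) >= 2:
                avg_rr = float(np.mean(rr_history[-8:]))
                if idx - accepted[-1] > 1.66 * avg_rr:
                    back = [
                        j for j in rejected
                        if accepted[-1] + refractory < j < idx - refractory
                        and mwi[j] > 0.5 * threshold()
                    ]
                    if back:
                        best = max(back, key=lambda j: mwi[j])
                        rr_history.append(best - accepted[-1])
                        accepted.append(best)
            if accepted:
                rr_history.append(idx - accepted[-1])
            accepted.append(idx)
            spki = 0.125 * amp + 0.875 * spki
        else:
            rejected.append(idx)
            npki = 0.125 * amp + 0.875 * npki

    peaks = sorted({_snap_to_signal_peak(x, i, snap) for i in accepted})
    peaks = [p for k, p in enumerate(peaks) if k == 0 or p - peaks[k - 1] >= refractory]
    return PeakTrain(np.asarray(peaks, dtype=np.int64), fs)


def detect_hamilton(sig: WaveSignal) -> PeakTrain:
    """Adaptive-threshold detector on the rectified, 80 ms smoothed signal.

    Candidate local maxima are accepted when they exceed 0.45 times the
    mean of the last 8 accepted peak amplitudes (noise peak amplitudes
    tracked symmetrically for the initial level), with a 200 ms refractory
    period and the same search-back rule as :func:`detect_pan_tompkins`.
    """
    if sig.fs < 100:
        raise ValueError("detect_hamilton requires fs >= 100 Hz")
    x = _check_signal(sig, min_duration_s=2.0)
    fs = sig.fs
    env = uniform_filter1d(np.abs(x), size=max(int(round(0.080 * fs)), 1))
    cand = _local_maxima(env)
    cand = cand[env[cand] > 0]
    if cand.size == 0:
        return PeakTrain(np.empty(0, dtype=np.int64), fs)

    refractory = int(round(0.200 * fs))
    snap = int(round(0.075 * fs))
    sig_amps: List[float] = [float(env[: int(2 * fs)].max())]
    noise_amps: List[float] = [0.0]
    accepted: List[int] = []
    rejected: List[int] = []
    rr_history: List[int] = []

    def threshold() -> float:
        return 0.45 * float(np.mean(sig_amps[-8:]))

    for idx in cand:
        idx = int(idx)
        if accepted and idx - accepted[-1] < refractory:
            continue
        amp = float(env[idx])
        if amp > threshold():
            if accepted and len(rr_history) >= 2:
                avg_rr = float(np.mean(rr_history[-8:]))
                if idx - accepted[-1] > 1.66 * avg_rr:
                    back = [
                        j for j in rejected
                        if accepted[-1] + refractory < j < idx - refractory
                        and env[j] > 0.5 * threshold()
                    ]
                    if back:
                        best = max(back, key=lambda j: env[j])
                        rr_history.append(best - accepted[-1])
                        accepted.append(best)
                        sig_amps.append(float(env[best]))
            if accepted:
                rr_history.append(idx - accepted[-1])
            accepted.append(idx)
            sig_amps.append(amp)
        else:
            rejected.append(idx)
            noise_amps.append(amp)

    peaks = sorted({_snap_to_signal_peak(x, i, snap) for i in accepted})
    peaks = [p for k, p in enumerate(peaks) if k == 0 or p - peaks[k - 1] >= refractory]
    return PeakTrain(np.asarray(peaks, dtype=np.int64), fs)


def detect_elgendi(
    sig: WaveSignal,
    w1_ms: float = 97.0,
    w2_ms: float = 611.0,
    beta: float = 0.08,
) -> PeakTrain:
    """Two-moving-average block detector on the squared signal.

    Blocks where the event average (``w1_ms``) exceeds the beat average
    (``w2_ms``) plus ``beta`` times the mean squared signal are candidate
    complexes; blocks shorter than ``w1_ms`` are rejected and each
    surviving block contributes its maximum (earliest sample on ties).
    """
    if sig.fs < 100:
        raise ValueError("detect_elgendi requires fs >= 100 Hz")
    x = _check_signal(sig, min_duration_s=2.0)
    fs = sig.fs
    y = x * x
    w1 = max(int(round(w1_ms * fs / 1000.0)), 1)
    w2 = max(int(round(w2_ms * fs / 1000.0)), 1)
    ma_event = uniform_filter1d(y, size=w1)
    ma_beat = uniform_filter1d(y, size=w2)
    thr = ma_beat + beta * float(y.mean())
    active = ma_event > thr
    if not active.any():
        return PeakTrain(np.empty(0, dtype=np.int64), fs)
    padded = np.r_[False, active, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    peaks = [
        int(s + np.argmax(y[s:e]))
        for s, e in zip(starts, stops)
        if e - s >= w1
    ]
    return PeakTrain(np.asarray(peaks, dtype=np.int64), fs)


def detect_gradient(sig: WaveSignal) -> PeakTrain:
    """Absolute-gradient steepness detector (QRS-complex style).

    The absolute gradient, smoothed over 100 ms, is compared to 1.5x its
    750 ms rolling mean; qualifying stretches at least 40% as long as the
    median stretch become complexes, each contributing the local maximum of
    the input signal, with a 300 ms minimum separation (larger peak wins).
    """
    if sig.fs < 100:
        raise ValueError("detect_gradient requires fs >= 100 Hz")
    x = _check_signal(sig, min_duration_s=2.0)
    fs = sig.fs
    absgrad = np.abs(np.gradient(x))
    smooth = uniform_filter1d(absgrad, size=max(int(round(0.100 * fs)), 1))
    avg = uniform_filter1d(smooth, size=max(int(round(0.750 * fs)), 1))
    # scale-proportional floor so numerically silent stretches stay inactive
    floor = np.finfo(float).eps * 64.0 * float(smooth.max())
    active = smooth > 1.5 * avg + floor
    if not active.any():
        return PeakTrain(np.empty(0, dtype=np.int64), fs)
    padded = np.r_[False, active, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    lengths = stops - starts
    min_len = 0.4 * float(np.median(lengths))
    min_sep = int(round(0.300 * fs))
    peaks: List[int] = []
    for s, e, L in zip(starts, stops, lengths):
        if L < min_len:
            continue
        p = int(s + np.argmax(x[s:e]))
        if peaks and p - peaks[-1] < min_sep:
            if x[p] > x[peaks[-1]]:
                peaks[-1] = p
            continue
        peaks.append(p)
    return PeakTrain(np.asarray(peaks, dtype=np.int64), fs)


# ---------------------------------------------------------------------------
# probabilistic combiner
# ---------------------------------------------------------------------------

def promac_combine(
    sig: WaveSignal,
    methods: Sequence[str],
    sigma_ms: float = 10.0,
    threshold: float = 0.33,
) -> PeakTrain:
    """Probabilistic fusion of several detectors.

    Each method's detections become a binary impulse train convolved with a
    Gaussian of standard deviation ``sigma_ms``; the per-method signals are
    accumulated, normalised to a maximum of 1, and the local maxima above
    ``threshold`` are the fused peaks.
    """
    if not methods:
        raise ValueError("promac_combine needs at least one method")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    x = _check_signal(sig)
    fs = sig.fs
    sigma = sigma_ms * fs / 1000.0
    half = max(int(round(4 * sigma)), 1)
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    acc = np.zeros(x.size)
    for name in methods:
        fn = get_detector(name)
        train = fn(sig)
        impulses = np.zeros(x.size)
        impulses[train.indices] = 1.0
        acc += np.convolve(impulses, kernel, mode="same")
    peak = acc.max()
    if peak <= 0:
        return PeakTrain(np.empty(0, dtype=np.int64), fs)
    acc /= peak
    cand = _local_maxima(acc)
    peaks = cand[acc[cand] > threshold]
    return PeakTrain(peaks.astype(np.int64), fs)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

Detector = Callable[[WaveSignal], PeakTrain]

_REGISTRY: Dict[str, Detector] = {}


def register_detector(name: str, fn: Detector, overwrite: bool = False) -> None:
    """Register a detector callable (plug-in point for external methods)."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"detector {name!r} already registered")
    _REGISTRY[name] = fn


def get_detector(name: str) -> Detector:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown detector {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_detectors() -> List[str]:
    return sorted(_REGISTRY)


register_detector("nabian2018", lambda s: detect_nabian(s, simplified=True))
register_detector("nabian2018_full", lambda s: detect_nabian(s, simplified=False))
register_detector("pantompkins1985", detect_pan_tompkins)
register_detector("hamilton2002", detect_hamilton)
register_detector("elgendi2010", detect_elgendi)
register_detector("neurokit", detect_gradient)
register_detector(
    "promac",
    lambda s: promac_combine(s, ["nabian2018", "neurokit", "elgendi2010"]),
)
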