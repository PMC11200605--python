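"""Channel selection, heart-rate variability, and averaged heartbeats.

With multi-patch recordings the best accelerometer channel must be picked
before heart-rate evaluation. Two criteria are offered: minimal absolute
HR difference against the ECG reference (needs ECG), and minimal SDNN of
the detected JJ intervals — an ECG-free proxy built on the observation
that a poorly detected beat train is also an implausibly variable one.

Detected beats also anchor averaged heartbeat traces, the raw material for
fiducial-point analysis of cardiac mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .detect import get_detector
from .evaluate import compute_hr, detect_reference_rpeaks, trim_peaks
from .preprocess import apply_pipeline
from .signals import ChannelId, PeakTrain, SyncRecord, WaveSignal

__all__ = ["BeatAverage", "sdnn", "select_channel", "average_beat"]


def sdnn(p: PeakTrain) -> float:
    """Standard deviation of successive beat intervals, in ms.

    Uses the population standard deviation (HRV-tooling convention; the
    sample/population distinction is negligible beyond ~100 beats). No
    ectopy or artifact exclusion is applied — intervals are taken as-is.
    """
    if len(p) < 3:
        raise ValueError("need >= 3 peaks (>= 2 intervals) for SDNN")
    return float(np.std(p.intervals_ms))


@dataclass(frozen=True)
class BeatAverage:
    """Anchored beat ensemble: per-beat traces and their mean."""

    pre_ms: float
    post_ms: float
    fs: float
    mean_trace: np.ndarray
    beat_matrix: np.ndarray  # beats x window samples
    anchor_count: int
    excluded_count: int

    @property
    def time_ms(self) -> np.ndarray:
        n = self.mean_trace.size
        return (np.arange(n) - round(self.pre_ms * self.fs / 1000.0)) * 1000.0 / self.fs

    def to_frame(self, include_beats: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time_ms, "mean": self.mean_trace})
        if include_beats:
            for k, row in enumerate(self.beat_matrix):
                df[f"beat_{k}"] = row
        return df

    def plot(self, ax=None):
        """Render the individual trajectories and their mean (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.time_ms
        for row in self.beat_matrix:
            ax.plot(t, row, color="0.7", lw=0.5)
        ax.plot(t, self.mean_trace, color="C1", lw=2)
        ax.axvline(0.0, color="k", ls=":", lw=0.8)
        ax.set_xlabel("time from anchor (ms)")
        ax.set_ylabel("amplitude")
        return ax


def average_beat(
    sig: WaveSignal,
    anchors: PeakTrain,
    pre_ms: float = 200.0,
    post_ms: float = 600.0,
) -> BeatAverage:
    """Stack ``[anchor - pre_ms, anchor + post_ms)`` windows and average.

    Amplitudes are not normalised. Anchors whose window would cross the
    signal bounds are excluded and counted in ``excluded_count``.
    """
    if anchors.fs != sig.fs:
        raise ValueError("anchor train and signal sampling rates differ")
    pre = int(round(pre_ms * sig.fs / 1000.0))
    post = int(round(post_ms * sig.fs / 1000.0))
    win = pre + post
    if win < 1:
        raise ValueError("window is empty")
    rows = []
    excluded = 0
    for a in anchors.indices:
        lo, hi = int(a) - pre, int(a) + post
        if lo < 0 or hi > sig.n_samples:
            excluded += 1
            continue
        rows.append(sig.samples[lo:hi])
    if not rows:
        raise ValueError("no anchor has a complete window inside the signal")
    beat_matrix = np.vstack(rows)
    return BeatAverage(
        pre_ms=pre_ms,
        post_ms=post_ms,
        fs=sig.fs,
        mean_trace=beat_matrix.mean(axis=0),
        beat_matrix=beat_matrix,
        anchor_count=len(rows),
        excluded_count=excluded,
    )


def select_channel(
    rec: SyncRecord,
    pipeline: str,
    detector: str,
    criterion: str = "hr_diff",
    r_detector: str = "neurokit",
) -> Tuple[ChannelId, pd.DataFrame]:
    """Pick the SCG channel minimising ``criterion`` over every (patch, axis).

    ``criterion="hr_diff"`` needs the ECG reference; ``criterion="sdnn"``
    is ECG-free. Ties resolve to the lexicographically smallest channel id
    (the report makes ties visible). Channels on which detection fails are
    scored NaN; if every channel fails, an error is raised.
    """
    if criterion not in ("hr_diff", "sdnn"):
        raise ValueError("criterion must be 'hr_diff' or 'sdnn'")
    r_train: Optional[PeakTrain] = None
    if criterion == "hr_diff":
        r_train = detect_reference_rpeaks(rec.ecg, r_detector)
        if len(r_train) < 2:
            raise ValueError("criterion hr_diff needs >= 2 reference R-peaks")
    records = []
    for cid in rec.channels:
        row: Dict[str, object] = {"channel": str(cid)}
        try:
            cleaned = apply_pipeline(rec.scg[cid], pipeline)
            j = get_detector(detector)(cleaned)
            if r_train is not None:
                j = trim_peaks(j, r_train)
                row["hr_scg"] = compute_hr(j)
                row["hr_ecg"] = compute_hr(r_train)
                row["score"] = abs(row["hr_scg"] - row["hr_ecg"])
            else:
                row["score"] = sdnn(j)
            row["n_peaks"] = len(j)
        except (ValueError, KeyError):
            row["score"] = math.nan
            row["n_peaks"] = 0
        records.append(row)
    report = pd.DataFrame(records)
    report["criterion"] = criterion
    if report["score"].isna().all():
        raise ValueError("detection failed on every channel")
    best_score = report["score"].min()
    report["tie"] = np.isclose(report["score"], best_score)
    # channels are iterated in sorted order, so idxmin already honours the
    # lexicographic tie-break
    best = ChannelId.parse(report.loc[report["score"].idxmin(), "channel"])
    return best, report
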