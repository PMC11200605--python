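"""Core domain types shared by every processing stage.

A recording is represented as a :class:`SyncRecord`: one ECG channel plus a
map of accelerometer (SCG) channels, all sampled on a common time base.
Detected beats are carried around as a :class:`PeakTrain` of strictly
increasing sample indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "WaveSignal",
    "ChannelId",
    "SyncRecord",
    "PeakTrain",
    "resample_record",
    "segment_episodes",
]


@dataclass(frozen=True)
class WaveSignal:
    """One uniformly sampled channel (ECG in mV or SCG acceleration, a.u.).

    Parameters
    ----------
    samples : array-like of float
        The signal samples. Must be non-empty and finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text channel label, e.g. ``"ECG-I"`` or ``"patch1_z"``.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "WaveSignal":
        """Return a copy carrying new samples (and optionally a new fs)."""
        return WaveSignal(samples, self.fs if fs is None else fs, self.label)


# Axis names follow the triaxial-accelerometer convention; "combined" covers
# single-channel datasets whose axes were merged at acquisition time (CEBS).
_AXES = ("x", "y", "z", "combined")


@dataclass(frozen=True, order=True)
class ChannelId:
    """Identifies one SCG channel by sensor patch and accelerometer axis."""

    patch: int
    axis: str

    def __post_init__(self) -> None:
        if self.patch < 0:
            raise ValueError("patch index must be >= 0")
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")

    def __str__(self) -> str:
        return f"patch{self.patch}_{self.axis}"

    @classmethod
    def parse(cls, text: str) -> "ChannelId":
        """Parse ``"patch<k>_<axis>"`` back into a ChannelId."""
        if not text.startswith("patch") or "_" not in text:
            raise ValueError(f"cannot parse channel id {text!r}")
        head, axis = text.split("_", 1)
        return cls(int(head[5:]), axis)


@dataclass(frozen=True)
class SyncRecord:
    """Time-aligned ECG channel plus one or more SCG channels."""

    ecg: WaveSignal
    scg: Dict[ChannelId, WaveSignal]
    fs: float = 0.0

    def __post_init__(self) -> None:
        if not self.scg:
            raise ValueError("at least one SCG channel is required")
        fs = self.fs if self.fs > 0 else self.ecg.fs
        n = self.ecg.n_samples
        for cid, sig in self.scg.items():
            if sig.fs != fs or self.ecg.fs != fs:
                raise ValueError(f"channel {cid} fs {sig.fs} != record fs {fs}")
            if sig.n_samples != n:
                raise ValueError(
                    f"channel {cid} length {sig.n_samples} != ECG length {n}"
                )
        object.__setattr__(self, "fs", float(fs))

    @property
    def n_samples(self) -> int:
        return self.ecg.n_samples

    @property
    def duration_s(self) -> float:
        return self.ecg.duration_s

    @property
    def channels(self) -> List[ChannelId]:
        return sorted(self.scg)


@dataclass(frozen=True)
class PeakTrain:
    """Strictly increasing sample indices of detected beats."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("peak indices must be non-negative")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    @property
    def intervals_ms(self) -> np.ndarray:
        """Successive beat-to-beat intervals in milliseconds."""
        return np.diff(self.indices) * 1000.0 / self.fs

    @classmethod
    def from_times_ms(cls, times_ms: Sequence[float], fs: float) -> "PeakTrain":
        idx = np.round(np.asarray(times_ms, dtype=float) * fs / 1000.0).astype(np.int64)
        return cls(idx, fs)


def _resample_channel(sig: WaveSignal, target_fs: float) -> WaveSignal:
    from fractions import Fraction

    frac = Fraction(target_fs / sig.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(sig.samples, up, down)
    return WaveSignal(out, target_fs, sig.label)


def resample_record(rec: SyncRecord, target_fs: float, allow_upsample: bool = False) -> SyncRecord:
    """Resample every channel of a record to ``target_fs``.

    Downsampling applies polyphase anti-alias filtering; upsampling is
    refused unless ``allow_upsample`` is set, since it adds no information.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be > 0")
    if target_fs == rec.fs:
        return rec
    if target_fs > rec.fs and not allow_upsample:
        raise ValueError(
            f"target_fs {target_fs} exceeds record fs {rec.fs}; "
            "pass allow_upsample=True to permit it"
        )
    ecg = _resample_channel(rec.ecg, target_fs)
    scg = {cid: _resample_channel(sig, target_fs) for cid, sig in rec.scg.items()}
    return SyncRecord(ecg=ecg, scg=scg, fs=target_fs)


def _slice_record(rec: SyncRecord, start: int, stop: int) -> SyncRecord:
    ecg = rec.ecg.with_samples(rec.ecg.samples[start:stop])
    scg = {
        cid: sig.with_samples(sig.samples[start:stop]) for cid, sig in rec.scg.items()
    }
    return SyncRecord(ecg=ecg, scg=scg, fs=rec.fs)


def segment_episodes(
    rec: SyncRecord,
    episode_s: float,
    n: int,
    seed: int,
    allow_overlap: bool | None = None,
) -> List[SyncRecord]:
    """Cut ``n`` random episodes of exactly ``episode_s`` seconds.

    Start offsets are drawn uniformly from the feasible range with a seeded
    generator, so the same seed always yields the same episodes. Episodes are
    half-open windows ``[start, start + episode_s)``. When ``n``
    non-overlapping episodes fit, starts are redrawn until disjoint unless
    ``allow_overlap=True``; when they cannot fit, overlap is allowed with a
    warning (or an error if ``allow_overlap=False``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ep_len = int(round(episode_s * rec.fs))
    if ep_len > rec.n_samples:
        raise ValueError(
            f"record ({rec.duration_s:.1f} s) shorter than episode ({episode_s} s)"
        )
    rng = np.random.default_rng(seed)
    max_start = rec.n_samples - ep_len
    fits_disjoint = n * ep_len <= rec.n_samples

    if fits_disjoint and allow_overlap is not True:
        # rejection-sample disjoint placements; falls back to a deterministic
        # grid layout jittered by the rng if rejection keeps failing
        for _ in range(200):
            starts = np.sort(rng.integers(0, max_start + 1, size=n))
            if n == 1 or np.all(np.diff(starts) >= ep_len):
                break
        else:
            slack = (rec.n_samples - n * ep_len) // max(n, 1)
            offs = rng.integers(0, slack + 1, size=n) if slack > 0 else np.zeros(n, int)
            starts = np.arange(n) * (ep_len + slack) + offs
    else:
        if not fits_disjoint:
            if allow_overlap is False:
                raise ValueError("record too short for non-overlapping episodes")
            warnings.warn(
                "record too short for non-overlapping episodes; allowing overlap",
                stacklevel=2,
            )
        starts = np.sort(rng.integers(0, max_start + 1, size=n))
    return [_slice_record(rec, int(s), int(s) + ep_len) for s in starts]
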