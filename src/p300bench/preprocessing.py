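"""Per-system filter chains, epoch extraction, and classifier features.

The on-line spelling path uses *causal* Butterworth band-pass filtering (a
real-time system cannot look ahead); offline analyses use zero-phase
forward-backward filtering.  Epochs are cut relative to each flash onset and
reduced to a feature vector by moving-average decimation per channel, then
concatenation across channels — the classical feature space for SWLDA-based
P300 classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .synthetic_eeg import FlashEvent, FlashSchedule, RawRecording, SystemProfile

__all__ = [
    "FilterSpec",
    "EpochSet",
    "FeatureMatrix",
    "design_bandpass",
    "online_filter_for",
    "apply_filter",
    "extract_epochs",
    "build_features",
    "epoch_sample_count",
]


@dataclass(frozen=True)
class FilterSpec:
    """A realizable Butterworth band-pass.

    ``mode`` selects causal (forward-only, on-line plausible) or zero-phase
    (forward-backward, offline) application.  The second-order-section
    representation is designed lazily per sampling rate.
    """

    order: int
    band: tuple[float, float]
    mode: Literal["causal", "zero-phase"] = "zero-phase"

    def __post_init__(self) -> None:
        low, high = self.band
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 <= low < high:
            raise ValueError(f"invalid band {self.band}")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def sos(self, fs: float) -> np.ndarray:
        low, high = self.band
        if high >= fs / 2:
            raise ValueError(
                f"upper cut-off {high} Hz >= Nyquist for fs={fs}"
            )
        return signal.butter(self.order, self.band, btype="bandpass",
                             fs=fs, output="sos")

    def frequency_response(self, freqs: Sequence[float],
                           fs: float) -> np.ndarray:
        """Single-pass magnitude response at ``freqs`` (Hz)."""
        w, h = signal.sosfreqz(self.sos(fs), worN=np.asarray(freqs, float),
                               fs=fs)
        return np.abs(h)


def design_bandpass(order: int, low: float, high: float, fs: float,
                    mode: Literal["causal", "zero-phase"] = "zero-phase",
                    ) -> FilterSpec:
    """Design a Butterworth band-pass valid for sampling rate ``fs``.

    The designed (single-pass) magnitude response is −3 dB at both cut-offs,
    the Butterworth property.
    """
    spec = FilterSpec(order=order, band=(low, high), mode=mode)
    spec.sos(fs)  # validate against fs now rather than at application time
    return spec


def online_filter_for(profile: SystemProfile) -> FilterSpec:
    """The causal band-pass a system applies during on-line spelling."""
    return FilterSpec(order=profile.filter_order, band=profile.online_band,
                      mode="causal")


def apply_filter(recording: RawRecording | np.ndarray, spec: FilterSpec,
                 fs: float | None = None) -> RawRecording | np.ndarray:
    """Filter a recording (or bare array) along time; shape is preserved."""
    if isinstance(recording, RawRecording):
        out = apply_filter(recording.data, spec, fs=recording.fs)
        return RawRecording(out, recording.fs,
                            channel_names=recording.channel_names,
                            schedule=recording.schedule)
    if fs is None:
        raise ValueError("fs required when filtering a bare array")
    sos = spec.sos(fs)
    x = np.asarray(recording, dtype=float)
    if spec.mode == "causal":
        return signal.sosfilt(sos, x, axis=-1)
    return signal.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# epochs


@dataclass
class EpochSet:
    """Per-flash epochs (items × channels × samples) with target labels."""

    epochs: np.ndarray
    window: tuple[float, float]
    labels: np.ndarray            # boolean, True = target flash
    flash_meta: list[FlashEvent]  # (onset, kind, index, sequence, item)
    fs: float
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.epochs.shape[0]


def epoch_sample_count(window: tuple[float, float], fs: float) -> int:
    """Samples per epoch: ``floor(end·fs) − floor(start·fs) + 1``."""
    start, end = window
    return int(np.floor(end * fs)) - int(np.floor(start * fs)) + 1


def extract_epochs(recording: RawRecording,
                   window: tuple[float, float] = (0.0, 0.8)) -> EpochSet:
    """Cut one epoch per flash event, labelled target/non-target.

    A flash is a *target* iff its row or column contains the attended cell of
    the item being spelled.  Events whose window would extend past either end
    of the recording are dropped with a warning; the count is reported in
    ``n_dropped``.
    """
    start, end = window
    if not (-1.0 < start < end < 2.0):
        raise ValueError("window must satisfy -1 < start < end < 2 (seconds)")
    if recording.schedule is None:
        raise ValueError("recording carries no flash schedule")
    sched = recording.schedule
    fs = recording.fs
    n_samp = epoch_sample_count(window, fs)
    off0 = int(np.floor(start * fs))

    kept: list[FlashEvent] = []
    labels: list[bool] = []
    chunks: list[np.ndarray] = []
    dropped = 0
    for ev in sched.events:
        i0 = int(np.floor(ev.onset * fs)) + off0
        i1 = i0 + n_samp
        if i0 < 0 or i1 > recording.n_samples:
            dropped += 1
            continue
        chunks.append(recording.data[:, i0:i1])
        kept.append(ev)
        labels.append(sched.flash_hits_target(ev)
                      if sched.targets is not None else False)
    if dropped:
        warnings.warn(f"dropped {dropped} epoch(s) at recording boundaries",
                      stacklevel=2)
    epochs = (np.stack(chunks) if chunks
              else np.empty((0, recording.n_channels, n_samp)))
    return EpochSet(epochs, window, np.asarray(labels, bool), kept, fs,
                    n_dropped=dropped)


# ---------------------------------------------------------------------------
# features


@dataclass
class FeatureMatrix:
    """Classifier input: items × (channels × time-bins), labels ±1."""

    X: np.ndarray
    y: np.ndarray
    feature_map: list[tuple[int, int]]  # (channel, bin) per column
    flash_meta: list[FlashEvent]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")


def build_features(epochs: EpochSet, decimation_hz: float = 20.0,
                   channels: Sequence[int] | None = None) -> FeatureMatrix:
    """Moving-average decimate each channel and concatenate across channels.

    Each epoch channel is averaged within ``n_bins = floor(n_samples ·
    decimation_hz / fs)`` contiguous bins of (near-)equal width; with
    ``decimation_hz == fs`` the features are the raw samples.  Labels are
    +1 for target flashes and −1 for non-targets.
    """
    if decimation_hz > epochs.fs:
        raise ValueError("decimation rate cannot exceed the sampling rate")
    n_items, n_ch, n_samp = epochs.epochs.shape
    if channels is None:
        channels = list(range(n_ch))
    n_bins = int(np.floor(n_samp * decimation_hz / epochs.fs))
    if n_bins < 1:
        raise ValueError("decimation leaves zero bins per epoch")
    edges = np.floor(np.arange(n_bins + 1) * n_samp / n_bins).astype(int)

    cols = []
    fmap: list[tuple[int, int]] = []
    for ch in channels:
        for b in range(n_bins):
            cols.append(epochs.epochs[:, ch, edges[b]:edges[b + 1]]
                        .mean(axis=1))
            fmap.append((ch, b))
    X = (np.stack(cols, axis=1) if cols
         else np.empty((n_items, 0)))
    y = np.where(epochs.labels, 1.0, -1.0)
    return FeatureMatrix(X, y, fmap, epochs.flash_meta)
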