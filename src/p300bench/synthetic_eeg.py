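"""Seeded synthetic multichannel EEG with a P300 oddball structure.

This module generates the raw material every other stage of the package
consumes: row/column flash schedules for a matrix speller, background noise
whose band-limited RMS is calibrated to a named acquisition-system profile,
and full "recording" objects in which a P300-like deflection is added to the
noise for every flash that highlights the attended cell.

The three built-in :class:`SystemProfile` instances describe a hydrogel-based,
a tap-water-based, and a dry-electrode acquisition system: sampling rate, the
on-line band-pass applied during spelling, and the short-circuit noise floor
(RMS in the 0.1–40 Hz band) the simulated noise is calibrated to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "CHANNEL_NAMES",
    "DEFAULT_CHANNEL_WEIGHTS",
    "SystemProfile",
    "BUILTIN_PROFILES",
    "get_profile",
    "FlashEvent",
    "FlashSchedule",
    "ERPTemplate",
    "RawRecording",
    "make_flash_schedule",
    "generate_background_noise",
    "synthesize_session",
]

#: Electrode montage used throughout (extended 10–20 positions).
CHANNEL_NAMES: tuple[str, ...] = ("Fz", "Cz", "Pz", "PO7", "PO8", "Oz")

#: Relative P300 gain per channel: centro-parietal maximum, typical topography.
DEFAULT_CHANNEL_WEIGHTS: tuple[float, ...] = (0.5, 0.8, 1.0, 0.7, 0.7, 0.6)


@dataclass(frozen=True)
class SystemProfile:
    """Named acquisition-system configuration.

    Parameters
    ----------
    name
        Short identifier (``"hydrogel"``, ``"tap_water"``, ``"dry"``).
    fs
        Sampling rate in Hz.
    online_band
        ``(low, high)`` cut-offs in Hz of the band-pass applied to the
        spelling data.
    filter_order
        Butterworth order of that band-pass.
    shortcircuit_rms_target
        Noise floor of the system in μV RMS, measured in the 0.1–40 Hz band
        with the electrodes short-circuited; used as the calibration target of
        the synthetic noise.
    scalp_noise_scale
        Dimensionless multiplier applied to the short-circuit level when
        simulating scalp EEG (spontaneous EEG is far above the instrument
        floor).  A free simulation parameter, not a measured quantity.
    """

    name: str
    fs: float
    online_band: tuple[float, float]
    filter_order: int = 4
    shortcircuit_rms_target: float = 1.0
    scalp_noise_scale: float = 10.0

    def __post_init__(self) -> None:
        low, high = self.online_band
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= low < high < self.fs / 2):
            raise ValueError(
                f"band {self.online_band} invalid for fs={self.fs}"
            )
        if self.shortcircuit_rms_target < 0:
            raise ValueError("noise RMS target must be non-negative")

    @property
    def scalp_rms(self) -> float:
        """Calibrated scalp-simulation RMS (floor × scale), μV."""
        return self.shortcircuit_rms_target * self.scalp_noise_scale


BUILTIN_PROFILES: dict[str, SystemProfile] = {
    p.name: p
    for p in (
        SystemProfile("hydrogel", fs=256.0, online_band=(0.1, 60.0),
                      filter_order=4, shortcircuit_rms_target=0.68),
        SystemProfile("tap_water", fs=250.0, online_band=(0.1, 60.0),
                      filter_order=4, shortcircuit_rms_target=0.37),
        SystemProfile("dry", fs=256.0, online_band=(0.5, 30.0),
                      filter_order=4, shortcircuit_rms_target=0.82),
    )
}


def get_profile(name: str) -> SystemProfile:
    """Look up a built-in profile by name (``hydrogel``/``tap_water``/``dry``)."""
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(BUILTIN_PROFILES)}"
        ) from None


class FlashEvent(NamedTuple):
    """One row or column flash."""

    onset: float          # seconds from recording start
    kind: Literal["row", "col"]
    index: int            # row or column index within the matrix
    sequence: int         # 0-based sequence number within the item
    item: int             # 0-based spelled-item number


@dataclass
class FlashSchedule:
    """Ordered flash events plus the target ground truth.

    One *sequence* is a complete round in which every row and every column of
    the matrix flashes exactly once, so each cell is highlighted twice per
    sequence (once via its row, once via its column).
    """

    matrix_rows: int
    matrix_cols: int
    events: list[FlashEvent]
    soa: float
    flash_duration: float
    targets: list[tuple[int, int]] | None = None

    @property
    def n_items(self) -> int:
        if not self.events:
            return 0
        return max(e.item for e in self.events) + 1

    @property
    def n_sequences(self) -> int:
        """Sequences per item (schedules are homogeneous across items)."""
        if not self.events:
            return 0
        return max(e.sequence for e in self.events) + 1

    def events_for_item(self, item: int) -> list[FlashEvent]:
        return [e for e in self.events if e.item == item]

    def flash_hits_target(self, event: FlashEvent) -> bool:
        """Whether this flash highlights the attended cell of its item."""
        if self.targets is None:
            raise ValueError("schedule has no targets defined")
        row, col = self.targets[event.item]
        return (event.kind == "row" and event.index == row) or (
            event.kind == "col" and event.index == col
        )


@dataclass
class ERPTemplate:
    """Gaussian-bump event-related potential added to target flashes.

    ``peak_amplitude`` is in μV at the maximally weighted channel;
    ``peak_latency`` and ``width`` (the Gaussian sigma) are in seconds
    post-stimulus.  The default latency of 0.35 s sits inside the canonical
    250–500 ms P300 window.
    """

    peak_amplitude: float
    peak_latency: float = 0.35
    width: float = 0.06
    channel_weights: Sequence[float] = DEFAULT_CHANNEL_WEIGHTS

    def __post_init__(self) -> None:
        w = np.asarray(self.channel_weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("channel weights must be finite")
        if self.width <= 0:
            raise ValueError("template width must be positive")

    @property
    def support(self) -> tuple[float, float]:
        """Post-stimulus interval outside which the bump is treated as zero."""
        return (max(0.0, self.peak_latency - 4 * self.width),
                self.peak_latency + 4 * self.width)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the bump at post-stimulus times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.support
        out = self.peak_amplitude * np.exp(
            -0.5 * ((t - self.peak_latency) / self.width) ** 2
        )
        out[(t < lo) | (t > hi)] = 0.0
        return out


@dataclass
class RawRecording:
    """Multichannel signal (channels × samples, μV) with its flash schedule."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    schedule: FlashSchedule | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def truth(self) -> list[tuple[int, int]] | None:
        """Target cell per spelled item, if the schedule defines them."""
        return None if self.schedule is None else self.schedule.targets


# ---------------------------------------------------------------------------
# flash schedules


def make_flash_schedule(
    rows: int,
    cols: int,
    n_sequences: int,
    soa: float = 0.25,
    flash_duration: float = 0.0625,
    seed: int | np.random.SeedSequence | None = None,
    targets: Sequence[tuple[int, int]] | None = None,
    lead_in: float = 2.0,
    inter_item_gap: float = 2.0,
) -> FlashSchedule:
    """Build a randomized row/column flash schedule.

    Each sequence is an independent random permutation of the ``rows + cols``
    flashes, with the constraint that the same row/column never flashes twice
    in a row across a sequence (or item) boundary.  When ``targets`` is given,
    one block of ``n_sequences`` sequences is generated per target, separated
    by ``inter_item_gap`` seconds.

    Parameters mirror the conventional matrix-speller timing: ``soa`` is the
    stimulus-onset asynchrony between consecutive flashes and
    ``flash_duration`` the highlight time, both in seconds.
    """
    if rows < 1 or cols < 1 or rows + cols < 2:
        raise ValueError("invalid matrix geometry: need rows, cols >= 1")
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if not (soa > flash_duration > 0):
        raise ValueError("require soa > flash_duration > 0")

    target_list = list(targets) if targets is not None else None
    n_items = len(target_list) if target_list is not None else 1
    if target_list is not None:
        for r, c in target_list:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"target ({r}, {c}) outside matrix")

    rng = np.random.default_rng(seed)
    flashes = [("row", i) for i in range(rows)] + [("col", j) for j in range(cols)]
    events: list[FlashEvent] = []
    t = lead_in
    prev: tuple[str, int] | None = None
    for item in range(n_items):
        for seq in range(n_sequences):
            order = [flashes[k] for k in rng.permutation(len(flashes))]
            # forbid an immediate repeat across the boundary
            while len(flashes) > 1 and order[0] == prev:
                order = [flashes[k] for k in rng.permutation(len(flashes))]
            for kind, index in order:
                events.append(FlashEvent(t, kind, index, seq, item))
                t += soa
            prev = order[-1]
        t += inter_item_gap
    return FlashSchedule(rows, cols, events, soa, flash_duration, target_list)


# ---------------------------------------------------------------------------
# background noise


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float],
              order: int, guard_s: float = 0.0) -> float:
    """RMS of ``x`` after zero-phase Butterworth band-pass filtering.

    ``guard_s`` seconds are trimmed from each end *after* filtering so that
    the zero-phase filter's edge transients (which linger for seconds at a
    0.1 Hz high-pass edge) do not bias the estimate.
    """
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    g = int(round(guard_s * fs))
    if g > 0 and y.shape[-1] > 2 * g + 1:
        y = y[..., g:-g]
    return float(np.sqrt(np.mean(y**2)))


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                f_flat: float) -> np.ndarray:
    """1/f-amplitude noise, flat below ``f_flat`` to keep the power finite."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], f_flat))
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    return np.fft.irfft(spec, n=n)


def generate_background_noise(
    profile: SystemProfile,
    duration_s: float,
    seed: int | np.random.SeedSequence | None = None,
    scale: float = 1.0,
    n_channels: int | None = None,
    pink_fraction: float = 0.5,
    calibration_band: tuple[float, float] = (0.1, 40.0),
    calibration_order: int = 8,
) -> RawRecording:
    """Generate calibrated background noise (no events).

    The noise is a mixture of white and pink (1/f) components — by default
    each carrying half the in-band power — rescaled per channel so that the
    RMS inside ``calibration_band`` equals
    ``profile.shortcircuit_rms_target * scale``.  With the default
    ``scale=1`` this reproduces the system's short-circuit noise floor; pass
    ``scale=profile.scalp_noise_scale`` (as :func:`synthesize_session` does)
    for scalp-level noise.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= pink_fraction <= 1.0:
        raise ValueError("pink_fraction must be in [0, 1]")
    if n_channels is None:
        n_channels = len(CHANNEL_NAMES)
    names = (CHANNEL_NAMES if n_channels == len(CHANNEL_NAMES)
             else tuple(f"ch{i}" for i in range(n_channels)))

    n = int(round(duration_s * profile.fs))
    target = profile.shortcircuit_rms_target * scale
    # trim filter edge transients out of the calibration measurement
    guard = min(duration_s / 4.0, 10.0)
    rng = np.random.default_rng(seed)
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        if target == 0:
            data[ch] = 0.0
            continue
        white = rng.standard_normal(n)
        pink = _pink_noise(rng, n, profile.fs, f_flat=calibration_band[0])
        white /= _band_rms(white, profile.fs, calibration_band,
                           calibration_order, guard)
        pink /= _band_rms(pink, profile.fs, calibration_band,
                          calibration_order, guard)
        mix = (math.sqrt(1 - pink_fraction) * white
               + math.sqrt(pink_fraction) * pink)
        mix *= target / _band_rms(mix, profile.fs, calibration_band,
                                  calibration_order, guard)
        data[ch] = mix
    return RawRecording(data, profile.fs, channel_names=names)


# ---------------------------------------------------------------------------
# full sessions


def synthesize_session(
    profile: SystemProfile,
    schedule: FlashSchedule,
    erp: ERPTemplate,
    nontarget_erp: ERPTemplate | None = None,
    lapse_rate: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    noise_scale: float | None = None,
    pad_after: float = 1.5,
) -> RawRecording:
    """Render a recording: calibrated noise plus ERPs at target flashes.

    For every flash that highlights the attended cell the ERP template is
    added on each channel, scaled by its channel weight; with probability
    ``lapse_rate`` a target response is omitted (attention lapse).  An
    optional smaller ``nontarget_erp`` is added for every flash.  Noise and
    lapse randomness are drawn from independent streams spawned from ``seed``,
    so the rendered signal is the exact sample-wise sum of the noise-only and
    the noise-free renderings at the same seed.
    """
    if schedule.targets is None:
        raise ValueError("schedule must define targets")
    if not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("lapse_rate must be in [0, 1]")
    if noise_scale is None:
        noise_scale = profile.scalp_noise_scale

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    noise_ss, lapse_ss = ss.spawn(2)

    last_onset = schedule.events[-1].onset if schedule.events else 0.0
    duration = last_onset + pad_after
    rec = generate_background_noise(profile, duration, seed=noise_ss,
                                    scale=noise_scale)
    data, fs, n = rec.data, rec.fs, rec.n_samples
    weights_t = np.asarray(erp.channel_weights, dtype=float)
    lapse_rng = np.random.default_rng(lapse_ss)

    def _add(template: ERPTemplate, weights: np.ndarray,
             onset: float) -> None:
        lo, hi = template.support
        i0 = max(0, int(np.floor((onset + lo) * fs)))
        i1 = int(np.ceil((onset + hi) * fs)) + 1
        if i1 > n:
            raise ValueError(
                "ERP window extends beyond the recording; increase pad_after"
            )
        t_rel = np.arange(i0, i1) / fs - onset
        data[:, i0:i1] += weights[:, None] * template.waveform(t_rel)[None, :]

    for ev in schedule.events:
        if schedule.flash_hits_target(ev):
            if lapse_rate == 0.0 or lapse_rng.random() >= lapse_rate:
                _add(erp, weights_t, ev.onset)
        if nontarget_erp is not None:
            _add(nontarget_erp,
                 np.asarray(nontarget_erp.channel_weights, float), ev.onset)

    return RawRecording(data, fs, channel_names=rec.channel_names,
                        schedule=schedule)


def with_amplitude(erp: ERPTemplate, amplitude: float) -> ERPTemplate:
    """Copy of ``erp`` with a different peak amplitude."""
    return replace(erp, peak_amplitude=amplitude)
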