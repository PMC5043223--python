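"""Short-circuit noise characterization bench.

Reproduces the technical-test analysis chain applied to each acquisition
system's noise floor: band-limit the signal to 0.1–40 Hz with a zero-phase
8th-order Butterworth filter, drop a head and tail exclusion window (one
minute each by default, guarding against operator movement artifacts),
then compute the overall RMS, a Gaussian-smoothed RMS trace, an amplitude
histogram, and a single-sided amplitude spectrum.

Filtering is applied to the full recording and the exclusion windows are
dropped afterwards, so the windows also absorb the zero-phase filter's edge
transients; samples inside them influence the analyzed segment only through
the filter's impulse-response tail, which has decayed to numerical
insignificance after a few seconds at these band edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic_eeg import RawRecording

__all__ = ["NoiseReport", "analyze_noise", "compare_profiles",
           "gaussian_fir_kernel"]


@dataclass
class NoiseReport:
    """Band-limited noise characterization of one recording."""

    band: tuple[float, float]
    fs: float
    rms_overall: float                       # μV
    rms_trace: tuple[np.ndarray, np.ndarray]  # (times s, smoothed RMS μV)
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges μV, counts)
    amplitude_spectrum: tuple[np.ndarray, np.ndarray]  # (Hz, μV)
    excluded_seconds: tuple[float, float]
    n_samples_analyzed: int
    label: str | None = None


def gaussian_fir_kernel(fs: float, bt: float = 0.1, span: float = 4.0,
                        symbol_time: float = 1.0) -> np.ndarray:
    """Unit-sum Gaussian FIR smoothing kernel.

    ``h(t) ∝ exp(−t²/(2δ²))`` with ``δ = √(ln 2)/(2π·bt)`` in symbol-time
    units, truncated to ``span`` symbol periods and sampled at ``fs``
    (oversampling factor = ``fs · symbol_time`` samples per symbol).  The
    defaults give a kernel whose standard deviation is ≈1.3 s — a
    seconds-scale smoother for RMS envelopes.
    """
    delta = np.sqrt(np.log(2.0)) / (2.0 * np.pi * bt)
    sps = fs * symbol_time
    n_half = int(round(span / 2 * sps))
    t = np.arange(-n_half, n_half + 1) / sps  # symbol units
    h = np.exp(-(t**2) / (2.0 * delta**2))
    return h / h.sum()


def analyze_noise(
    recording: RawRecording | np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] = (0.1, 40.0),
    filter_order: int = 8,
    exclude: tuple[float, float] = (60.0, 60.0),
    hist_bins: int = 100,
    smoother_bt: float = 0.1,
    smoother_span: float = 4.0,
    label: str | None = None,
) -> NoiseReport:
    """Characterize band-limited noise in a recording.

    Accepts a :class:`~p300bench.synthetic_eeg.RawRecording` or a bare
    (channels × samples) / 1-D array with explicit ``fs``.  Raises
    ``ValueError`` when the recording is not longer than the exclusion
    windows.  With multichannel input the RMS pools all channels; the
    amplitude spectrum is the per-channel average.
    """
    if isinstance(recording, RawRecording):
        data, fs = recording.data, recording.fs
    else:
        if fs is None:
            raise ValueError("fs required for array input")
        data = np.atleast_2d(np.asarray(recording, dtype=float))

    head, tail = exclude
    i0 = int(round(head * fs))
    i1 = data.shape[1] - int(round(tail * fs))
    if i1 - i0 < max(int(fs), 2):
        raise ValueError("recording shorter than the exclusion windows")

    sos = signal.butter(filter_order, band, btype="bandpass", fs=fs,
                        output="sos")
    x = signal.sosfiltfilt(sos, data, axis=-1)[:, i0:i1]
    n = x.shape[1]

    rms_overall = float(np.sqrt(np.mean(x**2)))

    # smoothed instantaneous RMS: Gaussian-FIR filter the mean square
    kernel = gaussian_fir_kernel(fs, bt=smoother_bt, span=smoother_span)
    power = np.mean(x**2, axis=0)
    if len(kernel) >= n:  # very short segments: fall back to the global mean
        trace = np.full(n, np.sqrt(power.mean()))
    else:
        trace = np.sqrt(np.convolve(power, kernel, mode="same"))
    times = head + np.arange(n) / fs

    flat = x.ravel()
    span_uv = 4.0 * rms_overall if rms_overall > 0 else 1.0
    edges = np.linspace(-span_uv, span_uv, hist_bins + 1)
    counts, _ = np.histogram(np.clip(flat, edges[0], edges[-1]), bins=edges)

    spec = np.fft.rfft(x, axis=-1)
    amp = np.abs(spec) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:
        amp[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    return NoiseReport(
        band=band, fs=fs, rms_overall=rms_overall,
        rms_trace=(times, trace),
        histogram=(edges, counts),
        amplitude_spectrum=(freqs, amp.mean(axis=0)),
        excluded_seconds=(head, tail),
        n_samples_analyzed=int(flat.size),
        label=label,
    )


def compare_profiles(reports: list[NoiseReport]) -> pd.DataFrame:
    """Rank reports by overall RMS, ascending (quietest system first).

    The sort is stable: equal-RMS reports keep their input order.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    df = pd.DataFrame(
        {
            "label": [r.label or f"report{i}" for i, r in enumerate(reports)],
            "rms_uV": [r.rms_overall for r in reports],
            "band_low_hz": [r.band[0] for r in reports],
            "band_high_hz": [r.band[1] for r in reports],
        }
    )
    return df.sort_values("rms_uV", kind="stable").reset_index(drop=True)


def plot_noise_report(report: NoiseReport, path=None):
    """Three-panel figure: smoothed RMS trace, histogram, amplitude spectrum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    t, trace = report.rms_trace
    axes[0].plot(t, trace, color="goldenrod")
    axes[0].set(xlabel="time (s)", ylabel="RMS (μV)", title="smoothed RMS")
    edges, counts = report.histogram
    centers = (edges[:-1] + edges[1:]) / 2
    axes[1].bar(centers, counts, width=np.diff(edges), color="steelblue")
    axes[1].set(xlabel="amplitude (μV)", ylabel="count", title="histogram")
    f, a = report.amplitude_spectrum
    axes[2].plot(f, a)
    axes[2].set(xlim=(0, report.band[1] * 1.5), xlabel="frequency (Hz)",
                ylabel="amplitude (μV)", title="amplitude spectrum")
    fig.suptitle(report.label or "")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
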