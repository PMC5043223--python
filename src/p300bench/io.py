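"""On-disk interchange: TSV signal files with JSON sidecars, YAML configs.

A recording is stored as a tabular signal file (time column plus one μV
column per channel) together with a JSON event sidecar holding the sampling
rate, flash events, and target cells.  EDF recordings can be *read* through
:mod:`mne` when it is installed; the package itself writes the tabular pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import FeatureMatrix
from .speller_pipeline import SessionReport, SimulatorConfig
from .synthetic_eeg import (
    ERPTemplate,
    FlashEvent,
    FlashSchedule,
    RawRecording,
    get_profile,
)

__all__ = [
    "write_recording",
    "read_recording",
    "read_recording_edf",
    "write_features",
    "write_session_report",
    "session_report_markdown",
    "load_simulator_config",
]


def write_recording(rec: RawRecording, signal_path: str | Path,
                    sidecar_path: str | Path) -> None:
    """Write a recording as signal TSV + JSON event sidecar."""
    signal_path, sidecar_path = Path(signal_path), Path(sidecar_path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(rec.channel_names, rec.data):
        df[name] = row
    df.to_csv(signal_path, sep="\t", index=False, float_format="%.6f")

    sidecar: dict = {"fs": rec.fs, "channel_names": list(rec.channel_names)}
    if rec.schedule is not None:
        s = rec.schedule
        sidecar["schedule"] = {
            "matrix_rows": s.matrix_rows,
            "matrix_cols": s.matrix_cols,
            "soa": s.soa,
            "flash_duration": s.flash_duration,
            "targets": (None if s.targets is None
                        else [list(t) for t in s.targets]),
            "events": [[e.onset, e.kind, e.index, e.sequence, e.item]
                       for e in s.events],
        }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))


def read_recording(signal_path: str | Path,
                   sidecar_path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    df = pd.read_csv(signal_path, sep="\t")
    meta = json.loads(Path(sidecar_path).read_text())
    names = tuple(meta["channel_names"])
    data = df[list(names)].to_numpy().T
    schedule = None
    if "schedule" in meta:
        s = meta["schedule"]
        events = [FlashEvent(o, k, int(i), int(q), int(m))
                  for o, k, i, q, m in s["events"]]
        targets = (None if s["targets"] is None
                   else [tuple(t) for t in s["targets"]])
        schedule = FlashSchedule(s["matrix_rows"], s["matrix_cols"], events,
                                 s["soa"], s["flash_duration"], targets)
    return RawRecording(data, meta["fs"], channel_names=names,
                        schedule=schedule)


def read_recording_edf(path: str | Path) -> RawRecording:
    """Read the signal part of an EDF file (requires :mod:`mne`).

    EDF annotations are not mapped onto a flash schedule; attach one from a
    JSON sidecar if flash events are needed.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; the package works in μV
    return RawRecording(data, float(raw.info["sfreq"]),
                        channel_names=tuple(raw.ch_names))


def write_features(fm: FeatureMatrix, tsv_path: str | Path,
                   sidecar_path: str | Path) -> None:
    """Write a feature matrix as columnar TSV + JSON feature-map sidecar."""
    cols = {f"f{i}": fm.X[:, i] for i in range(fm.X.shape[1])}
    df = pd.DataFrame(cols)
    df.insert(0, "label", fm.y.astype(int))
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    Path(sidecar_path).write_text(json.dumps(
        {"feature_map": [list(m) for m in fm.feature_map]}, indent=1))


def _report_dict(report: SessionReport) -> dict:
    return {
        "profile": report.profile_name,
        "calibration": {
            "failed": report.calibration.failed,
            "n_sequences": report.calibration.n_sequences,
            "curve_percent":
                report.calibration.curve.accuracy_by_nseq.tolist(),
        },
        "tasks": [
            {
                "task": t.task,
                "outcome": t.outcome,
                "n_selections": t.n_selections,
                "n_correct": t.n_correct,
                "records": [
                    {"target": list(r.target), "selected": list(r.selected),
                     "n_sequences": r.n_sequences}
                    for r in t.records
                ],
            }
            for t in report.tasks
        ],
        "total_selections": report.total_selections,
        "total_correct": report.total_correct,
    }


def write_session_report(report: SessionReport, json_path: str | Path,
                         md_path: str | Path | None = None) -> None:
    """Write a session report as JSON (machine) and optional Markdown."""
    Path(json_path).write_text(json.dumps(_report_dict(report), indent=1))
    if md_path is not None:
        Path(md_path).write_text(session_report_markdown(report))


def session_report_markdown(report: SessionReport) -> str:
    lines = [f"# Session report — {report.profile_name}", ""]
    cal = report.calibration
    if cal.failed:
        lines += ["Calibration **failed** (cross-validated accuracy never "
                  "reached 100 % and stayed at or below 75 %); no tasks run."]
        return "\n".join(lines) + "\n"
    lines += [f"Calibration: {cal.n_sequences} flashing sequences chosen.",
              "", "| task | outcome | correct / selections |",
              "|------|---------|----------------------|"]
    for t in report.tasks:
        lines.append(f"| {t.task} | {t.outcome} | "
                     f"{t.n_correct} / {t.n_selections} |")
    lines += ["", f"Total: {report.total_correct} correct of "
                  f"{report.total_selections} selections."]
    return "\n".join(lines) + "\n"


def load_simulator_config(path: str | Path) -> tuple[SimulatorConfig, dict]:
    """Load a YAML simulation config.

    Recognized keys: ``profile`` (name), ``erp`` (mapping with
    ``peak_amplitude`` and optionally ``peak_latency``, ``width``,
    ``channel_weights``), ``lapse_rate``, ``noise_scale``, ``soa``,
    ``flash_duration``, ``seed``, ``words``, ``matrix``.  Returns the
    :class:`SimulatorConfig` plus a dict of the remaining entries
    (seed, words, …) for the caller.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    profile = get_profile(doc.pop("profile", "hydrogel"))
    erp_doc = doc.pop("erp", {}) or {}
    erp = ERPTemplate(
        peak_amplitude=float(erp_doc.get("peak_amplitude", 5.0)),
        peak_latency=float(erp_doc.get("peak_latency", 0.35)),
        width=float(erp_doc.get("width", 0.06)),
        channel_weights=erp_doc.get("channel_weights",
                                    ERPTemplate(1.0).channel_weights),
    )
    kwargs = {}
    for key in ("lapse_rate", "noise_scale", "soa", "flash_duration"):
        if key in doc:
            kwargs[key] = doc.pop(key)
    return SimulatorConfig(profile, erp, **kwargs), doc
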