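"""Matrix-speller decision logic, calibration, and session simulation.

This module turns per-flash classifier scores into character selections and
implements the adaptive calibration used before on-line spelling: the
training letters are classified with a leave-one-letter-out cross-validation
(LOLO-CV), producing an accuracy-versus-sequence-count curve, and the number
of flashing sequences for the on-line run is chosen from that curve — the
first sequence count reaching 100 % accuracy plus two, clamped into [8, 15];
if 100 % is never reached but the best accuracy exceeds 75 %, 15 sequences
are used; otherwise the calibration fails and must be repeated.

It also simulates a complete evaluation session: classifier training on the
word "BRAIN" (15 sequences per letter), then four tasks — two copy-spelling
tasks of two five-letter words each, a media-player menu task (6×3 matrix,
10 selections optimal, abort at 15) and a web-browser menu task (6×7 matrix,
10 selections optimal, abort at 18).  Wrong menu selections are recovered by
one corrective selection each, so a session spans 40–53 selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from . import swlda as _swlda
from .preprocessing import (
    FeatureMatrix,
    apply_filter,
    build_features,
    extract_epochs,
    online_filter_for,
)
from .synthetic_eeg import (
    ERPTemplate,
    FlashEvent,
    SystemProfile,
    make_flash_schedule,
    synthesize_session,
)

__all__ = [
    "SPELLER_CHARACTERS",
    "char_to_cell",
    "SimulatorConfig",
    "CalibrationCurve",
    "CalibrationResult",
    "TaskSpec",
    "SelectionRecord",
    "SessionResult",
    "SessionReport",
    "DEFAULT_TASKS",
    "aggregate_and_select",
    "build_training_features",
    "lolo_cv",
    "choose_n_sequences",
    "simulate_selection",
    "run_copy_spelling",
    "run_menu_task",
    "run_session",
]

#: Row-major character layout of the 6×6 spelling matrix.
SPELLER_CHARACTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def char_to_cell(ch: str, rows: int = 6, cols: int = 6) -> tuple[int, int]:
    """Map a character to its (row, col) cell in the spelling matrix."""
    idx = SPELLER_CHARACTERS.index(ch.upper())
    if idx >= rows * cols:
        raise ValueError(f"character {ch!r} outside the {rows}×{cols} matrix")
    return divmod(idx, cols)


@dataclass
class SimulatorConfig:
    """Everything needed to render and decode one selection.

    ``erp`` describes the simulated user's P300; ``noise_scale`` overrides
    the profile's scalp noise multiplier (use 0 for noise-free runs).
    """

    profile: SystemProfile
    erp: ERPTemplate
    nontarget_erp: ERPTemplate | None = None
    lapse_rate: float = 0.0
    soa: float = 0.25
    flash_duration: float = 0.0625
    window: tuple[float, float] = (0.0, 0.8)
    decimation_hz: float = 20.0
    noise_scale: float | None = None
    lead_in: float = 2.0


@dataclass
class CalibrationCurve:
    """LOLO-CV accuracy (percent) indexed by sequence count 1..N."""

    accuracy_by_nseq: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracy_by_nseq, dtype=float)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("curve must be a non-empty 1-D array")
        if np.any(a < 0) or np.any(a > 100):
            raise ValueError("accuracies must lie in [0, 100]")
        self.accuracy_by_nseq = a

    def __len__(self) -> int:
        return len(self.accuracy_by_nseq)


@dataclass
class CalibrationResult:
    """Chosen on-line sequence count, or a calibration failure."""

    curve: CalibrationCurve
    n_sequences: int | None

    @property
    def failed(self) -> bool:
        return self.n_sequences is None


@dataclass(frozen=True)
class TaskSpec:
    """One session task: copy-spelling or an abstractly simulated menu."""

    name: str
    matrix: tuple[int, int]
    optimal_selections: int
    abort_limit: int
    kind: Literal["copy-spell", "menu"]
    words: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.optimal_selections > self.abort_limit:
            raise ValueError("optimal_selections must not exceed abort_limit")
        if self.kind == "copy-spell" and not self.words:
            raise ValueError("copy-spell tasks need words")


#: The four session tasks: two copy-spelling blocks of two five-letter words,
#: a media-player menu (6×3), and a web-browser menu (6×7).
DEFAULT_TASKS: tuple[TaskSpec, ...] = (
    TaskSpec("Sp1", (6, 6), 10, 10, "copy-spell", ("SONNE", "BLUME")),
    TaskSpec("MmP", (6, 3), 10, 15, "menu"),
    TaskSpec("WeB", (6, 7), 10, 18, "menu"),
    TaskSpec("Sp2", (6, 6), 10, 10, "copy-spell", ("TRAUM", "KRAFT")),
)


class SelectionRecord(NamedTuple):
    target: tuple[int, int]
    selected: tuple[int, int]
    n_sequences: int


@dataclass
class SessionResult:
    """Per-selection log of one task."""

    task: str
    records: list[SelectionRecord]
    outcome: Literal["completed", "aborted"]

    @property
    def n_selections(self) -> int:
        return len(self.records)

    @property
    def n_correct(self) -> int:
        return sum(r.target == r.selected for r in self.records)


@dataclass
class SessionReport:
    """Full outcome of one simulated session (training + four tasks)."""

    profile_name: str
    calibration: CalibrationResult
    model: "_swlda.SWLDAModel | None"
    tasks: list[SessionResult] = field(default_factory=list)

    @property
    def total_selections(self) -> int:
        return sum(t.n_selections for t in self.tasks)

    @property
    def total_correct(self) -> int:
        return sum(t.n_correct for t in self.tasks)


# ---------------------------------------------------------------------------
# score aggregation


def aggregate_and_select(
    scores: np.ndarray,
    flash_meta: Sequence[FlashEvent],
    n_sequences: int,
    rows: int | None = None,
    cols: int | None = None,
) -> tuple[int, int]:
    """Sum flash scores per row/column index and pick the argmax cell.

    Only flashes from the first ``n_sequences`` sequences contribute.  Ties
    are broken toward the lowest index, which makes the read-out
    deterministic.  Raises ``ValueError`` when fewer complete sequences are
    available than requested.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(flash_meta):
        raise ValueError("scores and flash_meta lengths differ")
    avail = max((m.sequence for m in flash_meta), default=-1) + 1
    if n_sequences < 1 or n_sequences > avail:
        raise ValueError(
            f"requested {n_sequences} sequences but only {avail} available"
        )
    if rows is None:
        rows = max(m.index for m in flash_meta if m.kind == "row") + 1
    if cols is None:
        cols = max(m.index for m in flash_meta if m.kind == "col") + 1
    row_scores = np.zeros(rows)
    col_scores = np.zeros(cols)
    for s, m in zip(scores, flash_meta):
        if m.sequence >= n_sequences:
            continue
        if m.kind == "row":
            row_scores[m.index] += s
        else:
            col_scores[m.index] += s
    return int(np.argmax(row_scores)), int(np.argmax(col_scores))


# ---------------------------------------------------------------------------
# calibration


def build_training_features(
    cfg: SimulatorConfig,
    word: str = "BRAIN",
    n_sequences: int = 15,
    seed: int | np.random.SeedSequence | None = None,
    rows: int = 6,
    cols: int = 6,
) -> tuple[FeatureMatrix, list[tuple[int, int]]]:
    """Render the training word and return its feature matrix and targets."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    sched_ss, synth_ss = ss.spawn(2)
    targets = [char_to_cell(ch, rows, cols) for ch in word]
    sched = make_flash_schedule(rows, cols, n_sequences, soa=cfg.soa,
                                flash_duration=cfg.flash_duration,
                                seed=sched_ss, targets=targets,
                                lead_in=cfg.lead_in)
    rec = synthesize_session(cfg.profile, sched, cfg.erp, cfg.nontarget_erp,
                             cfg.lapse_rate, seed=synth_ss,
                             noise_scale=cfg.noise_scale)
    filtered = apply_filter(rec, online_filter_for(cfg.profile))
    epochs = extract_epochs(filtered, cfg.window)
    return build_features(epochs, cfg.decimation_hz), targets


def lolo_cv(
    features: FeatureMatrix,
    targets: Sequence[tuple[int, int]],
    rows: int = 6,
    cols: int = 6,
    swlda_params: dict | None = None,
) -> CalibrationCurve:
    """Leave-one-letter-out cross-validated accuracy per sequence count.

    For each held-out letter an SWLDA model is fitted on the remaining
    letters' epochs and the held-out letter is classified at every sequence
    count 1..N; the curve entry at n is the percentage of letters selected
    correctly using the first n sequences.
    """
    params = swlda_params or {}
    items = np.array([m.item for m in features.flash_meta])
    letters = np.unique(items)
    if len(letters) < 2:
        raise ValueError("LOLO-CV needs at least two training letters")
    n_seq = max(m.sequence for m in features.flash_meta) + 1

    correct = np.zeros(n_seq, dtype=int)
    for held in letters:
        train = items != held
        model = _swlda.fit_swlda(features.X[train], features.y[train],
                                 **params)
        test_idx = np.flatnonzero(~train)
        test_scores = _swlda.score(model, features.X[test_idx])
        test_meta = [features.flash_meta[i] for i in test_idx]
        for n in range(1, n_seq + 1):
            sel = aggregate_and_select(test_scores, test_meta, n, rows, cols)
            if sel == tuple(targets[held]):
                correct[n - 1] += 1
    return CalibrationCurve(100.0 * correct / len(letters))


def choose_n_sequences(
    curve: CalibrationCurve | Sequence[float],
    bounds: tuple[int, int] = (8, 15),
    fallback_threshold: float = 75.0,
) -> CalibrationResult:
    """Apply the adaptive sequence-count rule to a calibration curve.

    The first sequence count at which the curve reaches 100 % plus two,
    clamped into ``bounds``; if 100 % is never reached but the curve's
    maximum exceeds ``fallback_threshold`` percent, the upper bound is used;
    otherwise the calibration fails (``n_sequences`` is None — failure is a
    value, not an exception).
    """
    if not isinstance(curve, CalibrationCurve):
        curve = CalibrationCurve(np.asarray(curve, dtype=float))
    acc = curve.accuracy_by_nseq
    lo, hi = bounds
    perfect = np.flatnonzero(acc >= 100.0 - 1e-9)
    if perfect.size:
        m = int(perfect[0]) + 1  # 1-based sequence count
        return CalibrationResult(curve, int(np.clip(m + 2, lo, hi)))
    if acc.max() > fallback_threshold:
        return CalibrationResult(curve, hi)
    return CalibrationResult(curve, None)


# ---------------------------------------------------------------------------
# on-line simulation


def simulate_selection(
    target: tuple[int, int],
    model: "_swlda.SWLDAModel",
    n_sequences: int,
    cfg: SimulatorConfig,
    seed: int | np.random.SeedSequence | None = None,
    rows: int = 6,
    cols: int = 6,
) -> tuple[int, int]:
    """Render one selection's flashes and decode the chosen cell."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    sched_ss, synth_ss = ss.spawn(2)
    sched = make_flash_schedule(rows, cols, n_sequences, soa=cfg.soa,
                                flash_duration=cfg.flash_duration,
                                seed=sched_ss, targets=[target],
                                lead_in=cfg.lead_in)
    rec = synthesize_session(cfg.profile, sched, cfg.erp, cfg.nontarget_erp,
                             cfg.lapse_rate, seed=synth_ss,
                             noise_scale=cfg.noise_scale)
    filtered = apply_filter(rec, online_filter_for(cfg.profile))
    epochs = extract_epochs(filtered, cfg.window)
    fm = build_features(epochs, cfg.decimation_hz)
    scores = _swlda.score(model, fm.X)
    return aggregate_and_select(scores, fm.flash_meta, n_sequences, rows,
                                cols)


def run_copy_spelling(
    words: Sequence[str],
    model: "_swlda.SWLDAModel",
    n_sequences: int,
    cfg: SimulatorConfig,
    seed: int | np.random.SeedSequence | None = None,
    task_name: str = "copy-spell",
    rows: int = 6,
    cols: int = 6,
) -> SessionResult:
    """Copy-spell the given words letter by letter, without correction."""
    if model is None:
        raise ValueError("copy spelling requires a calibrated model")
    if not words:
        raise ValueError("no words to spell")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    letters = [ch for w in words for ch in w]
    records = []
    for ch, child in zip(letters, ss.spawn(len(letters))):
        target = char_to_cell(ch, rows, cols)
        selected = simulate_selection(target, model, n_sequences, cfg,
                                      seed=child, rows=rows, cols=cols)
        records.append(SelectionRecord(target, selected, n_sequences))
    return SessionResult(task_name, records, "completed")


def run_menu_task(
    spec: TaskSpec,
    model: "_swlda.SWLDAModel",
    n_sequences: int,
    cfg: SimulatorConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> SessionResult:
    """Simulate a menu-navigation task with investigator-guided correction.

    Each wrong selection costs one extra required correct selection (the
    simulated investigator points back to the right menu item) before task
    progress can resume; the task completes when ``optimal_selections``
    progress steps are made and aborts when ``abort_limit`` selections are
    spent.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rows, cols = spec.matrix
    rng_ss, *sel_ss = ss.spawn(spec.abort_limit + 1)
    rng = np.random.default_rng(rng_ss)
    records = []
    progress = 0
    pending_corrections = 0
    while progress < spec.optimal_selections and len(records) < spec.abort_limit:
        target = (int(rng.integers(rows)), int(rng.integers(cols)))
        selected = simulate_selection(target, model, n_sequences, cfg,
                                      seed=sel_ss[len(records)], rows=rows,
                                      cols=cols)
        records.append(SelectionRecord(target, selected, n_sequences))
        if selected == target:
            if pending_corrections:
                pending_corrections -= 1
            else:
                progress += 1
        else:
            pending_corrections += 1
    outcome = "completed" if progress >= spec.optimal_selections else "aborted"
    return SessionResult(spec.name, records, outcome)


def run_session(
    cfg: SimulatorConfig,
    tasks: Sequence[TaskSpec] = DEFAULT_TASKS,
    swlda_params: dict | None = None,
    seed: int | np.random.SeedSequence | None = None,
    training_word: str = "BRAIN",
    n_training_sequences: int = 15,
) -> SessionReport:
    """Simulate a full session: training, calibration, then the four tasks.

    Training uses the 6×6 matrix and 15 sequences per letter (each target
    letter highlighted 30 times).  On calibration failure the session halts
    with a failure report and no tasks are run — mirroring a protocol in
    which calibration must be repeated.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    train_ss, *task_ss = ss.spawn(len(tasks) + 1)

    features, targets = build_training_features(
        cfg, word=training_word, n_sequences=n_training_sequences,
        seed=train_ss)
    curve = lolo_cv(features, targets, swlda_params=swlda_params)
    calibration = choose_n_sequences(curve)
    if calibration.failed:
        return SessionReport(cfg.profile.name, calibration, model=None)

    model = _swlda.fit_swlda(features.X, features.y, **(swlda_params or {}))
    report = SessionReport(cfg.profile.name, calibration, model)
    n_seq = calibration.n_sequences
    for spec, child in zip(tasks, task_ss):
        if spec.kind == "copy-spell":
            result = run_copy_spelling(spec.words, model, n_seq, cfg,
                                       seed=child, task_name=spec.name,
                                       rows=spec.matrix[0],
                                       cols=spec.matrix[1])
        else:
            result = run_menu_task(spec, model, n_seq, cfg, seed=child)
        report.tasks.append(result)
    return report
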