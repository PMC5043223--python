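import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from p300bench.synthetic_eeg import (
    BUILTIN_PROFILES,
    CHANNEL_NAMES,
    ERPTemplate,
    SystemProfile,
    _band_rms,
    generate_background_noise,
    get_profile,
    make_flash_schedule,
    synthesize_session,
)


def highlight_counts(schedule):
    """How often each matrix cell was highlighted (row or column flash)."""
    counts = np.zeros((schedule.matrix_rows, schedule.matrix_cols), dtype=int)
    for ev in schedule.events:
        if ev.kind == "row":
            counts[ev.index, :] += 1
        else:
            counts[:, ev.index] += 1
    return counts


class TestFlashSchedule:
    @pytest.mark.parametrize(
        "rows,cols,n_seq,n_events,per_cell",
        [
            (6, 6, 15, 180, 30),  # training design: each letter lit 30 times
            (6, 6, 1, 12, 2),
            (6, 3, 2, 18, 4),
        ],
    )
    def test_event_and_highlight_counts(self, rows, cols, n_seq, n_events,
                                        per_cell):
        sched = make_flash_schedule(rows, cols, n_seq, seed=0)
        assert len(sched.events) == n_events
        assert np.all(highlight_counts(sched) == per_cell)

    def test_single_sequence_covers_each_row_and_column_once(self):
        sched = make_flash_schedule(6, 6, 1, seed=3)
        rows = sorted(e.index for e in sched.events if e.kind == "row")
        cols = sorted(e.index for e in sched.events if e.kind == "col")
        assert rows == list(range(6)) and cols == list(range(6))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rows=st.integers(1, 8), cols=st.integers(1, 8),
           n_seq=st.integers(1, 6), seed=st.integers(0, 1000))
    def test_schedule_invariants(self, rows, cols, n_seq, seed):
        sched = make_flash_schedule(rows, cols, n_seq, seed=seed)
        assert len(sched.events) == n_seq * (rows + cols)
        assert np.all(highlight_counts(sched) == 2 * n_seq)
        onsets = [e.onset for e in sched.events]
        assert np.all(np.diff(onsets) > 0)
        # within each sequence every row and column index occurs exactly once
        for s in range(n_seq):
            seq = [e for e in sched.events if e.sequence == s]
            assert sorted(e.index for e in seq if e.kind == "row") == list(
                range(rows))
            assert sorted(e.index for e in seq if e.kind == "col") == list(
                range(cols))
        # no identical flash twice in a row, across sequence boundaries too
        if rows + cols > 1:
            pairs = [(e.kind, e.index) for e in sched.events]
            assert all(a != b for a, b in zip(pairs, pairs[1:]))

    def test_seed_determinism(self):
        a = make_flash_schedule(6, 6, 4, seed=42)
        b = make_flash_schedule(6, 6, 4, seed=42)
        assert a.events == b.events

    def test_invalid_geometry_and_timing(self):
        with pytest.raises(ValueError):
            make_flash_schedule(0, 6, 1)
        with pytest.raises(ValueError):
            make_flash_schedule(6, 6, 0)
        with pytest.raises(ValueError):
            make_flash_schedule(6, 6, 1, soa=0.05, flash_duration=0.0625)

    def test_target_outside_matrix_rejected(self):
        with pytest.raises(ValueError):
            make_flash_schedule(6, 6, 1, targets=[(6, 0)])


class TestBackgroundNoise:
    def test_zero_amplitude_profile_gives_silence(self):
        prof = SystemProfile("null", fs=256.0, online_band=(0.1, 60.0),
                             shortcircuit_rms_target=0.0)
        rec = generate_background_noise(prof, 10.0, seed=0)
        assert np.all(rec.data == 0.0)

    def test_noise_is_seed_deterministic(self):
        prof = get_profile("tap_water")
        a = generate_background_noise(prof, 5.0, seed=9)
        b = generate_background_noise(prof, 5.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_background_noise(get_profile("dry"), 0.0)

    def test_white_noise_band_rms_matches_frequency_domain_oracle(self):
        # Monte-Carlo band-limited RMS of unit white noise vs the closed-form
        # value from the filter's squared magnitude response.
        fs, band, order = 512.0, (0.1, 40.0), 8
        rng = np.random.default_rng(2024)
        n = int(120 * fs)
        mc = np.mean([
            _band_rms(rng.standard_normal(n), fs, band, order, guard_s=10.0)
            for _ in range(10)
        ])
        freqs = np.linspace(0, fs / 2, 20001)
        sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
        # zero-phase application squares the magnitude response
        expected = np.sqrt(np.trapezoid(np.abs(h) ** 4, freqs) / (fs / 2))
        assert mc == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("name", sorted(BUILTIN_PROFILES))
    def test_calibrated_rms_close_to_profile_target(self, name):
        prof = get_profile(name)
        rec = generate_background_noise(prof, 60.0, seed=1)
        rms = _band_rms(rec.data, prof.fs, (0.1, 40.0), 8, guard_s=10.0)
        assert rms == pytest.approx(prof.shortcircuit_rms_target, rel=0.02)


class TestSynthesizeSession:
    def test_clean_recording_contains_exact_template_at_target_flash(self):
        from p300bench.synthetic_eeg import FlashEvent, FlashSchedule

        prof = get_profile("hydrogel")
        sched = FlashSchedule(6, 6, [FlashEvent(2.0, "row", 1, 0, 0)],
                              soa=0.25, flash_duration=0.0625,
                              targets=[(1, 2)])
        erp = ERPTemplate(peak_amplitude=5.0)
        rec = synthesize_session(prof, sched, erp, seed=0, noise_scale=0.0)
        i0 = int(np.floor(2.0 * rec.fs))
        t = np.arange(i0, i0 + int(0.8 * rec.fs)) / rec.fs - 2.0
        pz = list(CHANNEL_NAMES).index("Pz")
        expected = erp.channel_weights[pz] * erp.waveform(t)
        np.testing.assert_allclose(rec.data[pz, i0:i0 + len(t)], expected,
                                   atol=1e-12)

    def test_erp_addition_is_linear_in_noise(self):
        prof = get_profile("hydrogel")
        sched = make_flash_schedule(6, 6, 2, seed=5, targets=[(0, 0)])
        erp = ERPTemplate(peak_amplitude=5.0)
        full = synthesize_session(prof, sched, erp, seed=7)
        clean = synthesize_session(prof, sched, erp, seed=7, noise_scale=0.0)
        noise_only = synthesize_session(
            prof, sched, ERPTemplate(peak_amplitude=0.0), seed=7)
        np.testing.assert_array_equal(full.data,
                                      clean.data + noise_only.data)

    def test_full_lapse_equals_pure_noise(self):
        prof = get_profile("hydrogel")
        sched = make_flash_schedule(6, 6, 2, seed=5, targets=[(0, 0)])
        erp = ERPTemplate(peak_amplitude=50.0)
        lapsed = synthesize_session(prof, sched, erp, lapse_rate=1.0, seed=3)
        silent = synthesize_session(
            prof, sched, ERPTemplate(peak_amplitude=0.0), seed=3)
        np.testing.assert_array_equal(lapsed.data, silent.data)

    def test_requires_targets_and_pad(self):
        prof = get_profile("hydrogel")
        sched = make_flash_schedule(6, 6, 1, seed=0)
        with pytest.raises(ValueError):
            synthesize_session(prof, sched, ERPTemplate(5.0), seed=0)
        from p300bench.synthetic_eeg import FlashEvent, FlashSchedule

        one_flash = FlashSchedule(6, 6, [FlashEvent(1.0, "row", 0, 0, 0)],
                                  soa=0.25, flash_duration=0.0625,
                                  targets=[(0, 0)])
        with pytest.raises(ValueError):
            synthesize_session(prof, one_flash, ERPTemplate(5.0), seed=0,
                               pad_after=0.1)
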