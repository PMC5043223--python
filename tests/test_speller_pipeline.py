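import numpy as np
import pytest

from p300bench import speller_pipeline as sp
from p300bench.swlda import fit_swlda
from p300bench.synthetic_eeg import ERPTemplate, FlashEvent, get_profile


def meta_for(rows=6, cols=6, n_seq=1):
    """Deterministic flash metadata: rows then columns, per sequence."""
    events = []
    t = 0.0
    for s in range(n_seq):
        for r in range(rows):
            events.append(FlashEvent(t, "row", r, s, 0))
            t += 0.25
        for c in range(cols):
            events.append(FlashEvent(t, "col", c, s, 0))
            t += 0.25
    return events


def sequence_rule_oracle(curve, lo=8, hi=15, threshold=75.0):
    """Straight prose re-implementation of the sequence-count rule."""
    first_100 = None
    for i, v in enumerate(curve):
        if v == 100.0:
            first_100 = i + 1
            break
    if first_100 is not None:
        return min(max(first_100 + 2, lo), hi)
    if max(curve) > threshold:
        return hi
    return None


class TestAggregateAndSelect:
    def test_indicator_scores_recover_target(self):
        meta = meta_for(n_seq=3)
        target = (4, 2)
        scores = np.array([
            1.0 if (m.kind == "row" and m.index == 4)
            or (m.kind == "col" and m.index == 2) else 0.0
            for m in meta
        ])
        assert sp.aggregate_and_select(scores, meta, 3) == target

    def test_all_equal_scores_tie_break_to_origin(self):
        meta = meta_for(n_seq=2)
        assert sp.aggregate_and_select(np.ones(len(meta)), meta, 2) == (0, 0)

    def test_requesting_more_sequences_than_available_fails(self):
        meta = meta_for(n_seq=2)
        with pytest.raises(ValueError):
            sp.aggregate_and_select(np.ones(len(meta)), meta, 3)

    def test_later_sequences_ignored(self):
        meta = meta_for(n_seq=2)
        scores = np.zeros(len(meta))
        # huge scores only in sequence 2 must not affect a 1-sequence readout
        for i, m in enumerate(meta):
            if m.sequence == 1:
                scores[i] = 100.0
            elif m.kind == "row" and m.index == 3:
                scores[i] = 1.0
            elif m.kind == "col" and m.index == 1:
                scores[i] = 1.0
        assert sp.aggregate_and_select(scores, meta, 1) == (3, 1)

    def test_chance_level_accuracy_with_random_scores(self):
        # independent row/col argmax over 6×6 → P(correct) = 1/36
        rng = np.random.default_rng(123)
        meta = meta_for(n_seq=1)
        hits = 0
        trials = 3000
        for _ in range(trials):
            sel = sp.aggregate_and_select(rng.standard_normal(len(meta)),
                                          meta, 1)
            hits += sel == (2, 3)
        p = hits / trials
        se = np.sqrt((1 / 36) * (35 / 36) / trials)
        assert abs(p - 1 / 36) < 4 * se


class TestChooseNSequences:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([20, 40, 60, 80, 90, 100, 100], 8),    # 6 + 2
            ([20] * 10 + [100, 100, 100, 100, 100], 13),  # 11 + 2
            ([0, 0, 0, 100] + [100] * 11, 8),       # 4 + 2 clamped up to 8
            ([100] * 15, 8),                        # 1 + 2 clamped up to 8
            ([100] * 14 + [80], 8),
            ([20, 40, 60, 80, 80, 80], 15),         # max 80 > 75 → 15
            ([0, 20, 40, 60, 70, 70], None),        # max 70 → failure
            ([76], 15),
            ([75], None),                           # "higher than 75" strict
        ],
    )
    def test_rule_branches(self, curve, expected):
        result = sp.choose_n_sequences(curve)
        assert result.n_sequences == expected
        assert result.failed is (expected is None)

    def test_matches_prose_oracle_on_random_grid_curves(self):
        rng = np.random.default_rng(0)
        grid = np.arange(0.0, 101.0, 20.0)
        for _ in range(10_000):
            curve = rng.choice(grid, size=15)
            assert (sp.choose_n_sequences(curve).n_sequences
                    == sequence_rule_oracle(curve))

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            sp.choose_n_sequences([])


class TestLoloCV:
    def test_curve_shape_and_quantization(self, trained_features):
        features, targets = trained_features
        curve = sp.lolo_cv(features, targets)
        acc = curve.accuracy_by_nseq
        assert len(acc) == 15
        # five training letters → accuracies are multiples of 20 %
        np.testing.assert_allclose(acc % 20.0, 0.0, atol=1e-9)

    def test_high_snr_curve_reaches_ceiling(self, high_snr_cfg):
        features, targets = sp.build_training_features(
            high_snr_cfg, n_sequences=8, seed=np.random.SeedSequence(21))
        curve = sp.lolo_cv(features, targets)
        assert curve.accuracy_by_nseq.max() == 100.0
        assert curve.accuracy_by_nseq[-1] == 100.0

    def test_shuffled_labels_stay_well_below_threshold(self, trained_features):
        features, targets = trained_features
        rng = np.random.default_rng(5)
        shuffled = list(targets)
        # decouple targets from the rendered data: remap every letter's cell
        while any(a == b for a, b in zip(shuffled, targets)):
            rng.shuffle(shuffled)
        curve = sp.lolo_cv(features, shuffled)
        assert curve.accuracy_by_nseq.max() < 75.0

    def test_single_letter_rejected(self, trained_features):
        features, targets = trained_features
        keep = [i for i, m in enumerate(features.flash_meta) if m.item == 0]
        from p300bench.preprocessing import FeatureMatrix

        sub = FeatureMatrix(features.X[keep], features.y[keep],
                            features.feature_map,
                            [features.flash_meta[i] for i in keep])
        with pytest.raises(ValueError):
            sp.lolo_cv(sub, targets[:1])


class TestMenuTask:
    """Progress/correction bookkeeping, with selections stubbed out."""

    spec = sp.TaskSpec("MmP", (6, 3), 10, 15, "menu")

    def run_with(self, monkeypatch, outcomes):
        it = iter(outcomes)

        def fake_selection(target, model, n_sequences, cfg, seed=None,
                           rows=6, cols=6):
            ok = next(it)
            if ok:
                return target
            return (target[0], (target[1] + 1) % cols)

        monkeypatch.setattr(sp, "simulate_selection", fake_selection)
        return sp.run_menu_task(self.spec, model=None, n_sequences=8,
                                cfg=None, seed=0)

    def test_all_correct_completes_at_optimum(self, monkeypatch):
        result = self.run_with(monkeypatch, [True] * 15)
        assert result.outcome == "completed"
        assert result.n_selections == 10
        assert result.n_correct == 10

    def test_alternating_wrong_correct_aborts_at_limit(self, monkeypatch):
        result = self.run_with(monkeypatch, [False, True] * 10)
        assert result.outcome == "aborted"
        assert result.n_selections == 15

    def test_single_mistake_costs_one_extra_selection(self, monkeypatch):
        result = self.run_with(monkeypatch, [False] + [True] * 14)
        assert result.outcome == "completed"
        assert result.n_selections == 12  # 10 + wrong + corrective

    def test_accuracy_derives_exactly_from_records(self, monkeypatch):
        result = self.run_with(monkeypatch, [False, True] * 10)
        from p300bench.evaluation import accuracy

        assert accuracy(result) == pytest.approx(
            100.0 * result.n_correct / result.n_selections)


class TestEndToEnd:
    def test_copy_spelling_high_snr_is_perfect(self, high_snr_cfg):
        features, _ = sp.build_training_features(
            high_snr_cfg, n_sequences=8, seed=np.random.SeedSequence(31))
        model = fit_swlda(features.X, features.y)
        result = sp.run_copy_spelling(["SONNE", "BLUME"], model, 3,
                                      high_snr_cfg,
                                      seed=np.random.SeedSequence(32))
        assert result.n_selections == 10
        assert result.n_correct == 10

    def test_copy_spelling_is_seed_deterministic(self, high_snr_cfg):
        features, _ = sp.build_training_features(
            high_snr_cfg, n_sequences=8, seed=np.random.SeedSequence(31))
        model = fit_swlda(features.X, features.y)
        a = sp.run_copy_spelling(["KRAFT"], model, 2, high_snr_cfg, seed=9)
        b = sp.run_copy_spelling(["KRAFT"], model, 2, high_snr_cfg, seed=9)
        assert a.records == b.records

    def test_uncalibrated_model_rejected(self, high_snr_cfg):
        with pytest.raises(ValueError):
            sp.run_copy_spelling(["SONNE"], None, 8, high_snr_cfg, seed=0)

    def test_full_session_high_snr(self, high_snr_cfg):
        report = sp.run_session(high_snr_cfg, seed=1)
        assert not report.calibration.failed
        assert report.calibration.n_sequences == 8
        assert all(t.outcome == "completed" for t in report.tasks)
        assert report.total_selections == 40
        assert 40 <= report.total_selections <= 53

    def test_zero_snr_session_fails_calibration(self):
        cfg = sp.SimulatorConfig(get_profile("hydrogel"),
                                 ERPTemplate(peak_amplitude=0.0))
        report = sp.run_session(cfg, seed=2)
        assert report.calibration.failed
        assert report.model is None and report.tasks == []
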