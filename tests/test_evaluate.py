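"""Evaluation protocols, confusion bookkeeping, embedding and gait summary."""

import numpy as np
import pandas as pd
import pytest

from crawlemg.classify import ClassifierSpec, train
from crawlemg.evaluate import (analyze_self_selected, confusion, embed_2d,
                               proportions, run_protocol, summarize_gait)
from crawlemg.segment import CycleBoundaries

KNN = ClassifierSpec(kind="knn")


class TestRunProtocol:
    def test_leave_one_out_fold_count(self, mini_dataset):
        r = run_protocol(mini_dataset, "participant_independent", KNN, "fast", 0)
        assert len(r.fold_accuracies) == 3  # one fold per participant
        assert all(f.startswith("heldout-") for f in r.fold_ids)

    def test_three_fold_test_fractions(self, mini_dataset):
        r = run_protocol(mini_dataset, "multi_participant", KNN, "fast", 0)
        n = len(mini_dataset)
        per_fold = r.confusion.sum() / 3
        assert abs(per_fold - n / 3) <= 1
        assert r.confusion.sum() == n

    def test_participant_specific_runs_three_folds_each(self, mini_dataset):
        r = run_protocol(mini_dataset, "participant_specific", KNN, "fast", 0)
        assert len(r.fold_accuracies) == 3 * 3
        assert r.mean_accuracy == pytest.approx(np.mean(r.fold_accuracies))

    def test_mean_accuracy_definition(self, mini_dataset):
        r = run_protocol(mini_dataset, "participant_independent", KNN, "fast", 0)
        assert r.mean_accuracy == pytest.approx(np.mean(r.fold_accuracies))
        assert 0 <= r.mean_accuracy <= 100

    def test_confusion_row_sums_are_class_counts(self, mini_dataset):
        r = run_protocol(mini_dataset, "participant_independent", KNN, "fast", 0)
        counts = {m: sum(1 for s in mini_dataset if s.mode == m) for m in r.labels}
        np.testing.assert_array_equal(r.confusion.sum(axis=1),
                                      [counts[m] for m in r.labels])

    def test_unknown_protocol_rejected(self, mini_dataset):
        with pytest.raises(ValueError):
            run_protocol(mini_dataset, "bootstrap", KNN, "fast", 0)

    def test_single_participant_cannot_run_independent(self, mini_dataset):
        one = [s for s in mini_dataset if s.participant_id == "P1"]
        with pytest.raises(ValueError, match="participants"):
            run_protocol(one, "participant_independent", KNN, "fast", 0)

    def test_noiseless_cohort_is_perfectly_classified(self, noiseless_dataset):
        for kind in ("knn", "svm"):
            spec = ClassifierSpec(kind=kind)
            for protocol in ("participant_specific", "multi_participant",
                             "participant_independent"):
                r = run_protocol(noiseless_dataset, protocol, spec, "fast", 0)
                assert r.mean_accuracy == 100.0, (kind, protocol)

    def test_noiseless_cohort_bilstm_smoke(self, noiseless_dataset):
        spec = ClassifierSpec(kind="bilstm", hidden_units=16, epochs=40,
                              time_steps=50, dense_sizes=(32, 16))
        r = run_protocol(noiseless_dataset, "participant_independent", spec,
                         "fast", 0)
        assert r.mean_accuracy == 100.0

    def test_protocol_ordering_on_default_cohort(self, default_low_cohort_dataset):
        """Leave-one-participant-out is harder than within-participant
        cross-validation on the default cohort (generator-level property)."""
        ri = run_protocol(default_low_cohort_dataset, "participant_independent",
                          KNN, "low", 1)
        rs = run_protocol(default_low_cohort_dataset, "participant_specific",
                          KNN, "low", 1)
        assert ri.mean_accuracy <= rs.mean_accuracy
        assert ri.mean_accuracy > 12.5  # far above 8-class chance

    def test_deterministic_given_seed(self, mini_dataset):
        a = run_protocol(mini_dataset, "multi_participant", KNN, "fast", 7)
        b = run_protocol(mini_dataset, "multi_participant", KNN, "fast", 7)
        assert a.fold_accuracies == b.fold_accuracies
        np.testing.assert_array_equal(a.confusion, b.confusion)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["M1", "M2", "M2", "M3"]
        m = confusion(y, y)
        np.testing.assert_array_equal(m, np.diag([1, 2, 1]))

    def test_single_prediction_column(self):
        m = confusion(["M1", "M2", "M3"], ["M2", "M2", "M2"])
        assert m.sum(axis=0).tolist() == [0, 3, 0]

    def test_count_conservation(self, rng):
        labels = [f"M{i}" for i in range(1, 9)]
        y = rng.choice(labels, 200)
        p = rng.choice(labels, 200)
        assert confusion(y, p, labels).sum() == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["M1"], ["M1", "M2"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion(["M1"], ["M9"], labels=["M1", "M2"])


class TestEmbed2D:
    def test_shape_and_determinism(self, mini_dataset):
        sub = mini_dataset[:60]
        a = embed_2d(sub, seed=4)
        b = embed_2d(sub, seed=4)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_modes_form_separated_clusters(self, mini_dataset):
        from sklearn.metrics import silhouette_score
        emb = embed_2d(mini_dataset, seed=0)
        labels = [s.mode for s in mini_dataset]
        assert silhouette_score(emb, labels) > 0

    def test_too_few_samples_rejected(self, mini_dataset):
        with pytest.raises(ValueError):
            embed_2d(mini_dataset[:5], seed=0)


class TestProportionsAndSelfSelected:
    def test_printed_count_arithmetic(self):
        # medium speed: 92 of 99 self-selected cycles classified as trot
        medium = proportions({"M2": 92, "M1": 5, "M5": 2})
        assert medium["M2"] == pytest.approx(92.9, abs=0.05)
        # fast speed: 23 of 95 classified as the diagonal-sequence mode
        fast = proportions({"M2": 68, "M3": 23, "M1": 4})
        assert fast["M3"] == pytest.approx(24.2, abs=0.05)

    def test_proportions_sum_to_100(self, rng):
        counts = {f"M{i}": int(c) for i, c in enumerate(rng.integers(1, 50, 8), 1)}
        assert sum(proportions(counts).values()) == pytest.approx(100.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            proportions({})

    def test_self_selected_analysis(self, mini_dataset, mini_cohort):
        model = train(KNN, mini_dataset, seed=0)
        # relabel a copy of the dataset as self-selected probe cycles
        from crawlemg.features import EnvelopeCycle
        probes = [EnvelopeCycle(s.values, "self", s.participant_id, s.speed)
                  for s in mini_dataset[:40]]
        frame = analyze_self_selected(model, probes)
        for speed, grp in frame.groupby(level="speed"):
            assert grp["percent"].sum() == pytest.approx(100.0)
            assert grp["count"].sum() == sum(1 for s in probes if s.speed == speed)

    def test_empty_input_rejected(self, mini_dataset):
        model = train(KNN, mini_dataset, seed=0)
        with pytest.raises(ValueError):
            analyze_self_selected(model, [])


class TestSummarizeGait:
    def test_constructed_duty_factor(self):
        from crawlemg.synth import Trial
        b = CycleBoundaries(np.array([0, 2000, 4000]), np.array([1400, 3400]), 1000.0)
        trial = Trial(np.zeros((30, 4100)), np.zeros(4100), 1000.0, "P1",
                      "low", "M2", "M2", None)
        frame = summarize_gait([trial], [b])
        assert frame.loc["low", "duty_mean_pct"] == pytest.approx(70.0)
        assert frame.loc["low", "duty_sd_pct"] == pytest.approx(0.0)
        assert frame.loc["low", "n_cycles"] == 2

    def test_duty_factor_decreases_with_speed(self):
        from crawlemg.synth import SynthConfig, generate_cohort
        cfg = SynthConfig()
        trials = generate_cohort(cfg, 2, ["M2"], ["low", "medium", "fast"], 10, 3)
        frame = summarize_gait(trials)
        duties = frame.loc[["low", "medium", "fast"], "duty_mean_pct"]
        assert duties.is_monotonic_decreasing

    def test_recovers_configured_stance_fractions(self):
        from crawlemg.synth import SynthConfig, generate_cohort
        cfg = SynthConfig()
        trials = generate_cohort(cfg, 3, ["M4"], ["medium"], 12, 9)
        frame = summarize_gait(trials)
        n = frame.loc["medium", "n_cycles"]
        se = cfg.speeds["medium"].stance_sd * 100 / np.sqrt(n)
        want = cfg.speeds["medium"].stance_mean * 100
        assert abs(frame.loc["medium", "duty_mean_pct"] - want) <= 2 * se + 0.5
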