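"""Evaluation-suite tests: temporal fold construction, subsampling,
confusion counts and metrics (validated against the published benchmark
tables), paired t-tests, modality masking and CV bookkeeping."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meanbci.core import ConfigError, DataError
from meanbci.evaluate import (
    apply_modality_mask,
    block_sizes,
    class_metrics,
    confusion_counts,
    paired_ttest,
    round_half_up,
    run_cv,
    subsample,
    temporal_kfold,
)
from meanbci.model import TrainConfig
from meanbci.models import CnnBaseline, MeanNetwork
from meanbci.reference import (
    CONFUSION_COUNTS,
    INSTANCES_PER_CLASS,
    MODEL_ACCURACY_PCT,
    PRINTED_METRICS,
    TOTAL_INSTANCES,
)




def _counts_from_reference(subject: str):
    """Build a ConfusionCounts equivalent from the published counts."""
    from meanbci.evaluate import ConfusionCounts

    order = ("high", "medium", "low")
    tp, fp, tn, fn = {}, {}, {}, {}
    for state in order:
        tp[state], tn[state], fp[state], fn[state] = CONFUSION_COUNTS[subject][state]
    total = tp[order[0]] + tn[order[0]] + fp[order[0]] + fn[order[0]]
    matrix = np.zeros((3, 3), dtype=int)
    for i, s in enumerate(order):
        matrix[i, i] = tp[s]
    # off-diagonals unknown from the marginals; diagonal + total suffice for
    # accuracy, and per-class metrics only use the four marginal counts
    return ConfusionCounts(order, matrix, tp, fp, tn, fn), total


class TestFolds:
    def test_even_split(self):
        assert block_sizes(10, 5) == [2, 2, 2, 2, 2]

    def test_remainder_rule(self):
        assert block_sizes(11, 5) == [3, 2, 2, 2, 2]

    @given(n=st.integers(5, 50))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, n):
        labels = np.array(
            ["high"] * n + ["medium"] * n + ["low"] * n, dtype=object
        )
        times = np.arange(3 * n, dtype=float)
        plan = temporal_kfold(labels, times, 5)
        all_test = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(all_test) == list(range(3 * n))
        for f in range(5):
            assert not set(plan.test_indices(f)) & set(plan.train_indices(f))

    def test_blocks_are_contiguous_in_time(self):
        labels = np.array(["high"] * 10 + ["low"] * 10 + ["medium"] * 10, dtype=object)
        times = np.arange(30, dtype=float)
        plan = temporal_kfold(labels, times, 5)
        for blocks in plan.class_blocks.values():
            for blk in blocks:
                assert np.all(np.diff(times[blk]) > 0)
                assert np.all(np.diff(blk) == 1)

    def test_small_class_rejected(self):
        labels = np.array(["high"] * 3 + ["medium"] * 9 + ["low"] * 9, dtype=object)
        with pytest.raises(ConfigError, match="high"):
            temporal_kfold(labels, np.arange(21, dtype=float), 5)


class TestSubsample:
    def test_full_proportion_is_identity(self):
        idx = np.arange(17)
        out = subsample(idx, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(out), idx)

    def test_seeded_repeatability(self):
        idx = np.arange(100)
        a = subsample(idx, 0.5, np.random.default_rng(3))
        b = subsample(idx, 0.5, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_ceiling_count(self):
        assert subsample(np.arange(100), 0.8, np.random.default_rng(1)).size == 80

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            subsample(np.arange(10), 0.0, np.random.default_rng(0))


class TestConfusion:
    def test_hand_enumeration(self):
        y = np.array(["high", "high", "medium", "medium", "low"], dtype=object)
        yh = np.array(["high", "medium", "medium", "medium", "low"], dtype=object)
        c = confusion_counts(y, yh)
        assert (c.tp["high"], c.fp["high"], c.fn["high"], c.tn["high"]) == (1, 0, 1, 3)
        for lab in c.class_order:
            assert c.tp[lab] + c.fp[lab] + c.tn[lab] + c.fn[lab] == 5

    def test_perfect_predictions(self):
        y = np.array(["high", "medium", "low"] * 4, dtype=object)
        c = confusion_counts(y, y.copy())
        assert all(c.fp[l] == 0 and c.fn[l] == 0 for l in c.class_order)

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            confusion_counts(
                np.array(["high", "bogus"], dtype=object),
                np.array(["high", "high"], dtype=object),
            )

    def test_row_sums_equal_true_counts(self):
        rng = np.random.default_rng(0)
        labs = np.array(["high", "medium", "low"], dtype=object)
        y = labs[rng.integers(0, 3, 60)]
        yh = labs[rng.integers(0, 3, 60)]
        c = confusion_counts(y, yh)
        for i, lab in enumerate(c.class_order):
            assert c.matrix[i].sum() == np.sum(y == lab) == c.tp[lab] + c.fn[lab]


class TestMetricsAgainstReference:
    @pytest.mark.parametrize("subject", list(CONFUSION_COUNTS))
    def test_printed_metrics_roundtrip(self, subject):
        """class_metrics reproduces every published precision/recall/F1 from
        the published counts to 4 decimals."""
        counts, _ = _counts_from_reference(subject)
        m = class_metrics(counts)
        for state in counts.class_order:
            p, r, f1 = PRINTED_METRICS[subject][state]
            assert round_half_up(m.precision[state], 4) == pytest.approx(p, abs=5e-5)
            assert round_half_up(m.recall[state], 4) == pytest.approx(r, abs=5e-5)
            assert round_half_up(m.f1[state], 4) == pytest.approx(f1, abs=5e-5)

    @pytest.mark.parametrize("subject", list(CONFUSION_COUNTS))
    def test_tp_plus_fn_equals_class_count(self, subject):
        for state, n_true in zip(("high", "medium", "low"), INSTANCES_PER_CLASS[subject]):
            tp, _, _, fn = CONFUSION_COUNTS[subject][state]
            assert tp + fn == n_true

    def test_accuracy_consistency(self):
        """Sum of per-class TP over total instances reproduces the published
        overall accuracies."""
        for subject in ("S1", "S4"):
            tp_sum = sum(CONFUSION_COUNTS[subject][s][0] for s in ("high", "medium", "low"))
            acc = 100.0 * tp_sum / TOTAL_INSTANCES[subject]
            assert round_half_up(acc, 2) == pytest.approx(
                MODEL_ACCURACY_PCT.loc[subject, "MEAN"], abs=5e-3
            )

    def test_zero_denominator_warns_and_zeroes(self):
        y = np.array(["high", "high", "medium", "low"], dtype=object)
        yh = np.array(["medium", "medium", "medium", "low"], dtype=object)
        with pytest.warns(UserWarning):
            m = class_metrics(confusion_counts(y, yh))
        assert m.precision["high"] == 0.0 and m.degenerate


class TestPairedTtest:
    def test_small_consistent_difference_significant(self):
        rng = np.random.default_rng(0)
        b = 0.90 + 0.02 * rng.standard_normal(10)
        a = b + 0.01 + 0.001 * rng.standard_normal(10)
        _, p = paired_ttest(a, b)
        assert p < 0.05

    def test_antisymmetric_lists_give_zero_t(self):
        b = np.array([0.1, 0.2, 0.3, 0.4])
        t, _ = paired_ttest(b[::-1], b)
        assert abs(t) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            paired_ttest([0.1, 0.2], [0.1])

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            paired_ttest([0.5, 0.6], [0.4, 0.5])

    def test_benchmark_models_differ_significantly(self):
        """On the published per-subject accuracies every baseline differs
        from the attention network at p < 0.05."""
        mean_acc = MODEL_ACCURACY_PCT["MEAN"]
        for model in ("CNN", "RNN", "LSTM", "SVM"):
            _, p = paired_ttest(MODEL_ACCURACY_PCT[model], mean_acc)
            assert p < 0.05, model


class TestModalityMask:
    def test_eeg_only_shape(self, small_features):
        masked = apply_modality_mask(small_features, ["eeg"])
        assert masked.freq_maps.shape[1] == 11
        assert masked.scalars.shape[1] == 0
        assert masked.n_features == 11 * 93

    def test_aux_keeps_scalars(self, small_features):
        masked = apply_modality_mask(small_features, ["eeg", "aux"])
        assert masked.scalars.shape[1] == 2

    def test_unknown_group_rejected(self, small_features):
        with pytest.raises(ConfigError):
            apply_modality_mask(small_features, ["nirs"])


class TestRunCv:
    def test_cycle_bookkeeping_svm(self, blob_features):
        report = run_cv(blob_features, "svm", k=5, reps=5, proportion=0.8, seed=0)
        assert report.n_cycles == 25
        # each cycle contributes ceil(p * n_test_fold) aggregated predictions
        n_per_class = 30
        fold_test = 3 * (n_per_class // 5)
        assert set(report.records["n_test"]) == {int(np.ceil(0.8 * fold_test))}
        assert len(report.y_true) == report.records["n_test"].sum()

    def test_deterministic_given_seed(self, blob_features):
        a = run_cv(blob_features, "svm", k=3, reps=2, seed=4)
        b = run_cv(blob_features, "svm", k=3, reps=2, seed=4)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        assert a.records.equals(b.records)

    def test_svm_separates_blobs(self, blob_features):
        report = run_cv(blob_features, "svm", k=5, reps=1, seed=0)
        assert report.metrics().accuracy > 0.9

    def test_mean_model_runs(self, blob_features):
        report = run_cv(
            blob_features, "mean", k=3, reps=1, seed=0,
            train_config=TrainConfig(epochs=4, lr=3e-3),
        )
        assert report.n_cycles == 3
        assert set(report.y_pred) <= {"high", "medium", "low"}

    def test_unknown_model_rejected(self, blob_features):
        with pytest.raises(ConfigError):
            run_cv(blob_features, "transformer")

    def test_cnn_shares_head_architecture(self):
        rng = np.random.default_rng(0)
        assert (
            MeanNetwork(15, 93, 2, rng).head.architecture_hash()
            == CnnBaseline(15, 93, 2, rng).head.architecture_hash()
        )

    def test_summary_renders(self, blob_features):
        report = run_cv(blob_features, "svm", k=3, reps=1, seed=0)
        text = report.summary()
        assert "accuracy" in text and "svm" in text
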