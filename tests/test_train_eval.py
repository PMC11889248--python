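"""Metrics against contingency/pairwise oracles; training loop and
transfer-learning weight-matching contracts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mnvit.model_zoo import PRESETS, build_model
from mnvit.pipeline import split_dataset
from mnvit.tensor import Tensor
from mnvit.train_eval import (TrainConfig, balanced_accuracy, evaluate,
                              f1_scores, load_checkpoint, load_pretrained,
                              report_from_outputs, roc_auc, save_checkpoint,
                              train)


def oracle_metrics(labels, preds):
    """Confusion-table arithmetic, written independently of sklearn."""
    tp = np.sum((labels == 1) & (preds == 1))
    tn = np.sum((labels == 0) & (preds == 0))
    fp = np.sum((labels == 0) & (preds == 1))
    fn = np.sum((labels == 1) & (preds == 0))
    rec1 = tp / (tp + fn) if tp + fn else 0.0
    rec0 = tn / (tn + fp) if tn + fp else 0.0
    prec1 = tp / (tp + fp) if tp + fp else 0.0
    prec0 = tn / (tn + fn) if tn + fn else 0.0
    f1_1 = 2 * prec1 * rec1 / (prec1 + rec1) if prec1 + rec1 else 0.0
    f1_0 = 2 * prec0 * rec0 / (prec0 + rec0) if prec0 + rec0 else 0.0
    return (rec0 + rec1) / 2, (f1_0 + f1_1) / 2


def pairwise_auc(labels, scores):
    """Count wins + half-ties over all (positive, negative) pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBalancedAccuracy:
    def test_constant_predictor_scores_half(self):
        labels = np.array([0, 0, 0, 1, 1])
        assert balanced_accuracy(labels, np.ones(5)) == 0.5
        assert balanced_accuracy(labels, np.zeros(5)) == 0.5

    def test_perfect_predictions(self):
        labels = np.array([0, 1, 0, 1])
        assert balanced_accuracy(labels, labels) == 1.0

    def test_worked_example(self):
        got = balanced_accuracy(np.array([0, 0, 0, 1]), np.array([0, 0, 1, 1]))
        assert abs(got - 5 / 6) < 1e-12

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            balanced_accuracy(np.zeros(4), np.zeros(4))


class TestF1:
    def test_perfect_macro(self):
        macro, per_class = f1_scores(np.array([0, 1, 1]), np.array([0, 1, 1]))
        assert macro == 1.0 and list(per_class) == [1.0, 1.0]

    def test_worked_example(self):
        macro, per_class = f1_scores(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
        np.testing.assert_allclose(per_class, [0.5, 0.5])
        assert macro == 0.5

    def test_degenerate_predictions_warn_and_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            macro, per_class = f1_scores(np.array([0, 1]), np.array([0, 0]))
        assert per_class[1] == 0.0

    def test_thousand_random_draws_match_contingency_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            preds = rng.integers(0, 2, n)
            bal_o, f1_o = oracle_metrics(labels, preds)
            assert abs(balanced_accuracy(labels, preds) - bal_o) < 1e-12
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    macro, _ = f1_scores(labels, preds)
            assert abs(macro - f1_o) < 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc(np.array([0, 1, 0, 1]), np.full(4, 0.3)) == 0.5

    def test_eight_sample_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        scores = np.round(rng.uniform(0, 1, 8), 1)  # coarse grid forces ties
        assert abs(roc_auc(labels, scores) - pairwise_auc(labels, scores)) < 1e-12

    def test_many_seeded_pairwise_oracles(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.uniform(0, 1, n), 1)
            assert abs(roc_auc(labels, scores) - pairwise_auc(labels, scores)) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.uniform(0, 1, 30)
        a = roc_auc(labels, scores)
        assert abs(roc_auc(labels, np.exp(3 * scores) + 5) - a) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(4), np.arange(4.0))


class TestMetricsReport:
    def test_avg_acc_equals_mean_recall_and_counts_conserve(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        preds = rng.integers(0, 2, 40)
        scores = rng.uniform(0, 1, 40)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = report_from_outputs(labels, preds, scores)
        assert abs(rep.avg_acc - np.mean(rep.per_class_recall)) < 1e-12
        assert np.sum(rep.confusion) == rep.n == 40
        # metrics recomputed from the returned confusion table agree
        cm = np.array(rep.confusion)
        recomputed = (cm[0, 0] / cm[0].sum() + cm[1, 1] / cm[1].sum()) / 2
        assert abs(recomputed - rep.avg_acc) < 1e-12


def tiny_cfg(**kw):
    kw.setdefault("num_classes", 2)
    kw.setdefault("input_size", 32)
    return replace(PRESETS["Model_DSC"], **kw)


@pytest.fixture(scope="module")
def tiny_split_manifest(tmp_path_factory):
    from mnvit.synthetic import easy_spec, generate_dataset

    out = tmp_path_factory.mktemp("tinypool")
    _, manifest = generate_dataset(60, 0.5, easy_spec(32), seed=13, out_dir=out)
    return split_dataset(manifest, ratios=(0.6, 0.2, 0.2), seed=13)


class TestTrainLoop:
    def test_loss_decreases_and_history_recorded(self, tiny_split_manifest, tmp_path):
        model = build_model(tiny_cfg(), seed=3)
        cfg = TrainConfig(batch_size=8, epochs=3, input_side=32, seed=3)
        hist = train(model, tiny_split_manifest, cfg, out_dir=tmp_path)
        assert len(hist.epochs) == 3
        assert hist.epochs[-1]["train_loss"] < hist.epochs[0]["train_loss"]
        assert hist.checkpoint_path is not None

    def test_first_epoch_deterministic_for_fixed_seed(self, tiny_split_manifest):
        losses = []
        for _ in range(2):
            model = build_model(tiny_cfg(), seed=3)
            cfg = TrainConfig(batch_size=8, epochs=1, input_side=32, seed=3)
            hist = train(model, tiny_split_manifest, cfg, eval_val=False)
            losses.append(hist.epochs[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_freeze_trunk_keeps_trunk_fixed(self, tiny_split_manifest):
        model = build_model(tiny_cfg(), seed=4)
        before = {n: p.data.copy() for n, p in model.named_parameters()}
        cfg = TrainConfig(batch_size=8, epochs=1, input_side=32, seed=4,
                          freeze_trunk=True)
        train(model, tiny_split_manifest, cfg, eval_val=False)
        for n, p in model.named_parameters():
            if n.startswith("fc."):
                assert not np.array_equal(p.data, before[n])
            else:
                np.testing.assert_array_equal(p.data, before[n])

    def test_single_class_training_rejected(self, tiny_split_manifest):
        man = tiny_split_manifest.copy()
        man = man[(man["split"] != "train") | (man["label"] == 0)]
        model = build_model(tiny_cfg(), seed=5)
        with pytest.raises(ValueError, match="both classes"):
            train(model, man, TrainConfig(batch_size=8, epochs=1, input_side=32))


class TestEvaluate:
    def test_constant_model_scores_half(self, tiny_split_manifest):
        model = build_model(tiny_cfg(), seed=6).eval()
        model.fc.weight.data[...] = 0
        model.fc.bias.data[...] = 0
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = evaluate(model, tiny_split_manifest, "test", input_side=32)
        assert rep.avg_acc == 0.5


class TestCheckpointsAndTransfer:
    def test_round_trip_preserves_logits(self, tmp_path, rng):
        model = build_model(tiny_cfg(), seed=7)
        save_checkpoint(model, tmp_path / "m.npz")
        clone = load_checkpoint(tmp_path / "m.npz")
        x = rng.normal(0, 1, (2, 3, 32, 32)).astype(np.float32)
        model.eval(), clone.eval()
        np.testing.assert_array_equal(model(Tensor(x)).data, clone(Tensor(x)).data)

    def test_identical_preset_matches_everything(self, tmp_path):
        model = build_model(tiny_cfg(), seed=8)
        save_checkpoint(model, tmp_path / "m.npz")
        fresh = build_model(tiny_cfg(), seed=9)
        rep = load_pretrained(fresh, tmp_path / "m.npz")
        assert rep.skipped == [] and rep.reinitialized == []
        assert rep.matched == len(list(fresh.named_parameters())) + \
            len(list(fresh.named_buffers()))

    def test_baseline_into_decomposed_skips_decomposed_convs(self, tmp_path):
        base = build_model(replace(PRESETS["MobileViT"], num_classes=2, input_size=32), seed=1)
        save_checkpoint(base, tmp_path / "base.npz")
        dd = build_model(tiny_cfg(), seed=2)
        before_stem = dd.stem.layers[0].weight.data.copy()
        rep = load_pretrained(dd, tmp_path / "base.npz")
        assert any("local_conv" in n or "fusion" in n for n in rep.skipped)
        assert not np.array_equal(dd.stem.layers[0].weight.data, before_stem)
        assert rep.matched > 0

    def test_head_reinitialized_when_excluded(self, tmp_path):
        src = build_model(replace(PRESETS["Model_DSC"], num_classes=1000, input_size=32), seed=1)
        save_checkpoint(src, tmp_path / "src.npz")
        dst = build_model(tiny_cfg(), seed=2)
        head_before = dst.fc.weight.data.copy()
        rep = load_pretrained(dst, tmp_path / "src.npz", exclude_head=True)
        assert any(n.startswith("fc.") for n in rep.reinitialized)
        np.testing.assert_array_equal(dst.fc.weight.data, head_before)
        # trunk fully matched: nothing skipped outside the head
        assert all(n.startswith("fc.") for n in rep.skipped)

    def test_missing_checkpoint_raises_io_error(self, tmp_path):
        model = build_model(tiny_cfg(), seed=1)
        with pytest.raises(IOError):
            load_pretrained(model, tmp_path / "absent.npz")
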