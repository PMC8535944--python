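"""Fold splitting, backends, confusion-matrix metrics and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartkit.classify import (
    ConfusionMatrix,
    Example,
    TrainConfig,
    aggregate_folds,
    compute_metrics,
    evaluate,
    kfold_split,
    train_backend,
)
from heartkit.errors import LabelError, StratificationError, TrainingError


def items_of(n_per_class, classes=("a", "b", "c"), d=2, seed=0, groups_per_class=None):
    rng = np.random.default_rng(seed)
    items = []
    for ci, cls in enumerate(classes):
        g = groups_per_class or n_per_class
        for i in range(n_per_class):
            items.append(
                Example(
                    x=rng.standard_normal(d) + 10 * ci,
                    label=cls,
                    group=f"{cls}-rec{i % g}",
                    id=f"{cls}-{i}",
                )
            )
    return items


class TestKfold:
    def test_three_by_three(self):
        items = items_of(3)
        splits = kfold_split(items, 3, seed=0)
        for _, val in splits:
            labels = [items[i].label for i in val]
            assert sorted(labels) == ["a", "b", "c"]

    def test_partition_property(self):
        items = items_of(5)
        splits = kfold_split(items, 3, seed=1)
        all_val = [i for _, val in splits for i in val]
        assert sorted(all_val) == list(range(len(items)))
        for train, val in splits:
            assert set(train).isdisjoint(val)
            assert sorted(train + val) == list(range(len(items)))

    def test_groups_never_straddle(self):
        items = items_of(8, groups_per_class=4)
        splits = kfold_split(items, 3, seed=2)
        for train, val in splits:
            tg = {items[i].group for i in train}
            vg = {items[i].group for i in val}
            assert tg.isdisjoint(vg)

    def test_deterministic(self):
        items = items_of(4)
        assert kfold_split(items, 3, seed=9) == kfold_split(items, 3, seed=9)

    def test_small_class_rejected(self):
        items = items_of(2)
        with pytest.raises(StratificationError):
            kfold_split(items, 3, seed=0)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), folds=st.integers(2, 4))
    def test_partition_sweep(self, seed, folds):
        items = items_of(6, groups_per_class=6)
        splits = kfold_split(items, folds, seed)
        all_val = sorted(i for _, val in splits for i in val)
        assert all_val == list(range(len(items)))


class TestBackends:
    def test_logistic_separable_is_perfect(self):
        items = items_of(10, classes=("a", "b"))
        model = train_backend(items, TrainConfig())
        assert model.predict(items) == [it.label for it in items]

    def test_single_class_rejected(self):
        items = items_of(5, classes=("a",))
        with pytest.raises(TrainingError):
            train_backend(items, TrainConfig())

    def test_logistic_deterministic(self):
        items = items_of(6)
        cfg = TrainConfig(seed=3)
        p1 = train_backend(items, cfg).predict(items)
        p2 = train_backend(items, cfg).predict(items)
        assert p1 == p2

    @staticmethod
    def image_items(n_per_class, seed=0):
        # two visually distinct synthetic image classes
        rng = np.random.default_rng(seed)
        items = []
        for ci, cls in enumerate(("dark", "bright")):
            for i in range(n_per_class):
                base = 60 + 130 * ci
                img = np.clip(
                    rng.normal(base, 25, (480, 640, 3)), 0, 255
                ).astype(np.uint8)
                items.append(Example(x=img, label=cls, group=f"{cls}-{i}", id=f"{cls}{i}"))
        return items

    def test_small_cnn_overfits_tiny_set(self):
        items = self.image_items(10)
        cfg = TrainConfig(
            backend="small_cnn", learning_rate=0.05, epochs=200, seed=0, batch_size=5
        )
        model = train_backend(items, cfg)
        assert model.predict(items) == [it.label for it in items]

    def test_small_cnn_deterministic(self):
        items = self.image_items(4)
        cfg = TrainConfig(backend="small_cnn", learning_rate=0.05, epochs=20, seed=1)
        assert train_backend(items, cfg).predict(items) == train_backend(items, cfg).predict(items)

    def test_external_pretrained_unavailable(self):
        with pytest.raises(TrainingError):
            train_backend(items_of(3), TrainConfig(backend="external_pretrained"))


class TestEvaluateAndMetrics:
    def test_perfect_predictor_diagonal(self):
        items = items_of(4, classes=("a", "b"))
        model = train_backend(items, TrainConfig())
        cm = evaluate(model, items)
        assert cm.total == len(items)
        assert np.trace(cm.counts) == len(items)

    def test_unseen_label_rejected(self):
        items = items_of(4, classes=("a", "b"))
        model = train_backend(items, TrainConfig())
        stranger = Example(x=np.zeros(2), label="zz", group="g", id="x")
        with pytest.raises(LabelError):
            evaluate(model, [stranger])

    def test_hand_computed_two_class_matrix(self):
        cm = ConfusionMatrix(counts=np.array([[8, 2], [3, 7]]), class_names=["n", "p"])
        m = compute_metrics(cm)
        assert m["per_class"]["n"]["tpr"] == pytest.approx(0.8)
        assert m["per_class"]["n"]["ppv"] == pytest.approx(8 / 11)
        assert m["per_class"]["p"]["tpr"] == pytest.approx(0.7)
        assert m["multiclass_accuracy"] == pytest.approx(15 / 20)

    def test_diagonal_matrix_all_ones(self):
        cm = ConfusionMatrix(counts=np.diag([5, 3, 2]), class_names=["a", "b", "c"])
        m = compute_metrics(cm)
        for cls in ("a", "b", "c"):
            for metric in ("accuracy", "tpr", "ppv", "tnr"):
                assert m["per_class"][cls][metric] == 1.0

    def test_zero_denominator_reported_absent(self):
        # nothing predicted as class b -> PPV(b) undefined
        cm = ConfusionMatrix(counts=np.array([[5, 0], [3, 0]]), class_names=["a", "b"])
        m = compute_metrics(cm)
        assert m["per_class"]["b"]["ppv"] is None
        assert m["micro"]["ppv"] == pytest.approx(5 / 8)  # mean over defined values

    def test_metrics_bounded(self, rng):
        counts = rng.integers(0, 20, (3, 3))
        counts[0, 0] += 1
        m = compute_metrics(ConfusionMatrix(counts=counts, class_names=["a", "b", "c"]))
        for cls_metrics in m["per_class"].values():
            for v in cls_metrics.values():
                if v is not None:
                    assert 0.0 <= v <= 1.0


class TestAggregate:
    def test_identical_folds_pass_through(self):
        cm = ConfusionMatrix(counts=np.array([[4, 1], [1, 4]]), class_names=["a", "b"])
        rep = aggregate_folds([cm, cm, cm])
        single = compute_metrics(cm)
        for cls in ("a", "b"):
            for metric in ("accuracy", "tpr", "ppv", "tnr"):
                assert rep.folds_avg[cls][metric] == pytest.approx(
                    single["per_class"][cls][metric]
                )

    def test_two_fold_mean(self):
        cm1 = ConfusionMatrix(counts=np.array([[8, 2], [2, 8]]), class_names=["a", "b"])
        cm2 = ConfusionMatrix(counts=np.array([[9, 1], [1, 9]]), class_names=["a", "b"])
        rep = aggregate_folds([cm1, cm2])
        assert rep.folds_avg["a"]["tpr"] == pytest.approx((0.8 + 0.9) / 2)

    def test_double_loop_oracle(self, rng):
        cms = [
            ConfusionMatrix(counts=rng.integers(1, 15, (3, 3)), class_names=["a", "b", "c"])
            for _ in range(3)
        ]
        rep = aggregate_folds(cms)
        fms = [compute_metrics(cm) for cm in cms]
        for metric in ("accuracy", "tpr", "ppv", "tnr"):
            per_class_means = []
            for cls in ("a", "b", "c"):
                vals = [fm["per_class"][cls][metric] for fm in fms]
                per_class_means.append(np.mean(vals))
            assert rep.classes_avg[metric] == pytest.approx(np.mean(per_class_means))

    def test_table_layout(self):
        cm = ConfusionMatrix(counts=np.array([[4, 1], [1, 4]]), class_names=["a", "b"])
        table = aggregate_folds([cm, cm]).to_table()
        assert list(table.index) == ["Fold1", "Fold2", "Folds avg", "Classes avg"]
        assert ("accuracy", "a") in table.columns
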