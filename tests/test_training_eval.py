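import math

import numpy as np
import pytest
from scipy import stats as sps

from promoterbench.dataset_builder import (
    Interval,
    LabeledWindow,
    PromoterDataset,
)
from promoterbench.models import ArchitectureSpec, build_model
from promoterbench.training_eval import (
    INCOMPATIBLE,
    ConfusionCounts,
    EarlyStopper,
    MetricsReport,
    TrainingConfig,
    apply_sampling,
    confusion,
    cross_test,
    evaluate,
    kfold_cv,
    metrics,
    t_confidence_interval,
    train,
    _stratified_batches,
)


def direct_metrics(tp, fp, tn, fn):
    """Independent oracle: the four definitions evaluated directly."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return sn, sp, ppv, mcc


class TestMetrics:
    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(50, 0, 50, 0))
        assert (r.Sn, r.Sp, r.PPV, r.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_agrees_with_direct_formulas(self):
        r = metrics(ConfusionCounts(3, 1, 90, 2))
        assert (r.Sn, r.Sp, r.PPV, r.MCC) == pytest.approx(direct_metrics(3, 1, 90, 2))

    def test_random_tables_match_oracle(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 200, size=4))
            r = metrics(ConfusionCounts(tp, fp, tn, fn))
            e = direct_metrics(tp, fp, tn, fn)
            assert (r.Sn, r.Sp, r.PPV, r.MCC) == pytest.approx(e, abs=1e-12)

    def test_zero_denominator_flagged(self):
        r = metrics(ConfusionCounts(0, 0, 10, 5))
        assert r.PPV == 0.0 and "PPV" in r.undefined and "MCC" in r.undefined

    def test_mcc_zero_for_constant_prediction_on_balanced_set(self):
        # predict-all-I on a balanced set: TP=n, FP=n, TN=FN=0
        r = metrics(ConfusionCounts(50, 50, 0, 0))
        assert r.MCC == 0.0 and "MCC" in r.undefined

    def test_mcc_symmetric_under_class_swap(self, rng):
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 100, size=4))
        a = metrics(ConfusionCounts(tp, fp, tn, fn)).MCC
        b = metrics(ConfusionCounts(tn, fn, tp, fp)).MCC
        assert a == pytest.approx(b)


class TestConfusion:
    def test_perfect(self):
        c = confusion(["I"] * 5 + ["O"] * 5, ["I"] * 5 + ["O"] * 5)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 5, 0, 0)

    def test_all_predicted_positive(self):
        c = confusion(["I"] * 10, ["I"] * 2 + ["O"] * 8)
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 8, 0, 0)

    def test_matches_brute_force(self, rng):
        pred = ["I" if x else "O" for x in rng.integers(0, 2, 200)]
        true = ["I" if x else "O" for x in rng.integers(0, 2, 200)]
        c = confusion(pred, true)
        assert c.TP == sum(p == t == "I" for p, t in zip(pred, true))
        assert c.total == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["I"], ["I", "O"])


def _balanced_ds(rng, n_i, n_o, L=40):
    windows = [
        LabeledWindow("".join(rng.choice(list("ACGT"), L)), "I", Interval("c", i, i + L))
        for i in range(n_i)
    ]
    windows += [
        LabeledWindow("".join(rng.choice(list("ACGT"), L)), "O",
                      Interval("c", 10_000 + i, 10_000 + i + L))
        for i in range(n_o)
    ]
    return PromoterDataset(windows)


class TestSampling:
    def test_undersample_arithmetic(self, rng):
        ds = _balanced_ds(rng, 100, 10_000)
        out = apply_sampling(ds, "undersample", 10, rng_seed=0)
        assert sum(t == "I" for t in out.tags) == 100
        assert sum(t == "O" for t in out.tags) == 1000

    def test_oversample_arithmetic(self, rng):
        ds = _balanced_ds(rng, 100, 10_000)
        out = apply_sampling(ds, "oversample", 10, rng_seed=0)
        assert sum(t == "I" for t in out.tags) == 1000
        assert sum(t == "O" for t in out.tags) == 10_000
        originals = {w.sequence for w in ds if w.tag == "I"}
        assert {w.sequence for w in out if w.tag == "I"} <= originals

    def test_normal_identity(self, rng):
        ds = _balanced_ds(rng, 10, 20)
        assert apply_sampling(ds, "normal", 10, 0) is ds

    def test_oversample_preserves_distinct_nonpromoters(self, rng):
        ds = _balanced_ds(rng, 5, 50)
        out = apply_sampling(ds, "oversample", 5, rng_seed=1)
        assert {w.sequence for w in out if w.tag == "O"} == {
            w.sequence for w in ds if w.tag == "O"
        }

    def test_undersample_preserves_promoters(self, rng):
        ds = _balanced_ds(rng, 20, 100)
        out = apply_sampling(ds, "undersample", 2, rng_seed=1)
        assert [w.sequence for w in out if w.tag == "I"] == [
            w.sequence for w in ds if w.tag == "I"
        ]

    def test_no_promoters_errors(self, rng):
        ds = _balanced_ds(rng, 0, 10)
        with pytest.raises(ValueError):
            apply_sampling(ds, "undersample", 10, 0)


class TestStratifiedBatches:
    def test_proportions_within_one(self, rng):
        labels = np.array([1] * 30 + [0] * 90)
        batches = _stratified_batches(labels, 16, rng)
        assert sorted(int(i) for b in batches for i in b) == list(range(120))
        expected = 30 / 120
        for b in batches:
            frac = labels[b].mean()
            assert abs(frac * len(b) - expected * len(b)) <= 1.0


class TestEarlyStopping:
    def test_stops_after_patience_without_improvement(self):
        s = EarlyStopper(patience=5)
        assert not s.update(0, 0.8)
        stops = [s.update(e, 0.8) for e in range(1, 7)]
        assert stops == [False, False, False, False, True, True]
        assert s.best_epoch == 0

    def test_improvement_resets_counter(self):
        s = EarlyStopper(patience=2)
        s.update(0, 0.5)
        s.update(1, 0.4)
        assert not s.update(2, 0.6)
        assert not s.update(3, 0.5)
        assert s.update(4, 0.5)


class TestTraining:
    def test_learnable_planted_motif(self, tiny_planted_train, tiny_planted_test):
        # fast check that the loop actually learns; the full-scale
        # learnability bar is asserted in the acceptance suite
        spec = ArchitectureSpec("cnnprom_tata", input_length=100, conv_filters=8,
                                filter_lengths=(15,), pool_size=2, dense_units=16,
                                normalize=True, dropout=0.2)
        model = build_model(spec, seed=0)
        train(model, tiny_planted_train,
              TrainingConfig(max_epochs=30, patience=8, batch_size=32, seed=0))
        rep = evaluate(model, tiny_planted_test)
        assert rep.MCC >= 0.5

    def test_deterministic_under_seed(self, tiny_planted_train):
        def run():
            spec = ArchitectureSpec("cnnprom_tata", input_length=100, conv_filters=4,
                                    filter_lengths=(9,), pool_size=2, dense_units=8)
            model = build_model(spec, seed=7)
            res = train(model, tiny_planted_train,
                        TrainingConfig(max_epochs=3, patience=3, batch_size=32, seed=7))
            return [h["train_loss"] for h in res.history], res.best_val_mcc

        assert run() == run()

    def test_checkpoints_written_and_loadable(self, tmp_path, tiny_planted_train):
        from promoterbench.models import load_checkpoint

        spec = ArchitectureSpec("cnnprom_tata", input_length=100, conv_filters=4,
                                filter_lengths=(9,), pool_size=2, dense_units=8)
        model = build_model(spec, seed=0)
        res = train(model, tiny_planted_train,
                    TrainingConfig(max_epochs=3, patience=3, batch_size=32, seed=0,
                                   checkpoint_dir=str(tmp_path)))
        assert res.checkpoints and (tmp_path / "best.json").exists()
        best = load_checkpoint(tmp_path / "best.json")
        seqs = tiny_planted_train.sequences[:5]
        np.testing.assert_allclose(
            best.predict_scores(seqs), model.predict_scores(seqs)
        )

    def test_single_class_rejected(self, rng):
        ds = _balanced_ds(rng, 10, 0)
        spec = ArchitectureSpec("cnnprom_tata", input_length=40, conv_filters=2,
                                filter_lengths=(5,), pool_size=2, dense_units=4)
        with pytest.raises(ValueError):
            train(build_model(spec), ds, TrainingConfig(max_epochs=1, patience=1))


class TestConfidenceInterval:
    def test_zero_variance_collapses(self):
        assert t_confidence_interval([0.9, 0.9, 0.9]) == (0.9, 0.9)

    def test_matches_closed_form(self):
        # k=3 scores {0.8, 0.9, 1.0}: mean 0.9, sd 0.1, t(0.995, df=2)
        lo, hi = t_confidence_interval([0.8, 0.9, 1.0], level=0.99)
        t = sps.t.ppf(0.995, 2)
        half = t * 0.1 / math.sqrt(3)
        assert (lo, hi) == pytest.approx((0.9 - half, 0.9 + half))

    def test_interval_contains_mean(self, rng):
        vals = rng.random(10).tolist()
        lo, hi = t_confidence_interval(vals)
        assert lo <= float(np.mean(vals)) <= hi


class TestKfold:
    def test_folds_partition_dataset(self, tiny_planted_train):
        spec = ArchitectureSpec("cnnprom_tata", input_length=100, conv_filters=2,
                                filter_lengths=(9,), pool_size=2, dense_units=4)
        report = kfold_cv(spec, tiny_planted_train, k=3,
                          config=TrainingConfig(max_epochs=2, patience=2,
                                                batch_size=32, seed=0))
        assert len(report.folds) == 3
        for name, (lo, hi) in report.ci.items():
            assert lo <= report.mean[name] <= hi


class TestCrossTest:
    def test_matrix_matches_direct_evaluation(self, rng, tiny_planted_train,
                                              tiny_planted_test):
        spec = ArchitectureSpec("cnnprom_tata", input_length=100, conv_filters=2,
                                filter_lengths=(9,), pool_size=2, dense_units=4)
        models = {"a": build_model(spec, seed=0), "b": build_model(spec, seed=1)}
        datasets = {"tr": tiny_planted_train, "te": tiny_planted_test}
        matrix = cross_test(models, datasets)
        assert len(matrix.cells) == 4
        for (mn, dn), cell in matrix.cells.items():
            assert cell == evaluate(models[mn], datasets[dn])

    def test_incompatible_lengths_marked(self, rng, tiny_planted_train):
        spec = ArchitectureSpec("cnnprom_tata", input_length=60, conv_filters=2,
                                filter_lengths=(9,), pool_size=2, dense_units=4)
        matrix = cross_test({"m": build_model(spec)}, {"d": tiny_planted_train})
        assert matrix.cells[("m", "d")] == INCOMPATIBLE

    def test_serialization(self, tmp_path, tiny_planted_test):
        spec = ArchitectureSpec("cnnprom_tata", input_length=100, conv_filters=2,
                                filter_lengths=(9,), pool_size=2, dense_units=4)
        matrix = cross_test({"m": build_model(spec)}, {"d": tiny_planted_test})
        matrix.to_json(tmp_path / "m.json")
        matrix.to_tsv(tmp_path / "m.tsv")
        assert (tmp_path / "m.json").exists() and (tmp_path / "m.tsv").exists()
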