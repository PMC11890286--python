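"""Metrics, stratified protocols, and end-to-end training behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ncfuse as nf
from ncfuse.training import report_from_predictions, usable_indices, subset_mask


def metrics_by_formula(conf):
    """Independent recomputation of all metrics from a confusion matrix."""
    conf = np.asarray(conf, dtype=float)
    k = conf.shape[0]
    n = conf.sum()
    acc = np.trace(conf) / n
    # MCC, multiclass (covariance form)
    t = conf.sum(axis=1)      # true counts
    p = conf.sum(axis=0)      # predicted counts
    c = np.trace(conf)
    num = c * n - t @ p
    den = np.sqrt(n * n - p @ p) * np.sqrt(n * n - t @ t)
    mcc = num / den if den > 0 else 0.0
    prec, rec, f1 = [], [], []
    for i in range(k):
        pr = conf[i, i] / p[i] if p[i] > 0 else 0.0
        rc = conf[i, i] / t[i] if t[i] > 0 else 0.0
        prec.append(pr)
        rec.append(rc)
        f1.append(2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0)
    return acc, mcc, np.mean(f1), np.mean(prec), np.mean(rec)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3] * 5)
        r = report_from_predictions(y, y, 4)
        assert r.accuracy == 1.0 and r.mcc == 1.0 and r.macro_f1 == 1.0

    def test_constant_prediction_on_balanced_data(self):
        y = np.array([0, 1, 2, 3] * 10)
        r = report_from_predictions(y, np.zeros_like(y), 4)
        assert np.isclose(r.accuracy, 0.25)
        assert np.isclose(r.mcc, 0.0)

    def test_random_confusions_match_formulas(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            y_true = rng.integers(0, k, size=200)
            y_pred = rng.integers(0, k, size=200)
            r = report_from_predictions(y_true, y_pred, k)
            conf = np.zeros((k, k), dtype=int)
            for a, b in zip(y_true, y_pred):
                conf[a, b] += 1
            assert np.array_equal(r.confusion, conf)
            acc, mcc, f1, prec, rec = metrics_by_formula(conf)
            assert np.isclose(r.accuracy, acc, atol=1e-9)
            assert np.isclose(r.mcc, mcc, atol=1e-9)
            assert np.isclose(r.macro_f1, f1, atol=1e-9)
            assert np.isclose(r.macro_precision, prec, atol=1e-9)
            assert np.isclose(r.macro_recall, rec, atol=1e-9)

    def test_absent_class_metrics_zero_with_warning(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="absent"):
            r = report_from_predictions(y_true, y_pred, 3)
        assert r.accuracy == 1.0
        assert np.isclose(r.macro_f1, 2 / 3)       # class 2 contributes zero


class TestStratifiedFolds:
    def _dataset(self, n=100, k_classes=4):
        cfg = nf.SynthConfig(n_per_class=n // k_classes, seed=9,
                             classes=[nf.ClassSpec(f"c{i}", "ACGUACGU", 4 + i,
                                                   np.ones(10))
                                      for i in range(k_classes)])
        return nf.simulate_dataset(cfg)

    def test_folds_partition_and_are_proportional(self):
        ds = self._dataset()
        folds = nf.stratified_folds(ds, 10, seed=0)
        labels = ds.labels()
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(len(ds)))     # exact partition
        for tr, va in folds:
            assert len(va) == 10
            counts = np.bincount(labels[va], minlength=4)
            assert (np.abs(counts - 2.5) <= 0.5).all()     # 2 or 3 per class
            assert set(tr) | set(va) == set(range(len(ds)))
            assert not set(tr) & set(va)

    def test_class_smaller_than_k_named_in_error(self):
        ds = self._dataset(n=100)
        ds.samples = ds.samples[:78]                        # truncate last class
        with pytest.raises(ValueError, match="c3"):
            nf.stratified_folds(ds, 10)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            nf.stratified_folds(self._dataset(), 1)


class TestTrain:
    def _separable_expression_dataset(self, n=60):
        """Two classes whose expression profiles are linearly separable."""
        classes = [nf.ClassSpec("lo", "ACGUACGU", 4, np.full(6, 1.0)),
                   nf.ClassSpec("hi", "GGCCGGCC", 8, np.full(6, 12.0))]
        cfg = nf.SynthConfig(n_per_class=n // 2, classes=classes,
                             n_conditions=6, missing_expr_frac=0.0, seed=5,
                             modalities=("expression",),
                             signal_strengths={"expression": 1.0})
        return nf.simulate_dataset(cfg)

    def test_separable_expression_set_reaches_high_accuracy(self):
        ds = self._separable_expression_dataset()
        cfg = nf.ModelConfig.from_dataset(ds)
        model, history = nf.train(ds, cfg, nf.desk_train_config(seed=0,
                                                                epochs=30))
        assert nf.evaluate(model, ds).accuracy >= 0.95
        assert history[-1] < history[0]

    def test_zero_epochs_is_a_no_op(self, tiny_dataset):
        cfg = nf.ModelConfig.from_dataset(tiny_dataset)
        model, history = nf.train(tiny_dataset, cfg,
                                  nf.desk_train_config(seed=0, epochs=0))
        assert history == []
        assert not model.fitted
        ref = nf.MultiModalClassifier(cfg, seed=0)
        for a, b in zip(model.parameters(), ref.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_same_seed_gives_identical_history(self):
        ds = self._separable_expression_dataset(n=30)
        cfg = nf.ModelConfig.from_dataset(ds)
        _, h1 = nf.train(ds, cfg, nf.desk_train_config(seed=7, epochs=4))
        _, h2 = nf.train(ds, cfg, nf.desk_train_config(seed=7, epochs=4))
        assert h1 == h2

    def test_unlabelled_dataset_rejected(self, tiny_dataset):
        ds = tiny_dataset.subset(range(10))
        ds.samples = [type(s)(id=s.id, seq=s.seq, graph=s.graph,
                              expression=s.expression, mask=s.mask, label=None)
                      for s in ds.samples]
        cfg = nf.ModelConfig.from_dataset(ds)
        with pytest.raises(ValueError, match="labelled"):
            nf.train(ds, cfg, nf.desk_train_config())


class TestProtocols:
    def test_usable_indices_respects_subset(self, tiny_dataset):
        smask = subset_mask(tiny_dataset.modality_names, ("expression",))
        idx = usable_indices(tiny_dataset, smask)
        assert len(idx) == tiny_dataset.masks()[:, 2].sum()

    def test_cross_validate_returns_k_reports(self):
        cfg_s = nf.SynthConfig(n_per_class=20, seed=3, missing_expr_frac=0.0,
                               modalities=("expression",))
        ds = nf.simulate_dataset(cfg_s)
        cfg = nf.ModelConfig.from_dataset(ds)
        reports = nf.cross_validate(ds, 3, cfg,
                                    nf.desk_train_config(seed=0, epochs=6))
        assert len(reports) == 3
        assert sum(r.n for r in reports) == len(ds)
        summary = nf.summarize_reports(reports)
        assert set(summary) == {"accuracy", "mcc", "macro_f1",
                                "macro_precision", "macro_recall"}

    def test_ablation_bookkeeping(self, tiny_dataset):
        subsets = [("sequence",), ("structure",), ("expression",),
                   tiny_dataset.modality_names]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nf.ablation(tiny_dataset, subsets,
                              nf.ModelConfig.from_dataset(tiny_dataset),
                              nf.desk_train_config(seed=0, epochs=2))
        assert len(res) == 4
        assert set(res) == {tuple(s) for s in subsets}

    def test_ablation_rejects_empty_subset(self, tiny_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            nf.ablation(tiny_dataset, [()],
                        nf.ModelConfig.from_dataset(tiny_dataset),
                        nf.desk_train_config())

    def test_missing_sample_study_shares_test_split(self, tiny_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra, rc = nf.missing_sample_study(
                tiny_dataset, nf.ModelConfig.from_dataset(tiny_dataset),
                nf.desk_train_config(seed=0, epochs=2))
        assert ra.n == rc.n                         # identical test samples
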