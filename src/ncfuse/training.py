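"""End-to-end training, evaluation metrics, cross-validation, and the
modality-ablation and missing-data study harnesses.

Training minimises batch cross-entropy with Adam; every source of
randomness (initialisation, shuffling, dropout, splits) flows from the
single seed in :class:`TrainConfig`. Metrics are the standard multiclass
suite: accuracy, Matthews correlation coefficient, and macro-averaged
F1/precision/recall, all derivable from the confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix, matthews_corrcoef
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifier import cross_entropy_from_logits
from .model import ModelConfig, MultiModalClassifier, PreparedSample, prepare_dataset
from .io_formats import MultiModalDataset


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    early_stopping_patience: Optional[int] = 10
    validation_fraction: float = 0.1
    modality_subset: Optional[Tuple[str, ...]] = None   # None = all modalities

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.modality_subset is not None and len(self.modality_subset) == 0:
            raise ValueError("modality_subset must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.modality_subset is not None:
            d["modality_subset"] = list(self.modality_subset)
        return d


@dataclass
class EvalReport:
    accuracy: float
    mcc: float
    macro_f1: float
    macro_precision: float
    macro_recall: float
    confusion: np.ndarray
    n: int

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "mcc": self.mcc,
                "macro_f1": self.macro_f1,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall, "n": self.n}


def desk_train_config(seed: int = 0, epochs: int = 16, **overrides) -> TrainConfig:
    """Training settings sized for the bundled synthetic datasets on one CPU:
    a short fixed-epoch schedule with a slightly raised learning rate and no
    early-stopping split (the datasets are small and the schedule short)."""
    base = dict(epochs=epochs, batch_size=64, learning_rate=2e-3, seed=seed,
                early_stopping_patience=None, validation_fraction=0.0)
    base.update(overrides)
    return TrainConfig(**base)


def subset_mask(modality_names: Sequence[str],
                subset: Optional[Sequence[str]]) -> np.ndarray:
    if subset is None:
        return np.ones(len(modality_names), dtype=bool)
    subset = set(subset)
    unknown = subset - set(modality_names)
    if unknown:
        raise ValueError(f"unknown modalities in subset: {sorted(unknown)}")
    return np.array([m in subset for m in modality_names], dtype=bool)


# ------------------------------------------------------------------ training

def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def usable_indices(dataset: MultiModalDataset,
                   smask: np.ndarray) -> np.ndarray:
    """Indices of samples with at least one present modality under `smask`.

    When training or evaluating on a modality subset, samples whose every
    requested modality is missing cannot contribute and are dropped.
    """
    return np.flatnonzero((dataset.masks() & smask[None, :]).any(axis=1))


def train(dataset: MultiModalDataset, model_cfg: ModelConfig,
          train_cfg: TrainConfig,
          prepared: Optional[List[PreparedSample]] = None,
          ) -> Tuple[MultiModalClassifier, List[float]]:
    """Train a model end-to-end on a labelled dataset.

    Returns the trained model and the per-epoch mean training loss. With
    `early_stopping_patience` set and `validation_fraction` > 0, a stratified
    validation split monitors the loss and the best parameter state is
    restored. `epochs=0` returns the freshly initialised model untouched.
    """
    train_cfg.validate()
    if len(dataset) == 0 or any(s.label is None for s in dataset.samples):
        raise ValueError("training requires a fully labelled dataset")
    labels = dataset.labels()
    from .nn import Adam   # local import to keep module load cheap

    smask = subset_mask(dataset.modality_names, train_cfg.modality_subset)
    model = MultiModalClassifier(model_cfg, seed=train_cfg.seed)
    history: List[float] = []
    if train_cfg.epochs == 0:
        return model, history

    if prepared is None:
        prepared = prepare_dataset(dataset, model_cfg)
    rng = np.random.default_rng(train_cfg.seed + 1)

    usable = usable_indices(dataset, smask)
    if len(usable) < len(prepared):
        warnings.warn(f"{len(prepared) - len(usable)} sample(s) have none of "
                      f"the requested modalities and are excluded from training")
        dataset = dataset.subset(usable)
        prepared = [prepared[i] for i in usable]
        labels = labels[usable]
    val_idx: Optional[np.ndarray] = None
    train_idx = np.arange(len(prepared))
    patience = train_cfg.early_stopping_patience
    if patience is not None and train_cfg.validation_fraction > 0:
        counts = np.bincount(labels)
        if counts.min() >= 2 and train_cfg.validation_fraction * len(prepared) >= len(counts):
            train_idx, val_idx = train_test_split(
                train_idx, test_size=train_cfg.validation_fraction,
                random_state=train_cfg.seed, stratify=labels)
        else:
            patience = None

    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    best_val, best_state, stale = np.inf, None, 0
    for _epoch in range(train_cfg.epochs):
        model.train()
        epoch_losses = []
        for batch_idx in _iter_batches(len(train_idx), train_cfg.batch_size, rng):
            batch = [prepared[i] for i in train_idx[batch_idx]]
            y = labels[train_idx[batch_idx]]
            logits, _, _, _ = model.forward(batch, smask)
            loss = cross_entropy_from_logits(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}; "
                    f"lr={train_cfg.learning_rate}, batch={train_cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))

        if val_idx is not None:
            val_loss = _dataset_loss(model, prepared, labels, val_idx, smask,
                                     train_cfg.batch_size)
            if val_loss < best_val - 1e-6:
                best_val, best_state, stale = val_loss, model.state_dict(), 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.fitted = True
    return model, history


def _dataset_loss(model, prepared, labels, idx, smask, batch_size) -> float:
    model.eval()
    losses, weights = [], []
    for start in range(0, len(idx), batch_size):
        sel = idx[start:start + batch_size]
        logits, _, _, _ = model.forward([prepared[i] for i in sel], smask)
        loss = cross_entropy_from_logits(logits, labels[sel])
        losses.append(float(loss.data))
        weights.append(len(sel))
    return float(np.average(losses, weights=weights))


# ------------------------------------------------------------------- metrics

def evaluate(model: MultiModalClassifier, dataset: MultiModalDataset,
             prepared: Optional[List[PreparedSample]] = None,
             modality_subset: Optional[Sequence[str]] = None,
             batch_size: int = 64) -> EvalReport:
    """Evaluate on a labelled dataset; all metrics come from the confusion
    matrix over the dataset's full class list."""
    labels = dataset.labels()
    if prepared is None:
        prepared = prepare_dataset(dataset, model.cfg)
    smask = subset_mask(dataset.modality_names, modality_subset)
    usable = usable_indices(dataset, smask)
    if len(usable) < len(prepared):
        warnings.warn(f"{len(prepared) - len(usable)} sample(s) have none of "
                      f"the requested modalities and are excluded from evaluation")
        prepared = [prepared[i] for i in usable]
        labels = labels[usable]
    preds = []
    for start in range(0, len(prepared), batch_size):
        preds.append(model.predict(prepared[start:start + batch_size], smask))
    y_pred = np.concatenate(preds)
    k = max(len(dataset.class_names), int(labels.max()) + 1, int(y_pred.max()) + 1)
    return report_from_predictions(labels, y_pred, k)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            n_classes: int) -> EvalReport:
    conf = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    accuracy = float(np.trace(conf) / conf.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # sklearn warns on degenerate classes
        mcc = float(matthews_corrcoef(y_true, y_pred))
    row = conf.sum(axis=1).astype(float)     # support per true class
    col = conf.sum(axis=0).astype(float)     # predictions per class
    diag = np.diag(conf).astype(float)
    absent = (row == 0) & (col == 0)
    if absent.any():
        warnings.warn(
            f"classes {np.flatnonzero(absent).tolist()} absent from both truth "
            "and prediction; their per-class metrics are defined as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return EvalReport(accuracy=accuracy, mcc=mcc,
                      macro_f1=float(f1.mean()),
                      macro_precision=float(precision.mean()),
                      macro_recall=float(recall.mean()),
                      confusion=conf, n=int(conf.sum()))


def summarize_reports(reports: Sequence[EvalReport]) -> Dict[str, Tuple[float, float]]:
    """Mean and SD of each metric across reports (e.g. cross-validation folds)."""
    out = {}
    for metric in ("accuracy", "mcc", "macro_f1", "macro_precision", "macro_recall"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=float)
        out[metric] = (float(vals.mean()), float(vals.std()))
    return out


# ---------------------------------------------------------------- protocols

def stratified_split(dataset: MultiModalDataset, test_fraction: float,
                     seed: int, complete_test: bool = False,
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split; with `complete_test`, test samples
    are drawn only from samples that have every modality present."""
    labels = dataset.labels()
    idx = np.arange(len(dataset))
    if complete_test:
        complete = dataset.masks().all(axis=1)
        test_pool = idx[complete]
        tr, te = train_test_split(test_pool, test_size=test_fraction,
                                  random_state=seed, stratify=labels[test_pool])
        train_idx = np.concatenate([idx[~complete], tr])
        return np.sort(train_idx), np.sort(te)
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=labels)
    return np.sort(tr), np.sort(te)


def stratified_folds(dataset: MultiModalDataset, k: int,
                     seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition; every sample appears in exactly one
    validation fold and per-fold class counts are within 1 of proportional."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = dataset.labels()
    names = dataset.class_names or [str(c) for c in np.unique(labels)]
    counts = np.bincount(labels, minlength=len(names))
    for c, cnt in enumerate(counts):
        if 0 < cnt < k:
            raise ValueError(
                f"class {names[c]!r} has {cnt} samples, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(dataset: MultiModalDataset, k: int, model_cfg: ModelConfig,
                   train_cfg: TrainConfig) -> List[EvalReport]:
    """k-fold stratified cross-validation: one model per fold, evaluated on
    its held-out fold."""
    prepared = prepare_dataset(dataset, model_cfg)
    reports = []
    for tr, va in stratified_folds(dataset, k, seed=train_cfg.seed):
        model, _ = train(dataset.subset(tr), model_cfg, train_cfg,
                         prepared=[prepared[i] for i in tr])
        reports.append(evaluate(model, dataset.subset(va),
                                prepared=[prepared[i] for i in va],
                                modality_subset=train_cfg.modality_subset))
    return reports


def ablation(dataset: MultiModalDataset,
             subsets: Sequence[Sequence[str]],
             model_cfg: ModelConfig, train_cfg: TrainConfig,
             test_fraction: float = 0.2,
             ) -> Dict[Tuple[str, ...], EvalReport]:
    """Train one model per modality subset on an identical split and seed,
    so subset scores are directly comparable.

    The shared test split is drawn from complete samples (every modality
    present) so that each subset model is scored on identical samples;
    training uses every sample usable under its subset.
    """
    for s in subsets:
        if len(s) == 0:
            raise ValueError("ablation subsets must be non-empty")
    prepared = prepare_dataset(dataset, model_cfg)
    tr, te = stratified_split(dataset, test_fraction, train_cfg.seed,
                              complete_test=True)
    results: Dict[Tuple[str, ...], EvalReport] = {}
    for subset in subsets:
        cfg = TrainConfig(**{**train_cfg.to_dict(),
                             "modality_subset": tuple(subset)})
        model, _ = train(dataset.subset(tr), model_cfg, cfg,
                         prepared=[prepared[i] for i in tr])
        results[tuple(subset)] = evaluate(
            model, dataset.subset(te), prepared=[prepared[i] for i in te],
            modality_subset=tuple(subset))
    return results


def missing_sample_study(dataset: MultiModalDataset, model_cfg: ModelConfig,
                         train_cfg: TrainConfig, test_fraction: float = 0.2,
                         ) -> Tuple[EvalReport, EvalReport]:
    """Compare training on all samples (masking the missing modalities)
    against training on complete samples only, on one shared test set of
    complete samples.

    Returns (report_all, report_complete_only).
    """
    complete = dataset.masks().all(axis=1)
    if complete.all():
        warnings.warn("dataset has no incomplete samples; the two protocols "
                      "coincide up to training stochasticity")
    prepared = prepare_dataset(dataset, model_cfg)
    tr, te = stratified_split(dataset, test_fraction, train_cfg.seed,
                              complete_test=True)
    test_ds = dataset.subset(te)
    test_prep = [prepared[i] for i in te]

    model_all, _ = train(dataset.subset(tr), model_cfg, train_cfg,
                         prepared=[prepared[i] for i in tr])
    report_all = evaluate(model_all, test_ds, prepared=test_prep,
                          modality_subset=train_cfg.modality_subset)

    tr_complete = tr[complete[tr]]
    model_c, _ = train(dataset.subset(tr_complete), model_cfg, train_cfg,
                       prepared=[prepared[i] for i in tr_complete])
    report_c = evaluate(model_c, test_ds, prepared=test_prep,
                        modality_subset=train_cfg.modality_subset)
    return report_all, report_c
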