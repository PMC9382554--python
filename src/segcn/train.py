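"""Training loop, cross-validation, and evaluation metrics.

Optimization is plain SGD with multiplicative per-epoch learning-rate decay
(factor 0.9 by default).  Reporting follows the two conventions used for
relation extraction: plain accuracy, and micro-F1 pooled over the positive
(non-null) classes — a prediction of the null class is neither a true nor a
false positive.  Metrics are computed from the confusion matrix by hand;
the test suite cross-checks them against scikit-learn.
"""

from __future__ import annotations


import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import SGD
from .corpus import LabelSet, RelationInstance, Vocabulary, build_vocabulary
from .model import ModelConfig, SEGCN

logger = logging.getLogger("segcn")


# ------------------------------------------------------------------- metrics


def confusion_matrix(
    gold: Sequence[str], pred: Sequence[str], labels: Sequence[str]
) -> np.ndarray:
    """Rows gold, columns predicted, in `labels` order."""
    index = {lb: i for i, lb in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for g, p in zip(gold, pred, strict=True):
        mat[index[g], index[p]] += 1
    return mat


def precision_recall_f1(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class P/R/F1 from a confusion matrix; 0 where undefined."""
    tp = np.diag(mat).astype(float)
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    return precision, recall, f1


def micro_f1_non_null(mat: np.ndarray, labels: Sequence[str], null_label: str | None) -> float:
    """Micro-F1 from pooled TP/FP/FN of the positive classes only."""
    tp = fp = fn = 0.0
    for i, lb in enumerate(labels):
        if null_label is not None and lb == null_label:
            continue
        tp += mat[i, i]
        fp += mat[:, i].sum() - mat[i, i]
        fn += mat[i, :].sum() - mat[i, i]
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


@dataclass
class EvalReport:
    accuracy: float
    micro_f1: float
    labels: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, tuple[float, float, float]]  # label -> (P, R, F1)
    n: int

    def summary(self) -> dict:
        return {
            "n": self.n,
            "accuracy": round(self.accuracy, 4),
            "micro_f1": round(self.micro_f1, 4),
            "per_class": {
                lb: {"precision": round(p, 4), "recall": round(r, 4), "f1": round(f, 4)}
                for lb, (p, r, f) in self.per_class.items()
            },
        }


def report_from_predictions(
    gold: Sequence[str], pred: Sequence[str], labels: Sequence[str], null_label: str | None
) -> EvalReport:
    mat = confusion_matrix(gold, pred, labels)
    precision, recall, f1 = precision_recall_f1(mat)
    return EvalReport(
        accuracy=float(np.trace(mat)) / len(gold),
        micro_f1=micro_f1_non_null(mat, labels, null_label),
        labels=tuple(labels),
        confusion=mat,
        per_class={lb: (float(precision[i]), float(recall[i]), float(f1[i])) for i, lb in enumerate(labels)},
        n=len(gold),
    )


def evaluate(model: SEGCN, corpus: Sequence[RelationInstance], null_label: str | None = None) -> EvalReport:
    if not corpus:
        raise ValueError("cannot evaluate on an empty corpus")
    if null_label is None:
        null_label = model.label_set.null_label
    gold = [inst.label for inst in corpus]
    pred = [model.predict(inst) for inst in corpus]
    return report_from_predictions(gold, pred, model.label_set.labels, null_label)


def length_stratified_eval(
    model: SEGCN, corpus: Sequence[RelationInstance], bins: Sequence[tuple[int, int]]
) -> dict[tuple[int, int], EvalReport]:
    """Evaluate separately per sentence-length bin [lo, hi); empty bins are
    absent from the result rather than reported as zero."""
    out: dict[tuple[int, int], EvalReport] = {}
    for lo, hi in bins:
        members = [inst for inst in corpus if lo <= len(inst.tokens) < hi]
        if members:
            out[(lo, hi)] = evaluate(model, members)
    return out


# ------------------------------------------------------------------ training


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_dev_score: float = -np.inf


def split_dev(
    corpus: Sequence[RelationInstance], fraction: float, seed: int
) -> tuple[list[RelationInstance], list[RelationInstance]]:
    """Seeded random split; `fraction` (e.g. 0.1) goes to the dev set."""
    order = np.random.default_rng(seed).permutation(len(corpus))
    n_dev = max(1, int(round(fraction * len(corpus))))
    dev_idx = set(order[:n_dev].tolist())
    train = [corpus[i] for i in range(len(corpus)) if i not in dev_idx]
    dev = [corpus[i] for i in sorted(dev_idx)]
    return train, dev


def train(
    train_corpus: Sequence[RelationInstance],
    dev_corpus: Sequence[RelationInstance] | None,
    config: ModelConfig,
    vocab: Vocabulary | None = None,
    label_set: LabelSet | None = None,
) -> tuple[SEGCN, TrainLog]:
    """Fit a model by SGD; returns the best-dev checkpoint and the log.

    Without an explicit dev corpus, 10% of the training set is split off
    (seeded).  Model selection and early stopping (patience
    `config.patience`) use dev micro-F1 when the label set has a null
    class, dev accuracy otherwise.  Identical seed gives an identical
    trajectory on CPU.
    """
    if dev_corpus is None:
        train_corpus, dev_corpus = split_dev(train_corpus, 0.1, config.seed)
    if label_set is None:
        null = None
        labels = LabelSet.from_instances(list(train_corpus) + list(dev_corpus), null)
        label_set = labels
    for inst in dev_corpus:
        if inst.label not in label_set.labels:
            raise ValueError(f"dev label {inst.label!r} absent from training label set")
    if vocab is None:
        vocab = build_vocabulary(
            list(train_corpus) + list(dev_corpus), dim=config.embedding_dim, seed=config.seed
        )
    model = SEGCN(config, vocab, label_set)
    optimizer = SGD(
        model.parameters(),
        lr=config.lr,
        momentum=config.momentum,
        decay=config.lr_decay,
        clip_norm=config.clip_norm,
    )
    rng = np.random.default_rng(config.seed + 1)
    log = TrainLog()
    best_arrays = model.state_arrays()
    stale = 0
    use_f1 = label_set.null_label is not None
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_corpus))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            optimizer.zero_grad()
            for j in batch:
                loss = model.loss(train_corpus[j], train_rng=rng if config.dropout > 0 else None)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}; training diverged")
                loss.backward()
                losses.append(float(loss.data))
            optimizer.step(scale=1.0 / len(batch))
        dev_report = evaluate(model, dev_corpus)
        dev_score = dev_report.micro_f1 if use_f1 else dev_report.accuracy
        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "train_loss": float(np.mean(losses)),
            "dev_accuracy": dev_report.accuracy,
            "dev_micro_f1": dev_report.micro_f1,
        }
        log.epochs.append(record)
        logger.info(
            "epoch %d lr=%.4f loss=%.4f dev_acc=%.4f dev_f1=%.4f",
            epoch, optimizer.lr, record["train_loss"], dev_report.accuracy, dev_report.micro_f1,
        )
        if dev_score > log.best_dev_score:
            log.best_dev_score = dev_score
            log.best_epoch = epoch
            best_arrays = model.state_arrays()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                logger.info("early stop at epoch %d (patience %d)", epoch, config.patience)
                break
        optimizer.decay_lr()
    model.load_state_arrays(best_arrays)
    return model, log


def crossvalidate(
    corpus: Sequence[RelationInstance], config: ModelConfig, folds: int = 5
) -> dict:
    """Seeded k-fold cross-validation; returns mean and sd of test accuracy.

    Folds are a disjoint partition of a seeded permutation; each fold's
    model trains on the remaining folds (with an internal 10% dev split).
    """
    if folds > len(corpus):
        raise ValueError(f"{folds} folds but only {len(corpus)} instances")
    order = np.random.default_rng(config.seed).permutation(len(corpus))
    chunks = np.array_split(order, folds)
    label_set = LabelSet.from_instances(corpus)
    vocab = build_vocabulary(corpus, dim=config.embedding_dim, seed=config.seed)
    accuracies = []
    fold_reports = []
    for k, test_idx in enumerate(chunks):
        test = [corpus[i] for i in test_idx]
        rest = [corpus[i] for j, c in enumerate(chunks) if j != k for i in c]
        model, _ = train(rest, None, config, vocab=vocab, label_set=label_set)
        report = evaluate(model, test)
        accuracies.append(report.accuracy)
        fold_reports.append(report.summary())
        logger.info("fold %d accuracy %.4f", k, report.accuracy)
    return {
        "mean_accuracy": float(np.mean(accuracies)),
        "sd_accuracy": float(np.std(accuracies, ddof=1)) if folds > 1 else 0.0,
        "fold_accuracies": [float(a) for a in accuracies],
        "fold_reports": fold_reports,
    }
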