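"""Subject-level splitting, grouped cross-validation folds and the training loop."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .nn.autograd import Tensor, cross_entropy
from .models import SequenceClassifier
from .types import SegmentSet


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 12
    optimizer: str = "sgd"
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "sgd":
            raise ValueError("only plain SGD is supported")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint subject-level train/validation/test assignment."""

    train_subjects: Tuple[str, ...]
    val_subjects: Tuple[str, ...]
    test_subjects: Tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        tr, va, te = map(set, (self.train_subjects, self.val_subjects, self.test_subjects))
        if tr & va or tr & te or va & te:
            raise ValueError("train/val/test subject sets must be pairwise disjoint")

    @property
    def all_subjects(self) -> Tuple[str, ...]:
        return self.train_subjects + self.val_subjects + self.test_subjects


@dataclass(frozen=True)
class FoldPlan:
    """An ordered partition of the cohort into cross-validation folds."""

    folds: Tuple[Tuple[str, ...], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [s for fold in self.folds for s in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds must be disjoint")

    def train_test(self, i: int) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
        test = self.folds[i]
        train = tuple(s for j, fold in enumerate(self.folds) if j != i for s in fold)
        return train, test


def _largest_remainder(counts: Mapping[str, int], frac: float) -> Dict[str, int]:
    """Per-stratum allocation of ceil(frac * total), largest remainders first."""
    total = int(math.ceil(frac * sum(counts.values())))
    raw = {g: frac * c for g, c in counts.items()}
    alloc = {g: int(math.floor(r)) for g, r in raw.items()}
    leftover = total - sum(alloc.values())
    order = sorted(counts, key=lambda g: (-(raw[g] - alloc[g]), g))
    for g in order:
        if leftover <= 0:
            break
        if alloc[g] < counts[g]:
            alloc[g] += 1
            leftover -= 1
    return alloc


def _strata(groups: Mapping[str, str]) -> Dict[str, List[str]]:
    strata: Dict[str, List[str]] = {}
    for sid in sorted(groups):
        strata.setdefault(groups[sid], []).append(sid)
    return strata


def split_subjects(
    groups: Mapping[str, str],
    test_frac: float = 0.3,
    val_frac: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Group-stratified subject-level split.

    The test set takes ceil(test_frac * n) subjects, allocated across strata
    by largest remainder; the validation set takes ceil(val_frac * n_train)
    of the remaining training portion the same way.
    """
    if not 0 < test_frac < 1 or not 0 <= val_frac < 1:
        raise ValueError("fractions must lie in (0, 1)")
    if len(groups) < 3:
        raise ValueError("need at least 3 subjects to split")
    rng = np.random.default_rng(seed)
    strata = {g: list(rng.permutation(s)) for g, s in _strata(groups).items()}
    counts = {g: len(s) for g, s in strata.items()}
    n_test = _largest_remainder(counts, test_frac)
    test: List[str] = []
    pool: Dict[str, List[str]] = {}
    for g, subjects in strata.items():
        test.extend(subjects[: n_test[g]])
        pool[g] = subjects[n_test[g]:]
    n_val = _largest_remainder({g: len(s) for g, s in pool.items()}, val_frac)
    val: List[str] = []
    train: List[str] = []
    for g, subjects in pool.items():
        val.extend(subjects[: n_val[g]])
        train.extend(subjects[n_val[g]:])
    if not train:
        raise ValueError("split leaves no training subjects")
    return SplitPlan(tuple(train), tuple(val), tuple(test), seed=seed)


def make_folds(groups: Mapping[str, str], k: int, seed: int = 0) -> FoldPlan:
    """Group-stratified partition into k near-equal folds (round-robin deal)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(groups):
        raise ValueError(f"k={k} exceeds cohort size {len(groups)}")
    rng = np.random.default_rng(seed)
    folds: List[List[str]] = [[] for _ in range(k)]
    for g, subjects in _strata(groups).items():
        shuffled = list(rng.permutation(subjects))
        for i, sid in enumerate(shuffled):
            folds[i % k].append(sid)
    return FoldPlan(tuple(tuple(f) for f in folds), seed=seed)


def assert_no_leakage(
    train_subjects: Sequence[str], test_subjects: Sequence[str]
) -> None:
    """Guard against subject identity appearing on both sides of a boundary."""
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise AssertionError(f"subject leakage across split: {sorted(overlap)}")


@dataclass
class TrainingHistory:
    epoch: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    train_acc: List[float] = field(default_factory=list)
    val_acc: List[float] = field(default_factory=list)


def _evaluate_loss_acc(model: SequenceClassifier, X: np.ndarray,
                       y: np.ndarray, batch_size: int) -> Tuple[float, float]:
    model.eval_mode()
    losses: List[float] = []
    correct = 0
    for start in range(0, len(X), batch_size):
        xb = X[start:start + batch_size]
        yb = y[start:start + batch_size]
        logits = model.logits(Tensor(xb))
        losses.append(float(cross_entropy(logits, yb).data) * len(xb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / len(X), correct / len(X)


def train(
    model: SequenceClassifier,
    train_set: SegmentSet,
    val_set: SegmentSet,
    cfg: TrainConfig = TrainConfig(),
) -> Tuple[SequenceClassifier, TrainingHistory]:
    """Plain mini-batch SGD with per-epoch train/validation monitoring.

    The validation set is never used for weight updates; history lists have
    exactly ``cfg.epochs`` entries.  Given a fixed seed the run is
    deterministic.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    X, y, _ = train_set.to_arrays()
    has_val = len(val_set) > 0
    if has_val:
        Xv, yv, _ = val_set.to_arrays()
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    model.set_dropout_rng(dropout_rng)
    history = TrainingHistory()
    params = list(model.parameters())
    for epoch in range(cfg.epochs):
        model.train_mode()
        order = shuffle_rng.permutation(len(X))
        epoch_loss = 0.0
        correct = 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.logits(Tensor(xb))
            loss = cross_entropy(logits, yb)
            model.zero_grad()
            loss.backward()
            if cfg.learning_rate > 0:
                for p in params:
                    if p.grad is not None:
                        p.data -= cfg.learning_rate * p.grad
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        history.epoch.append(epoch)
        history.train_loss.append(epoch_loss / len(X))
        history.train_acc.append(correct / len(X))
        if has_val:
            vl, va = _evaluate_loss_acc(model, Xv, yv, cfg.batch_size)
        else:
            vl, va = float("nan"), float("nan")
        history.val_loss.append(vl)
        history.val_acc.append(va)
    model.eval_mode()
    return model, history


def predict(
    model: SequenceClassifier, segments: SegmentSet, batch_size: int = 64
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-segment class probabilities and argmax labels in evaluation mode."""
    if len(segments) == 0:
        raise ValueError("empty segment set")
    X, _, _ = segments.to_arrays()
    if X.shape[1:] != (model.config.in_channels, model.config.in_length):
        raise ValueError(
            f"segments of shape {X.shape[1:]} do not match model input "
            f"({model.config.in_channels}, {model.config.in_length})"
        )
    probs = np.concatenate([
        model.predict_proba(X[i:i + batch_size])
        for i in range(0, len(X), batch_size)
    ])
    return probs, probs.argmax(axis=1)
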