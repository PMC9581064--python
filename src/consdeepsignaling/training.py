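"""Cross-validated training, staged learning rates and permutation nulls.

The evaluation protocol: five-fold cross-validation; each fold trains for
100 epochs of mini-batch MSE minimization under a staged learning-rate
schedule (high rates early, decaying in fixed epoch bands to avoid
oscillation); per-fold and averaged train/test MSE and Pearson r are
reported.  Model significance is assessed against a permutation null:
labels are shuffled, the model retrained from scratch with the identical
protocol, and the empirical p-value of the observed Pearson r computed
from the null ECDF, with Benjamini-Hochberg FDR across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import ModelState

__all__ = [
    "LRSchedule",
    "CONSDEEP_SCHEDULE",
    "DNN_SCHEDULE",
    "lr_at_epoch",
    "FoldSplit",
    "kfold_split",
    "pearson",
    "Adam",
    "train",
    "MetricReport",
    "cross_validate",
    "PermutationNull",
    "permutation_null",
]

logger = logging.getLogger("consdeepsignaling")


@dataclass(frozen=True)
class LRSchedule:
    """Staged learning rates: (first_epoch, last_epoch, rate) bands that
    partition [1, max_epoch] with non-increasing rates."""

    stages: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        prev_end, prev_rate = 0, np.inf
        for start, end, rate in self.stages:
            if start != prev_end + 1:
                raise ValueError(f"stages must partition epochs contiguously; "
                                 f"stage starts at {start}, expected {prev_end + 1}")
            if end < start:
                raise ValueError(f"empty stage [{start}, {end}]")
            if rate <= 0:
                raise ValueError(f"non-positive learning rate {rate}")
            if rate > prev_rate:
                raise ValueError("learning rates must be non-increasing across stages")
            prev_end, prev_rate = end, rate

    @property
    def max_epoch(self) -> int:
        return self.stages[-1][1]


# The two printed staged schedules: same five rates, different epoch bands.
CONSDEEP_SCHEDULE = LRSchedule((
    (1, 30, 1e-3), (31, 40, 1e-4), (41, 50, 5e-5), (51, 70, 1e-5), (71, 100, 1e-6)))
DNN_SCHEDULE = LRSchedule((
    (1, 15, 1e-3), (16, 30, 1e-4), (31, 50, 5e-5), (51, 70, 1e-5), (71, 100, 1e-6)))


def lr_at_epoch(schedule: LRSchedule, epoch: int) -> float:
    """The learning rate of the unique stage containing ``epoch`` (1-based)."""
    if epoch < 1 or epoch > schedule.max_epoch:
        raise ValueError(f"epoch {epoch} outside [1, {schedule.max_epoch}]")
    for start, end, rate in schedule.stages:
        if start <= epoch <= end:
            return rate
    raise AssertionError("unreachable: stages partition the epoch range")


@dataclass
class FoldSplit:
    """k-fold assignment: sample index -> fold id in [0, k)."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def kfold_split(n_samples: int, k: int, seed: int) -> FoldSplit:
    """Seeded uniform permutation cut into k contiguous blocks.

    The ``n_samples mod k`` leftover samples are appended to the last
    fold(s), largest-last: e.g. 16,761 samples in 5 folds give test folds
    of 3352/3352/3352/3352/3353.
    """
    if k < 1 or n_samples < k:
        raise ValueError(f"need n_samples >= k >= 1, got n={n_samples}, k={k}")
    base, rem = divmod(n_samples, k)
    sizes = [base] * k
    for i in range(rem):  # extras to the last folds, largest fold last
        sizes[k - 1 - i] += 1
    perm = np.random.default_rng(seed).permutation(n_samples)
    assignments = np.empty(n_samples, dtype=int)
    start = 0
    for fold, size in enumerate(sizes):
        assignments[perm[start:start + size]] = fold
        start += size
    return FoldSplit(k, assignments, seed)


def pearson(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Product-moment correlation; constant input is an explicit error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError(f"need two equal-length 1-D vectors of size >= 2, "
                         f"got {y.shape} and {y_hat.shape}")
    dy = y - y.mean()
    dh = y_hat - y_hat.mean()
    denom = np.sqrt((dy @ dy) * (dh @ dh))
    if denom == 0:
        raise ValueError("Pearson r undefined: at least one input is constant")
    return float((dy @ dh) / denom)


class Adam:
    """Adam with default moments (b1=0.9, b2=0.999, eps=1e-8).

    Zero gradients produce zero updates, so exactly-masked weights stay
    exactly zero through any number of steps.
    """

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.l2 > 0:  # L2 regularizer: adds l2 * ||W||^2 to the loss
                g = g + 2.0 * p.l2 * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: ModelState,
          X: np.ndarray,
          y: np.ndarray,
          schedule: LRSchedule,
          epochs: int = 100,
          batch_size: int = 256,
          seed: int = 0,
          grad_callback: Callable[[list], None] | None = None) -> list[float]:
    """Mini-batch MSE training under the staged learning-rate schedule.

    Deterministic given seeds (batch shuffling uses ``seed``, dropout
    streams are reset to the model's own seeds).  Returns the per-epoch
    mean training loss.  ``grad_callback`` receives the parameter list
    after each backward pass, before the optimizer step (used to audit
    gradient masking).
    """
    X = np.atleast_2d(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or y.size == 0:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
    if epochs > schedule.max_epoch:
        raise ValueError(f"epochs={epochs} exceeds schedule range {schedule.max_epoch}")
    rng = np.random.default_rng(seed)
    model.reset_dropout()
    opt = Adam(model.params())
    history: list[float] = []
    n = X.shape[0]
    for epoch in range(1, epochs + 1):
        lr = lr_at_epoch(schedule, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            pred = model.forward_batch(xb, train=True)
            resid = pred - yb
            loss = float(resid @ resid) / idx.size
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}")
            for p in model.params():
                p.zero_grad()
            model.backward_batch(2.0 * resid / idx.size)
            if grad_callback is not None:
                grad_callback(model.params())
            opt.step(lr)
            epoch_loss += loss * idx.size
        history.append(epoch_loss / n)
        logger.debug("epoch %d lr %.2e loss %.6f", epoch, lr, history[-1])
    return history


@dataclass
class MetricReport:
    """Per-fold and averaged train/test MSE and Pearson r, plus loss curves."""

    folds: list[int]
    train_mse: list[float]
    test_mse: list[float]
    train_pearson: list[float]
    test_pearson: list[float]
    loss_history: list[list[float]] = field(default_factory=list)

    @property
    def mean_train_pearson(self) -> float:
        return float(np.mean(self.train_pearson))

    @property
    def mean_test_pearson(self) -> float:
        return float(np.mean(self.test_pearson))

    @property
    def mean_train_mse(self) -> float:
        return float(np.mean(self.train_mse))

    @property
    def mean_test_mse(self) -> float:
        return float(np.mean(self.test_mse))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": self.folds, "train_mse": self.train_mse,
            "test_mse": self.test_mse, "train_pearson": self.train_pearson,
            "test_pearson": self.test_pearson})


def _mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    d = np.asarray(y) - np.asarray(y_hat)
    return float(d @ d) / d.size


def cross_validate(X: np.ndarray,
                   y: np.ndarray,
                   model_builder: Callable[[int], ModelState],
                   schedule: LRSchedule,
                   provenance: Sequence[tuple[str, str]] | None = None,
                   k: int = 5,
                   epochs: int = 100,
                   batch_size: int = 256,
                   seed: int = 0) -> tuple[MetricReport, pd.DataFrame]:
    """k-fold cross-validation of one architecture.

    ``model_builder(seed)`` must return a freshly initialized model; each
    fold gets a distinct derived seed.  Returns the metric report and a
    tidy predictions table (drug, cell_line, auc_true, auc_pred, fold).
    """
    split = kfold_split(len(y), k, seed)
    report = MetricReport([], [], [], [], [])
    rows = []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        model = model_builder(seed * 1009 + fold)
        history = train(model, X[tr], y[tr], schedule, epochs=epochs,
                        batch_size=batch_size, seed=seed * 2003 + fold)
        pred_tr, pred_te = model.predict(X[tr]), model.predict(X[te])
        report.folds.append(fold)
        report.train_mse.append(_mse(y[tr], pred_tr))
        report.test_mse.append(_mse(y[te], pred_te))
        report.train_pearson.append(pearson(y[tr], pred_tr))
        report.test_pearson.append(pearson(y[te], pred_te))
        report.loss_history.append(history)
        logger.info("fold %d: train r=%.4f test r=%.4f", fold,
                    report.train_pearson[-1], report.test_pearson[-1])
        for i, p in zip(te, pred_te):
            drug, cl = provenance[i] if provenance is not None else ("", "")
            rows.append({"drug": drug, "cell_line": cl, "auc_true": y[i],
                         "auc_pred": p, "fold": fold})
    predictions = pd.DataFrame(rows, columns=["drug", "cell_line", "auc_true",
                                              "auc_pred", "fold"])
    return report, predictions


@dataclass
class PermutationNull:
    """Permutation-null Pearson values and empirical p-values per fold."""

    n_perm: int
    folds: list[int]
    observed_train: list[float]
    observed_test: list[float]
    null_train: list[list[float]]
    null_test: list[list[float]]
    p_values: list[float]
    fdr: list[float]
    add_one_correction: bool = False

    @property
    def mean_null_train(self) -> float:
        return float(np.mean([v for fold in self.null_train for v in fold]))

    @property
    def mean_null_test(self) -> float:
        return float(np.mean([v for fold in self.null_test for v in fold]))


def _ecdf_p(observed: float, null: Sequence[float], add_one: bool) -> float:
    count = int(sum(v >= observed for v in null))
    if add_one:
        return (count + 1) / (len(null) + 1)
    return count / len(null)


def permutation_null(X: np.ndarray,
                     y: np.ndarray,
                     model_builder: Callable[[int], ModelState],
                     schedule: LRSchedule,
                     n_perm: int = 10,
                     k: int = 5,
                     epochs: int = 100,
                     batch_size: int = 256,
                     seed: int = 0,
                     observed: MetricReport | None = None,
                     per_fold: bool = True,
                     add_one_correction: bool = False) -> PermutationNull:
    """Label-shuffle null distribution of the train/test Pearson r.

    For each permutation the AUC labels are shuffled over all samples
    (seeded), the model retrained from scratch with the identical protocol
    on the same fold split, and the train/test Pearson recorded.  The
    empirical p-value per fold is the fraction of null test values at least
    as large as the observed one (``(r+1)/(n+1)`` correction optional);
    FDR across folds is Benjamini-Hochberg.

    ``per_fold=True`` draws ``n_perm`` independent permutations for every
    fold; ``False`` reuses one set of ``n_perm`` permutations globally.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed, _ = cross_validate(X, y, model_builder, schedule, k=k,
                                     epochs=epochs, batch_size=batch_size, seed=seed)
    split = kfold_split(len(y), k, seed)
    rng = np.random.default_rng(seed + 7919)
    global_perms = [rng.permutation(len(y)) for _ in range(n_perm)] if not per_fold else None
    null_train: list[list[float]] = []
    null_test: list[list[float]] = []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        fold_train, fold_test = [], []
        for p_i in range(n_perm):
            perm = global_perms[p_i] if global_perms is not None else rng.permutation(len(y))
            y_perm = y[perm]
            model = model_builder(seed * 1009 + fold + 104729 * (p_i + 1))
            train(model, X[tr], y_perm[tr], schedule, epochs=epochs,
                  batch_size=batch_size, seed=seed * 2003 + fold + 104729 * (p_i + 1))
            fold_train.append(pearson(y_perm[tr], model.predict(X[tr])))
            fold_test.append(pearson(y_perm[te], model.predict(X[te])))
            logger.info("fold %d perm %d: null test r=%.4f", fold, p_i, fold_test[-1])
        null_train.append(fold_train)
        null_test.append(fold_test)
    p_values = [_ecdf_p(observed.test_pearson[f], null_test[f], add_one_correction)
                for f in range(k)]
    fdr = list(multipletests(p_values, method="fdr_bh")[1])
    return PermutationNull(n_perm, list(range(k)), list(observed.train_pearson),
                           list(observed.test_pearson), null_train, null_test,
                           p_values, fdr, add_one_correction)
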