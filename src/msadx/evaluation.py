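"""Model evaluation: stratified folds, ROC-AUC, and nested cross-validation.

Predictive performance is summarised as one-vs-rest multiclass AUC: for each
subtype its predicted probability is scored against membership of that
subtype, and the three AUCs are averaged unweighted. Generalisation is
estimated by double (nested) cross-validation — an inner fold loop selects
hyperparameters on each outer-training split, the winner is refit on the full
outer-training split and scored on the untouched outer-test fold — so
hyperparameter selection never sees test cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .encoding import DesignMatrix, NormStats
from .pwl import PWLConfig, PWLParams, forward, train
from .registry import SUBTYPES

__all__ = ["FoldPlan", "DCVReport", "stratified_kfold", "roc_auc",
           "ovr_mean_auc", "double_cross_validate",
           "heldout_probability_table"]


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: np.ndarray  # per-case fold index in [0, k)
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class DCVReport:
    k_outer: int
    k_inner: int
    variant: str
    train_auc: list[float]
    test_auc: list[float]
    selected: list[dict]
    seed: int

    @property
    def train_mean(self) -> float:
        return float(np.mean(self.train_auc))

    @property
    def train_sd(self) -> float:
        return float(np.std(self.train_auc, ddof=1))

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_auc))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.test_auc, ddof=1))

    def to_dict(self) -> dict:
        return {
            "k_outer": self.k_outer, "k_inner": self.k_inner,
            "variant": self.variant, "seed": self.seed,
            "train_auc_per_fold": self.train_auc,
            "test_auc_per_fold": self.test_auc,
            "train_auc_mean": self.train_mean, "train_auc_sd": self.train_sd,
            "test_auc_mean": self.test_mean, "test_auc_sd": self.test_sd,
            "selected_per_fold": self.selected,
        }

    def __str__(self) -> str:
        return (f"{self.k_outer}-fold DCV (variant {self.variant}): "
                f"train AUC {self.train_mean:.3f} +/- {self.train_sd:.3f}, "
                f"test AUC {self.test_mean:.3f} +/- {self.test_sd:.3f}")


def stratified_kfold(labels, k: int, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold assignment.

    Within each class, cases are shuffled and dealt round-robin (with a
    per-class random fold offset), so per-fold class counts differ by at most
    one from proportional.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
        rng.shuffle(idx)
        offset = rng.integers(k)
        assignment[idx] = (np.arange(len(idx)) + offset) % k
    return FoldPlan(k, assignment, seed)


def roc_auc(scores, binary_labels) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # midranks
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def ovr_mean_auc(prob_table: np.ndarray, labels) -> tuple[dict, float]:
    """One-vs-rest AUC per class and their unweighted mean.

    Class c uses column c of the probability table as score and membership of
    class c as target.
    """
    P = np.asarray(prob_table, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OU":  # subtype strings -> class indices
        y = np.asarray([SUBTYPES.index(v) for v in y])
    per_class = {}
    for c in range(P.shape[1]):
        per_class[SUBTYPES[c] if c < len(SUBTYPES) else c] = \
            roc_auc(P[:, c], y == c)
    return per_class, float(np.mean(list(per_class.values())))


def _refit_norm(matrix: DesignMatrix, train_idx: np.ndarray) -> np.ndarray:
    """Re-standardise quantitative columns with training-split statistics.

    Standardisation is affine, so fitting fold statistics on already
    globally-standardised columns is identical to fitting them on raw values.
    """
    X = matrix.values.copy()
    for f in matrix.codebook.features:
        if f.encoding == "Q":
            col = X[train_idx, f.index]
            m, s = col.mean(), max(col.std(), 1e-8)
            X[:, f.index] = (X[:, f.index] - m) / s
    return X


def _subset(matrix: DesignMatrix, X: np.ndarray, idx: np.ndarray
            ) -> DesignMatrix:
    return DesignMatrix(X[idx], matrix.codebook, matrix.labels[idx],
                        matrix.norm_stats,
                        None if matrix.case_ids is None else matrix.case_ids[idx])


def _fit_and_auc(matrix: DesignMatrix, X: np.ndarray, train_idx, test_idx,
                 cfg: PWLConfig) -> tuple[float, float, PWLParams]:
    params = train(_subset(matrix, X, train_idx), cfg)
    y = matrix.y
    auc_tr = ovr_mean_auc(forward(params, X[train_idx]).probs, y[train_idx])[1]
    auc_te = ovr_mean_auc(forward(params, X[test_idx]).probs, y[test_idx])[1]
    return auc_tr, auc_te, params


def double_cross_validate(matrix: DesignMatrix,
                          config_grid: list[PWLConfig] | PWLConfig,
                          k_outer: int = 10, k_inner: int = 5,
                          seed: int = 0) -> DCVReport:
    """Nested cross-validation with hyperparameter selection by highest AUC.

    For each outer fold, every grid configuration is scored by ``k_inner``-fold
    CV on the outer-training split; the configuration with the highest mean
    inner test AUC is refit on the whole outer-training split and scored on
    the outer-training and outer-test cases. A singleton grid skips the inner
    loop (selection is trivial) but follows the identical outer protocol.
    Quantitative columns are re-standardised per outer-training split.
    """
    grid = [config_grid] if isinstance(config_grid, PWLConfig) else list(config_grid)
    if not grid:
        raise ValueError("config grid must be non-empty")
    for cfg in grid:
        if not isinstance(cfg, PWLConfig):
            raise ValueError(f"grid entries must be PWLConfig, got {type(cfg)}")
    y = matrix.y
    outer = stratified_kfold(y, k_outer, seed)
    train_aucs, test_aucs, selected = [], [], []
    for fold in range(k_outer):
        tr, te = outer.train_indices(fold), outer.test_indices(fold)
        X = _refit_norm(matrix, tr)
        if len(grid) == 1:
            best = grid[0]
        else:
            inner = stratified_kfold(y[tr], k_inner, seed + 1000 + fold)
            best, best_auc = None, -np.inf
            for cfg in grid:
                scores = []
                for ifold in range(k_inner):
                    itr = tr[inner.train_indices(ifold)]
                    ite = tr[inner.test_indices(ifold)]
                    _, auc_te, _ = _fit_and_auc(
                        matrix, X, itr, ite,
                        replace(cfg, seed=cfg.seed + fold * 100 + ifold))
                    scores.append(auc_te)
                mean_auc = float(np.mean(scores))
                if mean_auc > best_auc:
                    best, best_auc = cfg, mean_auc
        auc_tr, auc_te, _ = _fit_and_auc(
            matrix, X, tr, te, replace(best, seed=best.seed + fold))
        train_aucs.append(auc_tr)
        test_aucs.append(auc_te)
        selected.append({"n_epochs": best.n_epochs,
                         "layer_size": best.layer_size,
                         "n_inner_layers": best.n_inner_layers,
                         "learning_rate": best.learning_rate,
                         "reg_coef": best.reg_coef})
    return DCVReport(k_outer, k_inner, matrix.codebook.variant,
                     train_aucs, test_aucs, selected, seed)


def heldout_probability_table(matrix: DesignMatrix,
                              config: PWLConfig | None = None,
                              n_per_class: int = 10, seed: int = 0):
    """Hold out ``n_per_class`` random cases per subtype, train on the rest,
    and return their per-case probability table.

    Returns (table, params); the table has one row per held-out case with the
    true subtype, the three probabilities and the argmax call.
    """
    import pandas as pd

    cfg = PWLConfig() if config is None else config
    y = matrix.y
    rng = np.random.default_rng(seed)
    held = []
    for c in range(len(SUBTYPES)):
        idx = np.flatnonzero(y == c)
        if len(idx) <= n_per_class:
            raise ValueError(
                f"class {SUBTYPES[c]} has only {len(idx)} cases; "
                f"cannot hold out {n_per_class}")
        held.append(rng.choice(idx, size=n_per_class, replace=False))
    held = np.concatenate(held)
    train_idx = np.setdiff1d(np.arange(matrix.n), held)
    X = _refit_norm(matrix, train_idx)
    params = train(_subset(matrix, X, train_idx), cfg)
    pred = forward(params, X[held])
    table = pd.DataFrame(pred.probs, columns=list(SUBTYPES))
    table.insert(0, "true_subtype", matrix.labels[held])
    if matrix.case_ids is not None:
        table.insert(0, "case_id", matrix.case_ids[held])
    table["predicted"] = [SUBTYPES[i] for i in pred.probs.argmax(axis=1)]
    table.attrs["n_train"] = int(len(train_idx))
    return table, params
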