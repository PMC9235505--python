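"""Replicated hold-out evaluation protocol for MAKL.

One replication: stratified 80/20 train/test split; per-gene z-normalization
with training statistics; 4-fold stratified inner cross-validation over a
lambda-multiplier grid (default {0.9, 0.8, 0.7, 0.6}), scored by mean
validation AUROC with ties broken toward the larger multiplier (the sparser
model); refit on the full training split at the chosen multiplier; test-set
AUROC, selected sets and gene-coverage fraction recorded. R replications
run on independent child seeds of a master seed, so adding replications
never perturbs earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import group_lasso
from .datasets import ExpressionDataset
from .feature_sets import FeatureSetCollection, resolve
from .model import (
    _normalize_with,
    fit_makl,
    gene_coverage_fraction,
    predict_score,
    prepare_blocks,
    selected_sets,
    transform_blocks,
)

__all__ = [
    "EvaluationReport",
    "split_80_20",
    "zscore_fit_apply",
    "auroc",
    "inner_cv_select_lambda",
    "run_replications",
    "l1_linear_baseline_auroc",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = (0.9, 0.8, 0.7, 0.6)


@dataclass
class EvaluationReport:
    """Aggregated outcome of R replications.

    ``replications`` holds one row per replication (chosen multiplier, test
    AUROC, number of selected sets, gene-coverage fraction);
    ``set_table`` one row per gene set (selection frequency, mean eta).
    Aggregates are pure functions of the per-replication records.
    """

    auroc_per_replication: np.ndarray
    selection_frequency: dict
    mean_sets_selected: float
    mean_gene_fraction: float
    chosen_multipliers: list
    replications: pd.DataFrame = field(repr=False, default=None)
    set_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc_per_replication))

    def write_csvs(self, replication_path, selection_path):
        """Write the per-replication and per-set tables (UTF-8, headers)."""
        self.replications.to_csv(replication_path, index=False)
        self.set_table.to_csv(selection_path, index=False)


def split_80_20(dataset: ExpressionDataset, rng=None):
    """Stratified train/test split with round(0.8 N) training samples.

    Each class contributes proportionally (largest-remainder rounding),
    with at least one sample of each class on both sides. Disjoint and
    exhaustive by construction.
    """
    if dataset.y is None:
        raise ValueError("dataset has no labels")
    y = dataset.y
    n = dataset.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split 80/20")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    rng = np.random.default_rng(rng)
    n_train = int(round(0.8 * n))
    # proportional allocation, then largest remainders; clamp to keep both
    # classes represented on both sides
    exact = counts * n_train / n
    alloc = np.floor(exact).astype(int)
    remainder_order = np.argsort(-(exact - alloc))
    for c in remainder_order:
        if alloc.sum() == n_train:
            break
        alloc[c] += 1
    alloc = np.clip(alloc, 1, counts - 1)
    # re-balance if clamping changed the total
    while alloc.sum() < n_train:
        c = int(np.argmax(counts - 1 - alloc))
        if alloc[c] >= counts[c] - 1:
            break
        alloc[c] += 1
    while alloc.sum() > n_train:
        c = int(np.argmax(alloc - 1))
        if alloc[c] <= 1:
            break
        alloc[c] -= 1

    train_idx, test_idx = [], []
    for c, k in zip(classes, alloc):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        train_idx.extend(perm[:k].tolist())
        test_idx.extend(perm[k:].tolist())
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))
    return dataset.subset(train_idx), dataset.subset(test_idx)


def zscore_fit_apply(train_X, test_X):
    """Z-normalize: train columns to mean 0 / sample SD 1, test with the
    train statistics. Constant training columns map to all-zeros in both
    (guarded division, no NaN).

    Returns (train_Z, test_Z, means, sds).
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0, ddof=1)
    return (
        _normalize_with(train_X, means, sds),
        _normalize_with(test_X, means, sds),
        means,
        sds,
    )


def auroc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form (ties count one half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _stratified_folds(y, n_folds, rng):
    seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def inner_cv_select_lambda(
    train: ExpressionDataset,
    sets: FeatureSetCollection,
    D: int,
    S: int | None,
    grid=DEFAULT_GRID,
    rng=None,
    n_folds: int = 4,
    tol: float = 1e-5,
    max_iter: int = 3000,
    return_table: bool = False,
):
    """Pick a lambda multiplier by stratified inner cross-validation.

    For each fold the per-set bandwidths and maps are re-estimated on the
    fold's training part; the multiplier grid is fitted warm-started from
    large to small (sharing one lambda_max per fold) and scored by
    validation AUROC. The argmax of the mean validation AUROC is returned,
    ties broken toward the larger multiplier. Folds where a class vanishes
    are redrawn with a fresh seed, at most 5 times.
    """
    grid = sorted(set(float(g) for g in grid), reverse=True)
    if not grid or not all(0.0 < g <= 1.0 for g in grid):
        raise ValueError("grid must be non-empty with values in (0, 1]")
    if len(grid) == 1:
        return (grid[0], None) if return_table else grid[0]
    if train.y is None:
        raise ValueError("training dataset has no labels")
    rng = np.random.default_rng(rng)
    y = train.y

    folds = None
    for attempt in range(5):
        cand = _stratified_folds(y, n_folds, rng)
        if all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2
            for tr, va in cand
        ):
            folds = cand
            break
        logger.warning("one-class fold on attempt %d; refolding", attempt + 1)
    if folds is None:
        raise ValueError("could not build two-class folds in 5 attempts")

    val_auc = np.zeros((n_folds, len(grid)))
    for k, (tr, va) in enumerate(folds):
        Xtr, Xva = train.X[tr], train.X[va]
        ytr, yva = y[tr], y[va]
        Ztr_X, Zva_X, _, _ = zscore_fit_apply(Xtr, Xva)
        names, indices, maps, Ztr = prepare_blocks(
            Ztr_X, sets, D=D, S=S, rng=rng
        )
        Zva = transform_blocks(Zva_X, indices, maps)
        structure = group_lasso.GroupStructure.contiguous(
            [2 * D] * len(names)
        )
        lam_max = group_lasso.lambda_max(Ztr, ytr, structure)
        init = None
        for j, mult in enumerate(grid):
            gl = group_lasso.fit(
                Ztr, ytr, structure,
                lambda_multiplier=mult, tol=tol, max_iter=max_iter,
                lambda_max_value=lam_max, init=init,
            )
            init = gl
            scores = gl.intercept + Zva @ gl.coef
            val_auc[k, j] = auroc(scores, yva)

    means = val_auc.mean(axis=0)
    best = int(np.argmax(means))  # grid is descending: first max = larger mult
    table = pd.DataFrame(
        {"multiplier": grid, "mean_val_auroc": means}
    )
    logger.info("inner CV: chose multiplier %.2f (%s)", grid[best],
                ", ".join(f"{g:.2f}:{m:.3f}" for g, m in zip(grid, means)))
    if return_table:
        return grid[best], table
    return grid[best]


def run_replications(
    dataset: ExpressionDataset,
    sets: FeatureSetCollection,
    D: int = 150,
    S: int | None = None,
    grid=DEFAULT_GRID,
    R: int = 100,
    seed: int = 0,
    n_folds: int = 4,
    tol: float = 1e-5,
    max_iter: int = 3000,
) -> EvaluationReport:
    """R independent split/tune/fit/score cycles; aggregate the outcomes.

    ``sets`` may be unresolved; it is resolved once against the dataset's
    gene names. Per-replication failures propagate with the replication
    index attached.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if sets.resolved_indices is None:
        sets = resolve(sets, dataset.gene_names)
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(R)

    rows = []
    eta_records = {name: [] for name in sets.names}
    selected_records = {name: 0 for name in sets.names}
    for r in range(R):
        try:
            split_ss, cv_ss, fit_ss = rep_seeds[r].spawn(3)
            train, test = split_80_20(
                dataset, rng=np.random.default_rng(split_ss)
            )
            mult = inner_cv_select_lambda(
                train, sets, D=D, S=S, grid=grid,
                rng=np.random.default_rng(cv_ss), n_folds=n_folds,
                tol=tol, max_iter=max_iter,
            )
            model = fit_makl(
                train, sets, D=D, S=S, lambda_multiplier=mult,
                rng=np.random.default_rng(fit_ss), tol=tol,
                max_iter=max_iter,
            )
            scores = predict_score(model, test.X, test.gene_names)
            test_auc = auroc(scores, test.y)
            chosen = selected_sets(model)
            frac = gene_coverage_fraction(model, sets, dataset.n_genes)
        except Exception as exc:
            raise RuntimeError(f"replication {r} failed: {exc}") from exc
        for name, eta in zip(model.set_names, model.etas):
            eta_records[name].append(float(eta))
            if eta > 0:
                selected_records[name] += 1
        rows.append({
            "replication": r,
            "chosen_multiplier": mult,
            "test_auroc": test_auc,
            "n_sets_selected": len(chosen),
            "gene_fraction": frac,
        })
        logger.info(
            "replication %d: multiplier %.2f, AUROC %.3f, %d sets, "
            "%.3f of genes", r, mult, test_auc, len(chosen), frac,
        )

    reps = pd.DataFrame(rows)
    sel_freq = {name: selected_records[name] / R for name in sets.names}
    set_table = pd.DataFrame({
        "set": list(sets.names),
        "selection_frequency": [sel_freq[n] for n in sets.names],
        "mean_eta": [
            float(np.mean(eta_records[n])) if eta_records[n] else 0.0
            for n in sets.names
        ],
    })
    return EvaluationReport(
        auroc_per_replication=reps["test_auroc"].to_numpy(),
        selection_frequency=sel_freq,
        mean_sets_selected=float(reps["n_sets_selected"].mean()),
        mean_gene_fraction=float(reps["gene_fraction"].mean()),
        chosen_multipliers=reps["chosen_multiplier"].tolist(),
        replications=reps,
        set_table=set_table,
    )


def l1_linear_baseline_auroc(train: ExpressionDataset,
                             test: ExpressionDataset,
                             rng=None) -> float:
    """Test AUROC of an L1-regularized *linear* logistic model on raw genes.

    Cross-validated over a small C grid. Serves as the linear reference the
    kernel machine is compared against: a purely radial class signal is
    invisible to it.
    """
    Xtr, Xte, _, _ = zscore_fit_apply(train.X, test.X)
    seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
    clf = LogisticRegressionCV(
        Cs=np.logspace(-2, 1, 7),
        cv=4,
        penalty="l1",
        solver="liblinear",
        scoring="roc_auc",
        random_state=seed,
        max_iter=2000,
    )
    clf.fit(Xtr, train.y)
    return auroc(clf.decision_function(Xte), test.y)
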