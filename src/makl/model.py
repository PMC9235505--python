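"""End-to-end multiple approximate kernel learning.

Pipeline per fit: z-normalize genes with training statistics; for each
resolved gene set estimate a Gaussian-kernel bandwidth on that set's
columns, draw a random Fourier map, and compute the (N, 2D) approximation
block; concatenate blocks in set order into a single (N, 2DP) design; fit
the logistic group Lasso. The block norms eta_p = ||beta_p||_2 rank the
gene sets by relevance, and eta_p > 0 marks set p as selected.

Sets may overlap: a gene feeds every block whose set contains it (per-set
column selections, not a disjoint partition). The identical frozen maps
(sigma, Delta, b) used in fitting are applied to any new data at
prediction time.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field

import numpy as np

from . import group_lasso, rff
from .datasets import ExpressionDataset
from .feature_sets import FeatureSetCollection

__all__ = [
    "MAKLModel",
    "fit_makl",
    "predict_score",
    "selected_sets",
    "gene_coverage_fraction",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass
class MAKLModel:
    """A fitted MAKL classifier.

    Attributes
    ----------
    set_names : list of str
        Names of the gene sets that survived fitting, in block order.
    set_indices : list of list of int
        Per set, column indices into ``gene_names``.
    maps : list of RFFMap
        Frozen per-set random Fourier maps, aligned with ``set_names``.
    gene_names : list of str
        Training gene universe (column order of the training matrix).
    means, sds : ndarray
        Per-gene training normalization statistics (sample SD; constant
        genes carry sd = 0 and normalize to zero).
    gl_model : GroupLassoModel
        Fitted group-Lasso coefficients over the concatenated blocks.
    etas : ndarray
        Per-set block norms ||beta_p||_2, aligned with ``set_names``.
    """

    set_names: list
    set_indices: list
    maps: list
    gene_names: list
    means: np.ndarray
    sds: np.ndarray
    gl_model: group_lasso.GroupLassoModel
    D: int
    lambda_multiplier: float
    structure: group_lasso.GroupStructure = field(repr=False, default=None)

    @property
    def etas(self) -> np.ndarray:
        return self.gl_model.etas

    @property
    def n_sets(self) -> int:
        return len(self.set_names)


def _normalize_with(X, means, sds) -> np.ndarray:
    """Apply stored train statistics; constant columns map to zeros."""
    out = X - means
    nz = sds > 0
    out[:, nz] = out[:, nz] / sds[nz]
    out[:, ~nz] = 0.0
    return out


def prepare_blocks(Xn, sets: FeatureSetCollection, D: int,
                   S: int | None, rng):
    """Per-set bandwidths, maps and approximation blocks on normalized data.

    Sets whose bandwidth estimate degenerates (all sampled rows identical,
    e.g. constant columns after normalization) are dropped with a warning
    rather than aborting the fit.

    Returns (kept names, kept indices, maps, Z) with Z of width 2*D*P_kept.
    """
    if sets.resolved_indices is None:
        raise ValueError("feature sets must be resolved before fitting")
    rng = np.random.default_rng(rng)
    names, indices, maps, blocks = [], [], [], []
    for name, idx in zip(sets.names, sets.resolved_indices):
        cols = np.asarray(idx, dtype=int)
        Xp = Xn[:, cols]
        try:
            sigma = rff.estimate_sigma(Xp, S=S, rng=rng)
        except ValueError as exc:
            logger.warning("dropping set %s: %s", name, exc)
            continue
        logger.info("set %s: sigma = %.4g (d_p = %d)", name, sigma, len(idx))
        m = rff.sample_map(input_dim=Xp.shape[1], D=D, sigma=sigma, rng=rng)
        names.append(name)
        indices.append(list(idx))
        maps.append(m)
        blocks.append(rff.transform(Xp, m))
    if not names:
        raise ValueError("every feature set degenerated; nothing to fit")
    return names, indices, maps, np.hstack(blocks)


def transform_blocks(Xn, set_indices, maps) -> np.ndarray:
    """Apply stored per-set maps to normalized data and concatenate."""
    blocks = [
        rff.transform(Xn[:, np.asarray(idx, int)], m)
        for idx, m in zip(set_indices, maps)
    ]
    return np.hstack(blocks)


def fit_makl(
    train: ExpressionDataset,
    sets: FeatureSetCollection,
    D: int = 150,
    S: int | None = None,
    lambda_multiplier: float = 0.9,
    rng=None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> MAKLModel:
    """Fit MAKL on a training dataset at a fixed lambda multiplier.

    ``sets`` must be resolved against ``train.gene_names``. ``S`` is the
    row-subset size of the bandwidth heuristic (default min(N, 1000)).
    """
    if train.y is None:
        raise ValueError("training dataset has no labels")
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    means = train.X.mean(axis=0)
    sds = train.X.std(axis=0, ddof=1)
    Xn = _normalize_with(train.X, means, sds)

    names, indices, maps, Z = prepare_blocks(Xn, sets, D=D, S=S, rng=rng)
    structure = group_lasso.GroupStructure.contiguous([2 * D] * len(names))
    gl = group_lasso.fit(
        Z, y, structure,
        lambda_multiplier=lambda_multiplier, tol=tol, max_iter=max_iter,
    )
    return MAKLModel(
        set_names=names,
        set_indices=indices,
        maps=maps,
        gene_names=list(train.gene_names),
        means=means,
        sds=sds,
        gl_model=gl,
        D=D,
        lambda_multiplier=lambda_multiplier,
        structure=structure,
    )


def predict_score(model: MAKLModel, X_new, gene_names) -> np.ndarray:
    """Raw linear scores beta_0 + sum_p Z_p beta_p for new samples.

    ``gene_names`` must cover every training gene; columns are re-ordered
    to the training layout, normalized with the stored training statistics,
    and transformed with the stored frozen maps. Scores are log-odds, so
    they are monotone in predicted probability (AUROC-ready without a
    sigmoid).
    """
    X_new = np.asarray(X_new, dtype=float)
    gene_names = list(gene_names)
    pos = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in model.gene_names if g not in pos]
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"input is missing required genes: {shown}{more}")
    order = [pos[g] for g in model.gene_names]
    Xn = _normalize_with(X_new[:, order], model.means, model.sds)
    Z = transform_blocks(Xn, model.set_indices, model.maps)
    return model.gl_model.intercept + Z @ model.gl_model.coef


def selected_sets(model: MAKLModel) -> list:
    """Names of sets with eta_p > 0, ordered by descending eta_p.

    Zero blocks come out of the prox exactly zero, so no epsilon is needed.
    Ties are broken by block order for determinism.
    """
    etas = model.etas
    order = sorted(
        (p for p in range(model.n_sets) if etas[p] > 0.0),
        key=lambda p: (-etas[p], p),
    )
    return [model.set_names[p] for p in order]


def gene_coverage_fraction(model: MAKLModel, sets: FeatureSetCollection,
                           total_genes: int) -> float:
    """Fraction of the gene universe covered by the selected sets' genes.

    Overlapping sets are unioned, so shared genes count once.
    """
    if total_genes < 1:
        raise ValueError("total_genes must be >= 1")
    chosen = set(selected_sets(model))
    if sets.resolved_indices is None:
        raise ValueError("collection must be resolved")
    covered: set = set()
    for name, idx in zip(sets.names, sets.resolved_indices):
        if name in chosen:
            covered.update(int(i) for i in idx)
    return len(covered) / float(total_genes)


def save_model(model: MAKLModel, path):
    """Persist a fitted model to a single .npz archive (documented schema).

    Arrays: per-set Delta_{i}, offsets_{i}, indices_{i}, block_{i}; plus
    normalization statistics, intercept, metadata and name tables.
    """
    payload = {
        "set_names": np.array(model.set_names, dtype=np.str_),
        "gene_names": np.array(model.gene_names, dtype=np.str_),
        "means": model.means,
        "sds": model.sds,
        "intercept": np.array([model.gl_model.intercept]),
        "lambda": np.array([model.gl_model.lambda_]),
        "lambda_multiplier": np.array([model.lambda_multiplier]),
        "D": np.array([model.D]),
        "sigmas": np.array([m.sigma for m in model.maps]),
        "converged": np.array([int(model.gl_model.converged)]),
        "kkt": np.array([model.gl_model.kkt]),
    }
    for i, (m, idx, block) in enumerate(
        zip(model.maps, model.set_indices, model.gl_model.blocks)
    ):
        payload[f"Delta_{i}"] = m.Delta
        payload[f"offsets_{i}"] = m.offsets
        payload[f"indices_{i}"] = np.asarray(idx, dtype=int)
        payload[f"block_{i}"] = np.asarray(block, dtype=float)
    np.savez_compressed(path, **payload)


def load_model(path) -> MAKLModel:
    """Load a model archive written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        set_names = [str(s) for s in data["set_names"]]
        sigmas = data["sigmas"]
        maps, indices, blocks = [], [], []
        for i in range(len(set_names)):
            maps.append(rff.RFFMap(
                sigma=float(sigmas[i]),
                Delta=data[f"Delta_{i}"],
                offsets=data[f"offsets_{i}"],
            ))
            indices.append([int(j) for j in data[f"indices_{i}"]])
            blocks.append(data[f"block_{i}"])
        D = int(data["D"][0])
        structure = group_lasso.GroupStructure.contiguous(
            [len(b) for b in blocks]
        )
        gl = group_lasso.GroupLassoModel(
            intercept=float(data["intercept"][0]),
            blocks=blocks,
            lambda_=float(data["lambda"][0]),
            lambda_multiplier=float(data["lambda_multiplier"][0]),
            converged=bool(data["converged"][0]),
            kkt=float(data["kkt"][0]),
        )
        return MAKLModel(
            set_names=set_names,
            set_indices=indices,
            maps=maps,
            gene_names=[str(g) for g in data["gene_names"]],
            means=data["means"],
            sds=data["sds"],
            gl_model=gl,
            D=D,
            lambda_multiplier=float(data["lambda_multiplier"][0]),
            structure=structure,
        )
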