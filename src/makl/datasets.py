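"""In-memory container for a labelled expression matrix and CSV loaders.

The expression matrix is dense and real-valued, oriented samples x genes.
Labels are binary (0/1), one per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "load_expression", "load_labels"]


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with sample IDs and binary labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_genes)
        Dense expression values.
    gene_names : list of str
        Column names, unique.
    sample_ids : list of str
        Row identifiers, unique.
    y : ndarray of shape (n_samples,)
        Binary labels in {0, 1}.
    """

    X: np.ndarray
    gene_names: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    y: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples x genes matrix")
        n, d = self.X.shape
        if len(self.gene_names) != d:
            raise ValueError(
                f"gene_names length {len(self.gene_names)} != number of columns {d}"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != number of rows {n}"
            )
        if len(set(self.gene_names)) != d:
            raise ValueError("gene names must be unique")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (n,):
                raise ValueError("y must have one label per sample")
            if not np.isin(self.y, [0, 1]).all():
                raise ValueError("labels must be binary (0/1)")
            self.y = self.y.astype(int)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "ExpressionDataset":
        """Row subset preserving gene names; idx is any integer index array."""
        idx = np.asarray(idx)
        return ExpressionDataset(
            X=self.X[idx],
            gene_names=list(self.gene_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            y=None if self.y is None else self.y[idx],
        )


def load_expression(path, transpose: bool = False) -> ExpressionDataset:
    """Read an expression CSV: header of gene names, first column sample IDs.

    With ``transpose=True`` the file is genes x samples (single-cell export
    convention) and is flipped on read.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    return ExpressionDataset(
        X=df.to_numpy(dtype=float),
        gene_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def load_labels(path) -> pd.Series:
    """Read a two-column CSV (sample_id, label) into a Series indexed by ID."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise ValueError("labels file must have exactly one label column")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return s


def attach_labels(dataset: ExpressionDataset, labels: pd.Series) -> ExpressionDataset:
    """Align a label Series to the dataset's sample IDs and attach it."""
    try:
        y = labels.loc[dataset.sample_ids].to_numpy()
    except KeyError as exc:
        raise ValueError(f"labels missing for some samples: {exc}") from exc
    return ExpressionDataset(
        X=dataset.X,
        gene_names=dataset.gene_names,
        sample_ids=dataset.sample_ids,
        y=y,
    )
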