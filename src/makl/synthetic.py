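"""Synthetic expression data with named gene sets and a radial class signal.

The generator emulates the statistical structure MAKL targets: a dense
real-valued samples x genes matrix whose genes are organized into named
sets, correlated within a set (equicorrelated Gaussian blocks, correlation
``rho``), with a small number of "informative" sets carrying a *nonlinear*
label signal. The signal is radial: each informative set p contributes a
Gaussian bump exp(-||u_p - c_p||^2 / gamma) of the sample's profile u_p
on that set's genes around a fixed random center c_p. Bumps are
standardized (zero mean, unit variance over the cohort) before summing so
every informative set contributes comparably regardless of the realized
center; the summed score is thresholded at its median (forcing
near-balanced classes) and labels are then flipped with probability
``label_noise``.

A radial signal is exactly what a Gaussian-kernel machine can represent
and a linear model cannot, so a plain L1 linear logistic baseline on raw
genes is the natural control. The generator does not attempt sequencing
realism (FPKM marginals, library-size effects); it targets the method's
statistical structure only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .feature_sets import FeatureSetCollection, write_gmt

__all__ = ["SyntheticSpec", "generate", "write_fixture"]

# Center coordinates are drawn N(0, CENTER_SD^2): small, so the signal is
# dominated by its radial (even) component and stays hard for linear models.
CENTER_SD = 0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults define the package's standard fixture: 500 samples x 500
    genes in 20 disjoint sets of 25, 3 informative, within-set correlation
    0.3, 5% label flips.

    ``signal_scale`` sets the sharpness of the radial bumps via
    gamma_p = d_p / signal_scale: larger values narrow the bump and
    strengthen the nonlinear signal.
    ``overlap_fraction`` > 0 makes consecutive sets share that fraction of
    their genes (marginals are then only approximately unit-variance).
    """

    N: int = 500
    d: int = 500
    P: int = 20
    genes_per_set: int = 25
    k_informative: int = 3
    within_set_correlation: float = 0.3
    signal_scale: float = 1.0
    label_noise: float = 0.05
    seed: int = 7
    overlap_fraction: float = 0.0

    def __post_init__(self):
        if self.N < 2 or self.d < 1 or self.P < 1 or self.genes_per_set < 1:
            raise ValueError("N, d, P, genes_per_set must be positive")
        if not 0 <= self.k_informative <= self.P:
            raise ValueError("k_informative must be in [0, P]")
        if not 0.0 <= self.within_set_correlation < 1.0:
            raise ValueError("within_set_correlation must be in [0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.signal_scale <= 0:
            raise ValueError("signal_scale must be positive")
        stride = self._stride()
        span = (self.P - 1) * stride + self.genes_per_set
        if span > self.d:
            raise ValueError(
                f"{self.P} sets of {self.genes_per_set} genes at overlap "
                f"{self.overlap_fraction} need {span} genes, have {self.d}"
            )

    def _stride(self) -> int:
        return max(1, round(self.genes_per_set * (1 - self.overlap_fraction)))


def _set_layout(spec: SyntheticSpec):
    """Column index blocks per set (consecutive, optionally overlapping)."""
    stride = spec._stride()
    return [
        list(range(p * stride, p * stride + spec.genes_per_set))
        for p in range(spec.P)
    ]


def generate(spec: SyntheticSpec):
    """Draw one dataset from the spec.

    Returns (dataset, collection, informative_set_names). Gene names are
    G0001..; set names SET01..; the first ``k_informative`` sets carry the
    signal. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    N, d = spec.N, spec.d
    rho = spec.within_set_correlation
    layout = _set_layout(spec)

    X = rng.standard_normal((N, d))
    for idx in layout:
        g = rng.standard_normal(N)
        cols = np.asarray(idx)
        X[:, cols] = (
            np.sqrt(1.0 - rho) * X[:, cols] + np.sqrt(rho) * g[:, None]
        )

    m = spec.genes_per_set
    gamma = m / spec.signal_scale
    score = np.zeros(N)
    informative = list(range(spec.k_informative))
    for p in informative:
        c = rng.normal(0.0, CENTER_SD, size=m)
        U = X[:, np.asarray(layout[p])]
        bump = np.exp(-((U - c) ** 2).sum(axis=1) / gamma)
        score += (bump - bump.mean()) / bump.std()

    if spec.k_informative > 0:
        y = (score > np.median(score)).astype(int)
    else:
        y = rng.integers(0, 2, size=N)
    # stratified label noise: flip a round(eps * n_c) subset of each class,
    # so the noise rate is eps in both classes and the balance forced by
    # the median threshold survives the flips
    class_members = {cls: np.flatnonzero(y == cls) for cls in (0, 1)}
    for cls, members in class_members.items():
        k = int(round(spec.label_noise * members.size))
        if k > 0:
            flip = rng.choice(members, size=k, replace=False)
            y[flip] = 1 - cls

    gene_width = max(4, len(str(d)))
    gene_names = [f"G{j + 1:0{gene_width}d}" for j in range(d)]
    set_width = max(2, len(str(spec.P)))
    set_names = [f"SET{p + 1:0{set_width}d}" for p in range(spec.P)]
    sample_ids = [f"S{i + 1:04d}" for i in range(N)]

    dataset = ExpressionDataset(
        X=X, gene_names=gene_names, sample_ids=sample_ids, y=y
    )
    collection = FeatureSetCollection(
        names=set_names,
        members=[[gene_names[j] for j in idx] for idx in layout],
    )
    truth = [set_names[p] for p in informative]
    return dataset, collection, truth


def write_fixture(dataset: ExpressionDataset, sets: FeatureSetCollection,
                  out_dir) -> dict:
    """Write expression.csv, labels.csv and sets.gmt under ``out_dir``.

    Floats are printed with 17 significant digits so the CSV round-trips
    float64 exactly; the GMT file round-trips through ``read_gmt``.
    Returns the three paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = out / "expression.csv"
    labels = out / "labels.csv"
    gmt = out / "sets.gmt"

    df = pd.DataFrame(
        dataset.X, index=dataset.sample_ids, columns=dataset.gene_names
    )
    df.index.name = "sample_id"
    df.to_csv(expr, float_format="%.17g")

    if dataset.y is None:
        raise ValueError("dataset has no labels to write")
    pd.DataFrame(
        {"label": dataset.y}, index=pd.Index(dataset.sample_ids,
                                             name="sample_id")
    ).to_csv(labels)

    write_gmt(sets, gmt)
    return {"expression": expr, "labels": labels, "gmt": gmt}
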