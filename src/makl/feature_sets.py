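"""Gene-set collections: GMT parsing and resolution to expression columns.

A collection holds P ordered, uniquely named gene sets F_1..F_P. Before
model fitting each set's gene symbols are resolved to 0-based column
indices of a bound gene-name vector; symbols absent from the expression
matrix are intersected away (case-sensitive exact matching, no alias
translation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = ["FeatureSetCollection", "read_gmt", "resolve", "write_gmt"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureSetCollection:
    """Ordered, named gene sets, optionally resolved against a gene universe.

    Attributes
    ----------
    names : list of str
        Unique set identifiers, in collection order.
    members : list of list of str
        Gene symbols per set (duplicates removed, order preserved).
    resolved_indices : list of list of int, or None
        Per set, column indices into the gene-name vector the collection was
        resolved against; ``None`` until :func:`resolve` is called.
    """

    names: list
    members: list
    resolved_indices: list | None = None
    gene_universe: list | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.names) < 1:
            raise ValueError("no sets: a collection needs at least one gene set")
        if len(set(self.names)) != len(self.names):
            raise ValueError("set names must be unique")
        if len(self.members) != len(self.names):
            raise ValueError("names and members must align")
        if self.resolved_indices is not None:
            if len(self.resolved_indices) != len(self.names):
                raise ValueError("resolved_indices must align with names")
            for name, idx in zip(self.names, self.resolved_indices):
                if len(set(idx)) != len(idx):
                    raise ValueError(f"duplicate resolved index in set {name}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def sizes(self) -> list:
        """Per-set count of resolved genes (member count if unresolved)."""
        if self.resolved_indices is not None:
            return [len(ix) for ix in self.resolved_indices]
        return [len(m) for m in self.members]


def read_gmt(path) -> FeatureSetCollection:
    """Parse a GMT file (MSigDB dialect): name TAB description TAB genes...

    One set per line, order preserved; the description field is discarded and
    duplicate gene symbols within a line are dropped (first occurrence kept).

    Raises
    ------
    ValueError
        On a line with fewer than 3 tab-separated fields (reported with its
        line number), on a duplicate set name, or on an empty file.
    """
    names: list = []
    members: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in names:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            names.append(name)
            members.append(genes)
    if not names:
        raise ValueError(f"no sets found in GMT file {path}")
    return FeatureSetCollection(names=names, members=members)


def write_gmt(collection: FeatureSetCollection, path, description: str = "na"):
    """Write a collection back to GMT (round-trippable by :func:`read_gmt`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in zip(collection.names, collection.members):
            fh.write("\t".join([name, description] + list(genes)) + "\n")


def resolve(
    collection: FeatureSetCollection,
    gene_names,
    min_size: int = 1,
) -> FeatureSetCollection:
    """Bind each set's symbols to column indices of ``gene_names``.

    Members are intersected with ``gene_names`` (exact, case-sensitive);
    sets retaining fewer than ``min_size`` genes are dropped with a logged
    warning. Resolution is idempotent and preserves set and member order.

    Raises
    ------
    ValueError
        If ``gene_names`` is empty or has duplicates, or if every set is
        dropped ("no usable feature sets").
    """
    gene_names = list(gene_names)
    if not gene_names:
        raise ValueError("gene_names must be non-empty")
    pos = {g: i for i, g in enumerate(gene_names)}
    if len(pos) != len(gene_names):
        raise ValueError("gene_names must be unique")

    names, members, indices = [], [], []
    for name, genes in zip(collection.names, collection.members):
        kept = [g for g in genes if g in pos]
        if len(kept) < len(genes):
            logger.info(
                "set %s: %d of %d genes absent from expression matrix",
                name, len(genes) - len(kept), len(genes),
            )
        if len(kept) < min_size:
            logger.warning(
                "dropping set %s: %d resolved genes < min_size %d",
                name, len(kept), min_size,
            )
            continue
        names.append(name)
        members.append(kept)
        indices.append([pos[g] for g in kept])
    if not names:
        raise ValueError("no usable feature sets after resolution")
    return FeatureSetCollection(
        names=names,
        members=members,
        resolved_indices=indices,
        gene_universe=gene_names,
    )
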