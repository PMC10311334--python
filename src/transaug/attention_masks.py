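"""Sparse sets of gene pairs allowed to attend.

Masks come from co-expression correlations, from a PPI edge list, from
the union of both, or from a degree-preserving random relabelling of an
existing mask (the lesion control).  Pairs are stored as a sparse
coordinate set — never as a dense genes-by-genes matrix.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datasets_io import ExpressionDataset

__all__ = [
    "AttentionMask",
    "coexpression_mask",
    "ppi_mask",
    "merge_masks",
    "random_permutation_mask",
    "read_mask",
    "write_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class AttentionMask:
    """Ordered gene-index pairs permitted to exchange attention.

    Self-pairs are never stored (the attention layer always includes the
    self pair implicitly).  ``provenance`` is one of ``coexp``, ``ppi``,
    ``both``, ``random``.
    """

    pairs: set
    n_genes: int
    provenance: str
    source_seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = {(int(i), int(j)) for i, j in self.pairs}
        for i, j in self.pairs:
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise ValueError(f"pair ({i}, {j}) out of range for {self.n_genes} genes")
            if i == j:
                raise ValueError("self-pairs must not be stored in a mask")

    def __len__(self) -> int:
        return len(self.pairs)

    def degree_multiset(self) -> Counter:
        """Multiset of out-degrees over all nodes (zeros excluded)."""
        return Counter(Counter(i for i, _ in self.pairs).values())

    def is_symmetric(self) -> bool:
        return all((j, i) in self.pairs for i, j in self.pairs)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        arr = np.array(sorted(self.pairs), dtype=np.intp)
        return arr[:, 0], arr[:, 1]


def coexpression_mask(
    train: ExpressionDataset,
    threshold: float,
    max_pairs: int | None = None,
) -> AttentionMask:
    """Pairs of genes with |Pearson correlation| >= ``threshold`` on train.

    Constant genes have all their correlations treated as 0 (excluded)
    with a warning.  ``max_pairs`` optionally caps the number of
    undirected pairs, keeping the strongest correlations; the returned
    mask is always symmetric as a pair set.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if train.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    x = train.values
    sd = x.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} constant gene(s): correlations treated as 0",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    iu, ju = np.triu_indices(train.n_genes, k=1)
    strength = np.abs(corr[iu, ju])
    keep = strength >= threshold
    iu, ju, strength = iu[keep], ju[keep], strength[keep]
    if max_pairs is not None and len(iu) > max_pairs:
        top = np.argsort(strength)[::-1][:max_pairs]
        iu, ju = iu[top], ju[top]
    pairs = {(int(i), int(j)) for i, j in zip(iu, ju)}
    pairs |= {(j, i) for i, j in pairs}
    return AttentionMask(pairs, train.n_genes, "coexp", meta={"threshold": threshold})


def ppi_mask(edge_list_path, gene_ids, min_score: float = 0.0) -> AttentionMask:
    """Mask from a protein–protein interaction edge list.

    The TSV has columns ``gene_a``, ``gene_b``, ``score`` (header
    optional).  Edges are kept when both endpoints map to ``gene_ids``
    and ``score >= min_score``; unmapped edges are counted in
    ``mask.meta['n_unmapped']``.
    """
    table = pd.read_csv(edge_list_path, sep="\t", header=None, dtype=str)
    if table.shape[1] < 3:
        raise ValueError("edge list must have columns gene_a, gene_b, score")
    first = str(table.iloc[0, 2])
    try:
        float(first)
    except ValueError:  # header row present
        table = table.iloc[1:]
    index = {g: i for i, g in enumerate(gene_ids)}
    pairs = set()
    n_unmapped = 0
    for a, b, s in table.iloc[:, :3].itertuples(index=False):
        if float(s) < min_score:
            continue
        ia, ib = index.get(str(a)), index.get(str(b))
        if ia is None or ib is None:
            n_unmapped += 1
            continue
        if ia != ib:
            pairs.add((ia, ib))
            pairs.add((ib, ia))
    if not pairs:
        warnings.warn("no mappable PPI edges: mask is empty", UserWarning, stacklevel=2)
    logger.info("ppi_mask: %d ordered pairs, %d unmapped edges", len(pairs), n_unmapped)
    return AttentionMask(
        pairs, len(gene_ids), "ppi", meta={"n_unmapped": n_unmapped, "min_score": min_score}
    )


def merge_masks(a: AttentionMask, b: AttentionMask) -> AttentionMask:
    """Union of two masks over the same gene set (provenance ``both``)."""
    if a.n_genes != b.n_genes:
        raise ValueError(f"gene counts differ: {a.n_genes} vs {b.n_genes}")
    return AttentionMask(a.pairs | b.pairs, a.n_genes, "both")


def random_permutation_mask(
    source: AttentionMask, seed: int = 0, _permutation: np.ndarray | None = None
) -> AttentionMask:
    """Degree-preserving randomization: relabel genes by one permutation.

    Every pair (i, j) maps to (pi(i), pi(j)) under a single uniformly
    random permutation pi, so the pair count and per-node degree multiset
    (the graph-isomorphism class) are preserved exactly.
    ``_permutation`` is a test hook forcing a specific permutation.
    """
    if not source.pairs:
        raise ValueError("source mask is empty")
    if _permutation is not None:
        pi = np.asarray(_permutation, dtype=np.intp)
    else:
        pi = np.random.default_rng(seed).permutation(source.n_genes)
    pairs = {(int(pi[i]), int(pi[j])) for i, j in source.pairs}
    return AttentionMask(pairs, source.n_genes, "random", source_seed=seed)


def write_mask(mask: AttentionMask, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_genes={mask.n_genes} provenance={mask.provenance}\n")
        for i, j in sorted(mask.pairs):
            fh.write(f"{i}\t{j}\n")


def read_mask(path) -> AttentionMask:
    pairs = set()
    n_genes, provenance = None, "coexp"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n_genes="):
                        n_genes = int(tok.split("=", 1)[1])
                    elif tok.startswith("provenance="):
                        provenance = tok.split("=", 1)[1]
                continue
            i, j = line.split("\t")
            pairs.add((int(i), int(j)))
    if n_genes is None:
        n_genes = 1 + max((max(i, j) for i, j in pairs), default=-1)
    return AttentionMask(pairs, n_genes, provenance)
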