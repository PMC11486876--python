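"""Correlation structure of the gene panel and clustering of genes and samples.

Three views of the signature panel:

* pairwise Pearson correlation of genes across samples;
* agglomerative clustering of genes with distance = 1 - cosine similarity
  (average linkage), exported as a dendrogram / Newick string;
* fuzzy c-means partitioning of samples on the panel (genes z-scored first so
  high-variance genes do not dominate), giving soft memberships that sum to 1
  per sample plus the argmax hard label.

The fuzzy c-means solver is the standard Bezdek alternating-optimization
algorithm with fuzzifier m (default 2.0), random membership initialization
from a seed, and convergence when the largest membership change falls below
1e-6 (or 300 iterations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "FuzzyPartition",
    "gene_correlation",
    "cluster_genes_cosine",
    "dendrogram_to_newick",
    "fuzzy_cluster_samples",
    "match_labels",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Symmetric Pearson correlation matrix; constant genes give NaN (flagged)."""

    gene_ids: list[str]
    r: np.ndarray
    n: int
    constant_genes: list[str]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.gene_ids):
            for j, b in enumerate(self.gene_ids):
                if j > i:
                    rows.append(dict(gene_a=a, gene_b=b, r=self.r[i, j], n=self.n))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FuzzyPartition:
    sample_ids: list[str]
    membership: np.ndarray  # samples x c, rows sum to 1
    hard_label: np.ndarray  # argmax cluster, 1-based
    n_iter: int
    objective: float


def gene_correlation(
    m: ExpressionMatrix, panel: Sequence[str]
) -> CorrelationResult:
    """Pairwise Pearson correlation of panel genes across samples.

    A constant gene's correlations are undefined and reported as NaN (the
    gene is listed in ``constant_genes``), never coerced to 0.
    """
    sub = m.subset_genes(list(panel))
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    X = sub.values
    sd = X.std(axis=1, ddof=1)
    constant = [g for g, s in zip(sub.gene_ids, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    for i, s in enumerate(sd):  # constant genes: undefined, keep NaN off-diagonal
        if s == 0:
            r[i, :] = np.nan
            r[:, i] = np.nan
            r[i, i] = 1.0
    r = (r + r.T) / 2  # enforce exact symmetry against float noise
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationResult(
        gene_ids=sub.gene_ids, r=r, n=sub.shape[1], constant_genes=constant
    )


def cluster_genes_cosine(
    m: ExpressionMatrix, panel: Sequence[str]
) -> np.ndarray:
    """Average-linkage agglomerative clustering of genes by cosine distance.

    Distance between two genes is 1 - cosine similarity of their expression
    vectors across samples.  Returns a scipy linkage matrix (deterministic
    ordering).  A zero-norm gene vector is an error.
    """
    sub = m.subset_genes(list(panel))
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 panel genes to cluster")
    X = sub.values
    norms = np.linalg.norm(X, axis=1)
    zero = [g for g, nv in zip(sub.gene_ids, norms) if nv == 0]
    if zero:
        raise ValueError(f"zero-norm gene expression vectors: {zero}")
    d = pdist(X, metric="cosine")
    d = np.clip(d, 0.0, None)  # float noise can give tiny negatives
    return hierarchy.linkage(d, method="average")


def dendrogram_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def fuzzy_cluster_samples(
    m: ExpressionMatrix,
    panel: Sequence[str],
    c: int = 2,
    fuzzifier: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FuzzyPartition:
    """Fuzzy c-means partition of samples on the (z-scored) panel genes.

    Memberships are initialized uniformly at random from ``seed``, then
    centroids and memberships alternate until the maximum membership change
    is below ``tol`` or ``max_iter`` sweeps.  Hard labels (1-based) are the
    argmax memberships.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    sub = m.subset_genes(list(panel))
    n = sub.shape[1]
    if n < c:
        raise ValueError(f"need at least {c} samples")
    X = sub.values.T  # samples x genes
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    U = rng.random((n, c))
    U /= U.sum(axis=1, keepdims=True)
    expo = 2.0 / (fuzzifier - 1.0)
    objective = np.inf
    for it in range(1, max_iter + 1):
        W = U**fuzzifier
        centroids = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-expo / 2.0)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        change = np.abs(U_new - U).max()
        U = U_new
        objective = float((U**fuzzifier * d2).sum())
        if change < tol:
            break
    hard = U.argmax(axis=1) + 1
    return FuzzyPartition(
        sample_ids=sub.sample_ids,
        membership=U,
        hard_label=hard,
        n_iter=it,
        objective=objective,
    )


def match_labels(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute cluster labels to maximize overlap with a reference labeling.

    Uses the Hungarian assignment on the contingency table, so agreement
    statistics are invariant to arbitrary cluster numbering.
    """
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    la, ra = np.unique(labels), np.unique(reference)
    cont = np.zeros((len(la), len(ra)))
    for i, l in enumerate(la):
        for j, r in enumerate(ra):
            cont[i, j] = np.sum((labels == l) & (reference == r))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {la[i]: ra[j] for i, j in zip(rows, cols)}
    return np.array([mapping.get(l, l) for l in labels])
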