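"""Organ-system tissue-similarity analysis on active-reaction vectors.

Tissues are compared by the Euclidean distance between their binary
active-reaction vectors (for binary vectors this is the square root of the
Hamming distance).  For each organ-system group with at least three member
tissues, the observed mean within-group pairwise distance is compared with
the mean distances of randomly drawn tissue groups of the same size; the
permutation p-value is the proportion of random means *strictly* lower than
the observed one — so tight, biologically coherent groups get small p.
A classical principal-coordinates embedding is provided for visualization.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "pairwise_distances",
    "group_mean_distance",
    "permutation_pvalue",
    "GroupingResult",
    "pcoa",
]


def pairwise_distances(vectors: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between sample rows.

    ``vectors`` is sample x reaction; columns containing NaN (no-data
    reactions) are dropped before computing distances so every pair is
    compared on the same coordinates.
    """
    clean = vectors.dropna(axis=1, how="any")
    d = squareform(pdist(clean.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=vectors.index, columns=vectors.index)


def group_mean_distance(dist: pd.DataFrame, members: Sequence[str]) -> float:
    """Mean pairwise distance within a group of >= 3 samples.

    Groups of fewer than three tissues are rejected: a two-member "group
    mean" is a single pairwise distance and is excluded from the analysis.
    """
    members = list(members)
    if len(members) < 3:
        raise ValueError(
            f"group needs > 2 members (got {len(members)}); smaller organ "
            "systems are excluded from the similarity analysis"
        )
    sub = dist.loc[members, members].to_numpy(dtype=float)
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


@dataclass
class GroupingResult:
    group: str
    observed: float
    pvalue: float
    n_perm: int
    seed: int | None


def permutation_pvalue(
    dist: pd.DataFrame,
    members: Sequence[str],
    n_perm: int = 10000,
    seed: int | None = None,
    group: str = "",
    estimator: str = "strict",
) -> GroupingResult:
    """Permutation p-value for the within-group mean distance.

    Random groups of the same size are drawn uniformly without replacement
    from all samples (the observed group may recur).  ``estimator="strict"``
    uses p = #(random mean < observed) / n_perm, which can be exactly 0;
    ``"plus-one"`` uses the (r+1)/(n+1) variant that never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = list(members)
    observed = group_mean_distance(dist, members)
    n = dist.shape[0]
    if len(members) > n:
        raise ValueError("group larger than the number of samples")
    m = len(members)
    rng = np.random.default_rng(seed)
    d = dist.to_numpy(dtype=float)
    iu = np.triu_indices(m, k=1)
    lower = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        sub = d[np.ix_(idx, idx)]
        if sub[iu].mean() < observed:
            lower += 1
    if estimator == "strict":
        p = lower / n_perm
    elif estimator == "plus-one":
        p = (lower + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return GroupingResult(group=group, observed=observed, pvalue=p, n_perm=n_perm, seed=seed)


def pcoa(dist: pd.DataFrame, n_components: int = 2, tol: float = 1e-8):
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix
    and returns the top coordinates (sample x axis DataFrame), all
    eigenvalues in decreasing order, and the total magnitude of negative
    eigenvalues beyond tolerance (0 for a Euclidean-embeddable matrix) —
    reported, never silently clipped.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(1.0, float(abs(eigvals).max()))
    negative = float(-eigvals[eigvals < -tol * scale].sum())
    coords = np.zeros((n, n_components))
    for k in range(min(n_components, n)):
        if eigvals[k] > tol * scale:
            coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
    frame = pd.DataFrame(
        coords, index=dist.index, columns=[f"Axis{i + 1}" for i in range(n_components)]
    )
    return frame, eigvals, negative
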