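"""Which preprocessing decisions drive active-set variation?

The binary (config, tissue) x reaction table is filtered (no-data columns
and columns constant across all rows removed), each *row* centered to zero
mean, and decomposed by SVD.  Row centering is unusual for PCA but is the
documented procedure for this analysis; conventional column centering is
available as an option for sensitivity checks.

Per component, each decision factor (gene mapping, order, thresholding
approach, scheme, tissue) is attributed a share of the component: categories
are coded as integers 1..k, the Pearson correlation R between component
scores and codes is maximized over category orderings (exhaustively for
k <= 6, by the mean-score ordering heuristic above — which attains the
maximum for balanced designs), and 100*R^2 is reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "run_pca", "factor_attribution"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows x components (PC1, PC2, ...)
    explained: np.ndarray  # variance fraction per component, non-increasing
    removed: list[str]  # constant (all-active or never-active) columns


def run_pca(table: pd.DataFrame, center: str = "row") -> PCAResult:
    """SVD of the filtered, centered binary activity table.

    ``center`` is ``"row"`` (the documented procedure) or ``"column"``
    (conventional PCA) for sensitivity analysis.
    """
    data = table.dropna(axis=1, how="any")
    values = data.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    removed = list(data.columns[constant])
    values = values[:, ~constant]
    if values.shape[1] == 0:
        raise ValueError("no variation: all columns constant")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 rows after filtering")
    if center == "row":
        centered = values - values.mean(axis=1, keepdims=True)
    elif center == "column":
        centered = values - values.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown centering {center!r}")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("no variation after centering")
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=cols),
        explained=var / total,
        removed=removed,
    )


def _max_correlation(scores: np.ndarray, labels: pd.Series) -> float:
    """Max |Pearson R| between scores and integer-coded categories over
    category orderings (exhaustive for k <= 6, mean-score ordering above)."""
    cats = list(pd.unique(labels))
    k = len(cats)
    if k < 2:
        return 0.0
    codes_of = {c: i for i, c in enumerate(cats)}
    base = np.array([codes_of[v] for v in labels], dtype=int)
    if k <= 6:
        orderings = permutations(range(k))
    else:
        means = [scores[base == i].mean() for i in range(k)]
        rank = np.argsort(np.argsort(means))
        orderings = [tuple(rank)]
        logger.info("factor with %d categories: mean-score ordering heuristic", k)
    best = 0.0
    sc = scores - scores.mean()
    sc_norm = np.linalg.norm(sc)
    if sc_norm == 0:
        return 0.0
    for perm in orderings:
        coded = np.asarray(perm, dtype=float)[base]
        coded = coded - coded.mean()
        denom = np.linalg.norm(coded) * sc_norm
        if denom == 0:
            continue
        r = abs(float(sc @ coded) / denom)
        best = max(best, r)
    return best


def factor_attribution(
    pca: PCAResult, factors: pd.DataFrame, n_components: int = 3
) -> pd.DataFrame:
    """Percentage of each leading component attributed to each factor.

    ``factors`` carries one categorical column per factor, aligned with the
    score rows.  Entries are 100*R^2 with R the ordering-maximized Pearson
    correlation; a single-category factor gets 0 with a warning.
    """
    if not factors.index.equals(pca.scores.index):
        factors = factors.loc[pca.scores.index]
    n_components = min(n_components, pca.scores.shape[1])
    out = pd.DataFrame(
        index=[f"PC{i + 1}" for i in range(n_components)],
        columns=list(factors.columns),
        dtype=float,
    )
    for name in factors.columns:
        labels = factors[name]
        if labels.nunique() < 2:
            logger.warning("factor %r has a single category; attribution 0", name)
            out[name] = 0.0
            continue
        for i in range(n_components):
            r = _max_correlation(pca.scores.iloc[:, i].to_numpy(), labels)
            out.loc[f"PC{i + 1}", name] = 100.0 * r**2
    return out
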