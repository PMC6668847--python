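"""Pathway enrichment, predicted ubiquity, clustering, and false negatives.

For one thresholding method and one tissue, a pathway (network subsystem)
is enriched when the overlap between its reactions and the tissue's active
set is improbably large under sampling without replacement: with population
M (gene-associated reactions with data), pathway size K, active set size N
and overlap x, the upper-tail hypergeometric probability P(X >= x) is
compared to alpha (default 0.05, uncorrected — a Benjamini-Hochberg option
exists but is off by default).

Stacking the binary enrichment matrices E (pathway x tissue, one per
thresholding method) gives the predicted ubiquity matrix U: U[i, k] is the
number of tissues where pathway i is enriched under method k.  Pathways are
clustered on their U rows (complete linkage, Euclidean, cut at 5 clusters)
and each method's calls are scored against a curated list of known
pathway–tissue pairs by counting false negatives — known pairs the method
fails to enrich.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_pvalue",
    "enrichment_matrix",
    "ubiquity",
    "cluster_pathways",
    "load_known_pairs",
    "false_negatives",
]

CATEGORIES = ("tissue-specific", "group-specific", "ubiquitous")


def hypergeom_pvalue(M: int, K: int, N: int, x: int) -> float:
    """Upper tail P(X >= x), X ~ Hypergeom(population M, successes K, draws N)."""
    if not (0 <= K <= M and 0 <= N <= M and 0 <= x):
        raise ValueError("require 0 <= K, N <= M and x >= 0")
    return float(hypergeom.sf(x - 1, M, K, N))


def enrichment_matrix(
    calls: pd.DataFrame,
    pathway_map: dict[str, str] | pd.Series,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Binary pathway x tissue enrichment matrix E for one method's calls.

    ``calls`` is a binary reaction x sample table (NaN = no data).  The
    hypergeometric population is the set of reactions with data; pathways
    without any such reaction are skipped (and reported).  ``correction``
    may be ``"bh"`` for Benjamini-Hochberg across the pathways of a tissue.
    """
    pmap = pd.Series(pathway_map)
    with_data = calls.dropna(axis=0, how="any")
    population = [r for r in with_data.index if pmap.get(r, "") != ""]
    M = len(population)
    pmap = pmap.loc[population]
    pathways = sorted(pmap.unique())
    skipped = sorted(set(pd.Series(pathway_map).unique()) - set(pathways) - {""})
    if skipped:
        logger.info("pathways without observable reactions skipped: %s", skipped)
    data = with_data.loc[population]
    e = pd.DataFrame(0, index=pathways, columns=calls.columns, dtype=int)
    for tissue in calls.columns:
        active = data[tissue] > 0
        N = int(active.sum())
        if N == 0:
            continue
        pvals = {}
        for pw in pathways:
            in_pw = pmap == pw
            K = int(in_pw.sum())
            x = int((active & in_pw).sum())
            pvals[pw] = hypergeom_pvalue(M, K, N, x)
        pser = pd.Series(pvals)
        if correction == "bh":
            pser = _benjamini_hochberg(pser)
        elif correction is not None:
            raise ValueError(f"unknown correction {correction!r}")
        e[tissue] = (pser < alpha).astype(int).loc[pathways]
    return e


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    order = np.argsort(p.to_numpy())
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank
        running = min(running, p.iloc[idx] * m / i)
        adj[idx] = running
    return pd.Series(adj, index=p.index)


def ubiquity(methods: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Predicted ubiquity matrix U: pathway x method tissue counts.

    Each method's enrichment matrix is summed along the tissue dimension;
    all matrices must share pathway and tissue indices.
    """
    names = list(methods)
    first = methods[names[0]]
    for name in names[1:]:
        e = methods[name]
        if not (e.index.equals(first.index) and e.columns.equals(first.columns)):
            raise ValueError(f"enrichment matrix {name!r} has mismatched indices")
    return pd.DataFrame({name: methods[name].sum(axis=1) for name in names})


def cluster_pathways(u: pd.DataFrame, k: int = 5) -> pd.Series:
    """Cut a complete-linkage Euclidean dendrogram of U rows into k clusters.

    Deterministic: on equal merge heights the lowest-index pair merges
    first.  Cluster labels are integers 1..k.
    """
    if k > u.shape[0]:
        raise ValueError(f"cannot form {k} clusters from {u.shape[0]} pathways")
    z = linkage(u.to_numpy(dtype=float), method="complete", metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=u.index, name="cluster")


def load_known_pairs(path: str | Path) -> pd.DataFrame:
    """Load a curated pathway–tissue pair table (TSV).

    Requires ``pathway`` and ``tissue`` columns; any extra columns (e.g.
    ``category``, ``reference``) pass through.  Duplicate pairs are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("pathway", "tissue"):
        if col not in df.columns:
            raise ValueError(f"known-pairs table lacks column {col!r}")
    if df.duplicated(["pathway", "tissue"]).any():
        dup = df[df.duplicated(["pathway", "tissue"])].iloc[0]
        raise ValueError(f"duplicate pair ({dup['pathway']!r}, {dup['tissue']!r})")
    return df


def known_pair_categories(known: pd.DataFrame) -> pd.Series:
    """Per-pathway ubiquity category from pair counts: 1–2 tissues =
    tissue-specific, 3–10 = group-specific, more = ubiquitous."""
    counts = known.groupby("pathway")["tissue"].nunique()
    return counts.map(
        lambda c: "tissue-specific" if c <= 2 else ("group-specific" if c <= 10 else "ubiquitous")
    )


def false_negatives(
    methods: dict[str, pd.DataFrame],
    known: pd.DataFrame,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """False-negative counts per method, overall and grouped.

    A known pair (pathway, tissue) is a false negative for a method when its
    enrichment matrix has a 0 there.  Pairs referencing pathways or tissues
    absent from the matrices are reported and excluded.  Returns a tidy
    frame with one row per (method, pair) and helper aggregations via
    ``groupby``; columns: method, pathway, tissue, fn, cluster (if given).
    """
    first = methods[next(iter(methods))]
    valid = known[
        known["pathway"].isin(first.index) & known["tissue"].isin(first.columns)
    ]
    dropped = len(known) - len(valid)
    if dropped:
        logger.warning("%d known pairs reference unknown pathway/tissue ids", dropped)
    rows = []
    for name, e in methods.items():
        for _, pair in valid.iterrows():
            fn = int(e.loc[pair["pathway"], pair["tissue"]] == 0)
            row = {
                "method": name,
                "pathway": pair["pathway"],
                "tissue": pair["tissue"],
                "fn": fn,
            }
            if clusters is not None:
                row["cluster"] = clusters.get(pair["pathway"])
            rows.append(row)
    return pd.DataFrame(rows)


def fn_summary(fn_table: pd.DataFrame, by: str = "cluster") -> pd.DataFrame:
    """Pivot of false-negative counts: rows ``by`` group, columns method."""
    return fn_table.pivot_table(index=by, columns="method", values="fn", aggfunc="sum")
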