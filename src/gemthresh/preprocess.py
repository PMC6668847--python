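"""Orchestrate the preprocessing decision space.

Three decisions are crossed: gene mapping (GM1/GM2), thresholding scheme
(global50, global75, local25, local25-75, local25-90) and the order of the
two steps — Order 1 maps expression onto reactions first and thresholds the
resulting reaction expression, Order 2 thresholds gene expression first and
maps the thresholded values.  2 x 2 x 5 = 20 combinations.

Under Order 1 the local threshold must live at the reaction level.  With GM1
a reaction's expression is a single dominating gene value per sample, so the
gene rule transfers: t_r = clamp(mean over samples of reaction expression).
With GM2 several isoenzyme genes contribute, so the threshold is the sum of
clamped mean contributions: t_r = sum over top-level OR alternatives of
clamp(mean over samples of that alternative's mapped value); a rule without
a top-level OR is treated as a single alternative.  Global schemes always
threshold against the pooled *gene*-expression percentile bound, under both
orders.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpr_eval import GM1, GM2, _evaluate_rule_matrix, map_expression_to_reactions
from .model_io import OR, ExpressionMatrix, MetabolicNetwork
from .thresholding import (
    GLOBAL,
    PRESETS,
    ThresholdScheme,
    apply_thresholds,
    percentile_bounds,
    scheme_thresholds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "enumerate_configs",
    "run_order1",
    "run_order2",
    "run_config",
    "run_all",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """One combination of (gene mapping, step order, thresholding scheme)."""

    gene_mapping: str  # GM1 | GM2
    order: int  # 1: map then threshold; 2: threshold then map
    scheme: ThresholdScheme

    def __post_init__(self) -> None:
        if self.gene_mapping not in (GM1, GM2):
            raise ValueError(f"unknown gene mapping {self.gene_mapping!r}")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")

    @property
    def name(self) -> str:
        return f"{self.gene_mapping}-O{self.order}-{self.scheme.name}"


_SCHEME_ORDER = ["global50", "global75", "local25", "local25-75", "local25-90"]


def enumerate_configs() -> list[PreprocessConfig]:
    """All 20 decision combinations, in canonical (GM, order, scheme) order."""
    return [
        PreprocessConfig(gm, order, PRESETS[s])
        for gm in (GM1, GM2)
        for order in (1, 2)
        for s in _SCHEME_ORDER
    ]


def _binarize(activity: pd.DataFrame) -> pd.DataFrame:
    """activity value -> {0,1}; NaN (no data) preserved."""
    vals = activity.to_numpy(dtype=float)
    out = (vals > 0).astype(float)
    out[np.isnan(vals)] = np.nan
    return pd.DataFrame(out, index=activity.index, columns=activity.columns)


def run_order2(
    network: MetabolicNetwork,
    expr: ExpressionMatrix,
    gene_mapping: str,
    scheme: ThresholdScheme,
) -> pd.DataFrame:
    """Threshold gene expression, then map through GPRs.

    Returns the reaction x sample *activity* table (thresholded gene values
    pushed through the rules); a reaction is active where its value is > 0.
    """
    tset = scheme_thresholds(expr, scheme)
    gene_activity = apply_thresholds(expr.data, tset)
    thresholded = ExpressionMatrix(gene_activity)
    return map_expression_to_reactions(network, thresholded, gene_mapping)


def _or_alternatives(rule):
    return rule.children if rule.kind == OR else (rule,)


def _order1_thresholds(
    network: MetabolicNetwork,
    expr: ExpressionMatrix,
    reaction_expr: pd.DataFrame,
    gene_mapping: str,
    scheme: ThresholdScheme,
) -> pd.Series:
    """Per-reaction activity thresholds for the map-then-threshold order."""
    if scheme.approach == GLOBAL:
        (bound,) = percentile_bounds(expr, [scheme.p_low])
        return pd.Series(float(bound), index=reaction_expr.index)

    ps = [scheme.p_low] + ([scheme.p_up] if scheme.is_t2 else [])
    bounds = percentile_bounds(expr, ps)
    lower = float(bounds[0])
    upper = float(bounds[1]) if scheme.is_t2 else np.inf

    if gene_mapping == GM1:
        means = reaction_expr.mean(axis=1)  # NaN rows stay NaN
        return means.clip(lower=lower, upper=upper)

    # GM2: sum of clamped mean contributions of the OR alternatives.
    out = {}
    for rxn in network.reactions:
        if rxn.gpr is None:
            out[rxn.id] = np.nan
            continue
        total, any_data = 0.0, False
        for child in _or_alternatives(rxn.gpr):
            vals = _evaluate_rule_matrix(child, expr.data, GM2)
            if np.isnan(vals).all():
                continue
            any_data = True
            total += float(np.clip(np.nanmean(vals), lower, upper))
        out[rxn.id] = total if any_data else np.nan
    return pd.Series(out).loc[reaction_expr.index]


def run_order1(
    network: MetabolicNetwork,
    expr: ExpressionMatrix,
    gene_mapping: str,
    scheme: ThresholdScheme,
) -> pd.DataFrame:
    """Map expression onto reactions, then threshold reaction expression."""
    reaction_expr = map_expression_to_reactions(network, expr, gene_mapping)
    t = _order1_thresholds(network, expr, reaction_expr, gene_mapping, scheme)
    vals = reaction_expr.to_numpy(dtype=float)
    tarr = t.to_numpy(dtype=float)[:, None]
    out = np.where(vals >= tarr, vals, 0.0)
    out[np.isnan(vals)] = np.nan
    return pd.DataFrame(out, index=reaction_expr.index, columns=reaction_expr.columns)


def run_config(
    network: MetabolicNetwork, expr: ExpressionMatrix, config: PreprocessConfig
) -> pd.DataFrame:
    """Binary active-reaction calls (reaction x sample) for one configuration."""
    runner = run_order1 if config.order == 1 else run_order2
    activity = runner(network, expr, config.gene_mapping, config.scheme)
    return _binarize(activity)


def run_all(
    network: MetabolicNetwork,
    expr: ExpressionMatrix,
    configs: list[PreprocessConfig] | None = None,
) -> pd.DataFrame:
    """Binary activity table over every configuration and sample.

    Rows are a (config, sample) MultiIndex, columns the gene-associated
    reactions; entries are 1 (active), 0 (inactive) or NaN (no data —
    identical across configurations, since it depends only on data
    coverage).  Per-row active-set sizes are logged.
    """
    if configs is None:
        configs = enumerate_configs()
    gene_assoc = [r.id for r in network.gene_associated()]
    blocks = []
    for cfg in configs:
        calls = run_config(network, expr, cfg).loc[gene_assoc]
        block = calls.T  # samples x reactions
        block.index = pd.MultiIndex.from_product(
            [[cfg.name], block.index], names=["config", "sample"]
        )
        blocks.append(block)
        for sample, row in block.iterrows():
            logger.info("active set %s/%s: %d", cfg.name, sample[1], int(row.sum()))
    return pd.concat(blocks, axis=0)


def active_set_sizes(table: pd.DataFrame) -> pd.Series:
    """Number of active reactions per (config, sample) row."""
    return table.sum(axis=1, skipna=True).astype(int)


def factor_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Decompose a run_all row index into decision factors.

    Returns per-row labels for gene_mapping, order, scheme_approach,
    scheme, and tissue — the factors whose influence the decision analysis
    attributes.
    """
    rows = []
    for config_name, sample in table.index:
        gm, order, scheme = config_name.split("-", 2)
        rows.append(
            {
                "gene_mapping": gm,
                "order": order,
                "scheme_approach": "global" if scheme.startswith("global") else "local",
                "scheme": scheme,
                "tissue": sample,
            }
        )
    return pd.DataFrame(rows, index=table.index)
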