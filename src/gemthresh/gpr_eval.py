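"""Evaluate GPR rules against gene values and classify GPR structure.

Two gene-mapping conventions are supported:

* **GM1** — enzyme complexes (AND) take the minimum over subunit genes,
  isoenzymes (OR) the maximum over alternatives: one isoenzyme dominates.
* **GM2** — AND is again the minimum, but OR *sums* the alternatives, so the
  reaction sees the total capacity of all its isoenzymes.

Unmeasured genes are never imputed: a missing child is dropped from an OR
aggregation, while an AND with any missing subunit is itself missing (a
complex with an unmeasured subunit has unknown abundance).  A rule that is
missing everywhere yields "no data" for its reaction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model_io import AND, GENE, OR, ExpressionMatrix, GPRRule, MetabolicNetwork

__all__ = [
    "GM1",
    "GM2",
    "evaluate_gpr",
    "determinant_genes",
    "map_expression_to_reactions",
    "classify_gpr_patterns",
    "GPRPatterns",
]

GM1 = "GM1"
GM2 = "GM2"


def _check_method(method: str) -> None:
    if method not in (GM1, GM2):
        raise ValueError(f"unknown gene-mapping method {method!r}")


def evaluate_gpr(
    rule: GPRRule, values: Mapping[str, float | None], method: str
) -> float | None:
    """Evaluate a rule against a gene -> value map; ``None`` means missing.

    Returns the mapped reaction value, or ``None`` if the rule is missing
    (any missing AND child, or all OR children missing).
    """
    _check_method(method)
    if rule.kind == GENE:
        v = values.get(rule.gene)  # type: ignore[arg-type]
        if v is not None and v < 0:
            raise ValueError(f"negative value for gene {rule.gene!r}")
        return v
    results = [evaluate_gpr(c, values, method) for c in rule.children]
    if rule.kind == AND:
        if any(r is None for r in results):
            return None
        return min(results)  # type: ignore[type-var]
    present = [r for r in results if r is not None]
    if not present:
        return None
    return max(present) if method == GM1 else sum(present)


def determinant_genes(
    rule: GPRRule, values: Mapping[str, float | None], method: str
) -> set[str]:
    """Genes whose values arithmetically determine ``evaluate_gpr``'s result.

    AND contributes the leaf-set of its minimal child(ren); OR under GM1 the
    maximal child(ren); OR under GM2 every non-missing child (all summands
    matter).  Ties keep all tied branches.  A missing rule yields the empty
    set.
    """
    _check_method(method)
    value, dets = _eval_with_determinants(rule, values, method)
    return dets if value is not None else set()


def _eval_with_determinants(
    rule: GPRRule, values: Mapping[str, float | None], method: str
) -> tuple[float | None, set[str]]:
    if rule.kind == GENE:
        v = values.get(rule.gene)  # type: ignore[arg-type]
        return (v, {rule.gene} if v is not None else set())  # type: ignore[arg-type]
    results = [_eval_with_determinants(c, values, method) for c in rule.children]
    if rule.kind == AND:
        if any(v is None for v, _ in results):
            return None, set()
        best = min(v for v, _ in results)  # type: ignore[type-var]
        dets: set[str] = set()
        for v, d in results:
            if v == best:
                dets |= d
        return best, dets
    present = [(v, d) for v, d in results if v is not None]
    if not present:
        return None, set()
    if method == GM1:
        best = max(v for v, _ in present)
        dets = set()
        for v, d in present:
            if v == best:
                dets |= d
        return best, dets
    total = sum(v for v, _ in present)
    dets = set()
    for _, d in present:
        dets |= d
    return total, dets


# ---------------------------------------------------------------------------
# Vectorized mapping over a whole expression matrix
# ---------------------------------------------------------------------------


def _evaluate_rule_matrix(rule: GPRRule, expr: pd.DataFrame, method: str) -> np.ndarray:
    """Evaluate one rule across all samples at once; NaN marks missing."""
    n = expr.shape[1]
    if rule.kind == GENE:
        if rule.gene in expr.index:
            return expr.loc[rule.gene].to_numpy(dtype=float)
        return np.full(n, np.nan)
    stacked = np.vstack(
        [_evaluate_rule_matrix(c, expr, method) for c in rule.children]
    )
    if rule.kind == AND:
        return stacked.min(axis=0)  # NaN propagates: missing subunit kills complex
    mask = np.isnan(stacked)
    all_missing = mask.all(axis=0)
    if method == GM1:
        with np.errstate(all="ignore"):
            out = np.nanmax(stacked, axis=0)
    else:
        out = np.where(mask, 0.0, stacked).sum(axis=0)
    out = np.asarray(out, dtype=float)
    out[all_missing] = np.nan
    return out


def map_expression_to_reactions(
    network: MetabolicNetwork, expr: ExpressionMatrix, method: str
) -> pd.DataFrame:
    """Reaction x sample mapped-expression table.

    Rows cover every reaction; reactions without a rule, or whose rule is
    missing in the data, carry NaN ("no data") and are excluded from
    active/inactive calls downstream.
    """
    _check_method(method)
    df = expr.data
    rows = {}
    for rxn in network.reactions:
        if rxn.gpr is None:
            rows[rxn.id] = np.full(df.shape[1], np.nan)
        else:
            rows[rxn.id] = _evaluate_rule_matrix(rxn.gpr, df, method)
    return pd.DataFrame.from_dict(rows, orient="index", columns=df.columns).loc[
        network.reaction_ids
    ]


# ---------------------------------------------------------------------------
# Structural GPR patterns
# ---------------------------------------------------------------------------

NO_RULE = "no-rule"
SPECIALIST = "specialist"
PROMISCUOUS = "promiscuous"
ISOENZYMATIC = "isoenzymatic"
MULTIMERIC = "multimeric"
ISOENZYMATIC_MULTIMERIC = "isoenzymatic-multimeric"


@dataclass
class GPRPatterns:
    """Per-reaction structural labels and per-gene promiscuity counts."""

    labels: dict[str, str] = field(default_factory=dict)
    promiscuity: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def classify_gpr_patterns(network: MetabolicNetwork) -> GPRPatterns:
    """Label each reaction's GPR shape and count gene promiscuity.

    Single-leaf rules split by promiscuity of the gene: ``specialist`` when
    the gene occurs in exactly one reaction, ``promiscuous`` otherwise.
    ``multimeric`` rules contain AND but no OR, ``isoenzymatic`` OR but no
    AND, ``isoenzymatic-multimeric`` both.
    """
    promiscuity: dict[str, int] = {}
    for rxn in network.reactions:
        if rxn.gpr is None:
            continue
        for g in rxn.gpr.genes():
            promiscuity[g] = promiscuity.get(g, 0) + 1
    labels: dict[str, str] = {}
    for rxn in network.reactions:
        rule = rxn.gpr
        if rule is None:
            labels[rxn.id] = NO_RULE
        elif rule.kind == GENE:
            labels[rxn.id] = (
                SPECIALIST if promiscuity[rule.gene] == 1 else PROMISCUOUS
            )
        else:
            has_and, has_or = rule.contains_and(), rule.contains_or()
            if has_and and has_or:
                labels[rxn.id] = ISOENZYMATIC_MULTIMERIC
            elif has_and:
                labels[rxn.id] = MULTIMERIC
            else:
                labels[rxn.id] = ISOENZYMATIC
    return GPRPatterns(labels=labels, promiscuity=promiscuity)
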