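"""Metabolic-network and expression-matrix containers and their readers/writers.

A genome-scale metabolic network associates each reaction with an optional
gene-protein-reaction (GPR) boolean rule — AND for the subunits of an enzyme
complex, OR for isoenzymes — and a subsystem (pathway) label.  Expression data
is a non-negative gene x sample matrix in FPKM-like units.

The GPR grammar here is deliberately strict: AND and OR are n-ary, and mixing
the two operators at one parenthesis level without explicit grouping is a
syntax error rather than a silent precedence choice.  Recon-style rules are
fully parenthesized, so real model strings parse unchanged.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "GPRRule",
    "GPRSyntaxError",
    "Reaction",
    "MetabolicNetwork",
    "ExpressionMatrix",
    "parse_gpr",
    "load_network",
    "write_network",
    "load_expression",
    "write_expression",
]


# ---------------------------------------------------------------------------
# GPR rule trees
# ---------------------------------------------------------------------------

GENE = "gene"
AND = "and"
OR = "or"


@dataclass(frozen=True)
class GPRRule:
    """A node of a GPR boolean expression tree.

    ``kind`` is ``"gene"`` for a leaf (with a non-empty ``gene`` identifier)
    or ``"and"`` / ``"or"`` for an internal node with >= 2 ordered children.
    Instances are immutable and compare structurally.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRRule", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == GENE:
            if not self.gene:
                raise ValueError("gene leaf requires a non-empty identifier")
            if self.children:
                raise ValueError("gene leaf cannot have children")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node requires >= 2 children")
            if self.gene is not None:
                raise ValueError("internal node cannot carry a gene id")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    # -- constructors -------------------------------------------------------

    @staticmethod
    def leaf(gene: str) -> "GPRRule":
        return GPRRule(GENE, gene=gene)

    @staticmethod
    def and_(*children: "GPRRule") -> "GPRRule":
        return GPRRule(AND, children=tuple(children))

    @staticmethod
    def or_(*children: "GPRRule") -> "GPRRule":
        return GPRRule(OR, children=tuple(children))

    # -- queries ------------------------------------------------------------

    def leaves(self) -> Iterator["GPRRule"]:
        if self.kind == GENE:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def genes(self) -> set[str]:
        """Set of all gene identifiers appearing in the tree."""
        return {leaf.gene for leaf in self.leaves()}  # type: ignore[misc]

    def contains_and(self) -> bool:
        return self.kind == AND or any(c.contains_and() for c in self.children)

    def contains_or(self) -> bool:
        return self.kind == OR or any(c.contains_or() for c in self.children)

    # -- serialization ------------------------------------------------------

    def to_string(self) -> str:
        """Render the tree; re-parsing the result reproduces the tree."""
        if self.kind == GENE:
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.kind != GENE:
                s = f"({s})"
            parts.append(s)
        return f" {self.kind} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


class GPRSyntaxError(ValueError):
    """Malformed GPR string; carries the offending token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a rule tree.

    ``and`` / ``or`` are case-insensitive; every other token is a gene
    identifier.  Operators are n-ary: ``g1 or g2 or g3`` becomes one OR node
    with three children.  Mixing ``and`` and ``or`` at the same parenthesis
    level is rejected as ambiguous.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRSyntaxError("empty GPR string", 0)
    rule, pos = _parse_expr(tokens, 0, text)
    if pos != len(tokens):
        raise GPRSyntaxError(
            f"unexpected token {tokens[pos][0]!r}", tokens[pos][1]
        )
    return rule


def _parse_expr(tokens: list[tuple[str, int]], i: int, text: str) -> tuple[GPRRule, int]:
    terms: list[GPRRule] = []
    operator: str | None = None
    term, i = _parse_term(tokens, i, text)
    terms.append(term)
    while i < len(tokens) and tokens[i][0].lower() in (AND, OR):
        op = tokens[i][0].lower()
        if operator is None:
            operator = op
        elif op != operator:
            raise GPRSyntaxError(
                f"mixed 'and'/'or' at one level without parentheses", tokens[i][1]
            )
        i += 1
        term, i = _parse_term(tokens, i, text)
        terms.append(term)
    if operator is None:
        return terms[0], i
    return GPRRule(operator, children=tuple(terms)), i


def _parse_term(tokens: list[tuple[str, int]], i: int, text: str) -> tuple[GPRRule, int]:
    if i >= len(tokens):
        pos = len(text)
        raise GPRSyntaxError("dangling operator or empty expression", pos)
    tok, pos = tokens[i]
    if tok == "(":
        rule, i = _parse_expr(tokens, i + 1, text)
        if i >= len(tokens) or tokens[i][0] != ")":
            raise GPRSyntaxError("unbalanced parentheses", pos)
        return rule, i + 1
    if tok == ")":
        raise GPRSyntaxError("unexpected ')'", pos)
    if tok.lower() in (AND, OR):
        raise GPRSyntaxError(f"operator {tok!r} where a gene was expected", pos)
    return GPRRule.leaf(tok), i + 1


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    id: str
    gpr: GPRRule | None = None
    subsystem: str = ""


@dataclass
class MetabolicNetwork:
    """Ordered reaction list with GPR rules and subsystem (pathway) labels."""

    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reaction identifiers: {dup}")

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        """Gene universe: union of leaf genes over all GPR rules."""
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out

    def gene_associated(self) -> list[Reaction]:
        """Reactions that carry a GPR rule."""
        return [r for r in self.reactions if r.gpr is not None]

    def subsystems(self) -> dict[str, str]:
        """reaction id -> subsystem label."""
        return {r.id: r.subsystem for r in self.reactions}


# ---------------------------------------------------------------------------
# Expression container
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample abundance matrix (FPKM-like units).

    Genes present in a network but absent from the matrix are never imputed;
    :meth:`missing_genes` reports them so downstream mapping can treat them
    as unmeasured.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValueError("expression matrix needs >= 1 gene and >= 1 sample")
        if df.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            rows, cols = (values < 0).nonzero()
            g, s = df.index[rows[0]], df.columns[cols[0]]
            raise ValueError(f"negative expression value at gene {g!r}, sample {s!r}")
        self.data = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def missing_genes(self, network: MetabolicNetwork) -> set[str]:
        """Network genes with no row in this matrix (left unmeasured)."""
        return network.genes - set(self.data.index)

    def pooled_values(self):
        """All entries as a flat array (the 'overall expression distribution')."""
        return self.data.to_numpy(dtype=float).ravel()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_TAB_COLUMNS = ["reaction_id", "gpr", "subsystem"]


def load_network(path: str | Path, format: str = "auto") -> MetabolicNetwork:
    """Load a network from SBML (Level 3 + fbc gene associations) or from the
    tabular TSV dialect with columns reaction_id / gpr / subsystem.

    ``format="auto"`` infers SBML from a ``.xml``/``.sbml`` suffix.
    """
    path = Path(path)
    if format == "auto":
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular"
    if format == "sbml":
        return _load_sbml(path)
    if format == "tabular":
        return _load_tabular(path)
    raise ValueError(f"unknown network format {format!r}")


def _load_tabular(path: Path) -> MetabolicNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TAB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"network table {path} lacks columns {missing}")
    reactions = []
    for _, row in df.iterrows():
        gpr_text = row["gpr"].strip()
        rule = None
        if gpr_text:
            try:
                rule = parse_gpr(gpr_text)
            except GPRSyntaxError as exc:
                raise ValueError(
                    f"unparseable GPR for reaction {row['reaction_id']!r}: {exc}"
                ) from exc
        reactions.append(Reaction(row["reaction_id"], rule, row["subsystem"]))
    return MetabolicNetwork(reactions)


def _load_sbml(path: Path) -> MetabolicNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    reactions = []
    for rxn in model.reactions:
        gpr_text = rxn.gene_reaction_rule.strip()
        rule = None
        if gpr_text:
            try:
                rule = parse_gpr(gpr_text)
            except GPRSyntaxError as exc:
                raise ValueError(
                    f"unparseable GPR for reaction {rxn.id!r}: {exc}"
                ) from exc
        reactions.append(Reaction(rxn.id, rule, rxn.subsystem or ""))
    return MetabolicNetwork(reactions)


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the tabular TSV dialect (round-trips through :func:`load_network`)."""
    rows = [
        {
            "reaction_id": r.id,
            "gpr": r.gpr.to_string() if r.gpr is not None else "",
            "subsystem": r.subsystem,
        }
        for r in network.reactions
    ]
    pd.DataFrame(rows, columns=_TAB_COLUMNS).to_csv(path, sep="\t", index=False)


def load_expression(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Load a delimited gene x sample matrix (first column gene ids, header row
    sample ids).  Non-numeric cells and negative values are rejected with the
    offending coordinates."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = bad.to_numpy().nonzero()
        g, s = raw.index[rows[0]], raw.columns[cols[0]]
        raise ValueError(f"non-numeric expression cell at gene {g!r}, sample {s!r}")
    if numeric.isna().to_numpy().any():
        rows, cols = numeric.isna().to_numpy().nonzero()
        g, s = raw.index[rows[0]], raw.columns[cols[0]]
        raise ValueError(f"empty expression cell at gene {g!r}, sample {s!r}")
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene")
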