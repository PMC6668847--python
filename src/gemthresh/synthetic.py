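"""Self-contained synthetic fixtures: networks with realistic GPR-pattern
mixes and expression matrices with planted organ-system structure.

The generator emulates the statistical shape of a tissue atlas overlaid on a
genome-scale model: heavy-tailed (log-normal) FPKM-like abundances, a block
of housekeeping genes expressed highly everywhere, a block of always-low
genes that should never be called ON under a percentile-bounded scheme,
organ-system groups of samples sharing elevated pathway genes, and planted
pathway–tissue ground truth in three ubiquity categories (tissue-specific,
group-specific, ubiquitous).  Everything is deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import ExpressionMatrix, GPRRule, MetabolicNetwork, Reaction

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_network",
    "generate_expression",
    "generate_known_pairs",
    "generate_fixture",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study.

    ``pattern_mix`` gives the fractions of specialist / isoenzymatic /
    multimeric / mixed (isoenzymatic-multimeric) GPRs; the remainder of the
    reactions carry no rule.  ``effect_size`` is the fold-elevation of a
    planted pathway's genes in its target samples (1.0 ablates the planted
    structure).  Baseline abundances are log-normal; housekeeping genes draw
    from a higher log-normal band and always-low genes from a band far below
    the pooled lower percentile bound.
    """

    n_genes: int = 300
    n_reactions: int = 200
    n_samples: int = 32
    group_sizes: tuple[int, ...] = (6, 5, 4)
    pattern_mix: tuple[float, float, float, float] = (0.35, 0.25, 0.20, 0.10)
    n_tissue_specific: int = 2
    n_ubiquitous: int = 2
    reactions_per_pathway: int = 15
    effect_size: float = 8.0
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 1.0
    noise_sdlog: float = 0.4
    housekeeping_meanlog: float = 3.5
    housekeeping_sdlog: float = 0.2
    always_low_meanlog: float = -3.0
    always_low_sdlog: float = 0.3
    always_low_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_reactions, self.n_samples) < 1:
            raise ValueError("all counts must be positive")
        if sum(self.pattern_mix) > 1 + 1e-9:
            raise ValueError("pattern-mix fractions must sum to <= 1")
        if any(f < 0 for f in self.pattern_mix):
            raise ValueError("pattern-mix fractions must be non-negative")
        if any(g < 3 for g in self.group_sizes):
            raise ValueError("organ-system groups need >= 3 samples each")
        if sum(self.group_sizes) > self.n_samples:
            raise ValueError("group sizes exceed the number of samples")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")

    @property
    def pathways(self) -> list[str]:
        ts = [f"pathway_ts{i + 1}" for i in range(self.n_tissue_specific)]
        gs = [f"pathway_gs{i + 1}" for i in range(len(self.group_sizes))]
        ub = [f"pathway_ub{i + 1}" for i in range(self.n_ubiquitous)]
        return ts + gs + ub


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the data, for assertions."""

    sample_groups: dict[str, str | None] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    pathway_tissues: dict[str, tuple[str, ...]] = field(default_factory=dict)
    pathway_category: dict[str, str] = field(default_factory=dict)

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, grp in self.sample_groups.items():
            if grp is not None:
                out.setdefault(grp, []).append(sample)
        return out


def _pattern_counts(spec: FixtureSpec) -> dict[str, int]:
    names = ("specialist", "isoenzymatic", "multimeric", "mixed")
    counts = {n: int(round(f * spec.n_reactions)) for n, f in zip(names, spec.pattern_mix)}
    total = sum(counts.values())
    if total > spec.n_reactions:
        raise ValueError("pattern mix infeasible for the requested reaction count")
    counts["none"] = spec.n_reactions - total
    return counts


class _GenePool:
    """Draws genes for rules; tracks reuse so promiscuity arises naturally."""

    def __init__(self, genes: list[str], rng: np.random.Generator, reuse_prob: float = 0.3):
        self.free = list(genes)
        self.used: list[str] = []
        self.rng = rng
        self.reuse_prob = reuse_prob
        self._mint = 0

    def dedicated(self, minted_prefix: str) -> str:
        """A gene guaranteed to appear nowhere else (for specialist rules)."""
        if self.free:
            return self.free.pop()
        self._mint += 1
        return f"{minted_prefix}{self._mint:04d}"

    def draw(self, k: int, minted_prefix: str) -> list[str]:
        """k distinct genes, reusing already-placed genes some of the time."""
        chosen: list[str] = []
        while len(chosen) < k:
            pool = [g for g in self.used if g not in chosen]
            if pool and (not self.free or self.rng.random() < self.reuse_prob):
                chosen.append(pool[int(self.rng.integers(len(pool)))])
            elif self.free:
                g = self.free.pop()
                self.used.append(g)
                chosen.append(g)
            else:
                g = self.dedicated(minted_prefix)
                self.used.append(g)
                chosen.append(g)
        return chosen


def _build_rule(pattern: str, pool: _GenePool, rng: np.random.Generator, prefix: str) -> GPRRule | None:
    if pattern == "none":
        return None
    if pattern == "specialist":
        return GPRRule.leaf(pool.dedicated(prefix))
    if pattern == "isoenzymatic":
        k = int(rng.integers(2, 4))
        return GPRRule.or_(*[GPRRule.leaf(g) for g in pool.draw(k, prefix)])
    if pattern == "multimeric":
        k = int(rng.integers(2, 4))
        return GPRRule.and_(*[GPRRule.leaf(g) for g in pool.draw(k, prefix)])
    if pattern == "mixed":
        genes = pool.draw(3 + int(rng.integers(0, 2)), prefix)
        complex_part = GPRRule.and_(GPRRule.leaf(genes[0]), GPRRule.leaf(genes[1]))
        if len(genes) == 3:
            return GPRRule.or_(complex_part, GPRRule.leaf(genes[2]))
        return GPRRule.or_(
            complex_part, GPRRule.and_(GPRRule.leaf(genes[2]), GPRRule.leaf(genes[3]))
        )
    raise ValueError(f"unknown pattern {pattern!r}")


def generate_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Network with the requested GPR pattern mix and planted subsystems.

    Each planted pathway receives exactly ``reactions_per_pathway``
    gene-associated reactions drawing genes from a dedicated pool (so the
    expression generator can elevate a pathway coherently); the remaining
    reactions form the background.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _pattern_counts(spec)
    planted = spec.pathways
    n_gene_assoc = spec.n_reactions - counts["none"]
    if len(planted) * spec.reactions_per_pathway > n_gene_assoc:
        raise ValueError("more planted pathway reactions than gene-associated reactions")

    patterns = [p for p, c in counts.items() for _ in range(c)]
    rng.shuffle(patterns)

    # Subsystem assignment: planted pathways take random gene-associated slots.
    gene_assoc_idx = [i for i, p in enumerate(patterns) if p != "none"]
    rng.shuffle(gene_assoc_idx)
    subsystem = [BACKGROUND] * spec.n_reactions
    cursor = 0
    for pw in planted:
        for _ in range(spec.reactions_per_pathway):
            subsystem[gene_assoc_idx[cursor]] = pw
            cursor += 1

    # Gene pools: a dedicated slice per planted pathway, the rest background.
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    rng.shuffle(genes)
    pool_size = min(2 * spec.reactions_per_pathway, max(2, spec.n_genes // (len(planted) + 1)))
    pools: dict[str, _GenePool] = {}
    offset = 0
    for pw in planted:
        pools[pw] = _GenePool(genes[offset : offset + pool_size], rng)
        offset += pool_size
    pools[BACKGROUND] = _GenePool(genes[offset:], rng)

    reactions = []
    for i in range(spec.n_reactions):
        pw = subsystem[i]
        rule = _build_rule(patterns[i], pools[pw], rng, prefix=f"gx_{pw}_")
        reactions.append(Reaction(f"rxn_{i + 1:04d}", rule, pw))
    return MetabolicNetwork(reactions)


def _pathway_genes(network: MetabolicNetwork) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rxn in network.reactions:
        if rxn.gpr is not None:
            out.setdefault(rxn.subsystem, set()).update(rxn.gpr.genes())
    return out


def generate_expression(
    network: MetabolicNetwork, spec: FixtureSpec
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression matrix with planted structure, plus the ground truth.

    Rows cover every gene appearing in the network's rules.  Planted
    pathway genes are elevated ``effect_size``-fold in the pathway's target
    samples; ubiquitous-pathway genes are housekeeping (high everywhere);
    a fraction of background genes is always-low.
    """
    rng = np.random.default_rng(spec.seed + 1)
    samples = [f"tissue_{i + 1:02d}" for i in range(spec.n_samples)]

    truth = GroundTruth()
    cursor = 0
    for gi, size in enumerate(spec.group_sizes):
        for s in samples[cursor : cursor + size]:
            truth.sample_groups[s] = f"group{gi + 1}"
        cursor += size
    for s in samples[cursor:]:
        truth.sample_groups[s] = None
    ungrouped = samples[cursor:]

    pathway_genes = _pathway_genes(network)
    # Target samples per planted pathway.
    ts_pool = list(ungrouped) if ungrouped else list(samples)
    rng.shuffle(ts_pool)
    ts_cursor = 0
    for i in range(spec.n_tissue_specific):
        pw = f"pathway_ts{i + 1}"
        width = 2 if i % 2 == 0 else 1
        if ts_cursor + width > len(ts_pool):
            ts_cursor = 0
        targets = tuple(sorted(ts_pool[ts_cursor : ts_cursor + width]))
        ts_cursor += width
        truth.pathway_tissues[pw] = targets
    members = truth.group_members()
    for gi in range(len(spec.group_sizes)):
        pw = f"pathway_gs{gi + 1}"
        truth.pathway_tissues[pw] = tuple(members[f"group{gi + 1}"])
    for i in range(spec.n_ubiquitous):
        truth.pathway_tissues[f"pathway_ub{i + 1}"] = tuple(samples)
    for pw, tissues in truth.pathway_tissues.items():
        k = len(tissues)
        truth.pathway_category[pw] = (
            "tissue-specific" if k <= 2 else ("group-specific" if k <= 10 else "ubiquitous")
        )

    # Gene classes.
    all_genes = sorted(network.genes)
    planted_gene_of: dict[str, str] = {}
    for pw in spec.pathways:
        for g in pathway_genes.get(pw, ()):  # pools are disjoint by construction
            planted_gene_of[g] = pw
    background_genes = [g for g in all_genes if g not in planted_gene_of]
    n_low = min(int(round(spec.always_low_fraction * spec.n_genes)), len(background_genes))
    low_idx = rng.choice(len(background_genes), size=n_low, replace=False)
    always_low = {background_genes[i] for i in low_idx}
    for g in all_genes:
        if g in always_low:
            truth.gene_classes[g] = "always-low"
        elif g in planted_gene_of:
            pw = planted_gene_of[g]
            truth.gene_classes[g] = (
                "housekeeping" if pw.startswith("pathway_ub") else f"planted:{pw}"
            )
        else:
            truth.gene_classes[g] = "background"

    # Baseline levels and sample noise.
    base = np.empty(len(all_genes))
    for i, g in enumerate(all_genes):
        cls = truth.gene_classes[g]
        if cls == "always-low":
            base[i] = rng.lognormal(spec.always_low_meanlog, spec.always_low_sdlog)
        elif cls == "housekeeping":
            base[i] = rng.lognormal(spec.housekeeping_meanlog, spec.housekeeping_sdlog)
        else:
            base[i] = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog)
    noise = rng.lognormal(0.0, spec.noise_sdlog, size=(len(all_genes), spec.n_samples))
    values = base[:, None] * noise

    df = pd.DataFrame(values, index=all_genes, columns=samples)
    sample_pos = {s: j for j, s in enumerate(samples)}
    for i, g in enumerate(all_genes):
        cls = truth.gene_classes[g]
        if cls.startswith("planted:"):
            pw = cls.split(":", 1)[1]
            cols = [sample_pos[s] for s in truth.pathway_tissues[pw]]
            df.iloc[i, cols] *= spec.effect_size
    return ExpressionMatrix(df), truth


def generate_known_pairs(truth: GroundTruth) -> pd.DataFrame:
    """Planted pathway–tissue pairs in the curated-table layout."""
    rows = []
    for pw, tissues in truth.pathway_tissues.items():
        for t in tissues:
            rows.append(
                {
                    "pathway": pw,
                    "tissue": t,
                    "category": truth.pathway_category[pw],
                    "reference": "planted",
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "tissue", "category", "reference"])


def generate_fixture(spec: FixtureSpec | None = None):
    """Convenience: (network, expression, ground truth, known pairs)."""
    if spec is None:
        spec = FixtureSpec()
    network = generate_network(spec)
    expr, truth = generate_expression(network, spec)
    return network, expr, truth, generate_known_pairs(truth)
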