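"""GPR evaluation under GM1/GM2, determinant genes, pattern classification."""
import numpy as np
import pandas as pd
import pytest

from gemthresh import (
    ExpressionMatrix,
    GM1,
    GM2,
    GPRRule,
    MetabolicNetwork,
    Reaction,
    classify_gpr_patterns,
    determinant_genes,
    evaluate_gpr,
    map_expression_to_reactions,
    parse_gpr,
)

leaf, and_, or_ = GPRRule.leaf, GPRRule.and_, GPRRule.or_
RULE = or_(and_(leaf("g1"), leaf("g2")), leaf("g3"))


class TestEvaluate:
    @pytest.mark.parametrize(
        "method, rule, values, expected",
        [
            (GM1, RULE, {"g1": 2, "g2": 5, "g3": 3}, 3),  # max(min(2,5), 3)
            (GM2, RULE, {"g1": 2, "g2": 5, "g3": 3}, 5),  # min(2,5) + 3
            (GM1, leaf("g1"), {"g1": 7.5}, 7.5),
            (GM2, or_(leaf("g1"), leaf("g2"), leaf("g3")), {"g1": 1, "g2": 2}, 3),
            (GM1, or_(leaf("g1"), leaf("g2")), {"g2": 4}, 4),  # missing child dropped
            (GM1, and_(leaf("g1"), leaf("g2")), {"g1": 4}, None),  # missing subunit
            (GM2, or_(leaf("g1"), leaf("g2")), {}, None),  # all missing
        ],
    )
    def test_examples(self, method, rule, values, expected):
        assert evaluate_gpr(rule, values, method) == expected

    def test_oracle_equivalence_and_gm_ordering(self):
        """Matches an independent recursive oracle on 1000 random instances;
        GM1 <= GM2 everywhere (sum >= max for non-negative values)."""

        def oracle(rule, values, method):
            if rule.kind == "gene":
                return values.get(rule.gene)
            parts = [oracle(c, values, method) for c in rule.children]
            if rule.kind == "and":
                return None if None in parts else min(parts)
            parts = [p for p in parts if p is not None]
            if not parts:
                return None
            if method == GM1:
                return max(parts)
            return sum(parts)

        from test_model_io import _random_rule

        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(1000):
            rule = _random_rule(rng)
            values = {
                g: (None if rng.random() < 0.15 else float(np.round(rng.uniform(0, 10), 3)))
                for g in rule.genes()
            }
            values = {g: v for g, v in values.items() if v is not None}
            for method in (GM1, GM2):
                got = evaluate_gpr(rule, values, method)
                assert got == oracle(rule, values, method)
            v1 = evaluate_gpr(rule, values, GM1)
            v2 = evaluate_gpr(rule, values, GM2)
            if v1 is not None:
                assert v1 <= v2
                present = [values[l.gene] for l in rule.leaves() if l.gene in values]
                assert min(present) <= v2 <= sum(present) + 1e-12
                assert min(present) - 1e-12 <= v1 <= sum(present)
                checked += 1
        assert checked > 500  # most random instances evaluate to a value

    def test_monotone_in_each_gene(self):
        from test_model_io import _random_rule

        rng = np.random.default_rng(11)
        for _ in range(200):
            rule = _random_rule(rng)
            values = {g: float(rng.uniform(0, 10)) for g in rule.genes()}
            target = list(rule.genes())[int(rng.integers(len(rule.genes())))]
            bumped = dict(values)
            bumped[target] = values[target] + float(rng.uniform(0, 5))
            for method in (GM1, GM2):
                assert evaluate_gpr(rule, bumped, method) >= evaluate_gpr(
                    rule, values, method
                )


class TestDeterminantGenes:
    @pytest.mark.parametrize(
        "method, rule, values, expected",
        [
            (GM1, RULE, {"g1": 2, "g2": 5, "g3": 3}, {"g3"}),
            (GM2, RULE, {"g1": 2, "g2": 5, "g3": 3}, {"g1", "g3"}),
            (GM1, or_(leaf("g1"), leaf("g2")), {"g1": 4, "g2": 4}, {"g1", "g2"}),
            (GM1, and_(leaf("g1"), leaf("g2")), {"g1": 1}, set()),  # missing rule
        ],
    )
    def test_examples(self, method, rule, values, expected):
        assert determinant_genes(rule, values, method) == expected

    def test_subset_of_leaves_and_perturbation_sensitivity(self):
        from test_model_io import _random_rule

        rng = np.random.default_rng(23)
        for _ in range(200):
            rule = _random_rule(rng)
            values = {g: float(np.round(rng.uniform(0, 10), 2)) for g in rule.genes()}
            for method in (GM1, GM2):
                dets = determinant_genes(rule, values, method)
                assert dets <= rule.genes()
                base = evaluate_gpr(rule, values, method)
                for g in dets:
                    bumped = dict(values)
                    bumped[g] = values[g] + 1e-6
                    changed_value = evaluate_gpr(rule, bumped, method) != base
                    changed_ties = determinant_genes(rule, bumped, method) != dets
                    assert changed_value or changed_ties


class TestMapExpression:
    def test_per_sample_evaluation_and_no_rule(self):
        net = MetabolicNetwork(
            [Reaction("R1", parse_gpr("g1 or g2")), Reaction("R2", None)]
        )
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=["g1", "g2"])
        )
        out = map_expression_to_reactions(net, expr, GM1)
        assert out.loc["R1", "s1"] == 2.0
        assert out.loc["R1", "s2"] == 0.0
        assert out.loc["R2"].isna().all()

    def test_fully_missing_rule_is_no_data(self):
        net = MetabolicNetwork([Reaction("R1", parse_gpr("g9"))])
        expr = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["g1"]))
        assert map_expression_to_reactions(net, expr, GM2).loc["R1"].isna().all()

    def test_gm2_dominates_gm1_elementwise(self, default_fixture):
        network, expr, _, _ = default_fixture
        m1 = map_expression_to_reactions(network, expr, GM1)
        m2 = map_expression_to_reactions(network, expr, GM2)
        assert ((m2 - m1).fillna(0) >= -1e-9).all().all()
        assert m1.isna().equals(m2.isna())


class TestPatterns:
    def test_labels_and_promiscuity(self):
        net = MetabolicNetwork(
            [
                Reaction("R1", parse_gpr("gA")),
                Reaction("R2", parse_gpr("(g1 and g2) or g3")),
                Reaction("R3", parse_gpr("g1 or g3")),
                Reaction("R4", parse_gpr("g1 and g4")),
                Reaction("R5", None),
                Reaction("R6", parse_gpr("g3")),
            ]
        )
        pat = classify_gpr_patterns(net)
        assert pat.labels == {
            "R1": "specialist",
            "R2": "isoenzymatic-multimeric",
            "R3": "isoenzymatic",
            "R4": "multimeric",
            "R5": "no-rule",
            "R6": "promiscuous",  # single-leaf but g3 occurs in 3 reactions
        }
        assert pat.promiscuity["g1"] == 3
        assert pat.promiscuity["g3"] == 3
        assert pat.promiscuity["gA"] == 1
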