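"""Evaluate a gene-protein-reaction rule under both gene-mapping conventions.

The rule "(g1 and g2) or g3" describes a reaction catalyzed either by a
two-subunit complex (g1 AND g2) or by an isoenzyme g3.  GM1 lets the
strongest isoenzyme speak for the reaction (OR = max); GM2 adds isoenzyme
capacities (OR = sum).  Both take the weakest subunit of a complex
(AND = min).
"""
from gemthresh import GM1, GM2, determinant_genes, evaluate_gpr, parse_gpr

rule = parse_gpr("(g1 and g2) or g3")
values = {"g1": 2.0, "g2": 5.0, "g3": 3.0}

for method in (GM1, GM2):
    v = evaluate_gpr(rule, values, method)
    det = sorted(determinant_genes(rule, values, method))
    print(f"{method}: reaction expression = {v}  (determined by {det})")

# GM1: max(min(2, 5), 3) = 3 -- the isoenzyme g3 dominates.
# GM2: min(2, 5) + 3 = 5 -- the complex (limited by g1) and g3 both count.
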