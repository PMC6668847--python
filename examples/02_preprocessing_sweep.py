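"""Run all 20 preprocessing decision combinations on a synthetic study.

Generates a 200-reaction network and a 32-tissue expression matrix with
planted organ-system structure, applies every (gene mapping x order x
thresholding scheme) combination, and prints how the size of the active
reaction set depends on the decisions — the spread is the point: the same
data yield very different context-specific networks.
"""
from gemthresh import FixtureSpec, active_set_sizes, generate_fixture, run_all

network, expr, truth, known = generate_fixture(FixtureSpec(seed=0))
table = run_all(network, expr)

sizes = active_set_sizes(table)
per_config = sizes.groupby(level="config").agg(["min", "mean", "max"])
print(f"{table.shape[0]} (config, tissue) profiles over "
      f"{table.shape[1]} gene-associated reactions\n")
print(per_config.round(1).to_string())
print("\nActive-set size varies ~2x across decisions: thresholding choices,"
      "\nnot gene mapping, drive the spread (compare global50 vs global75).")
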