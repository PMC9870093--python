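"""Build a row-scaled cell-state heatmap along a regeneration branch.

Simulates a biliary program decaying and a hepatocyte program rising
along the hepatocyte branch of a post-ablation time course, then
averages expression per cell state and min-max scales each gene row.
"""

from hepaquant.expression import build_states, log_normalize, state_heatmap
from hepaquant.simulate import StateSimSpec, simulate_state_expression

states = ["mock.BEC", "0dpa.BEC", "1dpa.HC", "3dpa.HC", "7dpa.HC"]
programs = {
    "biliary": (
        ["anxa4", "krt18a.1"],
        {"mock.BEC": 10, "0dpa.BEC": 8, "1dpa.HC": 4, "3dpa.HC": 2, "7dpa.HC": 1},
    ),
    "hepatocyte": (
        ["fabp10a", "bhmt"],
        {"mock.BEC": 0.5, "0dpa.BEC": 0.5, "1dpa.HC": 1, "3dpa.HC": 5, "7dpa.HC": 10},
    ),
    "housekeeping": (["hk0", "hk1"], {s: 5.0 for s in states}),
}
counts, meta = simulate_state_expression(StateSimSpec(states, 60, programs, seed=5))
meta = build_states(meta.drop(columns="state"))
hm = state_heatmap(
    log_normalize(counts),
    meta.set_index("cell")["state"],
    ["anxa4", "krt18a.1", "fabp10a", "bhmt"],
    states,
)
print(hm.round(2).to_string())
print()
print("Each row is the state-averaged normalized expression scaled to")
print("[0, 1]: biliary genes peak at mock/0dpa and fade along the branch;")
print("hepatocyte genes return by 3-7 dpa.")
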