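"""Find cluster markers with the one-vs-rest positive-only Wilcoxon
test and identify a cluster from a three-marker panel.

Simulates two cell populations where the hepatocyte program (fabp10a,
tfa, cp) is 8-fold enriched in one cluster, then recovers those genes
as markers and assigns the cell type.
"""

from hepaquant.expression import find_markers, identify_cluster, log_normalize
from hepaquant.simulate import StateSimSpec, simulate_state_expression

programs = {
    "hepatocyte": (["fabp10a", "tfa", "cp"], {"mock.HC": 8.0, "mock.BEC": 1.0}),
    "biliary": (["anxa4", "krt18a.1", "alcama"], {"mock.HC": 1.0, "mock.BEC": 8.0}),
    "housekeeping": ([f"hk{i}" for i in range(44)], {"mock.HC": 2.0, "mock.BEC": 2.0}),
}
counts, meta = simulate_state_expression(
    StateSimSpec(["mock.HC", "mock.BEC"], 100, programs, dispersion=2.0, seed=7)
)
nm = log_normalize(counts)
markers = find_markers(nm, meta.set_index("cell")["cell_type"])

print(markers[["gene", "cluster", "log_fc", "p_adj"]].to_string(index=False))
panel = {
    "hepatocyte": ["fabp10a", "tfa", "cp"],
    "BEC": ["anxa4", "krt18a.1", "alcama"],
}
print()
print("cluster assignments:", identify_cluster(markers, panel))
print()
print("Each retained row is enriched in its cluster (log_fc > 0.25) with")
print("Bonferroni-adjusted rank-sum p < 0.05; a cluster needs >= 3 panel")
print("markers to be assigned a cell type.")
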