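"""Per-cell mitochondrial morphometrics and a two-condition comparison.

Builds a synthetic dataset of 30 control cells and 30 cells with 2.5x
fragmentation (fission at constant mitochondrial mass), computes the full
per-cell metric suite, and compares the connectivity score between the
groups by ANOVA with Tukey HSD.
"""

from mitoarm.metrics import compare_groups, compute_dataset_metrics
from mitoarm.simulate import NetworkGenParams, generate_networks

params = NetworkGenParams(
    n_cells_per_condition=30,
    condition_effects={"control": (1.0, 1.0), "fragmented": (2.5, 1.0)},
)
dataset, _ = generate_networks(params, seed=11)
metrics = compute_dataset_metrics(dataset)

print(metrics.groupby("condition")[
    ["phi", "avg_edge_length", "avg_degree", "connectivity_score"]
].mean().round(3))

cmp = compare_groups(metrics, "connectivity_score")
print(f"\nANOVA omnibus p = {cmp.omnibus_p:.2e}")
print(cmp.pairwise.to_string(index=False))

# The fragmented condition splits the same mitochondrial mass into more,
# shorter pieces: PHI (largest-component length fraction) and average edge
# length drop, so its connectivity score is lower; the Tukey row shows the
# difference is significant.
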