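# mitoarm

Quantitative analytics for studying how a protein segment — such as the
eight-residue N-terminal "arm" of the mitochondrial fission protein FIS1 —
affects mitochondrial network morphology and protein conformation.  The
package has two halves that share one workflow:

1. **Graph-theoretic mitochondrial morphometrics.**  Confocal z-stacks
   segmented into per-cell skeleton graphs (nodes = branch/end points,
   edges = tubule lengths in μm) are read, cleaned of two well-characterized
   segmentation artifact classes, and summarized per cell.
2. **Protein biophysics analytics.**  Tabular NMR and fluorescence analyses
   that report on whether the arm packs against the protein core: chemical
   shift perturbations, region-wise kernel densities, experiment-vs-ensemble
   shift comparisons, heteronuclear NOE ratios, relaxation-rate fits,
   ensemble atom distances, Stern–Volmer quenching and nanoDSF melting
   temperatures.

A seedable synthetic-data module generates inputs with the statistical
structure of each stage — plus ground-truth ledgers — so the entire pipeline
is testable without microscopy or spectrometer data.

## The core quantities

For one cell's network with total length *L*, the metric suite includes

- **PHI** = (length of largest connected component) / *L* ∈ (0, 1];
  1 means fully fused.
- **Average edge length** = *L* / #edges (μm).
- **Average degree** = Σₖ k·P(k), with P(k) the node degree distribution;
  for tree-like skeletons (degrees {1, 3, 4}) this equals
  FreeEnds·1 + 3way·3 + 4way·4.
- **Length-normalized counts**: nodes/μm, edges/μm, components/μm.
- **Connectivity score** =
  (PHI + AvgEdgeLength + AvgDegree) / (nodes/μm + edges/μm + components/μm),
  the ratio of pro-fusion to pro-fission factors.

Artifact filters applied before metrics: (i) remove 2-node/1-edge components
longer than 100 μm (legitimate ones run ~15–20 μm); (ii) remove components
whose length, rounded to 4 decimals, accounts for strictly more than 0.05%
of all components pooled over the dataset (bright-voxel noise repeats one
exact value thousands of times).

On the spectroscopy side: CSP Δδ = √(5·Δδ_H² + Δδ_N²); ΔΔΔδ =
|δ_OUT − δ_exp| − |δ_IN − δ_exp| (positive favors the arm-in ensemble);
hetNOE = I_sat/I_ref; R from I(t) = I₀e^(−Rt); Ksv from F₀/F = 1 + Ksv[Q];
Tm from the maximum of d(330/350 ratio)/dT.

## Worked example

```python
from mitoarm.metrics import compare_groups, compute_dataset_metrics
from mitoarm.simulate import NetworkGenParams, generate_networks

params = NetworkGenParams(
    n_cells_per_condition=30,
    condition_effects={"control": (1.0, 1.0), "fragmented": (2.5, 1.0)},
)
dataset, _ = generate_networks(params, seed=11)
metrics = compute_dataset_metrics(dataset)
print(metrics.groupby("condition")[["phi", "connectivity_score"]].mean())
print(compare_groups(metrics, "connectivity_score").omnibus_p)
```

prints

```
              phi  connectivity_score
condition
control     0.204               5.520
fragmented  0.122               1.215
2.0124...e-27
```

The "fragmented" condition splits the same mitochondrial mass into 2.5×
more, proportionally shorter pieces: the largest component holds a smaller
length fraction (PHI 0.20 → 0.12), edges are shorter, and the per-μm counts
rise, so the connectivity score collapses from 5.5 to 1.2; the ANOVA
omnibus p-value shows the group difference is far beyond chance.  The
scripts in `examples/` walk through each capability the same way
(morphometrics, artifact filtering, shift perturbations, relaxation/NOE,
fluorescence fits) and print what the numbers mean.

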