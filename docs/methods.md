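# Methods

This note records the models, defaults and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Network model and file dialect

A cell's mitochondrial skeleton is an undirected weighted multigraph:
self-loops and parallel edges are legal and counted as distinct edges (both
occur in skeletonized organelles), and a self-loop contributes 2 to its
node's degree.  Edge weights are physical lengths in μm; no unit conversion
is ever attempted.

Graph files follow the dialect: first line = node count; each following
line = `u v length` with 0-based integer indices.  Upstream segmentation
tools do not standardize 0- vs 1-based indexing, so the choice is an
assumption of this package; the delimiter is configurable and other
dialects can be added behind `read_gnet`.  Node coordinates, when present,
are carried for visualization only — no metric uses them.  Lengths are
written back with shortest-round-trip precision so that decimal-parsed
values (and the rounded keys below) survive I/O exactly.

## Artifact filters

Two artifact classes arise in automated segmentation of confocal stacks:

**Long two-node components.**  Spurious straight segments spanning a crop.
A component with exactly 2 nodes and 1 edge and length strictly greater
than 100 μm (default) is removed; genuine two-node mitochondria top out
around 15–20 μm, so the threshold sits far from real data.  The rule is
per-component, so per-cell and dataset-wide application are identical.

**Repeating components.**  Bright noise voxels segmented as tiny components
whose total length repeats — identically — many times across a dataset,
producing a spurious sub-1 μm shoulder on the component-length histogram.
Component identity is its length rounded to 4 decimals of μm (configurable):
unrounded floating lengths essentially never repeat unless they come from
the same artifact mechanism.  A key is removed when it actually repeats
(count ≥ 2) *and* its pooled frequency strictly exceeds 0.05% of all
components in the dataset.  Both conditions matter: the strict fraction
keeps the rule scale-aware, and the count floor keeps all-unique datasets
untouched regardless of size.  The rule presumes a large pooled dataset —
the threshold count grows linearly with dataset size while the chance
multiplicity of rounded real-valued lengths grows only logarithmically, so
at ~10⁴ components artifacts (hundreds of repeats) separate cleanly from
chance collisions (a handful).  On very small datasets the two populations
are not separable by frequency and the filter should not be trusted; the
length histogram (`length_histogram`) is the diagnostic for whether an
artifact mode exists at all.

Filtering is single-pass: frequencies are computed once on the pre-filter
dataset and never recomputed after removals, which makes each filter
idempotent and prevents removal cascades.  Filters run in the order
two-node → repetition.  Isolated (degree-0) nodes carry no length and are
dropped with a warning beforehand.  Every removal is logged with cell,
filter, size and length, so the log exactly accounts for the change in
component counts.

## Morphometrics

PHI takes "largest component" by summed length, not node count — it is
defined as a length fraction.  Its denominator is computed from the same
per-component sums as the numerator so a single-component network yields
exactly 1.0.  Average degree is Σₖ k·P(k) over *all* observed degrees; the
free-end/junction weighted sum is the special case for degree sets
⊆ {1, 3, 4}, and degree 2 (loops) is handled by the general form.  The
connectivity score mixes μm-bearing (average edge length) and μm⁻¹-bearing
(densities) terms; it is dimensionally heterogeneous by construction, so
scores are comparable only under the package-wide μm convention.

Cells left with no edges after filtering are excluded from group statistics
with a warning — their metrics are undefined, and imputing zeros would bias
the ANOVA.  Group comparison is one-way ANOVA plus Tukey HSD at family
level 0.05 (configurable); when every group is internally constant the F
statistic is undefined and the comparison is returned flagged `degenerate`
with NaN p-values rather than raising, since all-identical groups are a
legitimate degenerate input.  Per-cell values are summarized as mean ± SD
per condition (cells, not pooled components, are the unit of analysis).
Metric–metric correlation is Pearson's r, optionally computed on
per-condition means for population-level trend lines.

## Chemical-shift analytics

**CSP.**  Δδ_total = √(w·Δδ_H² + Δδ_N²) with w = 5 by default.  The
combination rule is printed ambiguously in parts of the literature
(w inside vs (5Δδ_H)²); the weight is a parameter — pass `h_weight=25` for
the alternative reading.  Residue matching is by residue number with an
explicit configurable offset (constructs of different lengths).  Flags mark
residues beyond mean + 1 SD and mean + 2 SD of the dataset's Δδ_total;
they are invariant under a global shift of both tables.

**Region KDE.**  f(x) = (1/hN)·Σ φ((x−xᵢ)/h), Gaussian kernel, evaluated
on a grid spanning the data ± 4h (where the kernel mass becomes
negligible, keeping the trapezoid integral within 1% of 1).  Default
bandwidth is the rule of thumb 0.9·min(SD, IQR/1.34)·N^(−1/5) — the
de-facto default of standard plotting density functions, stated explicitly
here so curves are reproducible.  Degenerate data (N = 1 or zero spread)
fall back to a configured minimum bandwidth with a warning.

**ΔΔΔδ.**  Per residue and dimension, |δ_OUT − δ_exp| − |δ_IN − δ_exp|,
where δ_OUT/δ_IN are per-residue means over the snapshot prediction tables
of each ensemble.  Positive values mean the experimental shift is closer to
the arm-in prediction.  Prediction tables are consumed, never produced:
shift prediction and the MD simulations behind the snapshots are external.
Residues missing from any of the three sources are excluded with a warning.

**hetNOE.**  ratio = I_sat/I_ref per residue; ratios may legitimately be
negative (mobile termini).  Uncertainty is attached only when a spectral
noise RMS is supplied (first-order propagation); there is no hidden error
model.

**Relaxation.**  Nonlinear least squares on I(t) = I₀e^(−Rt) (delays in
ms, rates reported in s⁻¹), initialized from a log-linear regression on the
positive intensities — on clean data the initializer is already near the
optimum, and on noisy data it prevents convergence to the wrong branch.
Duplicated delay points are reported as an RMS empirical scatter alongside
the covariance-based uncertainty.  Non-convergence returns a flagged
result with the solver message, never silent defaults.

**Ensemble distances.**  Euclidean atom–atom distances per model of a
multi-model PDB (parsed with Bio.PDB; alternate locations resolve to the
highest-occupancy conformer), summarized as mean ± SD across models.  The
SD is the population SD (ddof = 0): the ensemble's models are the whole
population of deposited states, and a single-model ensemble then reports
exactly 0.

## Fluorescence

Emission spectra are buffer-corrected by pointwise subtraction on a shared
grid; λmax takes the lowest wavelength on ties and is reported as undefined
for a flat corrected spectrum.  The Stern–Volmer fit fixes the intercept at
1 by default — F₀/F = 1 at zero quencher by definition — with a
free-intercept diagnostic mode; the fixed-intercept slope is the exact
least-squares solution Σc(y−1)/Σc².  Tm is the grid temperature of the
first-derivative maximum of the 330/350 signal after an optional centered
moving average (default 5 points; instrument software typically smooths,
and the setting is surfaced).  Smoothing uses a `valid` convolution on a
trimmed grid because edge extrapolation distorts sloped baselines; the melt
midpoint is interior by definition, so trimming loses nothing.  Ties go to
the lowest temperature; parabolic refinement around the maximum is
deliberately not applied by default (the extraction is defined as a grid
argmax, with error bounded by one grid step).  A curve whose derivative is
constant to rounding, or maximal at a scan boundary (flat or linear
baseline), raises a no-transition error instead of reporting a fake Tm.

## Synthetic data

The network generator emulates segmented single-cell data: a Poisson number
of components per cell, each grown as a random tree whose growing nodes
become 3-way junctions with probability `branching_prob` (4-way with a
small further probability), giving degree sets {1, 3, 4} as skeletonization
produces for tree-like organelles; edge lengths are i.i.d. log-normal with
median ≈ 2.7 μm (components ≈ 5–15 μm, matching the scale on which
legitimate two-node components run tens of μm).  The `fragmentation` dial
models fission at constant mitochondrial mass: it multiplies the expected
component count and divides the edge-length scale by the same factor, so
total length per cell is conserved while the network splits into more,
shorter pieces — adding components at fixed size would leave every per-μm
metric unchanged and miss the phenomenon.  Condition effects are
per-condition multipliers on fragmentation and branching.  Artifacts are
injected exactly as the filters expect them: repeated-length components all
share one exact value (default 0.5 μm), long two-node components are
uniform on (100, 300] μm, and every injection is recorded in a ground-truth
ledger sufficient to score filter sensitivity and specificity.

Not emulated: spatial coordinates, intensity information, and mitochondrial
"clumping" — a spatial/intensity phenomenon the graph does not encode
(elevated PHI is its graph-level signature, but no clump statistic is
generated or computed).  Cycles are absent by default (trees), so passing
tests say nothing about cycle-rich networks beyond the explicit loop unit
tests.  Real segmentation noise is also richer than the two injected
artifact classes; filter scores on synthetic data bound behavior only for
those classes.

Spectroscopy generators produce: linear quench series (exact 1 at zero
quencher); logistic two-state melt curves (derivative maximal exactly at
the midpoint); exponential decays on the standard R₁ delay grid
(20–1200 ms) with duplicated delays; NOE intensity pairs whose true ratios
are drawn per region (arm default: mean 0.80, SD 0.10 — the arm-in
condition; helix/loop 0.80, termini lower); and paired shift tables whose
differences follow a per-region perturbation model, arm-skewed by default.
Reference constants (Ksv 3.50/4.68 M⁻¹, Tm 82.4/79.6 °C, delay grids,
acrylamide series 0–500 mM) live as module constants so defaults match
realistic experiments.  All generators drive every draw from a single seed
argument.

## Problem sizes in the test suite

The suite exercises: PHI on 1,000 random single-component graphs; filter
recovery on a 500-cell, ~2×10⁴-component dataset (the scale at which the
frequency rule is designed to operate, see above); a 20-point × 30-cell
fragmentation sweep for score monotonicity; 200-replicate relaxation-bias
and 500-replicate quench-bias simulations at 2% and 1% noise; and
100-replicate NOE recovery.  These sizes give stable statistics for each
check while keeping the whole suite fast enough to run routinely.

## Known limitations

- The repetition filter's frequency identity is length-only; a true
  component whose length rounds to an over-threshold key is
  indistinguishable from the artifact class by construction.
- The connectivity score is not dimensionless; cross-study comparison
  requires identical units and identical filter settings.
- Relaxation fitting is single-exponential only; no model-free analysis,
  exchange terms, or diffusion-tensor modeling.
- Quenching analysis assumes purely collisional (linear) behavior; static
  quenching, inner-filter effects and multi-state unfolding thermodynamics
  are out of scope.
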