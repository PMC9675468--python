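# Methods

This note documents the models and procedures `cytostate` implements, the
assumptions behind them, what the synthetic-cohort generator does and does
not emulate, and the numerical choices made where the design was open.

## Preprocessing

Raw CyTOF ion intensities are nonnegative and heavy-tailed. The pipeline
applies the cytometry-standard variance-stabilizing transform
`asinh(x / c)` with cofactor `c = 5` (exposed as a parameter; projection
across cohorts enforces matching cofactors via model metadata). Channel
names in the `Metal_Isotope_Target` dialect are normalized by stripping the
isotope prefix and uppercasing, which is what makes cross-panel
intersection possible during projection.

Subsampling retains at most `n` cells per sample (default 10,000), drawn
without replacement by a per-sample RNG seeded from a hash of
`(global_seed, sample_id)`. Seeding per sample makes every downstream
patient-level output invariant to the order in which sample files are
listed or processed. Barcoding channels (e.g. CD45 isotopes) are removed
before any analysis; inputs are assumed pre-gated for viability.

The FCS 3.1 reader/writer in `cytostate._fcs` is a minimal in-package
implementation for list-mode float32 data (one dataset per file, `$MODE L`,
`$DATATYPE F`); round trips are exact to float32 resolution. CSV event
files are written with `%.17g` floats and read with round-trip parsing, so
CSV round trips are bit-exact.

## Pseudotime

The trajectory model is deliberately simple and deterministic: k-means
centroids (default 50) in 10-component PC space become graph nodes, the
Euclidean minimum spanning tree over centroids becomes the edge set, and
every cell is projected to its nearest point on any edge segment.
Pseudotime is the geodesic distance along the tree from the origin to the
cell's projected point, so cells projected at the origin get exactly 0.
This replaces learned principal graphs with an equivalent construction for
the linear (unbranched) topologies the method targets; branches, if the MST
has them, simply carry independent increasing time. Pseudotime is reported
unscaled by default (patient means are then on the PC-distance scale); a
rescale-to-max-1 option exists.

The origin is the leaf whose assigned cells have the highest mean z-scored
naive-marker (CCR7, CD45RA) expression; ties break to the lower node id
with a warning. PCA uses a deterministic sign convention (each loading's
largest-magnitude entry is positive), making embeddings reproducible across
runs and row permutations.

Marker-versus-pseudotime trends are tri-cube-weighted local means on a
100-point grid with bandwidth 0.15 of the pseudotime range — enough to show
transient mid-trajectory programs without an optimizer. A second,
independent ordering (`comp1_ordering`: the first PC score, oriented so
naive cells sit low, shifted to minimum 0) supports cross-method
concordance checks via pairwise Spearman correlation with BH adjustment.

Assumption to keep in mind: the first-PC ordering only matches geodesic
pseudotime when the state continuum is close to linear in marker space. On
the generator's three-pattern continuum (which bends, because the middle
pattern is transient) the two orderings agree only moderately; on a
two-pattern continuum they are rank-identical.

## Pattern discovery (NMF)

The factorization minimizes squared Frobenius reconstruction error
`‖X − WH‖²` with `W, H ≥ 0`, solved by hierarchical alternating least
squares (HALS): each factor column update is the exact nonnegative
coordinate minimizer, so the recorded per-iteration objective trace is
monotonically nonincreasing. This is a deterministic replacement for
Bayesian sparse-prior NMF samplers that preserves the factor contract the
downstream analysis relies on: continuous nonnegative cell weights and
coregulated marker amplitude sets. It carries no uncertainty intervals and
no sparsity prior — the single largest methodological substitution in the
package.

Initialization is nonnegative double SVD (NNDSVD) with nonpositive entries
filled at `sqrt(mean(X))` times a small seeded jitter. Two details matter:

- the fill magnitude is at the scale of the factors, not near zero — a
  near-zero fill stalls the early HALS sweeps and can leave the solver on a
  plateau short of the optimum, visibly degrading recovery of planted
  patterns;
- `sqrt(mean(X))` has the same degree-½ homogeneity in `X` as the SVD
  factors, which makes the entire fit exactly scale-equivariant: scaling
  the input by `c` leaves the (max-1-normalized) weights unchanged and
  scales the amplitudes by `c`.

After convergence each weight column is divided by its maximum (weights
range 0 to 1) and the inverse scale is absorbed into the amplitude rows, so
`WH` is unchanged and projected weights land directly on the source weight
scale. `k` defaults to 3; stopping is at relative objective change below
`tol` (default 1e-6) or `max_iter` (default 2000). Recovery benchmarks run
the solver deeper (`tol 1e-9`, up to 6000 iterations) because the flat
optimum region of NMF is reached slowly and solutions short of it differ in
exactly the low-weight cells that rank correlations are sensitive to.
Pattern annotation assigns each pattern to the marker program with the
highest mean z-scored amplitude over its signature markers, with suffixed
names and a warning on ties.

Known limitation: at cell-level noise sd 0.1, occasional cohort draws are
intrinsically hard — the global optimum itself (verified against an
independent coordinate-descent solver) recovers the terminal pattern's
weights with rank correlation slightly below 0.9, because cells with
near-zero true weight carry no rank information. This is a property of the
data regime, not the solver.

## Transfer learning (projection)

Projection restricts the source amplitude matrix to the markers shared with
the target panel (after dialect normalization; at least 3 shared markers
required) and solves, per target cell, nonnegative least squares
`min ‖x − wᵀA‖², w ≥ 0` with an active-set solver. Nonnegativity matches
the source factor definition; plain least squares can be recovered by
comparison tools but is not the default. No re-centering or re-scaling of
target markers is applied by default; weights are on the source model's
scale because the source scaling lives in the amplitudes (an optional
per-target max-1 rescale exists). Group comparisons of projected weights go
through the same patient-means + Welch + Holm machinery as native metrics.

## Clustering baseline

The discrete baseline is a kNN graph (default k=20) in PC space with
shared-neighbor (Jaccard) edge weights, partitioned by Leiden optimization
of resolution-parameterized modularity (RBConfiguration objective,
resolution default 1.0, seeded, labels relabeled by decreasing size).
Published resolutions from other toolchains are not portable to this
objective; the resolution is a free parameter, and recovering a planted
k-cluster structure typically needs a lower value than 1.0 on continuous
data. Cluster annotation mirrors pattern annotation (z-scored cluster
marker means against program signatures); per-patient cluster proportions
row-sum to 1. An optional per-batch centering of PC scores stands in for
heavier batch-correction machinery and is off by default.

## Patient metrics and statistics

Patient metrics are arithmetic means of per-cell values per (patient,
timepoint), with cell counts attached and a warning flag below 50 cells.
Group contrasts use Welch's unequal-variance two-sided t-test (a
pooled-variance test is deliberately not the default); within-patient
time-point contrasts use the one-sample t-test on differences. Degenerate
zero-variance inputs follow documented conventions: identical groups give
t=0, p=1; zero variance with unequal means is flagged. Holm–Bonferroni
adjustment is applied within each comparison family (families are defined
in the comparison design, not hard-coded); correlations use Spearman's rho
with BH FDR adjustment.

Survival uses a single-covariate Cox proportional-hazards fit by
Newton–Raphson on the Breslow partial likelihood (gradient tolerance 1e-8,
max 50 iterations, steps clipped to ±2). The default stratifier is the
median split of a patient-metric column, with ties at the median assigned
to "low" (a deterministic, documented convention); the continuous metric
can be used as the covariate directly. Monotone likelihood (complete
separation) is detected and flagged, with the confidence interval reported
as unbounded. Note that a two-group design in which one group holds all the
latest events is completely separated and has no finite estimate — small
test designs must interleave events across groups.

## Synthetic cohorts: what they emulate and what they do not

Each cell carries a latent state `t ∈ [0,1]` drawn from a Beta distribution
with mean `0.35 + group shift + timepoint shift + patient effect`
(concentration 4, mean clipped to [0.02, 0.98]). Patient effects are
Gaussian with sd 0.05 — chosen once as a realistic level of inter-patient
heterogeneity; it is what gives patient means a nondegenerate within-group
variance. Weight curves map `t` to `k` patterns: `(1−t)²` for the first
(naive) pattern, `t²` for the terminal pattern, and Gaussian bumps (width
0.16) centered on an interior grid for transient intermediates. Expression
on the arcsinh scale is `weights × amplitudes` plus Gaussian noise (sd 0.1
by default), mapped back to the raw ion scale by `sinh(·) × cofactor` and
floored at 0. Archetype amplitudes put signature markers at 2–3 (arcsinh
scale) and everything else at a 0.02–0.4 baseline, so each program's
signatures are strictly maximal in their own pattern.

Survival is exponential per patient with log-hazard
`log(h₀) + β × (patient-mean terminal weight)` (baseline hazard 0.03,
link β configurable, 0 by default); censoring marks a patient censored with
the configured probability and uniformly shortens the observed time.

Deliberate simplifications: the state continuum is 1-D and unbranched
(matching the linear naive→exhausted and naive→memory/effector transitions
the metrics target); noise is Gaussian on the transformed scale, not a
count model on raw ions; there are no doublets, debris, bead events,
spillover, acquisition drift, or batch effects (batch is a constant
column). Passing recovery tests on these cohorts therefore demonstrates the
correctness of the inference machinery on clean continuum-structured data,
not robustness to the full noise anatomy of real CyTOF runs.

## Benchmark configurations

The recovery benchmarks (tests and `scripts/acceptance.py`) use:

- a neutral single-group cohort of 10 patients × 500 cells (5,000 cells ×
  30 markers, 3 patterns, noise sd 0.1) for NMF, pseudotime and projection
  recovery — neutral so that recovery is measured without confounding group
  structure; NMF run at `tol 1e-9`, ≤6000 iterations;
- 50 smaller cohorts (3 patients × 500 cells, 30 trajectory nodes) for the
  origin-autoselection rate;
- 100 replicates of a 200-patient two-arm exponential survival design
  (planted HR 2, ~20% censoring) for hazard-ratio recovery, and 200 null
  replicates for the rejection rate;
- 1,000 reduced null cohorts and 100 shifted cohorts (12 patients/group ×
  500 cells) for the type-I error and power of the simulate → patient-means
  → Welch chain. The default planted shift (0.4 on the latent-state mean)
  produces a patient-mean difference of well over one pooled SD, the regime
  in which near-certain detection at p < 0.001 is expected.

These sizes are the package's own benchmark choices; all are regenerated at
run time from seeds.
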