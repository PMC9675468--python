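# cytostate

Continuous, patient-level T cell state metrics from mass cytometry (CyTOF).

Clinical immune monitoring usually summarizes cytometry data as discrete
cluster abundances. That throws away the continuous structure of T cell
biology — exhaustion and memory differentiation are gradual transitions, not
category switches — and can under- or overestimate differences between patient
groups. `cytostate` implements the complementary continuous workflow for
cohorts of per-sample CyTOF event tables:

1. **Preprocessing** — read FCS 3.0/3.1 or CSV event tables, normalize
   channel names (`Er168Di_CCR7` → `CCR7`), subsample cells per sample,
   remove barcoding channels (CD45 isotopes), and apply the arcsinh
   transform `x ↦ asinh(x / c)` with cofactor `c = 5`.
2. **Pseudotime** — PCA to 10 components, a principal graph (k-means
   centroids joined by a Euclidean minimum spanning tree), origin selection
   at the leaf with the highest naive-marker (CCR7⁺CD45RA⁺) score, and
   per-cell pseudotime as geodesic distance along the tree (0 at the origin).
3. **Patterns** — nonnegative matrix factorization `X ≈ W H` of the
   transformed matrix into cell-level pattern weights `W` (each column
   scaled to a maximum of 1) and marker-level amplitudes `H`, annotated to
   programs (naive, pre-exhaustion, exhaustion; or naive, memory, effector).
4. **Transfer learning** — projection of new cohorts onto learned
   amplitudes by per-cell nonnegative least squares, restricted to the
   shared marker panel, so signatures learned in one study can score
   another even when the antibody panels differ.
5. **Patient metrics and statistics** — per-patient means of pseudotime
   and pattern weights, cluster proportions (kNN + Leiden) as the discrete
   baseline, Welch and paired t-tests with Holm–Bonferroni adjustment,
   Spearman correlations with Benjamini–Hochberg FDR, and median-split Cox
   proportional-hazards survival fits.

A first-class synthetic-cohort generator (`cytostate.simulate`) plants a
latent 1-D state continuum per cell with group effects, paired time points,
patient heterogeneity and survival linked to pattern weights, so the whole
pipeline is testable end to end without patient data.

## Worked example

```python
import cytostate as cs
from scipy.stats import spearmanr

cfg = cs.CohortConfig(n_patients_per_group=6, n_cells_per_sample=1000, seed=0)
matrix, metadata, truth = cs.simulate_cohort(cfg)
cohort = cs.arcsinh_transform(matrix)
panel = cs.PanelSpec(markers=cohort.markers, programs=truth.archetypes.marker_programs)

emb = cs.pca_reduce(cohort, d=10)
traj = cs.fit_principal_graph(emb, n_nodes=50, seed=0)
cs.select_origin(traj, cohort, panel)
pt = cs.compute_pseudotime(traj)

model = cs.annotate_patterns(cs.fit_patterns(cohort, k=3, seed=0, n_iter=4000, tol=1e-9), panel)
print("patterns:", model.labels)
print("pseudotime vs latent state rho = %.3f" % spearmanr(pt, truth.latent_state).statistic)

pm = cs.patient_means(model.weights["exhaustion"].to_numpy(), cohort.cell_meta,
                      name="mean_weight_exhaustion")
pm = pm.merge(metadata[["patient_id", "group"]].drop_duplicates(), on="patient_id")
res = cs.unpaired_ttest(pm.loc[pm.group == "A", "mean_weight_exhaustion"],
                        pm.loc[pm.group == "B", "mean_weight_exhaustion"])
print("exhaustion weight, group A vs B: t = %.2f, p = %.2e" % (res.statistic, res.p))
```

Output:

```
patterns: ['preexhaustion', 'exhaustion', 'naive']
pseudotime vs latent state rho = 0.999
exhaustion weight, group A vs B: t = -15.09, p = 7.28e-06
```

The three NMF patterns are automatically annotated to the planted marker
programs; inferred pseudotime is rank-identical to the latent cell state; and
the planted group shift (group B sits further along the exhaustion continuum)
is detected in the patient-mean exhaustion weight (negative t: group A mean
is lower).

The same stages are available from the shell:

```bash
cytostate simulate --out data/ --seed 1
cytostate patterns --input-dir data/ --panel panel.json --k 3 --seed 0 --out-dir model/
cytostate run-all --config pipeline.json
```

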