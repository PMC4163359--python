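# Methods

## Pipeline model

Each subject contributes a (timepoints × ROIs) matrix of parcellated BOLD
time series. Functional connectivity is the Pearson correlation between
every ROI pair; the correlation matrix doubles as the adjacency matrix of
an undirected weighted graph and, thresholded, of three binary graphs.
Node-centrality vectors computed on these graphs are the classifier
features; discrimination between diagnostic groups is estimated by
leave-one-subject-out cross-validation (LOOCV) of a linear SVM, and the
trained hyperplane's coefficients localize the discriminative nodes.

## Conventions fixed project-wide

Several steps admit more than one defensible convention. The choices below
are fixed across the package and noted at the operation that implements
them:

* **Negative correlations** are excluded from the weighted graph (clipped
  to 0). Eigenvector centrality needs a nonnegative matrix for its Perron
  vector to be the meaningful object, and Burt's constraint interprets
  weights as investment proportions; positive cut-offs for the binary
  graphs point the same way. The count of clipped entries is recorded on
  each `WeightedGraph` so the alternative (retaining anticorrelations)
  can be studied later.
* **Binarization** uses strict `r > cutoff`. This keeps the three edge
  sets nested (0.25 ⊆ 0.15 ⊆ 0.1), which is asserted as a property test.
  No Fisher-z or absolute-value transform precedes thresholding.
* **Weighted path length** is `1/weight` — the standard similarity→cost
  transform; correlations are similarities, shortest-path algorithms need
  costs.
* **Closeness** of node *i* is |R(i)| / Σ_{j∈R(i)} d(i,j) over the nodes
  reachable from *i*: the reciprocal mean distance within the component.
  Isolated nodes score 0. This avoids infinite distances on disconnected
  subject graphs while preserving within-component ordering.
* **Betweenness** is the unnormalized Freeman sum of fractional
  shortest-path counts ρ_hj(i)/ρ_hj, endpoints excluded. Distances come
  from Dijkstra (scipy csgraph); per source, path counts σ and
  dependencies δ are propagated through the distance-ordered predecessor
  DAG by unit-triangular solves — Brandes' recursion in matrix form, which
  vectorizes well at n = 400. Raw (unnormalized) values are fine because
  features are standardized before classification.
* **Eigenvector centrality** is the leading eigenvector of the adjacency,
  max-normalized to 1, by power iteration from the uniform vector
  (sup-norm tolerance 1e-10, ≤1000 iterations, non-convergence raises with
  diagnostics). Iteration runs on the shifted matrix A + 0.1·(max
  strength)·I: the shift leaves eigenvectors unchanged but makes the
  Perron vector strictly dominant even on bipartite-dominant graphs (a
  star's spectrum is ±λ, where unshifted power iteration oscillates with
  period 2). On disconnected graphs the output concentrates on the
  component with the largest eigenvalue; the uniform start makes tie
  behaviour deterministic.
* **Burt's constraint** is Σ_{j∈N(i)} (p_ij + Σ_q p_iq p_qj)² with
  p_ij = a_ij/Σ_k a_ik. Isolated nodes get 0 with a per-node degeneracy
  flag rather than NaN, keeping feature matrices complete.

## Classification

* Linear SVM with fixed C = 1 (exposed in the config, never tuned on test
  folds). Centrality families live on wildly different scales (betweenness
  vs constraint), and max-margin classifiers are scale-sensitive, so
  features are standardized per LOOCV fold using training-fold mean/sd
  only; the held-out row is transformed with those statistics. A leakage
  test asserts the scaler ignores the held-out subject.
* The positive class is the patient group (all ADHD in the control task,
  the combined subtype in the subtype task), so *sensitivity* means
  patient detection. A single-class training fold predicts that class,
  keeping the LOOCV fold count equal to n under extreme imbalance; an
  all-identical feature table therefore collapses to the constant-majority
  triple (100%, 0%, 50%).
* The balanced score (sensitivity + specificity)/2 is the headline metric;
  integer-percent reporting rounds half away from zero (76.5 → 77%).
* Discriminative maps rank ROIs by |hyperplane coefficient| in the
  standardized feature space (ranking raw-space weights would conflate
  scale with importance), select ⌈0.05·n⌉ nodes with ties broken by
  ascending index (deterministic output), and are emitted when the cell's
  score clears the reporting gate (default 0.70; the gate is metadata, not
  part of the ranking).
* Pooled ("all"-scope) analyses concatenate sites with no harmonization or
  site covariate — deliberately, since the site-vs-pooled contrast is part
  of what the pipeline measures. Site means in `mean_vs_pooled` are
  unweighted.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-site paediatric
resting-state release, not its physiology:

* **Latent structure**: ROIs partitioned into `n_modules` contiguous
  blocks with constant within-module (default 0.35) and between-module
  (default 0.05) correlation — a stand-in for resting-state networks with
  a closed-form PSD guarantee (defaults: 400 ROIs, 8 modules).
* **Group effect**: every off-diagonal correlation incident to the
  `effect_nodes` set (default: 20 nodes, 5% of 400) is shifted by
  `effect_size` (default 0.2), clipped to ±0.99, then projected back to a
  correlation matrix (eigenvalue clipping + re-standardization). With
  three groups and one effect knob, the per-group multiplier is
  control 0, inattentive 0.5, combined 1.0 — controls sit at baseline,
  the combined presentation carries the full shift, and the inattentive
  group is intermediate, so both classification tasks are discriminable.
* **Subjects**: i.i.d. draws from N(0, Σ_group + σ²I) with site-specific
  noise σ and scan length. Putting the noise in the covariance (rather
  than post hoc on the series) keeps the subject-level target correlation
  analytically known: r_observed = r_latent/(1+σ²). Default sites mirror a
  five-site release with 609 subjects (340/159/110 across groups), one
  approximately balanced site and one site with very few combined
  subjects; scan lengths 100–232 timepoints and noise 0.4–0.8 vary by
  site.
* **Seeding**: per-subject generators derive from
  `SeedSequence(master_seed, spawn_key=(site_index, subject_index))`, so
  cohorts are bit-reproducible and independent of execution order.

Not modelled: haemodynamics, temporal autocorrelation, motion or other
structured artefacts, voxel-space data, and realistic effect sizes — no
reliable estimate of real between-group connectivity differences exists to
calibrate against, so `effect_size` defaults are chosen for testability.
Passing tests therefore demonstrate the *pipeline's* correctness and
calibration (null cohorts score at chance; planted effects are recovered),
not expected performance on real cohorts, where heterogeneity demonstrably
erodes predictive value.

## Test and simulation sizes

Oracle equivalence uses 200 random graphs (n ≤ 12) against brute-force
references (Floyd–Warshall, pruned exhaustive path enumeration, dense
eigendecomposition, direct formula loops) at tolerance 1e-8, plus an
independent python-igraph cross-check. Null calibration uses 100
effect-free cohorts of 60 subjects × 100 ROIs; signal recovery uses 20
cohorts of 80 subjects × 400 ROIs with effect 0.3 on 10 nodes; the
structural-fidelity run exercises the full default battery at 400 ROIs on
a 14-subject cohort. These sizes keep the full suite comfortably
desk-scale while exercising the pipeline at the parcellation size it
targets.

## Numerical notes

* Shortest-path equality tests in the betweenness predecessor DAG use a
  relative tolerance of 1e-9; with continuous random weights, ties at that
  scale are measure-zero, and Dijkstra's tree edges satisfy the equality
  exactly.
* PSD checks accept eigenvalues down to −1e-8·max(1, λ_max) before
  rejecting; the sampling factor clips negatives to zero.
* Zero-variance features inside an LOOCV fold get sd = 1 (they become
  constant zero after centring and carry no weight).
* Degenerate cases are total, not exceptional: empty graphs yield all-zero
  centrality vectors; isolated nodes yield closeness 0 and flagged
  constraint 0; infeasible (task, scope) cells become explicit skip
  records with a reason string rather than missing rows.
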