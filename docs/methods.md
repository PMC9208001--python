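# Methods

This note documents the models, conventions and design choices behind
`hierconn`, in the order the pipeline runs them.

## Synthetic cohort model

Each scan is a node × time matrix of i.i.d. multivariate normal timepoints,
`x_t ~ N(0, R_arm + σ² I)` with `σ = noise_sd`.  There is no temporal
autocorrelation, hemodynamic model, scanner noise or motion simulation: every
downstream statistic consumes only the Pearson matrix, for which stationary
Gaussian draws are sufficient.  The diagonal noise inflation shrinks the
observable correlations by `1/(1+σ²)`; the default `σ = 0.5` (factor 0.8)
puts empirical edge weights in the range typical of resting-state FC and
leaves the planted tier gaps resolvable at 230 timepoints, where the
sampling error of a correlation is ≈ 1/√T ≈ 0.066.

The target correlation `R_arm` plants three node tiers:

* modules: `n_modules` contiguous blocks; within-module correlation 0.30,
  between-module 0.05 (defaults);
* rich tier: `richclub_size` hub nodes dealt round-robin over the first half
  of the modules (the "core" modules); every hub ↔ core-tier pair gets a
  bonus of 0.35;
* feeder tier: the remaining nodes of the core modules; peripheral tier:
  the nodes of the non-core modules.

The hub bonus is deliberately restricted to hub ↔ core-tier edges.  If hubs
were boosted toward *all* nodes, every node would retain an edge to a hub
after thresholding and the peripheral class would be empty; concentrating
the core makes the generator produce the three-tier hierarchy the analysis
is designed to detect.  With the defaults (90 nodes, 6 modules, 13 hubs)
the planted tiers are 13 rich / 32 feeder / 45 peripheral, and the
classification stage recovers them exactly at 230 timepoints.

Disease and medication arms modify `R`:

* **OFF**: all core-tier internal pairs (both endpoints rich or feeder) are
  multiplied by `1 − attenuation_delta` (default 0.3) and
  peripheral–peripheral pairs by `1 + peripheral_boost_beta` (default 0.1).
  Attenuating the whole core — not only hub-incident edges — is what makes
  feeder-subnetwork strength fall in OFF, matching the qualitative pattern
  the pipeline is meant to recover; the peripheral boost models the
  compensatory degree increase of the periphery.
* **ON**: core pairs are multiplied by `1 − attenuation_delta·(1 −
  restoration_rho)` (default restoration 0.8) and the peripheral boost is
  absent, modeling the normalization under dopaminergic medication.

After the multiplicative edits the matrix is repaired to the nearest
positive-semidefinite correlation matrix by eigenvalue clipping at zero
followed by rescaling to unit diagonal — deterministic, and an identity
whenever the construction is already PSD.  `attenuation_delta = 0` with
`peripheral_boost_beta = 0` yields a null cohort whose arms are
exchangeable in distribution.

Covariates: age ~ N(60, 8²) years and sex ~ Bernoulli(0.5) are drawn
independently of group (matching a demographically matched study); an
optional `confound_age_shift` adds years to patients to exercise covariate
adjustment.  Mean framewise displacement is lognormal (median 0.15 mm,
σ_log = 0.4), uncorrelated with group.  Patient OFF/ON scans share age and
sex through the pair id but are drawn independently — paired tests remain
valid, they just get no within-pair correlation benefit.

What passing tests on these cohorts do **not** show: robustness to temporal
autocorrelation (which inflates correlation sampling variance), to motion
artifacts, to atlas or preprocessing choices, or to non-Gaussian BOLD
statistics.  The generator validates the *analysis machinery*, not the
physiology.

## Network construction

* FC = Pearson correlation of node time courses; negative correlations are
  set to zero **before** thresholding; the diagonal is zero.
* Proportional thresholding keeps the `round(S·n(n−1)/2)` strongest positive
  edges (round half away from zero; at n = 90, S = 0.2 this is 801 edges).
  The rounding rule is a convention the source material leaves open; it is
  fixed here and used everywhere.  Ties at the cutoff break by ascending
  (i, j) node index, so thresholding is deterministic, idempotent, and
  edge sets nest across densities.  Networks stay weighted; "degree" always
  means the binary count of retained edges, "strength" the weight sum.
* Consensus group average: an edge is kept iff nonzero in ≥ 60% of subjects
  (inclusive, configurable) and its weight is the mean over the subjects in
  which it is nonzero.
* Every scan is thresholded independently, including a patient's ON scan.

## Graph metrics

* Rich-club: `φʷ(k) = W₍>k₎ / Σ top-E₍>k₎ weights`, club membership by
  strict `degree > k`; undefined (NaN) where fewer than two nodes qualify
  or no club-internal edge exists.  This is the standard weighted rich-club
  ratio used by the common connectome toolboxes.
* Null model: degree-preserving double-edge swaps with weights traveling on
  the edges, 10 swap attempts per edge per surrogate, rejecting self-loops
  and duplicate edges; degree sequence and weight multiset are conserved
  exactly.  The normalized curve divides by the null-ensemble mean per k
  (NaN-aware); a null mean of zero yields an absent value.
* Communities: Louvain modularity maximization at resolution 1.0, best of
  `n_restarts` seeded restarts (default 100) — deterministic given the seed
  and cheaper than consensus clustering.  Isolated nodes become singletons.
* Participation coefficient uses binary edge counts `κ_is`, consistent with
  the binary degree convention (a weighted variant is available behind a
  flag).
* Global efficiency maps weights to lengths `l = 1/w` (the toolbox
  convention; `−log w` was rejected for comparability), takes Dijkstra
  shortest paths, and averages `1/d` with disconnected pairs contributing
  zero.  Subgraphs with fewer than two nodes have efficiency 0.

## Hierarchy

Rich nodes are the top `floor(0.15·n)` by degree (13 of 90; the floor is
fixed by that printed count), ties broken by strength then node index.
Feeder status is judged on the control group-average network only — subject
networks never re-classify.  Per-scan reports tally class strengths, class
efficiencies on induced subgraphs, whole-network degree sums per class, and
rich–feeder / feeder–peripheral interactions; rich–peripheral edges belong
to no named subnetwork and are tracked separately so that the edge-weight
conservation identity (class strengths + interactions + rich–peripheral =
total weight) can be asserted on every report.  Medication change rates are
`(OFF − ON)/OFF` (and the negated improvement rate), with zero-OFF pairs
flagged NaN and excluded from correlations.

## Inference

* Group contrasts use the Freedman–Lane scheme: residualize the outcome on
  the nuisance covariates, permute the residuals, re-residualize, and
  recompute the adjusted mean-difference statistic (a t-statistic variant is
  available behind a flag; under residual permutation the two give the same
  ordering for equal-variance designs).  Monte-Carlo p-values use the
  `(1+b)/(1+m)` convention; when there are no covariates and the number of
  distinct group assignments is at most `n_perm`, the test switches to
  exhaustive enumeration and reduces exactly to the classical two-sample
  permutation test.  The group indicator must not be collinear with the
  covariates.
* The paired OFF/ON comparison gates on a one-sample Kolmogorov–Smirnov
  test of the differences against a fitted normal at α = 0.05: paired t if
  normality is not rejected, Wilcoxon signed-rank otherwise; the branch
  taken is recorded.  All-zero differences are reported as degenerate with
  p = 1.
* BH-FDR is the statsmodels step-up; its agreement with a literal
  brute-force step-up is part of the test suite.
* NBS: per-edge two-tailed GLM t tests for the group effect (two-tailed
  because the direction is not prespecified), suprathreshold graph at the
  primary p, components scored by edge count against the Freedman–Lane
  permutation null of the maximum component size.
* Partial correlations residualize both variables on the covariates and use
  a t reference with `n − 2 − c` degrees of freedom; each result carries its
  Bonferroni family (27 for property–symptom analyses, 4 for the degree
  coupling analyses) and the implied per-test threshold.
* Uncorrected findings are never hidden: every record carries the raw p,
  the correction family, and the FDR/Bonferroni status.

## Sparsity selection

`as_published` mode fits the two-sample-t feature filter (p < 0.05) and the
per-feature [−1, 1] scaling on the full sample before leave-one-out
cross-validation, replicating the published procedure (LIBSVM-style
defaults: C = 1, RBF kernel, width 1/n_features); `nested` mode refits both
inside every training fold and is the statistically clean choice for new
analyses — the two can differ substantially at small n, which is exactly
the leakage the mode switch makes visible.  Ties in accuracy select the
lowest sparsity.  The label-permutation test re-runs the classification at
the selected sparsity only.

## Orchestration, seeds, problem sizes

`run_full_analysis` derives every stage seed from the single config seed by
fixed offsets, so identical configs give byte-identical report bundles
(JSON with sorted keys; no timestamps in outputs, timings go to the log).
A stage failure aborts with a stage-named message; files already written
(cohort table, classification, subnetwork reports) are kept.

Defaults mirror the emulated study design: 90 nodes, 230 timepoints,
30 + 30 subjects, sparsity 0.2, 1,000 rewiring nulls, 10,000 group
permutations, 5,000 NBS permutations.  The test suite and the acceptance
script run the same code at reduced sizes chosen to keep the full
validation loop interactive — e.g. 100 nulls for rich-club calibration,
500 permutations inside calibration loops, 20 cohort replicates for
recovery rates; each reduced size is stated where it is used.

## Known limitations

* The exact weighted rich-club formula of the emulated study was published
  only in supplementary material not available here; the standard toolbox
  definition is used.  If the original differs, only `rich_club_raw`
  changes.
* The community-detection algorithm behind the published diverse club is
  unspecified; Louvain at resolution 1.0 is this package's choice.
* Whether published "degree centrality" is binary degree or weighted
  strength is ambiguous; binary degree is the default, strength is a flag.
* Clinical scores are out of scope: the family-27 correlation machinery is
  exercised on synthetic scalars only (supply a `clinical_score` column to
  use it on real data).
* LOOCV accuracy at small n sits slightly below 50% under the null because
  removing one subject unbalances the training classes; this is a property
  of the procedure, not a bug.
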