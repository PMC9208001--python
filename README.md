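# hierconn

Hierarchical analysis of weighted functional connectomes: rich-club / feeder /
peripheral node taxonomy, diverse-club analysis, and covariate-adjusted
permutation inference, with a synthetic-cohort generator for end-to-end
validation.

## The problem

Resting-state fMRI studies of Parkinson's disease (and other disorders)
describe the brain as a weighted network: nodes are atlas regions, edge
weights are Pearson correlations between regional time courses.  A small set
of high-degree *rich-club* nodes forms a densely interconnected core; the
non-rich nodes that connect to it are *feeder* nodes and the remainder are
*peripheral*.  Comparing the three class-induced subnetworks between
patients OFF medication, the same patients ON medication, and controls asks
whether disease (and dopaminergic treatment) acts preferentially on the
network core — and whether the periphery compensates.

This package implements that complete analysis for anyone with per-subject
node × time matrices (or precomputed connectivity matrices) and a cohort
table.  It is atlas-agnostic: nodes are abstract labels.

## The statistics at its core

* **Weighted rich-club coefficient.**  For each degree level *k*, with
  *E₍>k₎* edges of total weight *W₍>k₎* among the nodes of degree > *k*,

  φʷ(k) = W₍>k₎ / Σ (the E₍>k₎ largest weights in the network),

  normalized as φʷ_norm(k) = φʷ(k) / ⟨φʷ_rand(k)⟩ over degree-preserving
  double-edge-swap surrogates (weights travel with edges).  φʷ_norm(k) > 1
  over a range of *k* indicates rich-club organization; presence is tested
  per *k* with one-sided one-sample t tests under BH-FDR.
* **Node taxonomy.**  Rich = top 15% of nodes by degree on the control
  consensus group-average network (exactly 13 of 90 nodes); feeder = non-rich
  nodes adjacent to a rich node; peripheral = the rest.  The *diverse club*
  is the analogous top 15% by participation coefficient
  P_i = 1 − Σ_s (κ_is/k_i)² over Louvain communities.
* **Subnetwork metrics per scan.**  Connection strength (weight sum within a
  class), weighted global efficiency (edge lengths 1/w), whole-network degree
  sums per class, and rich–feeder / feeder–peripheral interaction strengths.
* **Inference.**  Freedman–Lane permutation tests with age and sex as
  covariates (10,000 permutations; exhaustive for tiny groups); paired t or
  Wilcoxon tests gated by a Kolmogorov–Smirnov normality check for the
  OFF/ON contrast; network-based statistic (NBS) with a p < 0.05 primary
  threshold and a 5,000-permutation maximum-component-size null within the
  rich-club and feeder edge sets; partial correlations with Bonferroni
  families of 27 (0.05/27 = 0.00185) and 4 (0.0125).
* **Sparsity selection.**  Networks are proportionally thresholded; the
  density is either fixed (0.2 by default) or selected by LOOCV accuracy of
  an RBF-kernel SVM (C = 1, t-test feature filter, [−1, 1] scaling) over the
  grid 0.10–0.50 in steps of 0.02, with a label-permutation significance
  test.

The synthetic generator (`hierconn.simcohort`) draws Gaussian time series
from planted modular + rich-club correlation structure, with a patient-OFF
effect that attenuates core-tier edges and boosts peripheral–peripheral
edges, and an ON effect that partially restores the attenuation — so every
pipeline stage is testable with known ground truth.

## Worked example

```python
from hierconn import AnalysisConfig, SimConfig, run_full_analysis

cfg = AnalysisConfig(
    sim=SimConfig(n_controls=20, n_patients=20, seed=7),
    sparsity=0.2, n_nulls=50, n_perm_group=2000, n_perm_nbs=500,
    n_restarts=20, seed=7, outdir="demo",
)
report = run_full_analysis(cfg)
```

With this seed the run prints (via `report`):

```
rich nodes: 13 [0, 1, 2, 3, 4, 15, 16, 17, 18, 30, 31, 32, 33]
feeder/peripheral: 32 45
planted hubs recovered: True
strength_rich          stat=-9.31   p=0.0005   FDR=True
strength_feeder        stat=-17.34  p=0.0005   FDR=True
degsum_peripheral      stat=+172.35 p=0.0005   FDR=True
OFF degree coupling r=-0.737 p=4.85e-04 (threshold 0.0125)
NBS rich-club component sizes: [78] FWE p: [0.002]
```

Reading: of the 90 nodes, the 13 planted hubs are recovered as the rich
club.  Patients OFF medication have significantly weaker rich-club and
feeder subnetwork strength than controls (negative covariate-adjusted mean
differences, permutation p at the resolution floor, FDR-significant), while
the summed degree of peripheral nodes is *higher* — and across OFF scans
peripheral degree is negatively coupled to rich-club degree (r = −0.74,
below the family-of-4 Bonferroni threshold), the compensation signature.
NBS finds one suprathreshold component spanning all 78 rich-club edge pairs
with familywise-corrected p ≈ 0.002.

The same pipeline runs from the shell:

```bash
hierconn simulate --out cohort/ --seed 7
hierconn run --input-dir cohort/ --sparsity 0.2 --out results/ --seed 7
hierconn select-sparsity --input-dir cohort/ --mode as_published --out sel.json --seed 7
```

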