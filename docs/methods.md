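# Methods

`funconn` implements a graph-theoretical analysis of paired (pre/post)
resting-state functional-connectivity data, of the kind used to ask whether
a motor-learning or balance intervention reorganizes a brain network. This
note documents the model, the choices that were genuinely open, and what
the synthetic validation does and does not show.

## Network construction

A subject's session is a node × timepoint matrix (one row per parcellation
region). Edges are Pearson correlations between node time courses; the
matrix is symmetric with zero diagonal. Only positive correlations are
eligible as edges — negative functional correlations are discarded, not
rectified.

Sparsification is proportional ("sparsity") thresholding: at retention
fraction *p* the strongest `floor(p · n(n−1)/2)` positive edges are kept
with their weights (never binarized). Choices the convention leaves open,
fixed here:

* the denominator is all possible undirected pairs `n(n−1)/2`, not the
  count of positive edges, so *p* is a true network density;
* `floor()` for the quota;
* ties at the cutoff are broken by ascending `(i, j)` node order, which
  makes the sweep deterministic and the edge sets nested across *p*;
* if fewer positive edges exist than the quota, all are kept and a
  `SubQuotaWarning` records the achieved density (sparser-than-nominal
  networks are legitimate, not an error).

The default grid covers densities 0.06 to 0.40 in steps of 0.02 (18
thresholds). Per-threshold metric values are collapsed to a trapezoidal
area under the curve (AUC) against density, so group inference never
depends on one arbitrary threshold.

## Graph parameters

Six parameters, all on weighted undirected networks, with path lengths
`l_ij = 1/w_ij`:

* **Global Efficiency** — mean of `1/d_ij` over ordered pairs
  (`1/∞ := 0`); network integration.
* **Nodal Efficiency** (target node) — mean inverse distance from the
  node to all others; node integration.
* **Local Efficiency** (target node) — Global Efficiency of the subgraph
  induced by the node's neighbours, node removed, weights retained; 0 with
  fewer than two neighbours. This is the subgraph operationalization; the
  alternative cube-root path-triangle formula from the literature is
  deliberately not offered — one definition, stated and tested.
* **Modularity Q** — Newman's weighted Q at a partition found by seeded
  greedy multi-level (Louvain) optimization; the best of `restarts`
  independent seeded runs is reported (default 10 in the API, fewer in the
  large sweeps; see problem sizes below). Q evaluation is exact and
  separately testable from the optimizer.
* **Degree Centrality** — node strength (sum of incident weights); the
  input to hub classification.
* **Small-Worldness** — `σ = (C/C_rand)/(L/L_rand)` on the largest
  connected component. `C` is the mean Onnela clustering coefficient
  (geometric mean of triangle weights, max-normalized; the normalization
  cancels in the ratio). `L` is the characteristic path length over
  reachable pairs. The null ensemble preserves the degree sequence by
  Maslov–Sneppen double-edge swaps in which each edge carries its weight
  along every swap, so the weight multiset and total weight are conserved
  exactly; defaults are 100 nulls at 10 attempted swaps per edge. On a
  complete graph no legal swap changes anything, so σ = 1 identically —
  a useful exactness check.

All metrics except σ are computed on the thresholded network as-is,
including isolated nodes; no largest-component extraction.

A very sparse network can draw a null ensemble with no triangles at all
(`C_rand = 0`), for which σ is undefined. The strict API raises;
`small_worldness_robust` redraws the ensemble with a shifted seed, which
conditions the estimate on non-degenerate draws and is what the pipeline
uses. At realistic sizes (≥ 100 nodes, densities ≥ 0.06, ensembles ≥ 10)
degeneracy is effectively never seen.

## Hubs

Degree-centrality values from every node, threshold, subject and both
sessions are pooled into one distribution; the hub cutoff is
`mean + 1 × SD` (sample SD, inclusive ≥). Hub counts per subject/session
sum flags over nodes *and* thresholds — the pooled procedure uses no AUCs.
Counting per threshold and averaging is the natural alternative; summing
is the default because it keeps counts integral.

## Inference

Each parameter is compared pre vs post with a dependent test on
per-subject summaries (AUC, or hub count). Normality of the paired
differences is checked with Shapiro–Wilk at α = 0.05; normal → paired
t-test, otherwise Wilcoxon signed-rank (exact p where SciPy's policy
permits). All tests two-sided. Bonferroni correction uses the fixed
six-parameter family (m = 6). The effect size is
`d_z = mean(diff)/SD(diff)`; an "average-variance" d (mean difference over
the pooled SD of pre and post) is available via `effect_size="av"` since
intervention studies often report that flavour and the two can differ
noticeably.

The stability analysis repeats all six comparisons, uncorrected, for each
parcellation spec on three grids: total (6–40%), lower half (6–22%) and
upper half (24–40%). Cells decided by the Wilcoxon fallback are flagged
`non_comparable`: a W statistic cannot be read against t values.

## Synthetic cohorts

Real resting-state cohorts for this design are rarely shareable, so the
generator is a first-class module. It emulates: 23 subjects × 2 sessions,
116 nodes in 8 communities, 260 timepoints. Signals are multivariate
Gaussian draws from a block correlation matrix (`within = 0.40` inside
communities, `between = 0.08` elsewhere — typical resting-state
within/between-network correlation magnitudes). Per-subject heterogeneity
is symmetric Gaussian jitter (sd 0.05) on the off-diagonal correlations,
shared between a subject's two sessions so that paired differences are
driven by the session effect and sampling noise only. Matrices are
repaired to positive definite by eigenvalue clipping at 1e-8 followed by
re-standardization to unit diagonal. Everything derives from one seed via
`numpy` `SeedSequence` spawning; panels are bit-reproducible.

The intervention analogue raises every off-diagonal correlation among
{target node} ∪ its designated neighbourhood (the first
`neighbourhood_size` members of the target's community) by `effect_delta`
in the post session, before repair. Raising neighbour–neighbour edges (not
only target-incident ones) is deliberate: Local Efficiency measures
exactly that neighbourhood's mutual connectivity.

No temporal autocorrelation, haemodynamics, motion or physiological
confounds are modelled: the pipeline consumes Pearson correlations, for
which timepoint ordering is irrelevant. Passing tests therefore validate
the graph/inference machinery, not robustness to realistic fMRI noise.

### Effect-size calibration

The target effect scale is a standardized Local-Efficiency AUC difference
of d ≈ 0.89 — the magnitude of focal change this kind of intervention
study reports. `effect_delta` was calibrated once by simulation on the
replicate-study cohort (below): sweep `effect_delta`, run 40 cohorts each,
average the realized `d_z`; `effect_delta = 0.15` gives mean d_z ≈ 0.87
and is the frozen default. On the full-size 116-node default cohort the
same delta realizes a somewhat larger per-cohort d_z (≈ 0.9–1.3), because
the designated block sits more compactly inside the target's thresholded
neighbourhood there; the default was not re-tuned per configuration.

### What the injection does to the global parameters

The injection is *localized but not globally invisible*: under
proportional thresholding the boosted block occupies top weight ranks and
displaces edges elsewhere, which shifts Small-Worldness slightly downward
(replicate-study d_z ≈ −0.13; larger in magnitude at full 116-node scale).
Modularity is essentially untouched (d_z ≈ 0.09). This mirrors how such
designs behave empirically — a focal connectivity change leaves global
parameters statistically non-significant at n = 23 without their effect
sizes being exactly zero — and is measured, not hidden: the power study
reports raw rejection rates for both global parameters alongside the
corrected Local-Efficiency power.

## Problem sizes used in validation

Replicate-cohort studies (`funconn.studies`) keep n = 23 subjects and 260
timepoints but use a proportionally reduced parcellation — 48 nodes, 4
communities, neighbourhood 4, so the injected block covers the same ~1%
share of node pairs as in the full-size design — with a light σ ensemble
(3 nulls, 2 swaps per edge) and single-restart Louvain. The type-I study
runs 200 null cohorts; the power study 100 effect cohorts. These sizes are
the package's own trade-off between Monte-Carlo resolution and desk-scale
runtimes; the per-network computations are the pipeline's production code
paths throughout.

## Known limitations

* Gaussian, temporally white signals; no confound structure.
* Parcellations are abstracted to node counts and a target-node index; no
  atlas geometry, so cross-parcellation stability compares independently
  simulated panels, not re-parcellations of the same data.
* One σ definition (rewired-null σ), one Local-Efficiency definition, one
  clustering variant; alternatives are documented but not implemented.
* The Louvain optimizer is a heuristic; Q values are best-of-restarts and
  carry optimizer noise at small restart counts (damped in the default
  API setting).
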