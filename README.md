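# funconn

Graph-theoretical analysis of paired (pre/post) resting-state functional
connectomes: does an intervention — say, weeks of balance training —
reorganize a brain network, globally or around a specific region?

`funconn` is for researchers who already have node × timepoint signal
matrices (one region's mean BOLD time course per row, e.g. extracted with
nilearn from fMRIPrep output) and want the full chain from signals to
corrected group statistics:

1. **Edges** — Pearson correlation between every pair of node time
   courses; only positive weights kept (weighted, undirected, never
   binarized).
2. **Thresholding** — proportional (density) thresholding over a sparsity
   grid, default 6%…40% of all possible edges in 2% steps (18 networks per
   session).
3. **Parameters** — Global Efficiency, Modularity (Louvain-optimized
   Newman Q), Small-Worldness σ = (C/C_rand)/(L/L_rand) against
   degree-preserving rewired nulls, Degree Centrality, and the target
   node's Nodal and Local Efficiency. Path lengths are 1/w; definitions
   and conventions are spelled out in `docs/methods.md`.
4. **Aggregation** — each parameter's threshold curve is collapsed to an
   area under the curve (AUC), so inference never hangs on one arbitrary
   threshold. Hubs are classified against the pooled pre+post
   degree-centrality distribution (cutoff = mean + 1 SD) without AUCs.
5. **Inference** — paired two-sided tests per parameter (Shapiro–Wilk
   gate: t-test, or Wilcoxon signed-rank fallback), effect size
   d_z = mean(diff)/SD(diff), Bonferroni correction over the
   six-parameter family; plus a stability analysis across parcellation
   specs and threshold sub-ranges (total / 6–22% / 24–40%).

Because matched fMRI cohorts are rarely shareable, a synthetic-data module
generates realistic paired cohorts — modular block-correlated Gaussian
signals, per-subject jitter, and a calibrated post-session connectivity
increase among a designated target node's neighbourhood — so the whole
pipeline is testable end to end with a known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort (23 subjects × 2 sessions, 116 nodes, 260 timepoints,
`effect_delta = 0.15` injected around node 0 post-session):

```bash
python analysis/01_simulate_cohort.py      # writes scratch/data/ + manifest
python analysis/02_networks_and_metrics.py # 828 networks, 6 parameters, AUCs
python analysis/03_primary_inference.py    # the six corrected comparisons
python analysis/04_stability.py            # 3 parcellations x 3 threshold subsets
python analysis/05_calibration_studies.py  # type-I error and power (minutes)
```

`02` reports the bookkeeping and the small-world realism screen:

```
constructed 828 networks (23 subjects x 2 sessions x 18 thresholds)
small-world screen: 114 of 828 networks (13.8%) have sigma < 1
```

`03` prints the corrected primary analysis (seed 1):

```
        parameter     test  statistic  df  p_raw  p_corrected  effect_size_d
global_efficiency paired-t     0.9809  22 0.3373       1.0000         0.2045
       modularity paired-t     1.6234  22 0.1187       0.7125         0.3385
  small_worldness paired-t    -1.3205  22 0.2003       1.0000        -0.2753
          hubness paired-t     1.0066  22 0.3251       1.0000         0.2099
 nodal_efficiency paired-t     5.9665  22 0.0000       0.0000         1.2441
 local_efficiency paired-t     5.8909  22 0.0000       0.0000         1.2283
```

Read: the injected neighbourhood effect shows up exactly where it should —
the target node's Local (and Nodal) Efficiency increase survives
Bonferroni correction (t(22) ≈ 5.9, corrected p < 0.001, d_z ≈ 1.2) —
while the global parameters and hub counts stay non-significant at n = 23.

Equivalently from a shell, the same pipeline runs from a YAML config:

```bash
funconn simulate --n-subjects 23 --out scratch/data
funconn run config.yaml --seed 1
```

with a config supplying the synthetic block (or a `manifest:` CSV with
columns `subject,session,path` pointing at your own TSV matrices),
parcellation specs, grid and null-ensemble settings.

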