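# nichecnn

Weakly supervised spatial enrichment analysis for segmented multiplexed
imaging data (CODEX, IMC, CyCIF and similar). Given a per-cell flat table —
coordinates, marker intensities, cell-type annotations, and a sample-level
phenotype — `nichecnn` learns which *cell subsets*, defined by molecular
profile rather than by the annotated types, are spatially enriched in
neighborhoods associated with the phenotype. It is written for computational
biologists analyzing comparative imaging cohorts (disease vs. control,
good vs. poor outcome, high vs. low local signaling).

## The method in brief

A **multi-cell input** is the unordered set of marker vectors
[**C**]<sub>K×M</sub> of the k nearest cells around an anchor in one image,
carrying one label. Anchors are random cells (**global** analysis, label =
condition), all cells of a chosen anchor type plus background neighborhoods
(**local** analysis, labels = condition or BG), or typed anchors labeled by
the neighborhood mean of a functional marker whose column is removed from
the features (**functional** analysis, a regression on M−1 markers).

The model is a single-layer convolutional network over cells: per cell c and
filter f, `a_fc = relu(w_f · x_c + b_f)`; a pooling layer (mean or max)
summarizes each filter across the cells of an input, making the output
permutation invariant; a softmax or linear head maps the pooled vector to
the label. Hyperparameters (filter count, learning rate, dropout, L1) are
chosen by random search with best-validation-score selection.

Downstream, every cell is scored by the bias-free **filter response**
`w_f · x`; cells with positive response are *selected*, and

* per-patient selected-cell **frequencies** are compared across conditions
  with a two-sided Wilcoxon rank-sum test (the headline p-value is computed
  on held-out patients only),
* a per-cell-type **enrichment score**
  `ES_T = (K_T^S/E_T^S) / (K_T/E_T)`, with `E_T^S = K^S·N_T^S/N^S` and
  `E_T = K·N_T/N` (counts per image; S = selected, K = anchor-neighborhood,
  N = whole image), quantifies which types the selected subset concentrates
  in — ES > 1 means enrichment; cohort values are medians ± MAD,
* marker shifts between selected and non-selected cells are ranked by the
  two-sample **Kolmogorov–Smirnov statistic** (an effect size in [0, 1]).

A synthetic-cohort generator with planted, spatially localized,
condition-specific marker shifts makes the whole pipeline testable without
external data; `ground_truth_mask` exposes the planted cells for
precision/recall evaluation.

## Worked example

`examples/03_local_niche_analysis.py` generates a cohort in which
granulocyte-anchored niches exist in both conditions, but only in condition
groupA do 80% of niche-resident CD4 T cells carry a +3 sd PD1 shift. The
local analysis recovers this:

```
validation accuracy (3 classes incl. BG): 0.888
filter for groupA: validation p = 0.00433, held-out p = 0.00216 (direction groupA)
filter for groupB: validation p = 0.0771, held-out p = 0.00216 (direction groupA)
recall of planted cells by the groupA filter: 1.00

T-cell enrichment in the granulocyte niche (ES > 1 = enriched):
condition  median_es   mad
   groupA      1.274 0.032
   groupB      1.136 0.042

top markers separating selected from non-selected cells (KS score):
marker    ks direction
   PD1 0.680    higher
  CD68 0.166     lower
   CD4 0.157    higher
```

Reading the numbers: the model separates groupA, groupB, and background
neighborhoods with 89% validation accuracy; the filter attributed to groupA
selects cells whose per-patient frequency is higher in groupA with held-out
p = 0.0022 (the smallest value a 6-vs-6 rank-sum can produce); every planted
cell is recovered; the T-cell type is enriched in the niche, most strongly in
the affected condition; and PD1 — the planted marker — dominates the KS
ranking. The other examples cover cohort simulation (01), global analysis
(02), and functional regression (04).

A thin CLI wraps the shell-level entry points:

```bash
nichecnn simulate --seed 1 --out scratch/demo       # cohort + truth mask
nichecnn prepare raw.csv --schema schema.yaml --out prep.csv
nichecnn run-all --config run.yaml                  # full pipeline from YAML
```

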