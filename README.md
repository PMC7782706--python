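# pvseq

A Patch-seq analysis toolkit for morphologically identified hippocampal
parvalbumin (PV) interneurons. Patch-seq couples patch-clamp
electrophysiology, post hoc morphology, and single-cell RNA-seq in the same
neuron; this package implements the computational pipeline that sits on top
of such data once expression has been quantified to TPM:

* **Quality control** — cells are dropped when their unique-gene count or
  aligned-read count falls more than three (unscaled) median absolute
  deviations below the cohort median.
* **Differential expression gating** — genes enter testing only if
  TPM > 15 in at least five cells pooled over the two groups; a gene is
  called DE when |log2 fold difference| > 1 (with a 1 TPM pseudo-value) and
  Benjamini–Hochberg FDR < 0.05. The two-sample test is pluggable (Wilcoxon
  rank-sum on log2(TPM+1) by default).
* **Gene selection** — six methods behind one interface: chi-squared on
  log2 TPM, mutual information and ANOVA F on a binary expressed indicator,
  a fixed reference list, genes correlated with a reference list, and a
  rate-adjusted variable-gene rule with a TPM > 32 cutoff.
* **Balanced random-forest classification** — per repeat, the larger class
  is downsampled to the smaller one, 80% of cells train a fresh 100-tree
  forest, accuracy is scored on the held-out 20%; 100 repeats give overall
  and per-cell accuracies, with 50% as the chance baseline.
* **SVM-RFE** — linear support-vector recursive feature elimination down to
  the top 50 marker genes.
* **Reference mapping** — correlation k-nearest-neighbour mapping of query
  cells onto a reference 2-D embedding (mapped position = component-wise
  median of the k neighbours' coordinates).
* **CAM similarity** — between-type similarity matrices restricted to
  synaptic cell-adhesion molecule (CAM) genes, as the mean pairwise Pearson
  correlation of cells.
* **Age-transition detection** — the core statistic: expression is
  binarized at 0.6 TPM, cells are ordered by postnatal age, and each gene's
  best change point is the age boundary maximizing the loss of Gini
  impurity, `G = 1 − Σ p_i²`. Significance comes from a Monte Carlo null
  (100,000 shuffles of which cells express the gene; exhaustive enumeration
  doubles as an exact small-n oracle), followed by BH FDR at 0.10.
* **Electrophysiology features** — ten intrinsic parameters per cell from
  raw sweeps: input resistance, series resistance, capacitance (from a 5 mV
  voltage-clamp step), firing threshold (x-intercept of the 20–80% chord of
  a logistic fit to the F-I curve), dF/dI slope, spike-train attenuation,
  sag, and AP amplitude / half-width / symmetry.
* **Synthetic data** — a first-class generator that plants recoverable
  ground truth (fold changes, on/off age transitions, RC-membrane
  biophysics with a logistic F-I law) so every stage is testable without
  external data.

## Worked example

Plant a near-perfect on/off switch at P21 in one of 51 genes over 40 cells
spanning P10–P40, then scan for transitions:

```python
from pvseq import detect_transitions, extract_features
from pvseq.simulate import (SimulationConfig, TransitionSpec,
                            simulate_expression, simulate_sweeps)

cfg = SimulationConfig(
    n_cells_per_type={"vBC": 40}, n_genes=51, age_range=(10, 40),
    dropout_rate=0.3,
    transition_spec=[TransitionSpec(gene_index=0, onset_age_days=21,
                                    pre_fraction=0.05, post_fraction=0.95)],
    seed=7)
ds, truth = simulate_expression(cfg)
table = detect_transitions(ds, n_sims=100_000, seed=7)
print(table[table.significant])
```

```
  gene  split_position  split_age_days  pre_age_days  gini_loss direction       p      fdr  n_expressed
G00032               4              16            14   0.133472        up 0.00328 0.083639           31
G00000              12              23            20   0.420000        up 0.00001 0.000510           28
```

The planted gene `G00000` is recovered with the split boundary at the
planted onset (no cell aged 21–22 was drawn, so the boundary spans P20/P23)
at FDR 5×10⁻⁴; `G00032` is a chance admission of the FDR < 0.10 gate —
with 51 tested genes the gate tolerates the occasional false discovery by
construction. Extracting features from noiseless simulated sweeps
(configured truth: R_in 120 MΩ, R_s 12 MΩ, C 120 pF, sag 2.5 mV,
attenuation 1.2):

```python
feats = extract_features(simulate_sweeps(SimulationConfig(seed=7), "vBC-000"))
```

```
input_resistance_mohm       120.000
series_resistance_mohm       12.000
capacitance_pf              120.015
firing_threshold_pa         112.239
df_di_hz_per_pa               0.483
attenuation_ratio             1.205
sag_mv                        2.498
ap_amplitude_mv              85.333
ap_half_width_ms              0.365
ap_symmetry                   0.411
```

The passive parameters return within 0.02% of the configured truth; the AP
shape values are the analytic geometry of the attenuated triangular
template (peak-to-trough amplitude includes the 12 mV after-hyperpolarizing
trough).

A `pvseq` command-line interface mirrors the library
(`pvseq simulate | qc | de | select-genes | classify | map | transition |
ephys | cam-sim`); every flag mirrors a key of an optional YAML config.

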