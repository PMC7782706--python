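# Methods

This note documents the models, numerical choices, and open design
decisions behind `pvseq`, and what the synthetic-data tests do and do not
establish about real Patch-seq data.

## Data model

Expression is stored at rest in linear TPM (genes × cells), never
log-transformed in place, because every gating threshold in the pipeline is
defined in linear units: 0.6 TPM (expressed/not-expressed binarization),
15 TPM (differential-expression gate), 32 TPM (rate-adjusted variable-gene
rule). Operations that need a log scale (correlations, SVM, chi-squared,
fold differences) apply log2(TPM+1) transiently; the +1 pseudocount keeps
zeros at zero. Duplicate gene symbols on input are summed, matching the
convention of collapsing multiple Ensembl gene IDs onto one symbol.

Cell metadata carries the morphological vocabulary of CA1 PV interneurons:
five morphological types (vAAC, vBIC, hBIC, vBC, hBC) that factor into a
dendritic orientation (vertical/horizontal) and an axonal target class
(AAC/BC/BIC), plus SST-OLM as a non-PV control type. The hAAC token is
rejected by validation: that morphology was not observed in the recorded
population this pipeline targets, and accepting it silently would mask
typos. Alignment of an expression matrix with a metadata table keeps the
intersection of cells in *metadata* order, because the transition detector
downstream sorts by metadata age; alignment is idempotent.

## Synthetic expression data

`simulate_expression` draws, per gene, a baseline log2 mean from
Normal(4, 2) and, per cell, log2 expression from Normal(baseline, 0.7),
then zeroes each entry with probability `dropout_rate` (default 0.3).
Log-normal values with Bernoulli dropout — rather than negative-binomial
counts — because the pipeline consumes TPM, which is already normalized,
and all thresholds act on TPM. The per-cell scatter of 0.7 log2 units
(≈1.6-fold) was chosen once as a realistic magnitude for deeply sequenced
Patch-seq material.

Planted structure:

* **Fold changes** multiply one gene's values in one named type, so the
  ratio of group means equals the planted fold in expectation.
* **Transition genes** are binary: expressed with probability
  `pre_fraction` before the onset age and `post_fraction` at/after it,
  independently per cell; "expressed" values are drawn well above the
  0.6 TPM cutoff and dropout does not apply to them (the planted fractions
  *are* the expression probabilities).
* **Ages** are sampled uniformly on integer postnatal days of the
  configured range (default P10–P77, the span of the study design this
  emulates), with replicates per day allowed — this exercises the
  within-age-tie rules of the transition detector.

Default cohort sizes follow the study design (7 vAAC, 9 vBIC, 11 hBIC,
31 vBC, 9 hBC, 9 SST-OLM).

What the generator does *not* emulate: UMI counting noise, doublets,
ambient RNA, gene-gene correlation structure, or depth differences between
batches. Passing recovery tests on this generator therefore demonstrates
correctness of the algorithms under their stated assumptions, not
robustness to every artifact of real single-cell data.

## Synthetic sweeps

`simulate_sweeps` renders a single-compartment RC membrane. The
voltage-clamp test step (5 mV) produces a single-exponential transient with
I_peak = ΔV/R_s, I_ss = ΔV/(R_s+R_in), and τ = C·R_sR_in/(R_s+R_in), so the
passive parameters have closed-form truth. Current-clamp steps (1.5 s, from
−150 pA to +600 pA in 50 pA increments) charge with τ_m = R_in·C; spike
counts follow a logistic F-I law F(I) = Fmax/(1+exp(−(I−I0)/s)), spikes are
placed at regular inter-spike intervals and rendered from a piecewise
linear AP template (rise, fall to an after-hyperpolarizing trough,
recovery) added on top of the subthreshold trajectory. Rendering the
template additively matters: a fixed-baseline template would create a
voltage discontinuity while the membrane is still charging, which the
dV/dt spike detector would pick up as a spurious event. A linear amplitude
decay across the train makes the attenuation ratio (first/last amplitude)
analytic. Sag on the −150 pA step is a planted dip whose trough (exactly
the configured depth) is placed inside the 750–1000 ms measurement window,
with exponential relaxation before the 1500–2250 ms steady window — a
synthetic shape chosen so the windowed measurement recovers the configured
amplitude, not a biophysical model of HCN kinetics. Recording noise is off
by default; the noise knobs are configuration, not claims about real
recordings.

## QC and differential expression

The MAD is unscaled (median of absolute deviations from the median, no
1.4826 consistency factor). A cell fails QC when *either* metric is
strictly more than three MADs below its median; ties at the threshold pass.
When only a TPM matrix is available, the aligned-read count is not
recoverable; total TPM mass serves as a stand-in and the report flags it.

The DE machinery deliberately does not reimplement a negative-binomial
quasi-likelihood GLM: the contribution here is the gating protocol
(TPM > 15 in ≥ 5 cells pooled over both groups; |logFD| > 1 with a 1 TPM
pseudo-value; BH FDR < 0.05), and the two-sample test behind it is
pluggable and labeled in the output (`rank_sum` on log2(TPM+1) by default,
`welch_log` as the parametric alternative). "At least five cells in the two
groups" is read as pooled over both groups; the per-group reading is the
documented alternative.

## Gene selection

The binarization threshold for the mutual-information and ANOVA-F methods
reuses the 0.6 TPM cutoff of the transition detector for internal
consistency. The rate-adjusted variable-gene rule is a reconstruction:
for each gene, d = fraction of cells with TPM > 32 and m = mean log2 TPM
over those cells; genes are kept where d < exp(−1.5·(m−b)) + 0.02, with the
intercept b found by bisection so that exactly the requested number of
genes falls under the frontier (frontier ties resolved toward larger m).
The decay 1.5 and floor 0.02 are exposed as parameters. Genes never
exceeding the cutoff have undefined m and are excluded. All methods are
deterministic and equivariant to permuting cells; ranking ties break
alphabetically by gene symbol for reproducibility.

## Classification and mapping

The balanced random-forest protocol re-draws the class downsampling and the
(stratified) 80/20 split independently per repeat and trains a fresh
100-tree forest each time; forest hyperparameters beyond tree count are
library defaults and are recorded in the result object. Per-cell accuracy
is defined as correct classifications divided by test-set appearances over
the repeats.

A caution that the null-calibration tests made quantitative: on a *single*
realized null cohort (30+30 cells, 200 genes drawn from one distribution),
cross-validated accuracy is 0.50 only in expectation over cohorts — any one
cohort contains genes whose chance association with the labels is shared by
its train and test splits, giving a cohort-level standard deviation of
about 0.056 in mean accuracy. The chance-baseline benchmark therefore
averages the protocol over 30 independently simulated cohorts (10 repeats
each); the same caution applies when interpreting a single real dataset's
accuracy against the 50% baseline.

SVM-RFE trains a primal (deterministic) linear SVC on log2(TPM+1), ranks
genes by absolute weight — maximum across one-vs-rest weights for more
than two classes — and drops the lowest 10% per round until the requested
number remains. Collinear separators may split their weight; both or either
may survive.

kNN mapping uses 1 − Pearson correlation of log2(TPM+1) on the declared
gene set (k = 10 by default; the value is not canonical and is exposed).
Ties at the k-th neighbour break by reference cell order; the mapped
coordinate is the component-wise median of the k neighbours, which confines
every mapped point to the neighbours' bounding box. A rank-based
(Spearman) switch is provided for query/reference pairs with very different
sequencing depths. Constant query cells are flagged per cell and skipped
rather than failing the run.

## Transition detection

Expression is binarized at TPM strictly greater than 0.6 — a low cutoff,
because pseudo-alignment can assign trace abundance to unexpressed genes.
Genes expressed in fewer than six cells, or unexpressed in fewer than six,
are ignored (both-sided rule). Candidate change points are restricted to
boundaries between consecutive *distinct* ages: the order of cells within
one age is arbitrary, so allowing within-age splits would make the
statistic depend on an unreproducible ordering. The split score is the loss
of Gini impurity, parent minus size-weighted children; ties go to the
earliest boundary and all tied boundaries are reported.

The Monte Carlo null redistributes the gene's expressed count uniformly
over cells (100,000 draws by default) and records the maximum loss of each
draw; p = (1 + #{null ≥ observed}) / (1 + draws), the add-one form, so
simulated p-values are never exactly zero. Null distributions are cached
per (n_cells, n_expressed, age-multiplicity profile), since the
candidate-boundary layout determines the null. Exhaustive enumeration over
all C(n, k) arrangements is implemented as an exact oracle for small n and
reports the uncorrected fraction. Whether the original procedure's shuffles
respected age ties is unknown; restricting candidate splits to age
boundaries is a deliberate strengthening in favour of determinism. The
detector reports both raw p and BH FDR and gates on FDR < 0.10 by default
(a flag gates on raw p instead, since both conventions appear in practice).
Split ages are reported as the last age before and the first age at/after
the boundary.

## Electrophysiology features

The canonical ten parameters are: input resistance, series resistance,
capacitance, firing threshold, dF/dI, attenuation, sag, AP amplitude, AP
half-width, and AP symmetry; base width and trough amplitude are emitted as
auxiliary columns. Choices where the measurement is underdetermined:

* **R_in** partitions the series resistance out of the steady-state total:
  R_in = ΔV/I_ss − ΔV/I_peak.
* **Capacitance** integrates the transient charge, C_raw = Q/ΔV, and by
  default rescales by ((R_s+R_in)/R_in)² — the command step divides across
  R_s and the membrane, so the raw charge underestimates C by
  (R_in/(R_s+R_in))²; the correction uses the measured resistances.
* **AP detection**: dV/dt ≥ 20 V/s with a 1 ms refractory.
* **Firing threshold**: a 3-parameter logistic is fit to the F-I curve by
  bounded least squares (initialized from data quantiles); the 20% and 80%
  crossings are found numerically on the fitted curve and the chord through
  them is extrapolated to zero. For a symmetric logistic this equals
  I0 − (5/3)·ln 4·s in closed form, which the tests verify to < 0.1 pA.
* **dF/dI**: OLS slope over [I_first_spiking + 50, I_first_spiking + 300] pA.
* **Attenuation** = first/last AP amplitude on the maximal step (> 1 means
  decline), amplitude taken peak minus the dV/dt-crossing voltage.
* **Sag** = median V over 1500–2250 ms minus minimum V over 750–1000 ms of
  the −150 pA step (window times relative to step onset,
  config-overridable; the sag step is rendered longer than the ordinary
  1.5 s steps so both windows fit).
* **AP shape** averages peak-aligned APs from the first trace with ≥ 3 APs;
  amplitude defaults to peak-to-trough (a peak-to-baseline switch exists);
  symmetry = (t_peak − t_rise20%)/(t_fall20% − t_rise20%). Traces with
  fewer than three APs are excluded from shape analysis entirely.

All ten features are invariant to a DC offset on the voltage traces, which
the tests assert feature by feature.

## CAM similarity

Similarity between two types is the mean Pearson correlation over all
cross-type cell pairs on log2(TPM+1) restricted to the CAM genes (linear
scale available); the diagonal averages within-type pairs *excluding* self
pairs, which are identically 1 and would bias the diagonal upward. The CAM
catalogue itself is an input (one gene symbol per line); the package does
not curate it, and the test fixtures use synthetic gene lists.

## Problem sizes and calibration checks

The test suite's end-to-end checks use sizes chosen to make their Monte
Carlo error small relative to the asserted tolerances: the
enumeration-vs-simulation oracle covers every (n ≤ 12, 1 ≤ k < n) at
100,000 draws, with a one-retry sequential rule per combination (a single
draw outside 3 SE is a ~0.3% event even for an exact sampler across 66
simultaneous comparisons, so one failed combination is re-drawn once with
an independent seed); transition recovery uses 40 cells over P10–P40 with
a planted 0.05→0.95 switch at P21 among 50 null genes at 100,000 draws;
null FDR calibration averages 20 replicates of 200 null genes at 20,000
draws (p resolution 5×10⁻⁵, far finer than the 0.10 gate needs); the
chance-baseline benchmark averages 30 cohorts × 10 repeats. The full suite
runs in about two minutes on one CPU.

## Known limitations

* The rate-adjusted variable-gene frontier is a reconstruction of the
  cited approach, not a reproduction of its exact functional form.
* The Monte Carlo null conditions on the expressed count and the age
  profile but not on any gene-gene dependence; correlated gene families
  share false discoveries.
* The ephys extractor assumes a clean RC response to the test step; it does
  not implement bridge-balance correction, spike sorting, or ABF parsing.
* The simulator's spike placement is regular (optionally attenuated), so
  inter-spike-interval statistics carry no information; only count-derived
  features are meaningful on synthetic sweeps.
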