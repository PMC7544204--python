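# Methods

## Data model

The pipeline operates on two aligned intensity layers per screen — LFQ
(between-run comparable label-free quantification) and iBAQ (summed intensity
over theoretically observable peptides, whose within-run ratios proxy
relative copy number) — indexed by protein-group leader accession and
experiment id. An intensity of 0 in the input table always means "not
quantified in this run" and becomes an explicit missing cell; measured zeros
do not occur in this data type. The experiment design registers every IP run
with its bait, screen (`target_set`), extraction condition, replicate number,
vessel and case/control role; a condition is testable when it has at least
two case and two matched control runs.

Record-level filters: decoy ("Reverse") and contaminant groups are dropped,
as are groups whose razor+unique peptide count is below 2. The count cell
lists one number per group member; the filter uses the **maximum** over
members, so a group survives when any member is well evidenced (the rule is
stated per group; a per-member reduction had to be chosen). Homolog pairs
whose peptides are largely shared (by default MAGOH/MAGOHB) are merged by
summation per run on the linear scale; a missing member contributes 0 and the
merged cell is missing only when every member is missing.

## Imputation

Missingness in AP-MS is predominantly left-censored: detection falls off
with abundance. Imputation runs on the log2 scale (so draws are approximately
normal) within replicate groups — the runs sharing target set, condition and
role — and follows a three-branch decision tree:

| branch | condition | draw |
|---|---|---|
| A | group fully observed | none |
| B | partially missing, ≥ 2 observed | N(mean_obs, max(sd_obs, `sd_floor`)) |
| C | 0 or 1 observed in group | N(μ_col − `downshift`·σ_col, `width`·σ_col) per run |

Defaults: `downshift` 1.8 and `width` 0.3 (the de facto standard constants
for down-shifted imputation of left-censored proteomics data), `sd_floor` 0.2
log2 units (prevents degenerate draws when observed replicates happen to
coincide). μ_col and σ_col are the run's observed mean and sd; a run with
fewer than 3 observed values cannot support the censoring model and is an
error. Groups with exactly one observed value route their missing cells to
branch C, since a within-group sd cannot be estimated from one number; the
observed cell is never altered. All constants are configuration
(`ImputationParams`), so alternative branch rules can be swapped in without
code changes.

The completion is repeated `n_trials` = 100 times with seeds base_seed + k.
Observed cells are identical across trials; given the seed list the ensemble
is bit-reproducible.

## Normalization and testing

Each run is divided by its GFP (tag) intensity — subtraction on the log2
scale — which cancels capture-efficiency differences; the tag is present in
every run including tag-only controls, and after imputation is quantified
everywhere. The subsequent multiplication by c = (min + max)/2 of the
pre-normalization linear intensities restores the data's numeric range. The
min/max are taken globally over the matrix rather than per run: a single
coefficient is the only reading under which "restoring the original range"
is well defined, and any constant shift cancels in every two-sample
statistic (asserted by a dedicated test).

Per condition and trial, case and control runs are compared by unpaired
t-tests — Welch by default, since equal variances between bait captures and
tag-only controls is not a defensible assumption (a pooled-variance flag
exists); rows with zero variance on both sides get p = 1 when the means are
equal and p = 0 otherwise. BH adjustment is applied per (target set,
condition, trial) family across proteins. A protein is significant in a
trial when adjusted p ≤ α = 0.05 and log2FC ≥ 1, and passes overall when
significant in ≥ `min_trials` = 60 of 100 trials. Reported log2FC and
adjusted p are medians across trials: Rubin's rules do not apply to
BH-adjusted values, and medians are robust to the occasional extreme
completion. Proteins imputed in both groups are still tested — the stability
filter is the designated guard against the artifacts this can create.

## Complexes, stoichiometry, embedding

Complex enrichment is deterministic, not a hypergeometric test: per target,
a complex's protein ratio is the fraction of its catalog subunits in the
significant set, and the complex is displayed when the ratio is ≥ 0.5 (three
or more subunits) or exactly 1 (two subunits). Its displayed abundance is the
log10 of the mean control-subtracted linear LFQ intensity over members with
positive values, where control subtraction (mean case − mean control, missing
as 0) is computed per condition and averaged across the target's conditions
on the linear scale before the log (mean-then-log; a log-then-mean flag
exists). Differences that are zero or negative are undefined rather than
clipped.

Stoichiometry ratios use the raw (non-imputed) linear iBAQ layer:
log2(iBAQ_a/iBAQ_b) per run, defined only when both proteins were
quantified. Per-run global scaling cancels, so no normalization is applied.

For the embedding, each protein passing ≥ k significance tests (default
k = 1) gets a profile over **all case IP runs** of the screen — ensemble-mean
normalized log2 LFQ, so observed cells are exact and imputation jitter is
averaged out — and pairwise Euclidean distances are reduced to 3D by
classical (Torgerson) MDS: double-centering of −D²/2 and eigendecomposition,
keeping the top positive-eigenvalue axes. Classical MDS was chosen over
stress-minimizing SMACOF because it is deterministic and exact at intrinsic
dimension ≤ 3; axis signs are canonicalized (largest-magnitude coordinate
positive) for byte-reproducibility. The pre-screen view clusters experiment
columns by average-linkage Euclidean distance with missing values set to 0
(the convention for that display; linkage is configurable).

## Synthetic screens

The generator emulates the screen's statistical structure: baseline log2 LFQ
abundances N(24, 2); replicate noise sd 0.3; a bait expressed only in its own
case runs (log2 27); the GFP tag in every run (log2 26); interactors elevated
over control by per-condition effects (default uniform in [2, 6] log2
units); logistic detection in log2 intensity (midpoint 21, slope 1.2), which
censors roughly 12–20% of background cells, plus 2% MCAR dropout; and an
iBAQ layer equal to LFQ divided by a per-protein size factor drawn
log-uniformly in [5, 60]. Proteins can be pinned to true copy numbers (their
iBAQ intensity becomes copies × 2^20, kept above the detection midpoint so
ratios are observable), which makes stoichiometry recovery testable. The tag
is exempt from censoring — it is spiked at high abundance and its presence in
every run is a design guarantee the normalization contract relies on.

What the generator does **not** model: peptide-level identification,
between-run alignment artifacts, condition-specific solution chemistry,
correlated background (e.g. shared contaminant covariation), or batch
effects. Passing closed-loop tests therefore demonstrates the statistical
machinery under the stated missingness and noise model, not robustness to
every failure mode of real acquisitions.

## Benchmark problem sizes

The calibration experiments use 500 background proteins, one bait, 4
conditions × (4 case + 4 control) replicates and 100 imputation trials per
screen; type-I calibration averages 20 independent null screens, and
stoichiometry uses a two-target, four-condition screen (32 case runs) so
that ≥ 20 defined ratios survive censoring. These sizes give stable
fractions while keeping a full calibration run around a minute on one CPU.

## Known limitations

- The three-branch imputation scheme is this package's concrete
  instantiation of "impute differently by degree of need"; published
  variants differ in branch details and constants, which is why all
  constants are configuration.
- Median-across-trials summaries are not proper multiple-imputation pooling;
  they are used because BH-adjusted values do not admit Rubin's rules.
- The packaged NCBP design registry reconstructs per-condition replicate
  counts from printed totals (23/22/12 case IPs); it is a synthetic
  stand-in, suitable for dimensionality accounting, not a transcript of the
  original run sheet.
- Complex catalog redundancy (overlapping curated complexes) is flagged but
  not collapsed; curation is editorial and out of scope.
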