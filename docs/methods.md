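# Methods

This note records the modelling choices behind `maizegxe`: what each stage
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## The prediction problem

Grain yield (Mg/ha) of an F1 maize hybrid in a trial plot is modelled as a
function of genotype (allele dosages at a subset of loci), environment
(weather, soil, crop-simulator covariates of the location-year), and
management (treatment class, planting date). Trials are keyed by
`Env = location_year` and `Hybrid = Parent1/Parent2`. Models are trained on
all years up to a cutoff and evaluated on the following year — a temporal,
not random, split, because the practical question is forecasting a new
season. Nothing from the test year (including its yields, via imputation or
feature statistics) may reach any fitted quantity; the suite audits this.

## Synthetic trial network

`maizegxe.synthetic` generates the six tables of a trial network with an
additive ground-truth yield model:

    yield = baseline + state_effect + Σ_j β_j · dosage_j + treatment_offset
            − penalty · max(0, planting_doy − window_end) + ε,  clipped at 0

with defaults: baseline 9.44 Mg/ha (a typical training-period mean for US
maize trials, with the generator's dispersion bringing the overall spread
near a 3 Mg/ha standard deviation); state effects N(0, 1.5²); eight causal
loci at |β| = 0.3 Mg/ha per unit dosage with alternating signs; treatment
offsets from −2.5 (drought) to +0.5 (irrigated) Mg/ha; a late-planting
penalty of 0.05 Mg/ha per day beyond a 110–140 day-of-year window; residual
noise sd 1.0 Mg/ha. Genotype calls are drawn with <5% mass on
multi-allelic strings; genotype missingness is locus-structured — a
configurable fraction of loci is made ~85% missing, the rest complete —
mirroring the empirical pattern that missing-data loci tend to be missing
for most of the cohort. All randomness flows from one integer seed through
`numpy.random.SeedSequence`, so identical configs reproduce byte-identical
tables.

What the generator does **not** emulate: realistic weather dynamics (the 16
features are seasonal sinusoids plus noise, uncorrelated with yield),
crop-simulator physiology (the depth × stage fields are smooth random
surfaces given a weak additive link to the state effect), linkage
disequilibrium between loci, spatial field trends, or replicate plots.
Consequently a passing suite demonstrates that the pipeline's mechanics are
correct and that models recover effects that are truly additive in the
inputs; it does not demonstrate skill on real weather-driven yield
variation.

## Preprocessing

- **Treatment**: mode imputation over non-missing entries, ties broken
  lexicographically (determinism over fidelity; the mode in realistic data
  is "standard" by a wide margin).
- **Issue comments**: a configurable keyword → category map over six labels
  (animal attack, data issues, drought, storm, no issues, miscellaneous).
  Unmatched comments become "miscellaneous", empty ones "no issues".
- **Weather**: daily series pivot to `Feature_DayOfYear` wide format, then
  aggregate to 48 weeks of 7 days (week w covers days 7(w−1)+1..7w; days
  337+ discarded so the block is exactly 48×16). The aggregator defaults to
  the mean for all 16 features, with per-call override (sum/min/max) since
  cumulative features like precipitation arguably want sums. Environments
  with fewer than 336 distinct days are a hard error; input that already
  has 48 days is rejected rather than silently re-aggregated.
- **Soil / simulator covariates**: two-pass mean imputation — same
  location, other years; then same state. Cells that survive both passes
  (a feature absent at every year of a single-location state) fall back to
  the global column mean inside `preprocess` so the modelling frame is
  complete; the two-pass function itself reports and flags them.
- **Join**: inner on `Env` for per-environment tables; left on `Hybrid` for
  genotypes, with unmatched trait rows flagged and excluded from training
  (the alternative — imputing a genotype — would fabricate data).

## Genotype stage

Dosage codes {0, 0.5, 1} are the natural additive scale; 0.15 is a sentinel
for multi-allelic calls, deliberately distinct from any additive value.
Numeric input already in the code set passes through; numeric input outside
it raises, since silently re-encoding unknown codes would corrupt the
matrix. The informative-locus rule is expressed in cohort fractions
(0.8117 / 0.2029 of H hybrids) rather than the absolute counts it derives
from, so it scales to any cohort; the zero-count comparison is strict and
the heterozygote count non-strict, exactly as the rule is stated. The
default missing-locus policy removes any locus with a single missing call
(a >80%-missing threshold is available as a policy option). When the rule
keeps nothing (tiny degenerate cohorts), the stage falls back to all
complete loci rather than failing the whole pipeline, and reports it.

## Engineered yield features

The "mode" of a continuous yield column is defined as the most frequent
value after rounding to one decimal, smallest value on ties — a pragmatic
definition, since the mode of continuous data is otherwise ill-posed. The
unseen-combination imputation averages that mode with the state mean, per
statistic column. The state trend regresses row-level yields (not yearly
means) on calendar year; single-year states get slope 0 and the state mean
as intercept. Calendar year is used directly as the regressor; an index
from the first training year would give identical predictions with a
shifted intercept.

## Network engine and architectures

No deep-learning framework is part of the dependency set; `maizegxe.nn` is
a small, fully deterministic numpy engine providing exactly what the
architectures need: stride-1 valid Conv1D/Conv2D (im2col + matmul), average
pooling, dense layers, categorical embeddings (default dimension
min(8, ⌈cardinality/2⌉)), ELU activations, L1 regularization on designated
dense layers, and Adam. Gradients are pinned by central finite-difference
tests for every layer type, including through branch concatenation.

The single-modal network treats the concatenated flat vector as a 1-channel
sequence: conv(32, k=5) → conv(16, k=5) → average pool → two more convs →
flatten → three dense layers with a linear scalar output. The multimodal
network has six branches — weather (48×16, two 2-D convs), soil and
genotype (1-D blocks), metadata (embeddings for location and treatment
concatenated with numerics, two 1-D convs), the simulator soil block
(seven parallel 2-D sub-blocks, 3×3 kernels for the small 10×9 and 9×9
grids, concatenated), simulator phenology (1-D block) — concatenated into
two L1-regularized dense layers (default coefficient 1e-4) and a linear
output. Filter counts default to the 32→16/kernel-5 pattern and are fully
configurable; `small_cnn_config()` (8→4 filters) is the preset used by the
test suite and example runs, matching the reduced cohort sizes there.

Training minimizes MSE on a standardized target with Adam (default learning
rate 0.01, batch 32); every input block is mean/std standardized with
training-set statistics (embedding codes excluded). Runs are exactly
reproducible for a fixed seed — the engine has no nondeterministic paths.

## Oversampling and the ensemble

Treatments other than standard and late planting are minority classes; each
contributes 4,000 rows resampled with replacement, plus 1,000 rows
relabelled "late planting" to synthesize a scenario absent from training
(25,000 appended rows when five treatments are eligible). The relabelling
deliberately biases the late-planting prediction toward the donor
treatments' yields — the cost of predicting an unseen management class at
all. The XGBoost member sees only metadata and engineered yield features.
Ensemble weights are scanned over {0, 0.1, …, 1} against RMSE on a held-out
validation year (the last training year, both members fitted on earlier
years only; refitted on the full training period afterwards); ties resolve
toward the network.

## Evaluation

MAPE is implemented as mean(|y−ŷ|)/ȳ: the sum-form without 1/n would grow
with sample size, and relative-to-mean (rather than per-observation
percentage) avoids division by near-zero yields of failed plots. The
literal sum form is available behind `normalize=False`. Pearson r is
undefined (reported as missing) for n = 1 or constant vectors rather than
silently 0.

## Hybrid classification rule

The six-class rule is an explicit parameterization of an empirical
decision logic over per-(hybrid, treatment) yield summaries, applied in
fixed order: max ≤ t_low → extremely low; min ≥ t_high → extremely high;
straddling both thresholds with span > wide_span → wide range; then the
central statistic (median by default, mean by option) against t_high/t_low
for high/low; else moderate. Defaults t_low = 6, t_high = 10, wide_span =
8 Mg/ha align with a yield scale on which drought responses are bimodal
around 6 and 12 Mg/ha. The rule is total and order-monotone (uplifting all
yields never lowers the ordered class), both property-tested.

## Problem sizes in the suite

The test suite runs entirely on generated data: a 40-hybrid, 3-state tiny
cohort for unit tests; a ~300-row set for the sanity-fit check (the fitted
multimodal network's RMSE on its training rows must undercut the
constant-mean predictor — at this size and the default 1 Mg/ha noise,
out-of-year error is dominated by noise, so generalization is asserted at
the next size up); and an 800-row, 8-environment-per-year network on which
the multimodal model's test RMSE matches or beats the single-modal's in at
least 2 of 3 seeds. Baseline tree counts are reduced in quick runs; model
hyperparameter *defaults* always remain the reference values.

## Known limitations

- The engine is CPU-only and stride-1/valid-only; very large cohorts would
  want a framework backend behind the same model surface.
- The generator's independence of loci means locus-subset insensitivity
  holds only weakly (no linkage structure to make subsets exchangeable).
- Late-planting predictions inherit the oversampling bias discussed above.
- The classification thresholds are a documented reconstruction, not a
  fitted rule; they are CLI-configurable for other yield scales.
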