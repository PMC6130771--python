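# Methods

## The index

For a developmental expression matrix with stages *s* and genes *i*, and a
gene-level evolutionary parameter *E*, the transcriptome evolutionary
index at stage *s* is the expression-weighted mean

TEI_s = Σ_i E_i e_is / Σ_i e_is,

summed over the genes that carry *E*.  Genes missing the parameter are
dropped from numerator and denominator alike — never imputed — so each
parameter's profile is computed on its own gene set, whose size is
reported alongside the profile.  The index is invariant to rescaling any
stage's expression column and is always bounded by [min E, max E].

Weights are the *transformed* expression values.  The default transform is
log2(x+1): untransformed weights let a handful of extremely expressed
genes dominate the index, and the CI-ratio diagnostic (below) makes this
visible.  The +1 pseudocount maps zero expression to zero weight and keeps
weights nonnegative; √x needs no pseudocount; inputs that arrive already
log-transformed (microarray series) accept only the identity transform.
Scales are declared by the user, never inferred — silently guessing
between logged and linear data risks double transformation.

## Preprocessing

Count data are normalized per stage to counts-per-million (each column
rescaled to sum 10⁶) with no transcript-length correction, which is the
appropriate normalization for 3'-tag protocols where counts do not scale
with transcript length.  An optional low-expression filter removes genes
with mean linear expression across stages strictly below a threshold
(default 1), aimed at the high technical noise of lowly expressed genes in
single-embryo/single-cell-like data.  Both operations are strict about
degenerate input: an all-zero stage column is an error, not a silent NaN.

## Bootstrap confidence bands

Gene identities are resampled with replacement (the same resample reused
across all stages of a replicate, so every replicate is an internally
consistent curve), the index recomputed per replicate, and the band taken
as the empirical (1−level)/2 and 1−(1−level)/2 quantiles per stage
(type-7 linear-interpolation quantiles; default 10,000 replicates, 95%
level).  The point estimate always comes from the unresampled data, so the
displayed curve carries no resampling bias.  Resampling is implemented as
multinomial count vectors so each replicate is a single matrix product;
a replicate that happens to give a zero weight sum at a stage yields a NaN
that the quantile step ignores.

The CI-ratio diagnostic is the per-stage ratio of upper to lower CI
boundary — a scale-free width measure that can be compared across
transforms of the same data.  On heavy-tailed expression the ratio's range
across development is systematically smaller under log2 weights than under
untransformed weights (the acceptance suite measures this fraction).  The
ratio requires a positive lower bound; for parameters whose index can
cross zero, shift-parameterize first (add a constant to E, which shifts
the index by the same constant).

## Early-vs-middle permutation test

Stages carry period labels in contiguous blocks preMZT → early → middle →
late.  Pre-MZT stages reflect the maternally deposited transcriptome, not
zygotic regulation, and are excluded; late stages are highly divergent
under both competing models and are likewise excluded from the statistic.
The statistic Δe–m is the mean index over early stages minus the mean over
middle stages.

The null permutes the parameter values across genes with expression held
fixed.  Because Δe–m is linear in the parameter vector (with V the
column-normalized weight matrix, Δ = E·v where v is the difference of
row-means of V over early vs middle columns), each permutation is a dot
product and 10,000 permutations are cheap even for large gene sets.  Two
p-values are reported: the empirical tail with add-one correction,
(1 + #extreme)/(n_perm + 1), which can never be exactly zero, and a normal
approximation using the permuted values' mean and SD, which matches the
empirical tail to well under 0.02 at 10,000 permutations on approximately
normal nulls.  A constant parameter gives a degenerate null (SD 0); the
result is flagged and p set to 1.

Direction: for ω₀, phylostratum and paralog count, low values mean
conservation, so the hourglass predicts large positive Δe–m and the tested
tail is Δ ≥ Δ_obs.  For connectivity, high values mean constraint, so the
tail flips.  The test is one-sided by design: early conservation covers
both "early more conserved than middle" and "early ≈ middle", so only a
significantly lower middle index counts as hourglass evidence.

## Pleiotropy, Tau, retrogenes, duplicability

Expressed-calls are binary: either value > threshold (FPKM/CPM-style,
linear scales only) or, per stage, rank in the top ⌈q·G⌉ positions
(descending, average ranks for ties) — the rank rule is scale-free and
keeps the expressed count comparable across stages.  A gene is temporally
pleiotropic when it is expressed in strictly more than a breadth fraction
(default 0.5) of sampled stages.  Per-stage proportions divide pleiotropic
genes expressed at the stage by all genes expressed there; the chi-square
goodness-of-fit test takes expected counts proportional to per-stage
expressed totals (the natural null of a stage-constant pleiotropic
fraction), df = S−1.  Whether pre-MZT stages belong in the breadth
denominator is genuinely ambiguous; they are included by default and an
`exclude_premzt` flag is provided.

Tau = Σ_i (1 − x_i/max x) / (n−1) over n ≥ 2 tissues, after flooring
negative log-scale values at 0 and removing genes with no expression in
any tissue; testis-specific means top tissue = testis and Tau ≥ 0.8.
The retrogene trend is the Spearman correlation between stage rank and
per-stage median retrogene expression, computed after excluding
testis-specific genes when a tissue panel is available (retrogenes'
testis expression would otherwise confound the developmental trend);
with fewer than 5 stages the t-approximation is unreliable and an exact
permutation p over all S! orderings is used.  Spearman rho is computed as
the Pearson correlation of average ranks, which remains correct under
ties (medians of count data tie often).  The connectivity–duplicability
relation reports the Spearman correlation plus mean paralog count per
connectivity quantile bin (default 5), because a single rank correlation
cannot represent the rise-then-fall shape this relation sometimes takes;
an all-tied connectivity vector yields an explicit "undefined" flag.

The Wilcoxon rank-sum comparison (ω₀ between pleiotropic and
non-pleiotropic genes) uses exact enumeration when both groups are below
25 observations and tie-free, and the normal approximation with tie
correction otherwise.

## ω₀ branch resolution

A gene overlapping a duplication node carries two branch values of ω₀;
the branch following the duplication reflects the gene's own recent
selective regime, so that value is kept and the pre-duplication branch
discarded.  Genes with more than two branch records (nested duplications)
are rejected rather than resolved by an undocumented rule.

## Synthetic data generator

The generator emulates the moments of real developmental time courses,
not their mechanisms.  Each gene draws a lognormal baseline (median ≈ 30
counts), a peak period (probability proportional to the number of stages
per period), a peak stage within that period, and a smooth Gaussian stage
profile (width 1.5 stages, amplitude uniform on 2–6×).  Pre-MZT-peaking
genes thereby mimic maternal transcripts: high at the first stages,
decaying afterwards.  Noise is negative-binomial (dispersion 0.2, typical
of bulk RNA-seq) for count data or lognormal (σ = 0.5 on log2 scale) for
microarray-like intensities.

Coupling: under `hourglass`, genes peaking in the middle period form the
conserved group; under `early_conservation`, genes peaking early do; under
`null` no group is shifted.  One `effect_size` knob scales all parameter
shifts jointly, each on its parameter's own scale — at the default 1.0:
mean ω₀ 0.20 → 0.15 (gamma, shape 4), phylostratum drawn as
1 + Binomial(9, p) with p 0.50 → 0.40 (≈ 0.9 strata older), mean paralog
count 3 → 2, mean connectivity 20 → 25.  These defaults give the
early-vs-middle test essentially full power at 2000 genes while the null
stays at its nominal rejection rate; `effect_size=0` collapses every
pattern to the null.  Connectivity and paralog number come from a Gaussian
copula with the correlation chosen as r = 2·sin(π·ρ_s/6) to hit a target
Spearman ρ_s (default −0.2; discreteness of the margins attenuates the
realized value slightly).  Retrogene flags are Bernoulli with the odds
multiplied by `retro_late_enrichment` (default 3) for late-peaking genes.
The tissue panel gives a configurable fraction (default 5%) of genes a
construction with testis signal ≈ 8 (log scale) against ≈ 0.3 elsewhere,
which guarantees Tau ≥ 0.8 and top tissue testis.

What the generator does **not** emulate: replicate structure and batch
effects, length or GC biases, correlated gene modules (genes are
independent given their period), dropout, or any real species' stage
spacing.  Passing calibration on this generator therefore shows that the
statistics behave as designed under their own assumptions — it does not
by itself validate conclusions on any real dataset.

## Calibration scales and numerical choices

The acceptance suite runs at desk scale, chosen to keep the full suite in
a few minutes while leaving binomial noise well inside the asserted bands:
500 null datasets (1000 permutations each) for type-I error, 200 datasets
each for hourglass power and early-conservation specificity, 500
i.i.d.-gene datasets (500 genes, 1000 bootstrap replicates) for CI
coverage, 20 datasets at 10,000 permutations for the normal-vs-empirical
agreement, and 100 datasets for the transform-stability fraction.  The
coverage target uses a parameter drawn independently of expression, so
the population index equals the parameter's population mean exactly (the
ratio of expectations factorizes), avoiding any approximation in the
covered value.  Under the generator's early-conservation pattern the
conserved shift sits on early-peaking genes, which drives Δe–m negative;
the one-sided test then rejects at or below its nominal rate, and the
acceptance check asserts exactly that bound.

Determinism: every stochastic routine takes a seed; the pipeline derives
per-component seeds from one root seed via named substreams, so toggling
one analysis never changes another's results.  Quantiles are numpy's
default type-7 throughout.  Bootstrap and permutation matrices are built
in chunks capped at ~2·10⁷ elements to bound memory.

## Known limitations

* The early-vs-middle contrast deliberately ignores late stages; patterns
  that differ only in late development are indistinguishable to the test.
* The normal-approximation p-value degrades for very small gene sets or
  extremely skewed weight distributions; the empirical p is always
  reported and preferred there.
* Nested duplications (>2 ω₀ branch records) are rejected, not resolved.
* The pipeline consumes one expression column per stage; replicate
  merging must happen upstream.
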