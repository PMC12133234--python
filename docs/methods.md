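# Methods

## Language models and perplexity

Transcripts are ordered token sequences; tokenization lower-cases, strips
punctuation (tokens are maximal runs of word characters) and splits on
whitespace. Perplexity of a held-out transcript under a model is
`PP = exp(-(1/N) * sum ln p)`, which is invariant to the logarithm base;
natural logs are used internally.

Two model orders are supported. The unigram (1-g) model scores each word
without context; the bigram (2-g) model scores each word given its
predecessor, with every transcript treated as a single sequence wrapped in
`<s> ... </s>` (no sentence segmentation is attempted — spontaneous
interview speech has no reliable sentence boundaries in transcripts). The
number of scored positions N is the token count for order 1 and the token
count plus one for order 2 (the end marker is scored, the start marker is
not).

Smoothing is additive (add-k, default k = 1). The normalization
vocabulary is the *mapped training vocabulary*: training types with
frequency >= `min_count` (default 1), plus `<unk>` whenever the mapping
actually replaced training tokens. With the default `min_count = 1`
nothing is mapped and the vocabulary is exactly the observed training
types — e.g. training corpus "a a b" gives p(a) = (2+1)/(3+2) = 3/5 and
p(b) = 2/5. A held-out token outside the vocabulary maps to `<unk>` and
scores `k / (N + k·V)`, the add-k mass of one additional unseen type;
this keeps within-vocabulary probabilities normalized to exactly 1 while
guaranteeing every scored probability is positive under cross-validation.
For order 2, the outcome set additionally contains `</s>`, and an unseen
context falls back to the uniform smoothed distribution.

Per-participant scores use leave-one-participant-out cross-validation:
for each participant, both models are refit on the remaining n-1
transcripts and evaluated on the held-out one. Note that cross-validated
2-g perplexity is *not* guaranteed to lie below 1-g perplexity: with small
corpora, bigram statistics are sparse and heavily smoothed, and in the
synthetic corpora below the 2-g perplexity is in fact higher.

## Volumes, smoothing, TIV

Gray-matter maps are 3-D lattices with a NIfTI affine (RAS+ world
millimetres); a cohort must share one grid and affine — there is no
resampling, reorientation or segmentation. Data are float32 on disk,
float64 in computation.

Smoothing uses a Gaussian kernel specified by its full width at half
maximum, `sigma = FWHM / sqrt(8 ln 2)`, converted to per-axis voxel units
so anisotropic voxels are honoured. Boundaries use symmetric (reflected)
convolution: the resulting kernel matrix on the grid is symmetric and
doubly stochastic, so constant images are preserved exactly *and* the
total image sum is conserved — both properties are unit-tested. (A
truncated-and-renormalized kernel would satisfy only the first.)

Total intracranial volume is defined as voxel volume (mm^3, the absolute
determinant of the affine's linear part) times the summed intensities of
the supplied unsmoothed tissue maps, in ml. For the synthetic world this
definition is exact by construction; for real CAT12/SPM-derived data the
user should supply the toolbox's own TIV estimate instead if available.

## Voxel-wise regression and inference

The design matrix has a fixed column order: intercept, tested score (1-g
or 2-g perplexity), sex (0/1), education (years), TIV (ml). Rows are
complete cases (the dropped count is logged); full column rank is
verified, and a rank failure names the collinear columns. Fitting is
ordinary least squares per voxel, vectorized across voxels;
`t = beta / SE(beta)` with df = n - 5. Voxels whose residual variance
vanishes to floating-point precision get t = +/-inf (or 0 when the tested
beta also vanishes) and a logged warning.

Tests on perplexity maps are one-sided for positive associations by
default (higher perplexity — richer, less predictable speech — with
larger volume), selectable per call; the group-difference map (GLM with a
group indicator) is two-sided. The in-analysis mask defaults to voxels
whose cohort-mean intensity exceeds 0.1 x the global mean of the mean
image (the conventional implicit-mask analogue); an explicit mask can be
passed.

Cluster inference follows the uncorrected-voxel-threshold convention:
suprathreshold voxels (p < 0.001) are partitioned into connected
components (default 18-connectivity, face+edge; 6 and 26 available) and
components with at least k = 100 voxels are reported, sorted by peak t,
ties broken by extent then lexicographic peak index. Benjamini–Hochberg
FDR (via statsmodels) is available over any p-value set; the BH rejection
set always contains the Bonferroni set at the same level.

The confirmatory stage mirrors the sequential whole-brain → ROI design:
each surviving cluster's peak voxel is looked up in an atlas label volume,
and the *entire* anatomical region containing the peak (not the cluster
extent) becomes an a-priori mask; duplicate regions are deduplicated, and
peaks in unlabelled territory produce no ROI (logged). Within each ROI
the report gives the peak t, its coordinate and one-sided p, the largest
suprathreshold component, and a significance flag defined as peak
p < 0.001. The flag deliberately uses the peak-level criterion: the ROI
restriction is itself the multiplicity control in this design, and on
desk-scale grids an extent criterion inside a small mask would conflate
region size with significance (the extent is still reported).

## Cohort statistics

Between-group tests are pooled-variance (Student) t-tests, computable
from raw data or directly from printed mean/SD/n summaries — the two
agree to machine precision, and the summary form reproduces the reference
cohort's printed t values (education 2.73, TMT-A -2.65 vs printed -2.64,
TMT-B -3.44 vs -3.43, logical memory 4.88 and 6.17 vs 6.16, perplexities
1.29 and 1.34) to within one unit in the last printed digit; the residual
discrepancies come from the inputs themselves being rounded to two
decimals. Welch's correction is available by flag but pooled is the
default, matching how the reference values recompute. The sex row is a
Pearson chi-square without continuity correction (Yates by flag); the
reference table's 12/14 vs 5/7 split recomputes to 0.067 where 0.06 was
printed — the variant behind the printed value is unknown, and no
agreement is forced. Missing values are dropped per variable with
correspondingly reduced df, and per-variable N is reported. In the
reference cohort the logical-memory rows have N = 37 and 36; assigning
the missing cases to the healthy group is the only split consistent with
the printed df, and is the overridable default. The Bonferroni-adjusted
level is alpha/m; over the 10 table rows this gives 0.005. Partial
correlations are Pearson correlations of OLS residuals on the covariates,
with df = n - 2 - (number of covariates).

## Synthetic study generator

The generator is a first-class, tested component: it defines the
conditions under which the pipeline is validated.

**Cohort.** Demographics and neuropsychological scores are group-
conditional normal draws; sex is Bernoulli. The default means/SDs are the
published summary statistics of the reference two-group cohort (26 HC, 12
MCI; age ~74, education 13.0 +/- 3.4 vs 10.2 +/- 1.5 years, MMSE ~28.8,
TMT-A/B, immediate/delayed logical memory). Scores are drawn
independently within participant; real neuropsychological batteries are
inter-correlated, so the synthetic correlation matrix is not meant to
reproduce the reference one (only its marginals and group contrasts).

**Transcripts.** A two-state process per participant: with probability
`repetition_rate` the previous token is repeated (perseveration),
otherwise a fresh word is drawn from a Zipf-like distribution
(`rank^-exponent`) over the group's vocabulary. Each participant's
log-weights are jittered with SD `idiosyncrasy` (personal favourite
words), and each participant's repetition rate is jittered on the logit
scale with SD `repetition_jitter` (personal sequential habits). The
defaults (vocabulary 1500 vs 1450 words, exponent 1.0 vs 1.005,
repetition 0.040 vs 0.045 for HC vs MCI, idiosyncrasy 0.35, repetition
jitter 1.0, transcript lengths uniform on 700-900 tokens) were chosen
once so that the cross-validated scores land on the reference scale:
mean 1-g perplexity ~238 (reference: 197.9), a small non-significant
group difference, and r(1-g, 2-g) ~ 0.85 (reference: 0.841). The
repetition jitter is what keeps the two measures from being collinear:
it moves the sequential statistics (2-g) much more than the lexical ones
(1-g), as in real speech. The absolute 2-g level (~540) is higher than
the reference (~114) because add-1-smoothed bigrams on ~30k-token
training corpora are sparse; the reference system's corpus and smoothing
are unknown, and no attempt is made to match that scale.

**Brain phantoms.** The desk-scale default grid is 32 x 32 x 24 voxels of
0.98 x 0.98 x 1.8 mm; an ellipsoidal "brain" with a smooth base
gray-matter profile (peak 0.6) fills the grid. Per participant the map
is: base x (1 + 0.05 x head-size factor) + 0.03 x sex + 0.02 x
standardized education (both as multiples of the base pattern) + planted
ROI effects + i.i.d. N(0, 0.05) voxel noise, zero outside the brain. The
head-size factor drives TIV, so the TIV covariate is meaningful. Each
planted ROI is a voxel box whose participant-level factor is
`rho * z(score) + sqrt(1 - rho^2) * eps` with standard-normal eps, painted
with amplitude 0.06 — the planted partial correlation (given sex,
education, TIV) between score and ROI mean realizes the target rho (~0.61
measured at rho = 0.6); the marginal correlation is attenuated by the
covariate structure, by design. The atlas labels an enclosing anatomical
region around each painted box (regions are larger than clusters, as in
real atlases, so a smoothed peak that drifts slightly off the box still
falls in its region) and partitions the remaining brain into octant
background parcels so every brain voxel is labelled. TIV is computed from
the unsmoothed maps; analysis smooths at 8-mm FWHM.

**What the phantom does not emulate:** cortical anatomy and folding,
spatial autocorrelation of the noise field before smoothing, registration
error, tissue-class mixing, site or scanner effects, non-Gaussian
gray-matter distributions, and realistic inter-correlation of
neuropsychological scores. Passing calibration here shows the statistical
machinery is correct and the planted effects are recoverable at the
stated n — not that real effects of that size would be detected in real
images.

## Calibration experiments

Run by `tests/test_acceptance.py` and `scripts/acceptance.py` at
desk-scale problem sizes (chosen as the package's standard quick-check
configuration):

- *Null calibration*: 20 phantom cohorts with no planted effects; the
  pooled fraction of in-mask voxels with one-sided p < 0.001 must lie in
  the binomial 99% band around 0.001. This runs on unsmoothed maps with
  no planted regions because the binomial band presupposes independent
  voxels: smoothing (spatially) and a planted-but-null box (through its
  shared participant factor) both leave voxels marginally null but
  over-disperse the pooled count. Marginal uniformity of the null
  p-values is tested separately (pooled Kolmogorov–Smirnov).
- *Recovery*: with rho = 0.6 planted in one region, the ROI flag must
  fire in >= 80% of 20 seeds under the full pipeline including smoothing
  (measured: 0.95).
- *Specificity*: two regions, one tied to each score; each score must
  flag its own region more often than the other's over 20 seeds. Here the
  a-priori masks are the painted boxes themselves: on the small grid,
  enlarged atlas regions would abut midway between the two planted boxes
  and each would capture the other's smoothing halo.
- *Exact oracles*: perplexity vs brute-force probability products
  (<= 20-token corpora, agreement to 1e-9); vectorized voxel t vs
  independent per-voxel normal-equation fits (1e-8) and vs the
  correlation identity t = r sqrt(n-2)/sqrt(1-r^2) (1e-9); scipy
  component labelling vs breadth-first flood fill on 1000 random
  lattices; the worked BH example and BH ⊇ Bonferroni containment.

## Numerical choices and degenerate inputs

- Degenerate voxels (residual variance at floating-point zero) yield
  t = +/-inf with p in {0, 1}, or t = 0 for an all-constant voxel.
- Cluster peak ties break to the lexicographically smallest voxel index;
  cluster ordering ties break by extent, then peak index.
- Zero-FWHM smoothing is the identity; FWHM < 0, |rho| >= 1, overlapping
  ROI boxes, empty masks, empty corpora, single-transcript
  cross-validation, zero marginals and rank-deficient designs all raise
  immediately with descriptive messages.
- Gzip members are checksummed after decompression in the run manifest
  (the gzip header embeds a timestamp).
- Per-stage seeds are the first four bytes of SHA-256 of
  "(global seed):(stage name)", reduced mod 2^31: stages keep their random
  streams when unrelated configuration changes.

## Known limitations

- Add-k is the only smoothing family; interpolated or backoff models
  (Kneser–Ney) would change absolute perplexity scales substantially.
- No permutation or random-field cluster inference; the uncorrected
  voxel + extent convention and BH-FDR are what is implemented.
- The group-difference map supports covariates but the default pipeline
  runs it unadjusted.
- Atlas handling assumes integer label volumes on the analysis grid; no
  resampling between grids is provided.
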