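# lingvbm

Linking the predictability of spontaneous speech to regional gray-matter
volume in aging cohorts.

Language change is among the earliest signs of cognitive decline. One
summary of spontaneous speech is **perplexity** — the exponentiated
per-word cross-entropy of a speaker's transcript under an n-gram language
model,

```
PP = exp( -(1/N) * sum_i ln p(w_i | context_i) )
```

scored with a unigram model (1-g, each word in isolation) and a bigram
model (2-g, each word given its predecessor). Lower perplexity means more
predictable, more repetitive speech. `lingvbm` implements the full
statistical pipeline that relates these scores to structural brain
measures in a two-group elderly cohort (cognitively healthy controls and
participants with mild cognitive impairment):

1. **Per-participant perplexity** by leave-one-participant-out
   cross-validation: the models scoring a transcript are trained on all
   *other* participants' transcripts (add-k smoothing, `<unk>` mapping for
   out-of-vocabulary words).
2. **Cohort statistics**: pooled two-sample t-tests (from raw data or from
   published mean/SD/n summaries), chi-square for sex, Pearson and partial
   correlations, Bonferroni adjustment, and standard sample-description /
   correlation-matrix report tables.
3. **Voxel-based morphometry**: mass-univariate OLS of smoothed
   gray-matter maps on a perplexity score, controlling for sex, years of
   education and total intracranial volume; one-sided t maps; uncorrected
   voxel threshold p < 0.001 with a 100-voxel cluster-extent criterion;
   Benjamini–Hochberg FDR; and confirmatory ROI analysis on the atlas
   regions containing the whole-brain cluster peaks.
4. **A synthetic study generator** — cohort table, interview-like token
   streams, and gray-matter phantoms with planted score–volume
   correlations — so the whole pipeline is testable and calibrated without
   any private interview or MRI data.

It is aimed at researchers prototyping speech-based biomarkers of
cognitive aging who need a reproducible, fully seeded reference
implementation of this analysis chain.

## Worked example

```python
from lingvbm.pipeline import PipelineConfig, run_full

manifest = run_full(PipelineConfig(seed=1, out_dir="demo"))
```

This simulates 38 participants (26 HC, 12 MCI), generates transcripts,
scores them by cross-validated perplexity, builds the cohort tables, fits
the voxel-wise models for both scores on a 32 x 32 x 24 phantom grid
(0.98 x 0.98 x 1.8 mm voxels, 8-mm FWHM smoothing) with one planted ROI
(target partial correlation 0.6 with 1-g perplexity), and runs the
cluster-screen → ROI-confirmation sequence. Key outputs under `demo/`:

`clusters_pp1g.tsv` — surviving whole-brain clusters for the 1-g score:

```
name                        n_voxels  peak_t  x_mm   y_mm  z_mm
left middle temporal gyrus      2297    6.05  -2.94  2.94   7.2
```

The planted region is recovered: one suprathreshold cluster (p < 0.001,
k >= 100) whose peak lies in the atlas region of the planted effect. The
2-g map has no planted effect in this scenario and `clusters_pp2g.tsv` is
empty. The confirmatory `roi_report.tsv`:

```
score  roi                         peak_t  significant
pp_1g  left middle temporal gyrus    6.05         True
```

`table1.tsv` holds the sample-description statistics of the simulated
cohort (pooled t or chi-square per row, with the Bonferroni-adjusted
level 0.005 over its 10 tests); for seed 1 the groups differ in TMT-B
(t(36) = -5.45) and delayed logical memory (t(36) = 8.07), while the mean
1-g perplexity is 233.8 (SD 44.6) with no significant group difference —
the scale and pattern the generator is calibrated to. `manifest.json`
records per-stage seeds and content checksums; re-running with the same
seed reproduces every file checksum exactly.

The same stages are available as a CLI:

```bash
lingvbm run-all --seed 1 --out-dir demo
lingvbm perplexity --corpus transcripts.jsonl --out scores.tsv
lingvbm vbm --volumes vols/ --table cohort.tsv --scores scores.tsv \
        --score pp_1g --p 0.001 --k 100 --connectivity 18 --direction positive
```

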