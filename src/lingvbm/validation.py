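"""Calibration and cross-check experiments for the whole pipeline.

The imaging results of any single small cohort are not reproducible without
its original interviews and scans, so the package's quantitative validation
rests on properties that are checkable from first principles:

* recomputation of the reference cohort's between-group t statistics from
  their printed summary statistics;
* exact oracles (brute-force perplexity, per-voxel reference GLM fits,
  flood-fill connected components, hand-computed Benjamini-Hochberg);
* simulation calibration: the voxel-level false-positive rate under a null
  phantom, planted-effect recovery power, and score-ROI specificity under
  the two-ROI dissociation scenario.

Every function takes an explicit seed and derives all internal randomness
from it.
"""

from __future__ import annotations

import math
from collections import Counter, deque

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import reference
from .cohort_stats import bonferroni_alpha, two_sample_t_summary
from .ngram import BOS, EOS, UNK, Transcript, fit_ngram, loocv_perplexity, perplexity, scores_to_frame
from .synthetic import (
    BrainSimConfig,
    CohortConfig,
    RoiSpec,
    default_profiles,
    simulate_brain_volumes,
    simulate_cohort_table,
    simulate_transcripts,
)
from .vbm import build_design, fdr_correct, fit_voxelwise, roi_analysis
from .volume_io import compute_tiv, gaussian_smooth, masks_from_atlas

__all__ = [
    "reference_table_tstats",
    "brute_force_perplexity",
    "perplexity_oracle_max_error",
    "glm_oracle_max_error",
    "correlation_t_identity_max_error",
    "flood_fill_components",
    "cluster_oracle_mismatches",
    "null_calibration",
    "null_pvalue_uniformity",
    "roi_power",
    "dissociation_flags",
    "bh_hand_example_rejections",
    "bh_bonferroni_containment_violations",
    "synthetic_perplexity_summary",
]

#: variables whose between-group t is recomputable from printed summaries
TSTAT_VARIABLES = [
    "education_years",
    "tmt_a",
    "tmt_b",
    "lm_immediate",
    "lm_delayed",
    "pp_1g",
    "pp_2g",
]


def reference_table_tstats() -> dict[str, float]:
    """Pooled two-sample t statistics of the reference cohort, recomputed
    from the printed group means/SDs/ns (sufficient statistics)."""
    out = {}
    for var in TSTAT_VARIABLES:
        hc, mci = reference.GROUP_SUMMARIES[var]
        out[var] = two_sample_t_summary(hc, mci).statistic
    return out


# ---------------------------------------------------------------------------
# exact oracles


def brute_force_perplexity(
    training: list[Transcript],
    held_out: Transcript,
    order: int,
    k: float = 1.0,
    min_count: int = 1,
) -> float:
    """Direct probability-product perplexity, recomputed from raw counts.

    Independent of :class:`~lingvbm.ngram.NGramModel`: counts, vocabulary
    mapping and the add-k formula are re-derived here from scratch, and the
    perplexity is the N-th root of the inverse probability product.
    """
    raw: Counter = Counter()
    for tr in training:
        raw.update(tr.tokens)
    vocab = {w for w, c in raw.items() if c >= min_count}
    if len(vocab) < len(raw):
        vocab.add(UNK)

    def m(w):
        return w if w in vocab else UNK

    if order == 1:
        counts = Counter(m(w) for tr in training for w in tr.tokens)
        n = sum(counts.values())
        v = len(vocab)
        prod = 1.0
        toks = [m(w) for w in held_out.tokens]
        for w in toks:
            prod *= (counts.get(w, 0) + k) / (n + k * v)
        return prod ** (-1.0 / len(toks))
    pair: Counter = Counter()
    ctx: Counter = Counter()
    for tr in training:
        seq = [BOS, *(m(w) for w in tr.tokens), EOS]
        for a, b in zip(seq, seq[1:]):
            pair[(a, b)] += 1
            ctx[a] += 1
    v = len(vocab) + 1  # outcomes include </s>
    seq = [BOS, *(m(w) for w in held_out.tokens), EOS]
    prod = 1.0
    for a, b in zip(seq, seq[1:]):
        prod *= (pair.get((a, b), 0) + k) / (ctx.get(a, 0) + k * v)
    return prod ** (-1.0 / (len(seq) - 1))


def perplexity_oracle_max_error(seed: int, n_corpora: int = 50) -> float:
    """Max |PP - brute force PP| over random tiny corpora (<= 20 tokens)."""
    rng = np.random.default_rng(seed)
    alphabet = list("abcde")
    worst = 0.0
    for _ in range(n_corpora):
        n_tr = int(rng.integers(2, 5))
        corpus = []
        for i in range(n_tr):
            length = int(rng.integers(1, 6))
            toks = rng.choice(alphabet, size=length).tolist()
            corpus.append(Transcript(f"t{i}", toks))
        k = float(rng.choice([0.1, 0.5, 1.0]))
        mc = int(rng.choice([1, 2]))
        held, training = corpus[0], corpus[1:]
        if not training:
            continue
        for order in (1, 2):
            model = fit_ngram(training, order=order, k=k, min_count=mc)
            pp = perplexity(model, held)
            oracle = brute_force_perplexity(training, held, order, k=k, min_count=mc)
            worst = max(worst, abs(pp - oracle))
    return worst


def glm_oracle_max_error(seed: int, shape=(10, 10, 10), n: int = 38) -> float:
    """Max |t - t_ref| between the vectorized fit and an independent
    per-voxel normal-equations fit on a random fixture."""
    rng = np.random.default_rng(seed)
    x = np.column_stack(
        [
            np.ones(n),
            rng.normal(size=n),
            rng.integers(0, 2, n).astype(float),
            rng.normal(12, 3, n),
            rng.normal(1400, 100, n),
        ]
    )
    data = rng.normal(size=(n, *shape))
    from .vbm import DesignMatrix
    from .volume_io import VolumeImage

    design = DesignMatrix(
        matrix=x,
        columns=["intercept", "score", "sex", "education_years", "tiv_ml"],
        participant_ids=[str(i) for i in range(n)],
        tested="score",
    )
    vols = [VolumeImage(data[i], np.eye(4)) for i in range(n)]
    mask = np.ones(shape, dtype=bool)
    result = fit_voxelwise(vols, design, mask=mask)

    # independent reference: explicit per-voxel solve of the normal equations
    xtx_inv = np.linalg.inv(x.T @ x)
    df = n - x.shape[1]
    worst = 0.0
    y_flat = data.reshape(n, -1)
    t_flat = result.t.reshape(-1)
    for vidx in range(y_flat.shape[1]):
        y = y_flat[:, vidx]
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        s2 = resid @ resid / df
        t_ref = beta[1] / math.sqrt(s2 * xtx_inv[1, 1])
        worst = max(worst, abs(t_flat[vidx] - t_ref))
    return worst


def correlation_t_identity_max_error(seed: int, n: int = 38, n_voxels: int = 64) -> float:
    """Max deviation of the covariate-free voxel t from r*sqrt(n-2)/sqrt(1-r^2)."""
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    data = rng.normal(size=(n, 4, 4, n_voxels // 16))
    from .vbm import DesignMatrix
    from .volume_io import VolumeImage

    design = DesignMatrix(
        matrix=np.column_stack([np.ones(n), score]),
        columns=["intercept", "score"],
        participant_ids=[str(i) for i in range(n)],
        tested="score",
    )
    vols = [VolumeImage(data[i], np.eye(4)) for i in range(n)]
    result = fit_voxelwise(vols, design, mask=np.ones(data.shape[1:], bool))
    worst = 0.0
    for idx in np.ndindex(*data.shape[1:]):
        y = data[(slice(None), *idx)]
        r = np.corrcoef(score, y)[0, 1]
        t_ref = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        worst = max(worst, abs(result.t[idx] - t_ref))
    return worst


# ---------------------------------------------------------------------------
# connected components


def flood_fill_components(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first flood-fill labelling, independent of scipy.ndimage."""
    offsets = []
    for d in np.ndindex(3, 3, 3):
        off = tuple(v - 1 for v in d)
        if off == (0, 0, 0):
            continue
        manhattan = sum(abs(v) for v in off)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offsets.append(off)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in np.argwhere(binary):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            ijk = queue.popleft()
            for off in offsets:
                nb = tuple(a + b for a, b in zip(ijk, off))
                if any(v < 0 or v >= s for v, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not labels[nb]:
                    labels[nb] = current
                    queue.append(nb)
    return labels


def cluster_oracle_mismatches(seed: int, n_lattices: int = 1000) -> int:
    """Count lattices where scipy-based labelling disagrees with flood fill
    (component count or any component's voxel set)."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    ranks = {6: 1, 18: 2, 26: 3}
    for _ in range(n_lattices):
        size = int(rng.integers(4, 17))
        p = float(rng.uniform(0.15, 0.5))
        lattice = rng.random((size, size, max(4, size // 2))) < p
        conn = int(rng.choice([6, 18, 26]))
        ours, n_ours = ndimage.label(
            lattice, structure=ndimage.generate_binary_structure(3, ranks[conn])
        )
        ref = flood_fill_components(lattice, conn)
        if n_ours != ref.max():
            mismatches += 1
            continue
        # same partition iff the label images are related by a bijection
        ok = True
        for comp_id in range(1, n_ours + 1):
            ref_ids = np.unique(ref[ours == comp_id])
            if len(ref_ids) != 1 or (ref == ref_ids[0]).sum() != (ours == comp_id).sum():
                ok = False
                break
        if not ok:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# simulation calibration


def _pipeline_scores(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    transcripts = simulate_transcripts(table, default_profiles(), seed=seed)
    return scores_to_frame(loocv_perplexity(transcripts))


def _fit_for_score(table, scores, volumes, score):
    tiv = pd.DataFrame(
        {
            "participant_id": table["participant_id"],
            "tiv_ml": [compute_tiv([v]) for v in volumes],
        }
    )
    design = build_design(table.merge(tiv, on="participant_id"), scores, tested=score)
    return design


def null_calibration(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of in-mask voxels with one-sided p < 0.001 under a null
    phantom, pooled over seeds, on unsmoothed maps.

    The null phantom plants no effect regions (all rho = 0), leaving i.i.d.
    voxel noise, so the pooled exceedance count is exactly binomial.  (A
    planted box with rho = 0 keeps its voxels marginally null but they share
    the participant-level factor, which would widen the count distribution
    beyond binomial; smoothing would do the same spatially.)
    """
    rng = np.random.default_rng(seed)
    total = 0
    exceed = 0
    for i in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        table = simulate_cohort_table(CohortConfig(seed=s))
        scores = _pipeline_scores(table, seed=s + 1)
        cfg = BrainSimConfig(roi_specs=())
        volumes, _, _ = simulate_brain_volumes(table, scores, cfg, seed=s + 2)
        design = _fit_for_score(table, scores, volumes, "pp_1g")
        result = fit_voxelwise(volumes, design)
        p = result.p[result.mask]
        total += p.size
        exceed += int((p < 0.001).sum())
    return {"n_voxels": total, "n_exceed": exceed, "fraction": exceed / total}


def null_pvalue_uniformity(seed: int, n_seeds: int = 5) -> float:
    """Kolmogorov-Smirnov p-value for uniformity of the pooled null
    voxel-wise one-sided p-values (no planted effects, unsmoothed)."""
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        table = simulate_cohort_table(CohortConfig(seed=s))
        scores = _pipeline_scores(table, seed=s + 1)
        volumes, _, _ = simulate_brain_volumes(
            table, scores, BrainSimConfig(roi_specs=()), seed=s + 2
        )
        design = _fit_for_score(table, scores, volumes, "pp_1g")
        result = fit_voxelwise(volumes, design)
        pooled.append(result.p[result.mask])
    pooled = np.concatenate(pooled)
    return float(stats.kstest(pooled, "uniform").pvalue)


def roi_power(seed: int, n_seeds: int = 20, rho: float = 0.6) -> dict:
    """Fraction of seeds where the full pipeline's ROI analysis flags the
    planted region (peak one-sided p < 0.001), with 8-mm smoothing."""
    rng = np.random.default_rng(seed)
    flagged = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        table = simulate_cohort_table(CohortConfig(seed=s))
        scores = _pipeline_scores(table, seed=s + 1)
        cfg = BrainSimConfig(
            roi_specs=(
                RoiSpec(
                    label=1,
                    name="left middle temporal gyrus",
                    score="pp_1g",
                    rho=rho,
                    center=(9, 16, 12),
                ),
            )
        )
        raw, atlas, label_map = simulate_brain_volumes(table, scores, cfg, seed=s + 2)
        design = _fit_for_score(table, scores, raw, "pp_1g")
        smoothed = [gaussian_smooth(v, cfg.fwhm_mm) for v in raw]
        result = fit_voxelwise(smoothed, design)
        roi = [m for m in masks_from_atlas(atlas, label_map) if m.label == 1]
        report = roi_analysis(result, roi)
        flagged += int(report["significant"].iloc[0])
    return {"n_seeds": n_seeds, "n_flagged": flagged, "fraction": flagged / n_seeds}


# For the two-ROI specificity scenario the atlas regions equal the painted
# boxes: on the desk-scale grid, enlarged regions would abut midway between
# the two planted effects and each would catch the other's smoothing halo.
DISSOCIATION_ROIS = (
    RoiSpec(label=1, name="left middle temporal gyrus", score="pp_1g", rho=0.6,
            center=(9, 16, 12), region_half_size=(4, 4, 3)),
    RoiSpec(label=2, name="left precuneus", score="pp_2g", rho=0.6,
            center=(22, 16, 12), region_half_size=(4, 4, 3)),
)


def dissociation_flags(seed: int, n_seeds: int = 20) -> dict:
    """Two planted ROIs, one per score: per score, how often its own ROI vs
    the other score's ROI is flagged by the ROI analysis."""
    rng = np.random.default_rng(seed)
    own = {"pp_1g": 0, "pp_2g": 0}
    cross = {"pp_1g": 0, "pp_2g": 0}
    own_label = {"pp_1g": 1, "pp_2g": 2}
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        table = simulate_cohort_table(CohortConfig(seed=s))
        scores = _pipeline_scores(table, seed=s + 1)
        cfg = BrainSimConfig(roi_specs=DISSOCIATION_ROIS)
        raw, atlas, label_map = simulate_brain_volumes(table, scores, cfg, seed=s + 2)
        smoothed = [gaussian_smooth(v, cfg.fwhm_mm) for v in raw]
        rois = [m for m in masks_from_atlas(atlas, label_map) if m.label in (1, 2)]
        for score in ("pp_1g", "pp_2g"):
            design = _fit_for_score(table, scores, raw, score)
            result = fit_voxelwise(smoothed, design)
            report = roi_analysis(result, rois).set_index("label")
            own[score] += int(report.loc[own_label[score], "significant"])
            cross[score] += int(report.loc[3 - own_label[score], "significant"])
    return {"n_seeds": n_seeds, "own": own, "cross": cross}


# ---------------------------------------------------------------------------
# multiple testing


def bh_hand_example_rejections() -> int:
    """Rejections of the worked BH example [0.001, 0.01, 0.02, 0.05] at q=0.05."""
    reject, _ = fdr_correct(np.array([0.001, 0.01, 0.02, 0.05]), q=0.05)
    return int(reject.sum())


def bh_bonferroni_containment_violations(seed: int, n_vectors: int = 1000) -> int:
    """Vectors where some Bonferroni rejection is not also a BH rejection."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 50))
        p = rng.random(m) ** float(rng.uniform(0.5, 3.0))
        q = 0.05
        bh, _ = fdr_correct(p, q=q)
        bonf = p <= q / m
        if np.any(bonf & ~bh):
            violations += 1
    return violations


def synthetic_perplexity_summary(seed: int) -> dict:
    """Mean cross-validated perplexities of a default synthetic cohort."""
    table = simulate_cohort_table(CohortConfig(seed=seed))
    scores = _pipeline_scores(table, seed=seed + 1)
    return {
        "n": len(scores),
        "mean_pp_1g": float(scores["pp_1g"].mean()),
        "mean_pp_2g": float(scores["pp_2g"].mean()),
        "r_pp1g_pp2g": float(np.corrcoef(scores["pp_1g"], scores["pp_2g"])[0, 1]),
    }
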