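"""Synthetic study generator: cohort table, transcripts, gray-matter volumes.

Generates a full two-group (healthy control / mild cognitive impairment)
study so that every downstream stage — cross-validated perplexity, cohort
statistics, voxel-wise regression, ROI confirmation — can be exercised and
calibrated without any real interview audio or MRI data.

The pieces:

* ``simulate_cohort_table`` draws demographics and neuropsychological scores
  from group-conditional normal distributions whose default means/SDs are
  the published summary statistics of the reference cohort (26 HC, 12 MCI).
* ``simulate_transcripts`` emits token streams from a two-state process:
  with probability ``repetition_rate`` the previous token is repeated,
  otherwise a fresh word is drawn from a participant-specific Zipf-like
  lexicon.  Smaller vocabularies and more repetition — the impairment-like
  profile — give more predictable speech, hence lower cross-validated
  perplexity.
* ``simulate_brain_volumes`` builds gray-matter maps on a desk-scale grid
  (default 32 x 32 x 24 voxels of 0.98 x 0.98 x 1.8 mm) with planted
  score-volume correlations in designated box ROIs, covariate effects
  (sex, education, a global head-size factor driving TIV), and i.i.d.
  Gaussian voxel noise.  The planted ROI means are ``rho * z_score +
  sqrt(1 - rho^2) * eps`` with standard-normal ``eps``, which makes the
  target correlation analytically controllable; outside the ROIs voxel
  values are independent of the scores given the covariates.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ngram import Transcript
from .reference import GROUP_SUMMARIES, N_HC, N_MCI, SEX_COUNTS
from .volume_io import VolumeImage

__all__ = [
    "CohortConfig",
    "LanguageProfile",
    "RoiSpec",
    "BrainSimConfig",
    "default_profiles",
    "simulate_cohort_table",
    "simulate_transcripts",
    "simulate_brain_volumes",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "education_years",
    "mmse",
    "tmt_a",
    "tmt_b",
    "lm_immediate",
    "lm_delayed",
]

#: variables drawn from group-conditional normals (perplexity is computed
#: downstream from transcripts, never drawn)
_COHORT_VARIABLES = [
    "age",
    "education_years",
    "mmse",
    "tmt_a",
    "tmt_b",
    "lm_immediate",
    "lm_delayed",
]


def _default_group_params() -> dict[str, dict[str, tuple[float, float]]]:
    out: dict[str, dict[str, tuple[float, float]]] = {"HC": {}, "MCI": {}}
    for var in _COHORT_VARIABLES:
        hc, mci = GROUP_SUMMARIES[var]
        out["HC"][var] = (hc.mean, hc.sd)
        out["MCI"][var] = (mci.mean, mci.sd)
    return out


def _default_sex_p() -> dict[str, float]:
    return {
        g: m / (m + f) for g, (m, f) in SEX_COUNTS.items()
    }


@dataclass
class CohortConfig:
    """Group sizes and group-conditional distribution parameters.

    ``group_params[group][variable] = (mean, sd)``; ``sex_male_p[group]`` is
    the Bernoulli probability of being male (coded 1).  Defaults reproduce
    the reference cohort's distributions.
    """

    n_hc: int = N_HC
    n_mci: int = N_MCI
    group_params: dict = field(default_factory=_default_group_params)
    sex_male_p: dict = field(default_factory=_default_sex_p)
    seed: int = 0

    def __post_init__(self):
        if self.n_hc < 2 or self.n_mci < 2:
            raise ValueError("each group needs at least 2 participants")
        for g, params in self.group_params.items():
            for var, (mean, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {g}/{var}")
        for g, p in self.sex_male_p.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sex proportion for {g} outside [0, 1]")


def simulate_cohort_table(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """One row per participant, drawn from the configured group distributions."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    counts = [("HC", config.n_hc), ("MCI", config.n_mci)]
    idx = 0
    for group, n in counts:
        params = config.group_params[group]
        for _ in range(n):
            idx += 1
            row = {"participant_id": f"S{idx:03d}", "group": group}
            row["sex"] = int(rng.random() < config.sex_male_p[group])
            for var in _COHORT_VARIABLES:
                mean, sd = params[var]
                row[var] = float(rng.normal(mean, sd))
            rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@dataclass
class LanguageProfile:
    """Parameters of the two-state transcript process for one group.

    ``vocabulary_size`` words are available, weighted by a Zipf-like power
    law with exponent ``zipf_exponent``; each participant's log-weights are
    jittered by ``idiosyncrasy`` (an SD on the log scale) so speakers have
    personal favourite words.  ``repetition_rate`` is the probability of
    repeating the previous token; ``repetition_jitter`` is a per-participant
    SD on the logit of that rate, giving speakers individual sequential
    habits so the 2-g measure carries information beyond the 1-g one (the
    two perplexities end up strongly but not perfectly correlated, as in
    real interview speech).  Transcript lengths are uniform over
    ``length_range``.
    """

    vocabulary_size: int = 1500
    zipf_exponent: float = 1.0
    repetition_rate: float = 0.04
    repetition_jitter: float = 1.0
    length_range: tuple[int, int] = (700, 900)
    idiosyncrasy: float = 0.35

    def __post_init__(self):
        if self.vocabulary_size < 2:
            raise ValueError("vocabulary_size must be >= 2")
        if not 0 <= self.repetition_rate < 1:
            raise ValueError("repetition_rate must be in [0, 1)")
        if self.length_range[0] < 10 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid transcript length range")


def default_profiles() -> dict[str, LanguageProfile]:
    """Group profiles tuned so the cohort's cross-validated 1-g perplexity
    lands on the reference scale (mean around 150-250): the MCI profile has
    a smaller vocabulary and more repetition than the HC profile."""
    return {
        "HC": LanguageProfile(
            vocabulary_size=1500,
            zipf_exponent=1.0,
            repetition_rate=0.04,
            repetition_jitter=1.0,
            length_range=(700, 900),
            idiosyncrasy=0.35,
        ),
        "MCI": LanguageProfile(
            vocabulary_size=1450,
            zipf_exponent=1.005,
            repetition_rate=0.045,
            repetition_jitter=1.0,
            length_range=(700, 900),
            idiosyncrasy=0.35,
        ),
    }


def simulate_transcripts(
    table: pd.DataFrame,
    profiles: Mapping[str, LanguageProfile] | None = None,
    seed: int = 0,
) -> list[Transcript]:
    """One transcript per participant from the group's two-state process."""
    if len(table) == 0:
        raise ValueError("empty cohort table")
    if profiles is None:
        profiles = default_profiles()
    missing = set(table["group"]) - set(profiles)
    if missing:
        raise ValueError(f"no language profile for groups: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    out = []
    for _, row in table.iterrows():
        prof = profiles[row["group"]]
        v = prof.vocabulary_size
        ranks = np.arange(1, v + 1, dtype=float)
        logw = -prof.zipf_exponent * np.log(ranks)
        logw = logw + prof.idiosyncrasy * rng.standard_normal(v)
        w = np.exp(logw - logw.max())
        probs = w / w.sum()
        length = int(rng.integers(prof.length_range[0], prof.length_range[1] + 1))
        novel = rng.choice(v, size=length, p=probs)
        rep = prof.repetition_rate
        if prof.repetition_jitter > 0 and 0 < rep < 1:
            logit = np.log(rep / (1 - rep)) + prof.repetition_jitter * rng.standard_normal()
            rep = 1.0 / (1.0 + np.exp(-logit))
        repeat = rng.random(length) < rep
        repeat[0] = False
        tokens = np.empty(length, dtype=np.int64)
        tokens[0] = novel[0]
        for i in range(1, length):
            tokens[i] = tokens[i - 1] if repeat[i] else novel[i]
        words = [f"w{t:05d}" for t in tokens]
        out.append(Transcript(row["participant_id"], words))
    return out


@dataclass
class RoiSpec:
    """A planted-effect region with its enclosing anatomical atlas region.

    The effect is painted in a voxel-aligned box (``center`` +/-
    ``half_size``) with target correlation ``rho`` between the named score
    and the box's mean gray matter.  The atlas labels a larger enclosing box
    (``region_half_size``), mimicking that anatomical atlas regions are
    larger than the activation clusters they contain — after smoothing, a
    cluster peak can drift a little outside the painted box but should still
    fall inside its anatomical region.
    """

    label: int
    name: str
    score: str
    rho: float
    center: tuple[int, int, int]
    half_size: tuple[int, int, int] = (4, 4, 3)
    region_half_size: tuple[int, int, int] = (6, 6, 5)

    def __post_init__(self):
        if abs(self.rho) >= 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.label <= 0:
            raise ValueError("ROI label must be a positive integer")
        if any(r < h for r, h in zip(self.region_half_size, self.half_size)):
            raise ValueError("atlas region must enclose the effect box")

    def _slices(self, half, shape) -> tuple[slice, slice, slice]:
        sl = []
        for c, h, s in zip(self.center, half, shape):
            lo, hi = c - h, c + h + 1
            if lo < 0 or hi > s:
                raise ValueError(f"ROI {self.name!r} box exceeds the grid")
            sl.append(slice(lo, hi))
        return tuple(sl)

    def box(self, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        return self._slices(self.half_size, shape)

    def region(self, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        return self._slices(self.region_half_size, shape)


@dataclass
class BrainSimConfig:
    """Geometry, planted effects and nuisance structure of the phantom.

    ``noise_sd`` is i.i.d. Gaussian voxel noise on the unsmoothed map;
    ``effect_amplitude`` scales the planted ROI signal (per unit of the
    standardized ROI factor); sex/education effects are multiples of the
    base gray-matter pattern; ``global_effect`` is a per-participant head
    size factor that also drives total intracranial volume.  ``fwhm_mm`` is
    the smoothing the analysis pipeline applies downstream.
    """

    shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_mm: tuple[float, float, float] = (0.98, 0.98, 1.8)
    roi_specs: tuple[RoiSpec, ...] = (
        RoiSpec(
            label=1,
            name="left middle temporal gyrus",
            score="pp_1g",
            rho=0.6,
            center=(9, 16, 12),
        ),
    )
    sex_effect: float = 0.03
    education_effect: float = 0.02
    global_effect: float = 0.05
    noise_sd: float = 0.05
    effect_amplitude: float = 0.06
    base_intensity: float = 0.6
    fwhm_mm: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.shape):
            raise ValueError("grid shape must be >= 8 along every axis")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")
        labels = [r.label for r in self.roi_specs]
        if len(labels) != len(set(labels)):
            raise ValueError("ROI labels must be distinct")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        for ax, vs in enumerate(self.voxel_size_mm):
            aff[ax, ax] = vs
            aff[ax, 3] = -vs * self.shape[ax] / 2.0
        return aff


def _brain_base(config: BrainSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal brain mask and a smooth base gray-matter pattern."""
    grids = np.meshgrid(
        *[np.arange(s, dtype=float) for s in config.shape], indexing="ij"
    )
    r2 = sum(
        ((g - (s - 1) / 2.0) / (0.45 * s)) ** 2 for g, s in zip(grids, config.shape)
    )
    mask = r2 <= 1.0
    base = np.where(mask, config.base_intensity * (1.0 - 0.5 * r2), 0.0)
    return mask, base


def simulate_brain_volumes(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    config: BrainSimConfig,
    seed: int | None = None,
) -> tuple[list[VolumeImage], VolumeImage, dict[int, str]]:
    """Unsmoothed gray-matter maps with planted effects, plus the atlas.

    Returns ``(volumes, atlas, label_map)``: one map per participant (row
    order of ``table``), an integer label volume marking each planted ROI,
    and the label -> name map.  ROI boxes must not overlap.  The analysis
    pipeline is expected to compute TIV from these unsmoothed maps and then
    smooth with ``config.fwhm_mm``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    merged = table.merge(scores, on="participant_id", how="inner")
    if len(merged) != len(table):
        raise ValueError("scores are not joinable to every participant")
    n = len(merged)

    mask, base = _brain_base(config)
    shape = config.shape
    affine = config.affine

    # atlas: planted anatomical regions, then octant background parcels so
    # every in-brain voxel carries a label (as in a whole-brain atlas)
    atlas_data = np.zeros(shape, dtype=float)
    label_map: dict[int, str] = {}
    for spec in config.roi_specs:
        region = spec.region(shape)
        if (atlas_data[region] != 0).any():
            raise ValueError(f"ROI {spec.name!r} overlaps another ROI")
        atlas_data[region] = spec.label
        label_map[spec.label] = spec.name
    octant = np.zeros(shape, dtype=int)
    for ax, s in enumerate(shape):
        ix = (np.arange(s) >= s // 2).astype(int)
        octant += ix.reshape([-1 if a == ax else 1 for a in range(3)]) << ax
    background = mask & (atlas_data == 0)
    base_label = 100
    for o in range(8):
        sel = background & (octant == o)
        if sel.any():
            atlas_data[sel] = base_label + o
            label_map[base_label + o] = f"background parcel {o + 1}"

    def _zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    sex = merged["sex"].to_numpy(dtype=float)
    edu_z = _zscore(merged["education_years"].to_numpy(dtype=float))
    head = rng.standard_normal(n)  # global head-size factor -> TIV variation

    roi_factors = {}
    for spec in config.roi_specs:
        z = _zscore(merged[spec.score].to_numpy(dtype=float))
        eps = rng.standard_normal(n)
        roi_factors[spec.label] = spec.rho * z + np.sqrt(1 - spec.rho**2) * eps

    pattern = np.where(mask, base / max(config.base_intensity, 1e-12), 0.0)
    volumes = []
    for i in range(n):
        vol = base * (1.0 + config.global_effect * head[i])
        vol = vol + config.sex_effect * sex[i] * pattern
        vol = vol + config.education_effect * edu_z[i] * pattern
        for spec in config.roi_specs:
            box = spec.box(shape)
            vol = vol.copy()
            vol[box] += config.effect_amplitude * roi_factors[spec.label][i]
        noise = rng.standard_normal(shape) * config.noise_sd
        volumes.append(VolumeImage(np.where(mask, vol + noise, 0.0), affine))
    return volumes, VolumeImage(atlas_data, affine), label_map
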