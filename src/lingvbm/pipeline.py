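"""End-to-end orchestration: simulate -> perplexity -> stats -> VBM -> ROI.

Mirrors the sequential analysis strategy of the study design: a whole-brain
multiple regression of gray matter on each perplexity measure first screens
for suprathreshold clusters; the atlas regions containing the surviving
cluster peaks then become the a-priori masks of a confirmatory ROI analysis.

Every stage derives its own seed deterministically from the global seed and
the stage name, so the run is reproducible end to end and a stage keeps its
random stream when unrelated config changes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, vbm, volume_io
from .ngram import loocv_perplexity, scores_to_frame, write_transcripts_jsonl
from .synthetic import (
    BrainSimConfig,
    CohortConfig,
    LanguageProfile,
    RoiSpec,
    default_profiles,
    simulate_brain_volumes,
    simulate_cohort_table,
    simulate_transcripts,
)
from .vbm import (
    build_design,
    clusters_to_frame,
    fit_voxelwise,
    group_difference_tmap,
    roi_analysis,
    threshold_and_cluster,
)
from .volume_io import ROIMask, VolumeImage, gaussian_smooth, masks_from_atlas

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "select_rois_from_clusters",
    "run_full",
]

logger = logging.getLogger(__name__)

_STAGES = ("cohort", "transcripts", "volumes")


@dataclass
class PipelineConfig:
    """Nested configuration of every stage plus global seed and output dir."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    profiles: dict = field(default_factory=default_profiles)
    brain: BrainSimConfig = field(default_factory=BrainSimConfig)
    smoothing_fwhm_mm: float | None = None  # default: brain.fwhm_mm
    ngram_k: float = 1.0
    ngram_min_count: int = 1
    p_voxel: float = 0.001
    k_min: int = 100
    connectivity: int = 18
    direction: str = "positive"
    tested_scores: tuple[str, ...] = ("pp_1g", "pp_2g")
    seed: int = 0
    out_dir: str = "lingvbm_out"
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "profiles" in kwargs:
            kwargs["profiles"] = {
                g: LanguageProfile(**p) for g, p in kwargs["profiles"].items()
            }
        if "brain" in kwargs:
            b = dict(kwargs["brain"])
            if "roi_specs" in b:
                b["roi_specs"] = tuple(RoiSpec(**r) for r in b["roi_specs"])
            for key in ("shape", "voxel_size_mm"):
                if key in b:
                    b[key] = tuple(b[key])
            kwargs["brain"] = BrainSimConfig(**b)
        for key in ("tested_scores",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = {g: asdict(p) for g, p in self.profiles.items()}
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from (global seed, stage)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def select_rois_from_clusters(
    clusters: Sequence[vbm.Cluster],
    atlas: VolumeImage,
    label_map: Mapping[int, str],
) -> list[ROIMask]:
    """Whole atlas regions containing surviving cluster peaks.

    For each cluster, the atlas label at the peak voxel defines the ROI as
    the full anatomical region (not the cluster extent); duplicate labels
    are emitted once.  Peaks in unlabelled (0) territory yield no ROI and
    are logged.
    """
    labels_img = np.asarray(atlas.data).astype(int)
    seen: list[int] = []
    for c in clusters:
        label = int(labels_img[c.peak_ijk])
        if label == 0:
            logger.info(
                "cluster peak at %s lies in unlabelled territory; no ROI", c.peak_ijk
            )
            continue
        if label not in seen:
            seen.append(label)
    return [
        ROIMask(name=label_map.get(l, str(l)), label=l, mask=labels_img == l)
        for l in seen
    ]


def _file_checksum(path: Path) -> str:
    """Content checksum; gzip members are decompressed first because the
    gzip header embeds a timestamp."""
    import gzip

    data = path.read_bytes()
    if path.suffix == ".gz":
        data = gzip.decompress(data)
    return hashlib.md5(data).hexdigest()


def run_full(config: PipelineConfig) -> dict:
    """Execute all stages in order and write the report files.

    Outputs under ``config.out_dir``: cohort.tsv, transcripts.jsonl,
    scores.tsv, table1.tsv, correlations.tsv, clusters_<score>.tsv and
    tmap_<score>.nii.gz per tested score, roi_report.tsv, group_clusters.tsv,
    atlas.nii.gz + atlas_labels.tsv, and manifest.json.  Returns the
    manifest.  Any stage failure raises with the stage name; the partial
    manifest is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in _STAGES}
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": {},
        "outputs": {},
        "completed_stages": [],
    }

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def _register(path: Path):
        manifest["outputs"][path.name] = _file_checksum(path)

    stage = "init"
    try:
        # --- synthetic cohort -------------------------------------------
        stage = "cohort"
        table = simulate_cohort_table(config.cohort, seed=seeds["cohort"])
        table.to_csv(out / "cohort.tsv", sep="\t", index=False)
        _register(out / "cohort.tsv")
        manifest["counts"]["participants"] = len(table)
        manifest["completed_stages"].append(stage)

        # --- transcripts and cross-validated perplexity -----------------
        stage = "transcripts"
        transcripts = simulate_transcripts(
            table, config.profiles, seed=seeds["transcripts"]
        )
        write_transcripts_jsonl(transcripts, out / "transcripts.jsonl")
        _register(out / "transcripts.jsonl")
        manifest["counts"]["tokens"] = int(sum(len(t.tokens) for t in transcripts))
        manifest["completed_stages"].append(stage)

        stage = "perplexity"
        scores = scores_to_frame(
            loocv_perplexity(
                transcripts, k=config.ngram_k, min_count=config.ngram_min_count
            )
        )
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        _register(out / "scores.tsv")
        manifest["completed_stages"].append(stage)

        # --- cohort statistics ------------------------------------------
        stage = "stats"
        table1 = cohort_stats.build_table1(table, scores)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)
        _register(out / "table1.tsv")
        merged = table.merge(scores, on="participant_id")
        corr_vars = [
            v
            for v in cohort_stats.TABLE1_VARIABLES
            if v != "age" and v in merged.columns
        ]
        r, p = cohort_stats.correlation_matrix(merged, ["education_years", "sex"] + [
            v for v in corr_vars if v != "education_years"
        ])
        r.to_csv(out / "correlations.tsv", sep="\t")
        p.to_csv(out / "correlations_p.tsv", sep="\t")
        _register(out / "correlations.tsv")
        _register(out / "correlations_p.tsv")
        manifest["completed_stages"].append(stage)

        # --- synthetic brain volumes ------------------------------------
        stage = "volumes"
        raw_volumes, atlas, label_map = simulate_brain_volumes(
            table, scores, config.brain, seed=seeds["volumes"]
        )
        volume_io.save_volume(atlas, out / "atlas.nii.gz")
        volume_io.write_label_map(label_map, out / "atlas_labels.tsv")
        _register(out / "atlas.nii.gz")
        _register(out / "atlas_labels.tsv")
        tiv = pd.DataFrame(
            {
                "participant_id": table["participant_id"],
                "tiv_ml": [volume_io.compute_tiv([v]) for v in raw_volumes],
            }
        )
        tiv.to_csv(out / "tiv.tsv", sep="\t", index=False)
        _register(out / "tiv.tsv")
        fwhm = (
            config.brain.fwhm_mm
            if config.smoothing_fwhm_mm is None
            else config.smoothing_fwhm_mm
        )
        volumes = [gaussian_smooth(v, fwhm) for v in raw_volumes]
        if config.write_volumes:
            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for pid, v in zip(table["participant_id"], volumes):
                volume_io.save_volume(v, vol_dir / f"{pid}.nii.gz")
        manifest["counts"]["voxels"] = int(np.prod(config.brain.shape))
        manifest["completed_stages"].append(stage)

        # --- whole-brain VBM + ROI confirmation per score ---------------
        stage = "vbm"
        table_tiv = table.merge(tiv, on="participant_id")
        roi_reports = []
        for score in config.tested_scores:
            tag = score.replace("_", "")  # pp_1g -> pp1g in file names
            design = build_design(table_tiv, scores, tested=score)
            result = fit_voxelwise(volumes, design, direction=config.direction)
            volume_io.save_volume(
                VolumeImage(np.nan_to_num(result.t), result.affine),
                out / f"tmap_{tag}.nii.gz",
            )
            _register(out / f"tmap_{tag}.nii.gz")
            clusters = threshold_and_cluster(
                result,
                p_voxel=config.p_voxel,
                k_min=config.k_min,
                connectivity=config.connectivity,
            )
            cframe = clusters_to_frame(clusters, atlas=atlas, label_map=label_map)
            cframe.to_csv(out / f"clusters_{tag}.tsv", sep="\t", index=False)
            _register(out / f"clusters_{tag}.tsv")
            rois = select_rois_from_clusters(clusters, atlas, label_map)
            if rois:
                report = roi_analysis(
                    result,
                    rois,
                    p_voxel=config.p_voxel,
                    k_min=config.k_min,
                    connectivity=config.connectivity,
                )
                report.insert(0, "score", score)
                roi_reports.append(report)
        roi_report = (
            pd.concat(roi_reports, ignore_index=True)
            if roi_reports
            else pd.DataFrame(
                columns=[
                    "score",
                    "roi",
                    "label",
                    "n_voxels",
                    "peak_t",
                    "peak_p",
                    "x_mm",
                    "y_mm",
                    "z_mm",
                    "max_cluster_extent",
                    "significant",
                    "extent_ok",
                ]
            )
        )
        roi_report.to_csv(out / "roi_report.tsv", sep="\t", index=False)
        _register(out / "roi_report.tsv")
        manifest["completed_stages"].append(stage)

        # --- group-difference map ---------------------------------------
        stage = "group"
        gres = group_difference_tmap(volumes, table["group"])
        gclusters = threshold_and_cluster(
            gres,
            p_voxel=config.p_voxel,
            k_min=config.k_min,
            connectivity=config.connectivity,
        )
        clusters_to_frame(gclusters, atlas=atlas, label_map=label_map).to_csv(
            out / "group_clusters.tsv", sep="\t", index=False
        )
        _register(out / "group_clusters.tsv")
        manifest["completed_stages"].append(stage)
    except Exception as exc:  # abort with the stage name, keep partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    _write_manifest()
    return manifest
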