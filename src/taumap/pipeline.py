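"""End-to-end orchestration of the two analysis arms.

The quantitative arm mirrors the ipsilateral NFT-burden analysis: ROI
summary tables, average and frequency maps per Braak group, low-vs-high
Braak comparisons, paired ROI correlations, and vertex-wise
burden-vs-thickness cluster inference with the mean burden of a chosen
source ROI as the variable of interest (no covariates by default).

The semi-quantitative arm mirrors the contralateral-ratings analysis: four
vertex-wise models — tau (age, sex); tau (age, sex, TDP-43, alpha-syn);
TDP-43 (age, sex, tau, alpha-syn); alpha-syn (age, sex, tau, TDP-43) —
each with Freedman-Lane cluster FWE.

Every run writes a manifest recording the configuration snapshot, seed,
input and output digests, and per-stage status, so identical manifests
reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .burden import (
    average_map,
    frequency_map,
    group_compare,
    normalize_to_reference,
    roi_summary_table,
)
from .cohort import Cohort
from .config import PipelineConfig, default_config
from .consensus import analysis_roi_set
from .roistats import paired_roi_analysis
from .thickness import (
    SkeletonField,
    sample_to_template_skeleton,
    skeleton_thickness,
    voronoi_skeleton,
)
from .vertexstats import (
    DesignMatrix,
    cluster_extract,
    diffuse_smooth,
    freedman_lane_fwe,
    mesh_adjacency,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "measure_thickness_fields",
    "vertex_model_run",
    "run_quantitative_arm",
    "run_semiquant_arm",
    "SEMIQUANT_MODELS",
]

# (variable of interest, covariates) of the four semi-quantitative models
SEMIQUANT_MODELS: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("rating_tau", ("age", "sex")),
    ("rating_tau", ("age", "sex", "rating_tdp43", "rating_asyn")),
    ("rating_tdp43", ("age", "sex", "rating_tau", "rating_asyn")),
    ("rating_asyn", ("age", "sex", "rating_tau", "rating_tdp43")),
)


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    stages: Dict[str, str] = field(default_factory=dict)
    decisions: List[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=1, sort_keys=True)


def _validate_cohort_dir(d: Path, need_volumes: bool) -> None:
    required = [
        d / "template" / "labels.nii.gz",
        d / "template" / "skeleton.ply",
        d / "template" / "vertices.csv",
        d / "template" / "params.json",
        d / "specimens.csv",
        d / "fields",
    ]
    if need_volumes:
        required.append(d / "burden")
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "cohort directory incomplete; missing: " + ", ".join(missing)
        )


def measure_thickness_fields(
    cohort: Cohort, max_distance: Optional[float] = None
) -> List[SkeletonField]:
    """Estimate per-specimen thickness fields from the segmentations.

    Skeletonizes each specimen's binary segmentation, converts medial radii
    to thickness, and resamples onto the template skeleton. Specimens
    without a segmentation fall back to their stored thickness field.
    """
    template = cohort.template
    if max_distance is None:
        max_distance = 2.0 * float(np.mean(template.spacing))
    out = []
    for sp in cohort.specimens:
        if sp.segmentation is None:
            out.append(sp.field)
            continue
        skel = voronoi_skeleton(sp.segmentation, spacing=template.spacing)
        thick = skeleton_thickness(skel)
        fld = sample_to_template_skeleton(
            skel.points, thick, template.skeleton_vertices, max_distance
        )
        # slab dropout of the specimen's validity mask also invalidates the
        # corresponding skeleton vertices (sections without histology)
        fld = SkeletonField(
            thickness=fld.thickness, valid=fld.valid & sp.field.valid
        )
        out.append(fld)
    return out


def _field_matrix(fields: Sequence[SkeletonField]) -> Tuple[np.ndarray, np.ndarray]:
    thick = np.stack([f.thickness for f in fields], axis=0)
    valid = np.stack([f.valid for f in fields], axis=0)
    return thick, valid


def vertex_model_run(
    fields: Sequence[SkeletonField],
    design: DesignMatrix,
    template,
    config: PipelineConfig,
    seed: int,
    row_mask: Optional[np.ndarray] = None,
) -> Tuple[pd.DataFrame, object, list]:
    """Smooth, fit and permutation-correct one vertex-wise model.

    Smoothing precedes the validity screen, which uses the pre-smoothing
    validity pattern. Returns the cluster table plus the stat map and
    cluster list.
    """
    adjacency = mesh_adjacency(template.skeleton_faces, template.n_vertices)
    thick, valid_pre = _field_matrix(fields)
    if row_mask is not None:
        thick = thick[row_mask]
        valid_pre = valid_pre[row_mask]
    sm_fields = [
        diffuse_smooth(SkeletonField(thickness=t, valid=v), adjacency,
                       config.diffusion_T)
        for t, v in zip(thick, valid_pre)
    ]
    thick_s, _ = _field_matrix(sm_fields)
    # screen on the pre-smoothing validity pattern
    valid = valid_pre & np.isfinite(thick_s)
    stat, clusters, maxima = freedman_lane_fwe(
        thick_s,
        valid,
        design,
        adjacency,
        cluster_p=config.cluster_p,
        n_permutations=config.n_permutations,
        min_valid_fraction=config.min_valid_fraction,
        seed=seed,
    )
    rows = [
        dict(
            cluster_id=c.cluster_id,
            extent=c.extent,
            mass=round(c.mass, 10),
            corrected_p=c.corrected_p,
            vertices=" ".join(map(str, c.vertices.tolist())),
        )
        for c in clusters
    ]
    table = pd.DataFrame(
        rows, columns=["cluster_id", "extent", "mass", "corrected_p", "vertices"]
    )
    return table, stat, clusters


def run_quantitative_arm(
    cohort_dir,
    out_dir,
    config: Optional[PipelineConfig] = None,
    source_rois: Sequence[str] = ("PrS-PaS", "TE", "ERC", "BA35", "CA1"),
) -> RunManifest:
    """Run the ipsilateral quantitative-burden analysis arm.

    Burden-source ROIs default to the early (CA1, BA35, ERC) and late
    (pre/parasubiculum, Area TE) regions; each yields one vertex-wise model
    with the specimen's source-ROI mean burden as the variable of interest
    and no covariates.
    """
    config = config or default_config()
    d = Path(cohort_dir)
    out = Path(out_dir)
    _validate_cohort_dir(d, need_volumes=True)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    manifest.inputs["specimens.csv"] = tio.file_digest(d / "specimens.csv")

    cohort = tio.load_cohort(d)
    template = cohort.template
    rois = analysis_roi_set("combined_14")

    manifest.stages["thickness"] = "running"
    fields = measure_thickness_fields(cohort)
    manifest.stages["thickness"] = "done"

    manifest.stages["burden_maps"] = "running"
    table = roi_summary_table(cohort, rois, fields=fields)
    table.to_csv(out / "roi_summary.csv", index=False)
    normalize_to_reference(table, config.reference_roi).to_csv(
        out / "roi_summary_normalized.csv", index=False
    )
    burdens = [sp.burden for sp in cohort.specimens]
    groups = {
        g: [sp.burden for sp in cohort.specimens if sp.record.braak_group == g]
        for g in ("low", "high")
    }
    for gname, gvols in groups.items():
        if not gvols:
            continue
        mean, ncon = average_map(gvols)
        tio.save_volume(np.nan_to_num(mean, nan=0.0).astype(np.float32),
                        template.spacing, out / f"average_burden_{gname}.nii.gz")
        for thr in config.frequency_thresholds:
            fm = frequency_map(gvols, thr)
            tio.save_volume(
                np.nan_to_num(fm.values, nan=0.0).astype(np.float32),
                template.spacing,
                out / f"frequency_{gname}_thr{thr:g}.nii.gz",
            )
    ttest_rows = []
    for roi in rois:
        try:
            res = group_compare(table, cohort.records, roi.name)
            ttest_rows.append(dict(roi=roi.name, **res))
        except ValueError as e:
            logger.warning("group comparison skipped for %s: %s", roi.name, e)
    pd.DataFrame(ttest_rows).to_csv(out / "braak_group_ttests.csv", index=False)
    manifest.stages["burden_maps"] = "done"

    manifest.stages["roi_stats"] = "running"
    correlations = paired_roi_analysis(
        table,
        cohort.records,
        rois,
        n_boot=config.n_bootstrap,
        ci_level=config.ci_level,
        seed=config.seed,
    )
    pd.DataFrame([c.__dict__ for c in correlations]).to_csv(
        out / "roi_correlations.csv", index=False
    )
    manifest.stages["roi_stats"] = "done"

    manifest.stages["vertex_stats"] = "running"
    piv = table.pivot(index="specimen_id", columns="roi", values="mean_burden")
    order = [sp.record.specimen_id for sp in cohort.specimens]
    for src in source_rois:
        x = piv.loc[order, src].to_numpy(dtype=float)
        keep = np.isfinite(x)
        if keep.sum() < 5:
            manifest.decisions.append(
                f"vertex model for source ROI {src} skipped: "
                f"only {int(keep.sum())} specimens with valid burden"
            )
            continue
        design = DesignMatrix(
            X=np.column_stack([np.ones(int(keep.sum())), x[keep]]),
            contrast=np.array([0.0, 1.0]),
            sidedness="negative",
            columns=("intercept", f"burden_{src}"),
        )
        ctable, _, _ = vertex_model_run(
            fields, design, template, config, seed=config.seed, row_mask=keep
        )
        fname = f"clusters_burden_{src}.csv"
        ctable.to_csv(out / fname, index=False)
        manifest.outputs[fname] = tio.file_digest(out / fname)
    manifest.stages["vertex_stats"] = "done"

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in manifest.outputs and f.name != "manifest.json":
            manifest.outputs[f.name] = tio.file_digest(f)
    manifest.write(out / "manifest.json")
    return manifest


def run_semiquant_arm(
    cohort_dir,
    out_dir,
    config: Optional[PipelineConfig] = None,
    models: Sequence[Tuple[str, Tuple[str, ...]]] = SEMIQUANT_MODELS,
) -> RunManifest:
    """Run the contralateral semi-quantitative ratings analysis arm."""
    config = config or default_config()
    d = Path(cohort_dir)
    out = Path(out_dir)
    _validate_cohort_dir(d, need_volumes=False)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    manifest.inputs["specimens.csv"] = tio.file_digest(d / "specimens.csv")

    cohort = tio.load_cohort(d)
    template = cohort.template
    spec_df = tio.specimen_table(cohort.records)
    fields = measure_thickness_fields(cohort)

    for mi, (variable, covariates) in enumerate(models):
        missing_cols = [
            c for c in (variable, *covariates)
            if c not in ("age", "sex") and c not in spec_df.columns
        ]
        present = [
            c for c in (variable, *covariates)
            if c in spec_df.columns and spec_df[c].isna().all()
        ]
        if missing_cols or present:
            manifest.decisions.append(
                f"model {variable} ({', '.join(covariates)}) skipped: missing "
                f"rating columns {missing_cols + present}"
            )
            logger.warning("semiquant model skipped: %s", manifest.decisions[-1])
            continue
        design = DesignMatrix.from_table(
            spec_df, variable, covariates, sidedness="negative"
        )
        ctable, _, _ = vertex_model_run(
            fields, design, template, config, seed=config.seed + mi
        )
        fname = f"clusters_{variable}_m{mi}.csv"
        ctable.to_csv(out / fname, index=False)
        manifest.outputs[fname] = tio.file_digest(out / fname)
        manifest.stages[f"model_{mi}_{variable}"] = "done"

    manifest.write(out / "manifest.json")
    return manifest
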