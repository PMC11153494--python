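"""Reading and writing the pipeline's on-disk formats.

Volumes are NIfTI (spacing in the header), the skeleton is a PLY triangle
mesh, per-vertex fields and tables are CSV, and ground truth / manifests
are JSON. A cohort directory has the layout::

    template/labels.nii.gz     subregion label volume
    template/skeleton.ply      skeleton triangle mesh
    template/vertices.csv      vertex_id, label, u, v, thickness
    template/params.json       ribbon chart parameters
    specimens.csv              specimen_id, age, sex, b_score, braak_group,
                               rating_tau, rating_abeta, rating_tdp43,
                               rating_asyn
    truth.json                 generative ground truth
    burden/<id>_burden.nii.gz  per-specimen NFT burden
    burden/<id>_mask.nii.gz    per-specimen validity mask
    seg/<id>_seg.nii.gz        per-specimen binary segmentation
    fields/<id>_field.csv      per-specimen generated thickness field
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .atlas import LABEL_TABLE, TemplateAtlas
from .cohort import BurdenVolume, Cohort, GroundTruth, Specimen, SpecimenRecord
from .thickness import SkeletonField

__all__ = [
    "save_volume",
    "load_volume",
    "save_mesh",
    "load_mesh",
    "save_field",
    "load_field",
    "save_cohort",
    "load_cohort",
    "specimen_table",
    "records_from_table",
    "file_digest",
]


def save_volume(values: np.ndarray, spacing, path) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(values), affine)
    nib.save(img, str(path))


def load_volume(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_mesh(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(str(path))


def load_mesh(path) -> Tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


def save_field(field: SkeletonField, path) -> None:
    df = pd.DataFrame(
        dict(
            vertex_id=np.arange(field.n_vertices),
            thickness=field.thickness,
            valid=field.valid.astype(int),
        )
    )
    df.to_csv(path, index=False)


def load_field(path) -> SkeletonField:
    df = pd.read_csv(path)
    return SkeletonField(
        thickness=df["thickness"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
    )


def specimen_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                specimen_id=r.specimen_id,
                age=r.age,
                sex=r.sex,
                b_score=r.b_score,
                braak_group=r.braak_group,
                rating_tau=r.ratings.get("tau", np.nan),
                rating_abeta=r.ratings.get("abeta", np.nan),
                rating_tdp43=r.ratings.get("tdp43", np.nan),
                rating_asyn=r.ratings.get("asyn", np.nan),
            )
        )
    return pd.DataFrame(rows)


def records_from_table(df: pd.DataFrame) -> List[SpecimenRecord]:
    out = []
    for _, row in df.iterrows():
        ratings = {}
        for key, col in (
            ("tau", "rating_tau"),
            ("abeta", "rating_abeta"),
            ("tdp43", "rating_tdp43"),
            ("asyn", "rating_asyn"),
        ):
            if col in df.columns and np.isfinite(row[col]):
                ratings[key] = float(row[col])
        out.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                b_score=int(row["b_score"]),
                ratings=ratings,
            )
        )
    return out


def save_template(template: TemplateAtlas, tdir: Path) -> None:
    tdir.mkdir(parents=True, exist_ok=True)
    save_volume(template.label_volume.astype(np.int16), template.spacing,
                tdir / "labels.nii.gz")
    save_mesh(template.skeleton_vertices, template.skeleton_faces,
              tdir / "skeleton.ply")
    pd.DataFrame(
        dict(
            vertex_id=np.arange(template.n_vertices),
            label=template.vertex_labels,
            u=template.vertex_u,
            v=template.vertex_v,
            thickness=template.vertex_thickness,
        )
    ).to_csv(tdir / "vertices.csv", index=False)
    with open(tdir / "params.json", "w") as f:
        json.dump(
            dict(
                grid_shape=list(template.grid_shape),
                spacing=list(template.spacing),
                params=template.params,
                label_table={str(k): v for k, v in template.label_table.items()},
            ),
            f,
            indent=1,
        )


def load_template(tdir: Path) -> TemplateAtlas:
    labels, spacing = load_volume(tdir / "labels.nii.gz")
    verts, faces = load_mesh(tdir / "skeleton.ply")
    vdf = pd.read_csv(tdir / "vertices.csv")
    with open(tdir / "params.json") as f:
        meta = json.load(f)
    return TemplateAtlas(
        grid_shape=tuple(meta["grid_shape"]),
        spacing=tuple(meta["spacing"]),
        label_volume=np.asarray(labels, dtype=np.int16),
        skeleton_vertices=verts,
        skeleton_faces=faces,
        vertex_labels=vdf["label"].to_numpy(dtype=np.int16),
        vertex_thickness=vdf["thickness"].to_numpy(dtype=float),
        vertex_u=vdf["u"].to_numpy(dtype=float),
        vertex_v=vdf["v"].to_numpy(dtype=float),
        label_table={int(k): v for k, v in meta["label_table"].items()},
        params=meta["params"],
    )


def save_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_template(cohort.template, out / "template")
    specimen_table(cohort.records).to_csv(out / "specimens.csv", index=False)
    with open(out / "truth.json", "w") as f:
        json.dump(cohort.truth.to_dict(), f, indent=1)
    np.savetxt(out / "affected_vertices.csv",
               cohort.affected_vertices.astype(int), fmt="%d")
    (out / "fields").mkdir(exist_ok=True)
    for sp in cohort.specimens:
        sid = sp.record.specimen_id
        save_field(sp.field, out / "fields" / f"{sid}_field.csv")
        if sp.burden is not None:
            (out / "burden").mkdir(exist_ok=True)
            save_volume(sp.burden.values.astype(np.float32),
                        cohort.template.spacing,
                        out / "burden" / f"{sid}_burden.nii.gz")
            save_volume(sp.burden.valid_mask.astype(np.uint8),
                        cohort.template.spacing,
                        out / "burden" / f"{sid}_mask.nii.gz")
        if sp.segmentation is not None:
            (out / "seg").mkdir(exist_ok=True)
            save_volume(sp.segmentation.astype(np.uint8),
                        cohort.template.spacing,
                        out / "seg" / f"{sid}_seg.nii.gz")


def load_cohort(cohort_dir) -> Cohort:
    d = Path(cohort_dir)
    template = load_template(d / "template")
    records = records_from_table(pd.read_csv(d / "specimens.csv"))
    with open(d / "truth.json") as f:
        truth = GroundTruth.from_dict(json.load(f))
    affected = np.loadtxt(d / "affected_vertices.csv", dtype=int).astype(bool)
    specimens = []
    for rec in records:
        sid = rec.specimen_id
        fld = load_field(d / "fields" / f"{sid}_field.csv")
        burden = None
        seg = None
        bpath = d / "burden" / f"{sid}_burden.nii.gz"
        if bpath.exists():
            vals, _ = load_volume(bpath)
            mask, _ = load_volume(d / "burden" / f"{sid}_mask.nii.gz")
            burden = BurdenVolume(values=np.asarray(vals, dtype=float),
                                  valid_mask=np.asarray(mask) > 0)
        spath = d / "seg" / f"{sid}_seg.nii.gz"
        if spath.exists():
            seg_arr, _ = load_volume(spath)
            seg = np.asarray(seg_arr, dtype=np.uint8)
        specimens.append(
            Specimen(
                record=rec,
                burden=burden,
                segmentation=seg,
                field=fld,
                true_thickness=np.full(template.n_vertices, np.nan),
                vertex_burden=np.full(template.n_vertices, np.nan),
            )
        )
    return Cohort(template=template, specimens=specimens, truth=truth,
                  affected_vertices=affected)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
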