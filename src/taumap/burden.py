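"""ROI summaries, average and frequency maps of NFT burden.

Per-specimen burden volumes are summarized as masked ROI means (the mean of
the burden map over the ROI voxels where histology-derived measures exist),
voxelwise average maps over the cohort, and threshold frequency maps (the
fraction of valid specimens whose burden exceeds a threshold at each
voxel). Group comparisons between low (B0/B1) and high (B2/B3) Braak
specimens use Welch's two-sample t-test, and per-specimen ROI burden can be
normalized to a reference region (BA35, the transentorhinal cortex, the
earliest cortical site of tangle pathology).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import TemplateAtlas
from .cohort import BurdenVolume, Cohort, SpecimenRecord
from .consensus import RoiGrouping
from .thickness import SkeletonField

logger = logging.getLogger(__name__)

__all__ = [
    "RoiNotInLabelsError",
    "FrequencyMap",
    "masked_roi_mean",
    "roi_mean_thickness",
    "roi_summary_table",
    "average_map",
    "frequency_map",
    "normalize_to_reference",
    "group_compare",
]


class RoiNotInLabelsError(KeyError):
    """The ROI's label codes do not occur in the label volume at all."""


@dataclass
class FrequencyMap:
    """Per-voxel fraction of valid specimens with burden above a threshold.

    ``values`` is NaN where no specimen has valid data (``n_contributing``
    zero).
    """

    threshold: float
    values: np.ndarray
    n_contributing: np.ndarray


def masked_roi_mean(
    burden: BurdenVolume,
    labels: np.ndarray,
    roi: RoiGrouping,
) -> Tuple[float, int]:
    """Mean burden over the ROI voxels where measures are available.

    Returns ``(nan, 0)`` when the ROI exists in the label volume but every
    ROI voxel is masked out; raises :class:`RoiNotInLabelsError` when the
    ROI's codes are absent from the label volume altogether.
    """
    labels = np.asarray(labels)
    if labels.shape != burden.values.shape:
        raise ValueError("label volume and burden volume grids differ")
    codes = np.asarray(sorted(roi.member_codes))
    in_roi = np.isin(labels, codes)
    if not in_roi.any():
        raise RoiNotInLabelsError(
            f"ROI {roi.name!r} (codes {sorted(roi.member_codes)}) not present "
            "in the label volume"
        )
    sel = in_roi & burden.valid_mask
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(burden.values[sel].mean()), n


def roi_mean_thickness(
    field: SkeletonField,
    vertex_labels: np.ndarray,
    roi: RoiGrouping,
) -> Tuple[float, int]:
    """Mean thickness over the ROI's valid skeleton vertices."""
    codes = np.asarray(sorted(roi.member_codes))
    sel = np.isin(np.asarray(vertex_labels), codes) & field.valid
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(field.thickness[sel].mean()), n


def roi_summary_table(
    cohort_or_specimens,
    roi_set: Sequence[RoiGrouping],
    template: Optional[TemplateAtlas] = None,
    fields: Optional[Sequence[SkeletonField]] = None,
) -> pd.DataFrame:
    """One row per specimen x ROI with masked mean burden and thickness.

    ``mean_burden`` is NaN (missing), never zero, when no valid voxel
    exists. ``fields`` overrides the thickness fields used (e.g. measured
    fields from the skeletonization pipeline instead of the generated
    ones).
    """
    if isinstance(cohort_or_specimens, Cohort):
        cohort = cohort_or_specimens
        template = cohort.template
        specimens = cohort.specimens
    else:
        specimens = list(cohort_or_specimens)
        if template is None:
            raise ValueError("template required when passing raw specimens")
    rows = []
    for i, sp in enumerate(specimens):
        fld = fields[i] if fields is not None else sp.field
        for roi in roi_set:
            if sp.burden is not None:
                mean_b, n_valid = masked_roi_mean(
                    sp.burden, template.label_volume, roi
                )
            else:
                mean_b, n_valid = float("nan"), 0
            mean_t, _ = roi_mean_thickness(fld, template.vertex_labels, roi)
            rows.append(
                dict(
                    specimen_id=sp.record.specimen_id,
                    roi=roi.name,
                    mean_burden=mean_b,
                    n_valid_voxels=n_valid,
                    mean_thickness=mean_t,
                )
            )
    return pd.DataFrame(rows)


def _check_grids(volumes: Iterable[BurdenVolume]) -> Tuple[int, ...]:
    shapes = {v.values.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"burden volumes on mismatched grids: {shapes}")
    return shapes.pop()


def average_map(
    burdens: Sequence[BurdenVolume],
) -> Tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean burden over the specimens valid at each voxel.

    Returns ``(mean, n_contributing)``; the mean is NaN where no specimen
    is valid.
    """
    if len(burdens) < 1:
        raise ValueError("need at least one specimen")
    _check_grids(burdens)
    total = np.zeros(burdens[0].values.shape)
    count = np.zeros(burdens[0].values.shape, dtype=int)
    for b in burdens:
        total += np.where(b.valid_mask, b.values, 0.0)
        count += b.valid_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def frequency_map(burdens: Sequence[BurdenVolume], threshold: float) -> FrequencyMap:
    """Fraction of valid specimens with burden strictly above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(burdens) < 1:
        raise ValueError("need at least one specimen")
    _check_grids(burdens)
    above = np.zeros(burdens[0].values.shape, dtype=int)
    count = np.zeros(burdens[0].values.shape, dtype=int)
    for b in burdens:
        above += b.valid_mask & (b.values > threshold)
        count += b.valid_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(count > 0, above / np.maximum(count, 1), np.nan)
    return FrequencyMap(threshold=float(threshold), values=frac, n_contributing=count)


def normalize_to_reference(
    table: pd.DataFrame, reference_roi: str = "BA35"
) -> pd.DataFrame:
    """Divide each specimen's ROI burden means by its reference-ROI mean.

    Specimens whose reference mean is missing or not positive are dropped
    from the normalized output with a logged warning; for the rest, the
    reference ROI row is exactly 1.
    """
    if reference_roi not in set(table["roi"]):
        raise ValueError(f"reference ROI {reference_roi!r} not in table")
    out_frames: List[pd.DataFrame] = []
    eps = np.finfo(float).eps
    for sid, grp in table.groupby("specimen_id", sort=False):
        ref = grp.loc[grp["roi"] == reference_roi, "mean_burden"]
        ref_val = float(ref.iloc[0]) if len(ref) else float("nan")
        if not np.isfinite(ref_val) or ref_val <= eps:
            logger.warning(
                "specimen %s dropped from normalized table: reference ROI %s "
                "mean is %r",
                sid,
                reference_roi,
                ref_val,
            )
            continue
        g = grp.copy()
        g["mean_burden"] = g["mean_burden"] / ref_val
        out_frames.append(g)
    if not out_frames:
        return table.iloc[0:0].copy()
    return pd.concat(out_frames, ignore_index=True)


def group_compare(
    table: pd.DataFrame,
    records: Sequence[SpecimenRecord],
    roi: str,
) -> Dict[str, float]:
    """Welch two-sample t-test of ROI burden, low vs high Braak group.

    Returns the t statistic (high minus low), the two-sided p-value and the
    group means. Raises when either group has fewer than two nonmissing
    values, naming the offending group.
    """
    group_of = {r.specimen_id: r.braak_group for r in records}
    sub = table[table["roi"] == roi]
    vals = {"low": [], "high": []}
    for _, row in sub.iterrows():
        g = group_of.get(row["specimen_id"])
        if g is not None and np.isfinite(row["mean_burden"]):
            vals[g].append(float(row["mean_burden"]))
    for g in ("low", "high"):
        if len(vals[g]) < 2:
            raise ValueError(
                f"braak group {g!r} has {len(vals[g])} nonmissing values for "
                f"ROI {roi!r}; need at least 2"
            )
    res = stats.ttest_ind(vals["high"], vals["low"], equal_var=False)
    return dict(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_low=float(np.mean(vals["low"])),
        mean_high=float(np.mean(vals["high"])),
        n_low=len(vals["low"]),
        n_high=len(vals["high"]),
    )
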