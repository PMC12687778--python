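"""Voxel-level gradient saliency and its regional / hemispheric summaries.

Saliency derives from the gradient of the target-class pre-activation score
with respect to each input voxel, computed per subject at the class the
model predicts for that subject.  The default is gradient-times-input
(|gradient * voxel|), which carries per-subject magnitude information; the
plain absolute gradient is available as a mode.  Saliency is
nonnegative by construction and lives on the input grid, so it can be
averaged over atlas regions (subjects x regions matrix), projected on the
sagittal plane per hemisphere for overlays, and compared between
hemispheres with a pooled two-sample t-test over per-region averages
(df = n_L + n_R - 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy import stats

from .core import (
    BrainVolume,
    ParcellationAtlas,
    RegionSaliencyMatrix,
    ValidationError,
)
from .classifiers import LABELS, SeverityNet

__all__ = [
    "SaliencyVolume",
    "compute_saliency",
    "region_mean_saliency",
    "hemisphere_summary",
    "HemisphereSummary",
    "sagittal_projection",
]


@dataclass
class SaliencyVolume:
    """Nonnegative voxel attribution map on the input grid."""

    data: np.ndarray
    subject_id: str = ""
    target: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError("saliency volume must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("saliency volume has non-finite values")
        if float(self.data.min()) < 0:
            raise ValidationError("saliency must be nonnegative")


def compute_saliency(model: SeverityNet, volume, subject_id: str = "",
                     target: Optional[int] = None,
                     mode: str = "gradxinput") -> SaliencyVolume:
    """|d score(target class) / d voxel| (times the voxel, by default).

    ``target`` indexes the (low, high) label order and defaults to the
    model's predicted class for this volume.  The default ``gradxinput``
    mode multiplies the gradient by the input intensity before taking the
    absolute value: in a ReLU network the raw gradient is locally constant
    in the input, so gradient-times-input is what carries per-subject
    magnitude information into the cross-subject correlation analyses.
    ``mode='gradient'`` gives the plain absolute gradient.
    """
    if mode not in ("gradient", "gradxinput"):
        raise ValidationError(f"unknown saliency mode {mode!r}")
    g, t = model.input_gradient(volume, target=target)
    if mode == "gradxinput":
        data = volume.data if isinstance(volume, BrainVolume) else np.asarray(volume)
        g = g * data
    return SaliencyVolume(np.abs(g), subject_id=subject_id, target=LABELS[t])


def region_mean_saliency(saliency_volumes: Sequence[SaliencyVolume],
                         atlas: ParcellationAtlas,
                         groups: Sequence[str]) -> RegionSaliencyMatrix:
    """Mean saliency per (subject, region); background voxels excluded."""
    ids = atlas.region_ids
    counts = ndi.sum_labels(np.ones_like(atlas.labels), atlas.labels, index=ids)
    if np.any(counts == 0):
        empty = [int(r) for r, c in zip(ids, counts) if c == 0]
        raise ValidationError(f"regions with zero voxels in the atlas: {empty}")
    rows = []
    for sv in saliency_volumes:
        if sv.data.shape != atlas.labels.shape:
            raise ValidationError("saliency volume grid does not match the atlas")
        rows.append(ndi.mean(sv.data, atlas.labels, index=ids))
    return RegionSaliencyMatrix(
        values=np.asarray(rows, dtype=float),
        subject_ids=[sv.subject_id for sv in saliency_volumes],
        region_ids=ids,
        groups=list(groups),
        regions=atlas.regions.copy(),
    )


@dataclass
class HemisphereSummary:
    """LH/RH comparison of per-region mean saliency and high-low ranges."""

    lh_mean: float
    rh_mean: float
    t_stat: float
    p_value: float
    df: int
    range_lh_mean: float
    range_rh_mean: float
    range_t: float
    range_p: float
    range_df: int


def hemisphere_summary(matrix: RegionSaliencyMatrix, atlas: ParcellationAtlas,
                       cortical_only: bool = True) -> HemisphereSummary:
    """Pooled-variance two-sample t-test of LH vs RH per-region saliency.

    The test units are *regions*: each hemisphere contributes one average
    saliency value per region (mean over subjects), and df = n_L + n_R - 2.
    The per-region saliency *range* is |mean over high-severity subjects -
    mean over low-severity subjects|, compared between hemispheres the same
    way.
    """
    sel = {"is_cortical": True} if cortical_only else {}
    sides = {}
    for hemi in ("L", "R"):
        ids = atlas.ids_where(hemisphere=hemi, **sel)
        ids = [i for i in ids if i in set(matrix.region_ids)]
        if len(ids) < 2:
            raise ValidationError(
                f"hemisphere {hemi} has {len(ids)} regions; need >= 2 for the test"
            )
        sub = matrix.subset_regions(ids)
        sides[hemi] = sub

    def region_means(sub):
        return sub.values.mean(axis=0)

    def region_ranges(sub):
        hi = sub.rows_for_group("high")
        lo = sub.rows_for_group("low")
        if len(hi) == 0 or len(lo) == 0:
            return None
        return np.abs(hi.mean(axis=0) - lo.mean(axis=0))

    mL, mR = region_means(sides["L"]), region_means(sides["R"])
    t, p = stats.ttest_ind(mL, mR, equal_var=True)
    df = len(mL) + len(mR) - 2

    rL, rR = region_ranges(sides["L"]), region_ranges(sides["R"])
    if rL is not None:
        rt, rp = stats.ttest_ind(rL, rR, equal_var=True)
        rdf = len(rL) + len(rR) - 2
        r_means = (float(rL.mean()), float(rR.mean()))
    else:
        rt, rp, rdf, r_means = np.nan, np.nan, 0, (np.nan, np.nan)

    return HemisphereSummary(
        lh_mean=float(mL.mean()), rh_mean=float(mR.mean()),
        t_stat=float(t), p_value=float(p), df=df,
        range_lh_mean=r_means[0], range_rh_mean=r_means[1],
        range_t=float(rt), range_p=float(rp), range_df=rdf,
    )


def sagittal_projection(saliency: SaliencyVolume) -> dict:
    """Mean over each hemisphere's sagittal slices -> one 2D field each.

    Index 0 of the sagittal axis is the rightmost slice; for odd grids the
    exact mid-sagittal slice belongs to neither hemisphere and is excluded.
    """
    n = saliency.data.shape[0]
    half = n // 2
    right = saliency.data[:half]
    left = saliency.data[n - half:]
    return {"R": right.mean(axis=0), "L": left.mean(axis=0)}
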