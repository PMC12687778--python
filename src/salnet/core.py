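"""Shared domain types for the saliency-network pipeline.

The pipeline revolves around a handful of containers:

* :class:`BrainVolume` — a 3D scalar intensity field on a fixed isotropic
  grid, in ``(sagittal, coronal, axial)`` axis order.  Along the sagittal
  axis, *low* indices lie on the **right** hemisphere (index 0 is the
  rightmost slice), the convention used throughout.
* :class:`ParcellationAtlas` — an integer label volume plus a region table
  (hemisphere, lobe, cortical/subcortical flag, functional-network
  assignment), the frame over which voxel saliency is aggregated.
* :class:`SubjectRecord` — severity group plus SRS total and five subscores
  (absent for unscored controls).
* :class:`RegionSaliencyMatrix` — subjects x regions matrix of per-region
  mean saliency, the substrate of every downstream statistic.
* :class:`CohortTruth` — the synthetic generator's planted-effect map, used
  only by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: SRS subscore names, in the order used by every table in the package.
SUBSCORES = ("cognition", "awareness", "communication", "mannerisms", "motivation")

#: The eight functional networks used for involvement summaries.
NETWORKS = (
    "Default Mode",
    "Salience",
    "Frontoparietal",
    "Social",
    "Language",
    "Sensorimotor",
    "Dorsal/Ventral Attention",
    "Limbic/Emotion",
)

#: Severity split on the SRS total: high strictly above, low strictly below.
SRS_HIGH_MIN = 70.0
SRS_LOW_MAX = 59.0

GROUPS = ("high", "low", "control")
HEMISPHERES = ("L", "R", "midline")

#: Fixed anatomical axis order of every volume in the package.
AXES = ("sagittal", "coronal", "axial")

REGION_TABLE_COLUMNS = ("region_id", "name", "hemisphere", "lobe", "is_cortical", "network")


class SalnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SalnetError):
    """Malformed or internally inconsistent input."""


class SizingError(SalnetError):
    """A grid too small for the requested structure."""


class ProtocolError(SalnetError):
    """A violation of the train/test or control-handling protocol."""


@dataclass
class BrainVolume:
    """A nonnegative 3D intensity field on a fixed isotropic voxel grid."""

    data: np.ndarray
    voxel_size: float = 1.0
    axes: tuple = AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError(
                f"BrainVolume requires a 3D array, got {self.data.ndim}D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("BrainVolume data must be finite everywhere")
        if float(self.data.min()) < 0:
            raise ValidationError("BrainVolume data must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class SubjectRecord:
    """One subject: severity group and, for scored subjects, SRS scores."""

    subject_id: str
    group: str
    srs_total: Optional[float] = None
    subscores: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.group == "control":
            if self.srs_total is not None or self.subscores:
                raise ValidationError(
                    f"control subject {self.subject_id} must carry no SRS scores"
                )
            return
        if self.srs_total is None or self.subscores is None:
            raise ValidationError(
                f"scored subject {self.subject_id} is missing SRS fields"
            )
        missing = set(SUBSCORES) - set(self.subscores)
        if missing:
            raise ValidationError(
                f"subject {self.subject_id} is missing subscores {sorted(missing)}"
            )
        if self.group == "high" and not self.srs_total > SRS_HIGH_MIN:
            raise ValidationError(
                f"high-severity subject {self.subject_id} has SRS total "
                f"{self.srs_total}, not above the split {SRS_HIGH_MIN}"
            )
        if self.group == "low" and not self.srs_total < SRS_LOW_MAX:
            raise ValidationError(
                f"low-severity subject {self.subject_id} has SRS total "
                f"{self.srs_total}, not below the split {SRS_LOW_MAX}"
            )


@dataclass
class ParcellationAtlas:
    """Integer label volume (0 = background) plus its region table."""

    labels: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("atlas label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("atlas labels must be integers")
        missing_cols = set(REGION_TABLE_COLUMNS) - set(self.regions.columns)
        if missing_cols:
            raise ValidationError(f"region table missing columns {sorted(missing_cols)}")
        ids = self.regions["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate region_id in region table")
        bad_hemi = set(self.regions["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere values {sorted(bad_hemi)}")
        self.validate_labels()

    def validate_labels(self) -> None:
        """Cross-check label values against the region table."""
        present = set(np.unique(self.labels)) - {0}
        declared = set(int(i) for i in self.regions["region_id"])
        only_volume = sorted(present - declared)
        only_table = sorted(declared - present)
        if only_volume or only_table:
            raise ValidationError(
                "label volume and region table disagree: "
                f"labels only in volume {only_volume}, only in table {only_table}"
            )

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["region_id"].to_numpy(dtype=int)

    def ids_where(self, **conditions) -> np.ndarray:
        """Region ids matching all given column == value conditions."""
        mask = np.ones(len(self.regions), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.regions[col] == val).to_numpy()
        return self.regions.loc[mask, "region_id"].to_numpy(dtype=int)

    def region_attr(self, column: str) -> Mapping[int, object]:
        return dict(zip(self.regions["region_id"], self.regions[column]))


@dataclass
class CohortTruth:
    """Planted-effect ground truth of a synthetic cohort.

    ``loadings`` is regions x latents (rows follow the region table and are
    zero outside ``affected_regions``); ``subject_latents`` is subjects x
    latents; ``subscore_weights`` maps latents to the five SRS subscores.
    """

    affected_regions: frozenset
    loadings: pd.DataFrame
    subject_latents: pd.DataFrame
    subscore_weights: pd.DataFrame
    asymmetry_factor: float

    def block_of(self) -> Mapping[int, int]:
        """Map each affected region id to the latent it loads on."""
        out = {}
        arr = self.loadings.to_numpy()
        for i, rid in enumerate(self.loadings.index):
            if rid in self.affected_regions:
                out[int(rid)] = int(np.argmax(np.abs(arr[i])))
        return out


@dataclass
class RegionSaliencyMatrix:
    """Subjects x regions matrix of per-region mean saliency."""

    values: np.ndarray
    subject_ids: Sequence[str]
    region_ids: np.ndarray
    groups: Sequence[str]
    regions: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.shape != (len(self.subject_ids), len(self.region_ids)):
            raise ValidationError("saliency matrix shape does not match its labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("saliency matrix has non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.subject_ids), columns=self.region_ids)
        df.index.name = "subject_id"
        return df

    def subset_regions(self, ids: Sequence[int]) -> "RegionSaliencyMatrix":
        ids = np.asarray(ids, dtype=int)
        pos = {rid: i for i, rid in enumerate(self.region_ids)}
        cols = np.array([pos[i] for i in ids], dtype=int)
        regions = None
        if self.regions is not None:
            regions = self.regions.set_index("region_id").loc[ids].reset_index()
        return RegionSaliencyMatrix(
            self.values[:, cols], self.subject_ids, ids, self.groups, regions
        )

    def rows_for_group(self, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        return self.values[mask]
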