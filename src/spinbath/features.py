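"""Per-subject feature vectors: five MT model parameters x two hemispheres.

The classifier operates on (T2f, SDf, kf, kr, T2r) summarized over the left
and right caudate ROIs — ten features per subject in a fixed canonical
order.  Units span microseconds to arbitrary signal units, so features are
z-scored before clustering or eigenanalysis by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fitting import ParameterMaps

ROI_PARAMS = ("t2f", "sdf", "kf", "kr", "t2r")
HEMISPHERES = ("left", "right")
FEATURE_NAMES = tuple(f"{p}_{h}" for p in ROI_PARAMS for h in HEMISPHERES)


class MissingDataError(ValueError):
    """Raised when an ROI yields no usable voxels or a subject is missing."""


@dataclass(frozen=True)
class FeatureVector:
    """One subject's ten ROI features, in canonical order."""

    subject_id: str
    values: tuple[float, ...]
    statistic: str = "median"

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}")
        if not all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


@dataclass
class FeatureMatrix:
    """Subjects x features table, optionally z-scored.

    ``center``/``scale`` record the standardization applied (None for raw
    data) and allow an exact inverse transform.
    """

    data: pd.DataFrame
    center: pd.Series | None = None
    scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(FEATURE_NAMES):
            raise ValueError("feature matrix columns must follow the canonical order")
        if self.data.isna().any().any():
            raise MissingDataError("feature matrix contains missing cells")

    @property
    def standardized(self) -> bool:
        return self.center is not None

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def inverse(self) -> "FeatureMatrix":
        """Undo standardization; identity for raw matrices."""
        if not self.standardized:
            return FeatureMatrix(data=self.data.copy())
        raw = self.data * self.scale + self.center
        return FeatureMatrix(data=raw)


def extract_roi_vector(
    maps: ParameterMaps,
    nc_left: np.ndarray,
    nc_right: np.ndarray,
    subject_id: str,
    statistic: str = "median",
) -> FeatureVector:
    """Summarize the parameter maps over each hemisphere's caudate mask.

    Only converged in-mask voxels contribute.  An empty mask or an ROI with
    no converged voxels raises :class:`MissingDataError` rather than
    emitting NaN silently.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    reduce = np.median if statistic == "median" else np.mean
    hemis = {"left": np.asarray(nc_left, bool), "right": np.asarray(nc_right, bool)}
    converged = maps.maps["converged"] > 0.5
    usable = {}
    for name, m in hemis.items():
        if not m.any():
            raise MissingDataError(f"{subject_id}: empty {name} caudate mask")
        sel = m & converged
        if not sel.any():
            raise MissingDataError(f"{subject_id}: no converged voxels in {name} caudate")
        usable[name] = sel
    values = []
    for param in ROI_PARAMS:
        vol = maps.maps[param]
        for hemi in HEMISPHERES:
            values.append(float(reduce(vol[usable[hemi]])))
    return FeatureVector(subject_id=subject_id, values=tuple(values), statistic=statistic)


def assemble_feature_matrix(
    vectors: Iterable[FeatureVector], cohort: pd.DataFrame
) -> FeatureMatrix:
    """Stack feature vectors into a matrix whose row order follows the cohort.

    Duplicate or missing subject ids are validation errors naming the id.
    """
    by_id: dict[str, FeatureVector] = {}
    for v in vectors:
        if v.subject_id in by_id:
            raise MissingDataError(f"duplicate feature vector for subject {v.subject_id!r}")
        by_id[v.subject_id] = v
    rows = []
    for sid in cohort["subject_id"]:
        if sid not in by_id:
            raise MissingDataError(f"missing feature vector for subject {sid!r}")
        rows.append(by_id.pop(sid).as_dict())
    if by_id:
        raise MissingDataError(f"feature vectors for unknown subjects: {sorted(by_id)}")
    data = pd.DataFrame(rows, index=pd.Index(cohort["subject_id"], name="subject_id"),
                        columns=list(FEATURE_NAMES))
    return FeatureMatrix(data=data)


def standardize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scoring, recording center and scale for the inverse.

    A zero-variance column cannot be scaled and raises an error naming the
    feature.  Applying the transform to an already standardized matrix is
    an identity up to floating-point roundoff.
    """
    center = fm.data.mean()
    scale = fm.data.std(ddof=1)
    # constant columns can carry accumulation roundoff instead of exact zero
    dead = scale[scale <= 1e-12 * (center.abs() + 1.0)]
    if len(dead):
        raise ValueError(f"zero-variance feature(s): {list(dead.index)}")
    z = (fm.data - center) / scale
    return FeatureMatrix(data=z, center=center, scale=scale)
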