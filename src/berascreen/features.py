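"""Meta-feature extraction and input standardization.

A 360-point recording is summarized by 12 statistics fed to the network:
mean and sample standard deviation of the whole trace, mean and sample
standard deviation of each temporal quarter (four equal-length segments of 90
points), and the global minimum and maximum.  Two biological covariates —
cell age in days and generation number — can be appended, giving 14 inputs.

Inputs are z-scored with statistics fitted on training data only; the
second-order minimizers used for training assume comparably scaled inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .signal_synth import N_POINTS, TimeSeriesRecord

#: fixed feature order; serialized models rely on it
FEATURE_NAMES_12 = (
    "overall_mean",
    "overall_sd",
    "q1_mean",
    "q1_sd",
    "q2_mean",
    "q2_sd",
    "q3_mean",
    "q3_sd",
    "q4_mean",
    "q4_sd",
    "global_min",
    "global_max",
)
COVARIATE_NAMES = ("age_days", "generation")
FEATURE_NAMES_14 = FEATURE_NAMES_12 + COVARIATE_NAMES

_QUARTER = N_POINTS // 4  # 90 points per temporal quarter


def extract_meta_features(series: Sequence[float]) -> np.ndarray:
    """The 12 per-trace statistics, in the fixed :data:`FEATURE_NAMES_12` order.

    Quarters are the index ranges [0, 90), [90, 180), [180, 270), [270, 360);
    standard deviations use the sample (n-1) convention.
    """
    values = np.asarray(series, dtype=float)
    if values.shape != (N_POINTS,):
        raise ValidationError(
            f"series must contain exactly {N_POINTS} values, got shape {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("series contains non-finite values")
    quarters = values.reshape(4, _QUARTER)
    out = np.empty(12)
    out[0] = values.mean()
    out[1] = values.std(ddof=1)
    out[2:10:2] = quarters.mean(axis=1)
    out[3:10:2] = quarters.std(axis=1, ddof=1)
    out[10] = values.min()
    out[11] = values.max()
    return out


def build_input_vector(
    record: TimeSeriesRecord, include_covariates: bool = False
) -> np.ndarray:
    """Network input for one record: 12 meta-features, optionally + age and
    generation (appended in that order, generation as its integer value)."""
    if record.generation not in (1, 2, 3, 4):
        raise ValidationError("generation must be one of {1, 2, 3, 4}")
    features = extract_meta_features(record.values)
    if not include_covariates:
        return features
    return np.concatenate(
        [features, [float(record.age_days), float(record.generation)]]
    )


def build_feature_matrix(
    records: Iterable[TimeSeriesRecord], include_covariates: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked input vectors and 0/1 labels for a collection of records."""
    records = list(records)
    if not records:
        raise ValidationError("no records to featurize")
    X = np.vstack([build_input_vector(r, include_covariates) for r in records])
    y = np.array([r.label for r in records], dtype=float)
    return X, y


@dataclass(frozen=True)
class Standardizer:
    """Per-input location/scale fitted on training data (z-score).

    Constant training inputs get scale 1, so they map to exactly 0 rather
    than dividing by zero.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d) -> "Standardizer":
        return cls(np.asarray(d["mean"], float), np.asarray(d["scale"], float))


def fit_standardizer(X: np.ndarray) -> Standardizer:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("standardizer needs a non-empty 2-D feature matrix")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return Standardizer(mean_=mean, scale_=scale)


def apply_standardizer(standardizer: Standardizer, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return (X - standardizer.mean_) / standardizer.scale_
    if X.ndim != 2 or X.shape[1] != standardizer.mean_.shape[0]:
        raise ValidationError(
            f"feature matrix width {X.shape} does not match fitted "
            f"standardizer ({standardizer.mean_.shape[0]} inputs)"
        )
    return (X - standardizer.mean_) / standardizer.scale_
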