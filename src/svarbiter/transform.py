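"""Variance-stabilising transform and training-anchored standardisation.

Annotation values span orders of magnitude (depths, fractions, insert
sizes) and include zeros and negatives, so a plain log transform is not
available.  The inverse hyperbolic sine

    y = asinh(x) = log_e(x + sqrt(x^2 + 1))

behaves like log(2x) for large positive x but is defined (and smooth)
through zero and for negative values.  After the transform each annotation
is standardised with the mean and standard deviation measured on the
TRAINING (random-region) table only; those parameters are frozen, so
candidate scores do not depend on which other candidates happen to be in
the batch.  Masked cells are imputed with the standardised training mean
(0), which is neutral under L1 distance from the training centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationTable

__all__ = ["TransformModel", "asinh_transform", "fit_transform_model", "apply_transform"]

logger = logging.getLogger(__name__)


def asinh_transform(x):
    """Inverse hyperbolic sine, log_e(x + sqrt(x^2+1)); odd, defined on all reals."""
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("asinh_transform requires finite input")
    return np.arcsinh(x)


def inverse_asinh(y):
    return np.sinh(y)


@dataclass
class TransformModel:
    """Per-annotation asinh-scale standardisation parameters (training-anchored)."""

    mu: pd.Series
    sigma: pd.Series
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.mu.index.equals(self.sigma.index):
            raise ValueError("mu/sigma annotation mismatch")
        if (self.sigma <= 0).any():
            bad = self.sigma.index[self.sigma <= 0].tolist()
            raise ValueError(f"non-positive sigma for {bad}")

    @property
    def annotation_names(self) -> list[str]:
        return list(self.mu.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu, "sigma": self.sigma}).rename_axis("annotation")

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, float_format="%.12g")

    @staticmethod
    def load(path: str) -> "TransformModel":
        df = pd.read_csv(path, index_col=0)
        return TransformModel(df["mu"], df["sigma"])

    def invert(self, z: pd.DataFrame) -> pd.DataFrame:
        """Map standardised values back to the original annotation scale."""
        return np.sinh(z * self.sigma + self.mu)


def fit_transform_model(training: AnnotationTable) -> TransformModel:
    """Fit per-annotation mu/sigma on asinh-transformed training values.

    Masked cells are excluded from the moments; columns with fewer than two
    unmasked values or zero variance are dropped (and recorded) since they
    carry no standardisable information.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training rows")
    y = np.arcsinh(training.filled(np.nan))
    mu = y.mean(axis=0, skipna=True)
    sigma = y.std(axis=0, ddof=1, skipna=True)
    counts = y.notna().sum(axis=0)
    # constant columns can carry sigma ~ 1e-16 from accumulated rounding
    tol = np.maximum(np.abs(mu), 1.0) * 1e-12
    keep = (counts >= 2) & (sigma > tol)
    dropped = tuple(y.columns[~keep])
    if dropped:
        logger.warning("dropping %d constant/empty annotations: %s", len(dropped), dropped)
    return TransformModel(mu[keep], sigma[keep], dropped)


def apply_transform(model: TransformModel, table: AnnotationTable) -> AnnotationTable:
    """Standardise ``table`` with the frozen training parameters.

    z = (asinh(x) - mu) / sigma per cell; masked cells are imputed with 0
    (the standardised training mean) and stay flagged in the mask.  Columns
    follow the model's order; a model column missing from the table is an
    error.
    """
    missing = [c for c in model.annotation_names if c not in table.values.columns]
    if missing:
        raise KeyError(f"table lacks model annotations: {missing}")
    cols = model.annotation_names
    y = np.arcsinh(table.filled(np.nan)[cols])
    z = (y - model.mu) / model.sigma
    mask = table.mask[cols].copy()
    z = z.fillna(0.0)
    z.values[mask.to_numpy()] = 0.0
    return AnnotationTable(z, mask, table.row_flags)
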