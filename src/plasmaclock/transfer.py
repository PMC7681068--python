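"""Applying a clock to a cohort that measures only part of its panel.

When a target platform lacks some clock analytes, predictions made with
only the shared analytes are attenuated: restricted predictions regress on
chronological age with a slope b < 1.  No refit is performed; instead the
learning set provides a linear fit predicted = a + b * age whose affine
inversion (pred - a) / b corrects the slope offset.  The reported
"correction coefficient" is kappa = 1 / b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ClockModel, log_standardize, StandardizationParams, apply_columns
from .simulate import ProteomicCohort

logger = logging.getLogger("plasmaclock")

__all__ = [
    "TransferCorrection",
    "predict_with_subset",
    "estimate_correction",
    "apply_correction",
]


@dataclass(frozen=True)
class TransferCorrection:
    """Learning-set linear fit of restricted predictions on age."""

    shared_features: tuple[str, ...]
    a: float  # intercept (years)
    b: float  # slope (dimensionless)

    @property
    def kappa(self) -> float:
        """Correction coefficient 1/b."""
        return 1.0 / self.b


def predict_with_subset(
    model: ClockModel,
    cohort: ProteomicCohort,
    available: Iterable[str] | None = None,
) -> pd.Series:
    """Predict ages using only the clock features the cohort measures.

    Weights for missing features are simply omitted (equivalent to imputing
    the training mean on the z scale); the model is never refitted.
    """
    if model.standardization is None:
        raise ValueError("model carries no standardization parameters")
    if available is None:
        available = cohort.intensities.columns
    shared = model.feature_ids.intersection(pd.Index(available)).intersection(
        cohort.intensities.columns
    )
    if len(shared) == 0:
        raise ValueError("no overlap between available analytes and clock features")
    std = model.standardization
    sub_params = StandardizationParams(means=std.means[shared], sds=std.sds[shared])
    z, _ = log_standardize(apply_columns(cohort, shared), params=sub_params)
    preds = model.intercept + z.to_numpy() @ model.weights[shared].to_numpy()
    return pd.Series(preds, index=cohort.intensities.index, name="predicted_age")


def estimate_correction(
    model: ClockModel,
    learning_cohort: ProteomicCohort,
    available: Iterable[str],
) -> TransferCorrection:
    """Fit restricted predictions = a + b * age on the learning cohort."""
    shared = model.feature_ids.intersection(pd.Index(available))
    preds = predict_with_subset(model, learning_cohort, available=shared)
    ages = learning_cohort.ages.to_numpy(dtype=float)
    if np.ptp(preds.to_numpy()) == 0:
        raise ValueError("restricted predictions are constant; cannot estimate a slope")
    fit = stats.linregress(ages, preds.to_numpy())
    b = float(fit.slope)
    if abs(b) < 1e-8:
        raise ValueError(f"degenerate restricted clock: learning-set slope {b:.3g} ~ 0")
    corr = TransferCorrection(
        shared_features=tuple(shared), a=float(fit.intercept), b=b
    )
    logger.info(
        "transfer correction: |shared|=%d, a=%.3f, b=%.4f, kappa=%.3f",
        len(shared), corr.a, corr.b, corr.kappa,
    )
    return corr


def apply_correction(
    predictions: pd.Series | np.ndarray,
    correction: TransferCorrection,
    method: str = "affine",
) -> pd.Series | np.ndarray:
    """Correct restricted predictions for slope offset.

    ``"affine"`` (default) inverts the learning-set line: (pred - a) / b,
    which by construction restores slope 1 / intercept 0 on the learning
    set.  ``"scale"`` applies the bare multiplier kappa * pred.
    """
    if method == "affine":
        return (predictions - correction.a) / correction.b
    if method == "scale":
        return predictions * correction.kappa
    raise ValueError(f"unknown correction method {method!r}")
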