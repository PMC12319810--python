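"""Bias correction and ensemble inference.

Age-regression models systematically overestimate the age of young brains
and underestimate old ones (regression to the mean). The correction used
here models the brain-age difference (BAD = raw prediction - chronological
age) as a linear function of chronological age,

    BAD = alpha * age + beta,

fits (alpha, beta) by ordinary least squares on a validation set, and
subtracts the fitted trend from raw predictions. The final brain age is the
median over an ensemble of independently trained, per-member-corrected
models; the spread across members is reported as a per-scan variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateInputError, ShapeError

__all__ = [
    "BiasCorrection",
    "PredictionResult",
    "fit_bias_correction",
    "apply_bias_correction",
    "summarize_members",
    "ensemble_predict",
]


@dataclass(frozen=True)
class BiasCorrection:
    """Fitted linear trend of BAD on chronological age."""

    alpha: float
    beta: float
    fit_set_id: str = ""
    n_fit: int = 0

    def expected_bad(self, age):
        return self.alpha * np.asarray(age, dtype=float) + self.beta


@dataclass
class PredictionResult:
    """Per-scan ensemble output."""

    scan_id: str
    chronological_age: float
    raw: np.ndarray  # per-member raw ages
    corrected: np.ndarray  # per-member bias-corrected ages
    brain_age: float  # ensemble median of corrected ages
    bad: float  # brain_age - chronological_age
    variance: float  # sample variance of corrected member ages

    def as_row(self) -> dict:
        row = {"scan_id": self.scan_id, "age": self.chronological_age}
        for i, (r, c) in enumerate(zip(self.raw, self.corrected), start=1):
            row[f"ba_raw_m{i}"] = float(r)
            row[f"ba_corrected_m{i}"] = float(c)
        row.update(
            brain_age=self.brain_age, bad=self.bad, variance=self.variance
        )
        return row


def fit_bias_correction(
    raw_preds: Sequence[float],
    ages: Sequence[float],
    fit_set_id: str = "",
) -> BiasCorrection:
    """OLS fit of (raw - age) on age.

    The residuals of this fit have exactly zero mean and zero covariance
    with age, so corrected BAD on the fitting set is unbiased and
    age-decorrelated by construction.
    """
    raw = np.asarray(raw_preds, dtype=float).ravel()
    age = np.asarray(ages, dtype=float).ravel()
    if raw.size != age.size:
        raise ShapeError(f"length mismatch: {raw.size} vs {age.size}")
    if raw.size < 2:
        raise ShapeError("bias correction needs at least 2 points")
    if np.unique(age).size < 2:
        raise DegenerateInputError("bias correction needs >= 2 distinct ages")
    bad = raw - age
    alpha, beta = np.polyfit(age, bad, deg=1)
    return BiasCorrection(
        alpha=float(alpha), beta=float(beta), fit_set_id=fit_set_id,
        n_fit=int(raw.size),
    )


def apply_bias_correction(raw, age, corr: BiasCorrection):
    """corrected = raw - (alpha * age + beta); broadcasts over arrays."""
    out = np.asarray(raw, dtype=float) - corr.expected_bad(age)
    if out.ndim == 0:
        return float(out)
    return out


def summarize_members(
    corrected: Sequence[float], age: float, scan_id: str = "",
    raw: Sequence[float] | None = None,
) -> PredictionResult:
    """Collapse per-member corrected ages into the ensemble summary.

    The ensemble brain age is the median (mean of the middle two for even
    member counts); the variance is the sample variance across members
    (0 for a single member).
    """
    corr = np.asarray(corrected, dtype=float).ravel()
    if corr.size == 0:
        raise ConfigError("ensemble requires at least one member")
    brain_age = float(np.median(corr))
    variance = float(np.var(corr, ddof=1)) if corr.size > 1 else 0.0
    raw_arr = (
        np.asarray(raw, dtype=float).ravel()
        if raw is not None
        else np.full_like(corr, np.nan)
    )
    return PredictionResult(
        scan_id=scan_id,
        chronological_age=float(age),
        raw=raw_arr,
        corrected=corr,
        brain_age=brain_age,
        bad=brain_age - float(age),
        variance=variance,
    )


def ensemble_predict(
    members: Sequence[tuple], volume: np.ndarray, age: float,
    scan_id: str = "",
) -> PredictionResult:
    """Run every (model, BiasCorrection) member on a preprocessed volume.

    Each member's raw output is corrected with its own fitted trend; the
    median of the corrected outputs is the ensemble brain age.
    """
    if len(members) == 0:
        raise ConfigError("ensemble requires at least one member")
    raws = []
    correcteds = []
    for model, corr in members:
        r = float(model.predict(volume))
        raws.append(r)
        correcteds.append(apply_bias_correction(r, age, corr))
    return summarize_members(correcteds, age, scan_id=scan_id, raw=raws)
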