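"""Calibrate simulation parameters from a reference data matrix.

Given an experimental (or experiment-like) features × samples matrix,
estimate the statistics a realistic simulation should preserve: per-
feature means and variances, per-sample means, and a background-noise
variance.  The noise variance is the mean squared residual after
removing the best rank-k approximation (SVD truncation) of the
row-centered matrix, with the divisor adjusted for the k(m + n)
parameters absorbed by the removed rank.  Missing entries (NaN) are
ignored per-statistic; no imputation is performed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ValidationError
from .signal_design import NoiseSpec, SimulationConfig

__all__ = ["CalibrationReport", "calibrate", "suggest_k", "config_from_calibration"]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationReport:
    """Statistics estimated from a reference matrix (data units / units²)."""

    feature_means: np.ndarray
    feature_variances: np.ndarray
    sample_means: np.ndarray
    noise_sigma2_hat: float
    k_used: int

    @property
    def m(self) -> int:
        return len(self.feature_means)

    @property
    def n(self) -> int:
        return len(self.sample_means)

    def to_dict(self) -> dict:
        return {
            "feature_means": [float(v) for v in self.feature_means],
            "feature_variances": [float(v) for v in self.feature_variances],
            "sample_means": [float(v) for v in self.sample_means],
            "noise_sigma2_hat": float(self.noise_sigma2_hat),
            "k_used": int(self.k_used),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def suggest_k(reference: np.ndarray) -> int:
    """Default rank choice: elbow of the singular-value scree.

    Returns the index (1-based rank) of the largest drop ratio
    s_i / s_{i+1} over the leading singular values of the row-centered
    matrix.  Logged, never silently applied.
    """
    x = _centered_complete(np.asarray(reference, dtype=float))
    s = np.linalg.svd(x, compute_uv=False)
    s = s[s > 1e-12 * max(s[0], 1.0)]
    if len(s) < 2:
        return max(len(s), 1)
    ratios = s[:-1] / s[1:]
    k = int(np.argmax(ratios)) + 1
    logger.info("scree elbow suggests k=%d (drop ratio %.3g)", k, ratios[k - 1])
    return k


def _centered_complete(x: np.ndarray) -> np.ndarray:
    """Row-center, filling missing entries with the row mean (i.e. 0 after centering)."""
    row_means = np.nanmean(x, axis=1, keepdims=True)
    xc = x - row_means
    return np.where(np.isnan(xc), 0.0, xc)


def calibrate(reference: np.ndarray, k: int, feature_ids=None) -> CalibrationReport:
    """Estimate simulation parameters from a reference m × n matrix.

    ``k`` is the signal rank removed before residual-variance estimation
    (use :func:`suggest_k` for a scree-based default).
    """
    x = np.asarray(reference, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"reference must be 2-D, got shape {x.shape}")
    m, n = x.shape
    if m < 2 or n < 3:
        raise ValidationError(f"reference needs m >= 2 and n >= 3, got {m} x {n}")
    if not 0 <= k < min(m, n):
        raise ValidationError(f"k must satisfy 0 <= k < min(m, n) = {min(m, n)}, got {k}")

    missing = np.isnan(x)
    all_missing_rows = np.where(missing.all(axis=1))[0]
    if all_missing_rows.size:
        fid = feature_ids[all_missing_rows[0]] if feature_ids is not None else all_missing_rows[0]
        raise ValidationError(f"feature {fid!r} has no observed values")

    feature_means = np.nanmean(x, axis=1)
    with np.errstate(invalid="ignore"):
        feature_variances = np.nanvar(x, axis=1, ddof=1)
    feature_variances = np.nan_to_num(feature_variances, nan=0.0)
    sample_means = np.nanmean(x, axis=0)

    xc = _centered_complete(x)
    if k > 0:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        low_rank = (u[:, :k] * s[:k]) @ vt[:k]
    else:
        low_rank = np.zeros_like(xc)
    residual = np.where(missing, 0.0, xc - low_rank)
    n_obs = int((~missing).sum())
    dof = n_obs - k * (m + n)
    rss = float(np.sum(residual**2))
    noise_sigma2_hat = rss / dof if dof > 0 else rss / n_obs

    return CalibrationReport(
        feature_means=feature_means,
        feature_variances=feature_variances,
        sample_means=sample_means,
        noise_sigma2_hat=noise_sigma2_hat,
        k_used=int(k),
    )


def config_from_calibration(
    report: CalibrationReport,
    template: SimulationConfig,
    layer_id: Optional[str] = None,
) -> SimulationConfig:
    """Transfer calibrated noise and feature offsets into a config template.

    The target layer (default: the template's first) gets its noise set
    to ``noise_sigma2_hat`` and a per-feature offset vector equal to the
    calibrated feature means; everything else is untouched.
    """
    if layer_id is None:
        layer_id = template.layers[0].layer_id
    layer = template.layer(layer_id)
    if layer.m != report.m:
        raise ConfigurationError(
            f"template layer {layer_id!r} has m={layer.m} features but the calibration "
            f"report describes m={report.m}"
        )
    noise = dict(template.noise)
    noise[layer_id] = NoiseSpec(sigma2=float(report.noise_sigma2_hat))
    offsets = dict(template.feature_offsets or {})
    offsets[layer_id] = [float(v) for v in report.feature_means]
    return replace(template, noise=noise, feature_offsets=offsets)
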