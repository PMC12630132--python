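"""Score how well a factorization recovers the injected ground truth.

Factor models are identifiable only up to row permutation and sign, so
recovery is scored after an optimal one-to-one matching (Hungarian
assignment) of inferred to true factors on absolute Pearson correlation
of score rows.  Loading recovery is a detection problem: the true active
set is the nonzero support of the ground-truth loading row, the inferred
active set is thresholded at a fraction of the row's maximum |loading|,
and sensitivity / specificity are read off the confusion matrix.

A truncated-SVD factorization of the standardized, feature-concatenated
layers is provided as a built-in baseline so the simulate → analyze →
evaluate loop closes without external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._rng import substream
from .errors import ValidationError
from .model_core import LoadingMatrix, OmicLayer, ScoreMatrix, SimulatedDataset, simulate

__all__ = [
    "Factorization",
    "MatchedPair",
    "RecoveryReport",
    "match_factors",
    "loading_recovery",
    "evaluate_factorization",
    "baseline_factorize",
    "snr_sweep",
]

DEFAULT_ACTIVE_FRACTION = 0.05  # |loading| > 5% of the row max counts as active


@dataclass
class Factorization:
    """An inferred (Γ̂, {Λ̂_I}) pair from any method."""

    scores_hat: np.ndarray  # k̂ × n
    loadings_hat: Dict[str, np.ndarray]  # layer_id → k̂ × m_I
    method_label: str = "unknown"

    def __post_init__(self) -> None:
        # C-contiguous copies keep downstream BLAS results bit-reproducible
        self.scores_hat = np.ascontiguousarray(self.scores_hat, dtype=float)
        if self.scores_hat.ndim != 2:
            raise ValidationError(f"scores_hat must be 2-D, got shape {self.scores_hat.shape}")
        k_hat = self.scores_hat.shape[0]
        self.loadings_hat = {lid: np.ascontiguousarray(v, dtype=float) for lid, v in self.loadings_hat.items()}
        for lid, lam in self.loadings_hat.items():
            if lam.ndim != 2 or lam.shape[0] != k_hat:
                raise ValidationError(
                    f"loadings_hat[{lid!r}] shape {lam.shape} inconsistent with k_hat={k_hat}"
                )

    @property
    def k_hat(self) -> int:
        return self.scores_hat.shape[0]

    @property
    def n(self) -> int:
        return self.scores_hat.shape[1]


@dataclass
class MatchedPair:
    true_factor_id: str
    inferred_index: int
    correlation: float  # signed Pearson r of score rows


@dataclass
class RecoveryReport:
    """Per-factor and aggregate recovery scores against the ground truth."""

    matching: List[MatchedPair]
    per_factor_loading_sensitivity: Dict[str, Optional[float]]
    per_factor_loading_specificity: Dict[str, Optional[float]]
    unmatched_true: List[str]
    unmatched_inferred: List[int]
    method_label: str = "unknown"
    snr_context: Optional[float] = None

    @property
    def mean_abs_correlation(self) -> float:
        """Factor-level accuracy: mean |r| over matched pairs."""
        if not self.matching:
            return float("nan")
        return float(np.mean([abs(p.correlation) for p in self.matching]))

    @property
    def mean_sensitivity(self) -> float:
        vals = [v for v in self.per_factor_loading_sensitivity.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_specificity(self) -> float:
        vals = [v for v in self.per_factor_loading_specificity.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        """Loading-level accuracy: (mean sensitivity + mean specificity) / 2."""
        return (self.mean_sensitivity + self.mean_specificity) / 2.0

    def to_dict(self) -> dict:
        return {
            "method_label": self.method_label,
            "matching": [
                {"true_factor_id": p.true_factor_id, "inferred_index": p.inferred_index,
                 "correlation": p.correlation}
                for p in self.matching
            ],
            "per_factor_loading_sensitivity": self.per_factor_loading_sensitivity,
            "per_factor_loading_specificity": self.per_factor_loading_specificity,
            "unmatched_true": self.unmatched_true,
            "unmatched_inferred": self.unmatched_inferred,
            "mean_abs_correlation": None if not self.matching else self.mean_abs_correlation,
            "mean_sensitivity": None if np.isnan(self.mean_sensitivity) else self.mean_sensitivity,
            "mean_specificity": None if np.isnan(self.mean_specificity) else self.mean_specificity,
            "snr_context": self.snr_context,
        }


def _row_correlations(truth: np.ndarray, inferred: np.ndarray) -> np.ndarray:
    """Signed Pearson r between every (true row, inferred row) pair.

    Zero-variance rows correlate 0 with everything (they carry no signal
    to match on).
    """
    tc = truth - truth.mean(axis=1, keepdims=True)
    ic = inferred - inferred.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    inorm = np.linalg.norm(ic, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tc @ ic.T) / np.outer(tn, inorm)
    return np.nan_to_num(r, nan=0.0)


def match_factors(truth: ScoreMatrix, scores_hat: np.ndarray) -> Tuple[List[MatchedPair], List[str], List[int]]:
    """Optimal one-to-one matching of inferred to true factors.

    Maximizes the total |Pearson r| between true and inferred score rows
    (Hungarian assignment on the |r| matrix); the signed r of each pair
    is recorded.  Surplus factors on either side are returned unmatched.
    """
    scores_hat = np.ascontiguousarray(scores_hat, dtype=float)
    if scores_hat.ndim != 2:
        raise ValidationError(f"inferred scores must be 2-D, got shape {scores_hat.shape}")
    if scores_hat.shape[1] != truth.n:
        raise ValidationError(
            f"sample-count mismatch: truth has n={truth.n}, inferred has n={scores_hat.shape[1]}"
        )
    k, k_hat = truth.k, scores_hat.shape[0]
    if k == 0 or k_hat == 0:
        return [], list(truth.factor_ids), list(range(k_hat))

    r = _row_correlations(truth.values, scores_hat)
    rows, cols = linear_sum_assignment(-np.abs(r))
    matching = [
        MatchedPair(truth.factor_ids[i], int(j), float(r[i, j])) for i, j in zip(rows, cols)
    ]
    matched_true = {p.true_factor_id for p in matching}
    matched_inf = {p.inferred_index for p in matching}
    unmatched_true = [fid for fid in truth.factor_ids if fid not in matched_true]
    unmatched_inferred = [j for j in range(k_hat) if j not in matched_inf]
    return matching, unmatched_true, unmatched_inferred


def loading_recovery(
    true_row: np.ndarray,
    inferred_row: np.ndarray,
    active_fraction: float = DEFAULT_ACTIVE_FRACTION,
) -> Tuple[Optional[float], float]:
    """Sensitivity and specificity of active-feature detection for one factor.

    The true active set is the nonzero support of ``true_row``; inferred
    active entries are those with |value| above ``active_fraction`` times
    the row's max |value|.  An empty true support makes sensitivity
    undefined (returned as None, not 0).
    """
    true_row = np.asarray(true_row, dtype=float)
    inferred_row = np.asarray(inferred_row, dtype=float)
    if true_row.shape != inferred_row.shape:
        raise ValidationError(f"row shapes differ: {true_row.shape} vs {inferred_row.shape}")
    true_active = true_row != 0
    peak = np.max(np.abs(inferred_row)) if inferred_row.size else 0.0
    inferred_active = np.abs(inferred_row) > active_fraction * peak if peak > 0 else np.zeros_like(true_active)

    n_true = int(true_active.sum())
    n_neg = int((~true_active).sum())
    sensitivity = None if n_true == 0 else float((inferred_active & true_active).sum() / n_true)
    specificity = 1.0 if n_neg == 0 else float((~inferred_active & ~true_active).sum() / n_neg)
    return sensitivity, specificity


def evaluate_factorization(
    dataset: SimulatedDataset,
    factorization: Factorization,
    active_fraction: float = DEFAULT_ACTIVE_FRACTION,
    snr_context: Optional[float] = None,
) -> RecoveryReport:
    """Full recovery report: matched score correlations plus loading
    sensitivity/specificity pooled over the layers each factor loads on."""
    matching, unmatched_true, unmatched_inferred = match_factors(
        dataset.scores, factorization.scores_hat
    )
    sens: Dict[str, Optional[float]] = {}
    spec: Dict[str, Optional[float]] = {}
    idx_of = {fid: i for i, fid in enumerate(dataset.scores.factor_ids)}
    for pair in matching:
        i = idx_of[pair.true_factor_id]
        s_vals, p_vals = [], []
        for lid, true_lam in dataset.loadings.items():
            if lid not in factorization.loadings_hat:
                continue
            true_row = true_lam.values[i]
            inf_row = factorization.loadings_hat[lid][pair.inferred_index]
            if not np.any(true_row != 0):
                continue  # factor inactive on this layer; nothing to detect
            se, sp = loading_recovery(true_row, inf_row, active_fraction)
            if se is not None:
                s_vals.append(se)
            p_vals.append(sp)
        sens[pair.true_factor_id] = float(np.mean(s_vals)) if s_vals else None
        spec[pair.true_factor_id] = float(np.mean(p_vals)) if p_vals else None
    return RecoveryReport(
        matching=matching,
        per_factor_loading_sensitivity=sens,
        per_factor_loading_specificity=spec,
        unmatched_true=unmatched_true,
        unmatched_inferred=unmatched_inferred,
        method_label=factorization.method_label,
        snr_context=snr_context,
    )


def baseline_factorize(layers: Sequence[OmicLayer], k: int) -> Factorization:
    """Rank-k truncated SVD of the standardized, feature-concatenated layers.

    Each feature row is standardized (zero mean, unit variance; constant
    rows stay zero), layers are stacked along the feature axis, and the
    top-k SVD gives scores_hat = diag(s) · Vᵀ with loadings split back
    per layer.  Signs are fixed by making each factor's largest-|loading|
    entry positive, so the result is fully deterministic.
    """
    if not layers:
        raise ValidationError("at least one layer is required")
    n = layers[0].data.shape[1]
    for lay in layers:
        if lay.data.shape[1] != n:
            raise ValidationError(
                f"layer {lay.layer_id!r} has n={lay.data.shape[1]}, expected shared n={n}"
            )
    if not 1 <= k < n:
        raise ValidationError(f"k must satisfy 1 <= k < n={n}, got {k}")

    blocks = []
    for lay in layers:
        x = lay.data
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (x - mu) / sd
        blocks.append(np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0))
    stacked = np.vstack(blocks)

    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i] = -vt[i]

    scores_hat = s[:, None] * vt
    loadings_hat: Dict[str, np.ndarray] = {}
    offset = 0
    for lay in layers:
        m = lay.data.shape[0]
        loadings_hat[lay.layer_id] = u[offset : offset + m].T.copy()
        offset += m
    return Factorization(scores_hat=scores_hat, loadings_hat=loadings_hat, method_label="truncated_svd")


def snr_sweep(
    template,
    snr_grid: Sequence[float],
    replicates: int,
    seed: int,
    active_fraction: float = DEFAULT_ACTIVE_FRACTION,
) -> pd.DataFrame:
    """Recovery of the SVD baseline across an SNR grid.

    For each (snr, replicate) the template config is re-simulated with
    every layer's noise set to that SNR and a replicate-specific seed,
    factorized at the true k, and scored.  Returns one row per cell with
    columns ``snr, replicate, mean_abs_r, mean_sensitivity``.
    """
    if not len(snr_grid):
        raise ValidationError("snr_grid must be non-empty")
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    if template.k < 1:
        raise ValidationError("snr_sweep needs a template with at least one factor")

    from .signal_design import NoiseSpec  # local import avoids cycle at module load

    rows = []
    for si, snr in enumerate(snr_grid):
        for rep in range(replicates):
            rep_seed = int(substream(seed, "sweep", si, rep).integers(2**31))
            cfg = replace(
                template,
                noise={lid: NoiseSpec(snr=float(snr)) for lid in (l.layer_id for l in template.layers)},
                seed=rep_seed,
            )
            dataset = simulate(cfg)
            fac = baseline_factorize(dataset.layers, k=template.k)
            report = evaluate_factorization(dataset, fac, active_fraction, snr_context=float(snr))
            rows.append(
                {
                    "snr": float(snr),
                    "replicate": rep,
                    "mean_abs_r": report.mean_abs_correlation,
                    "mean_sensitivity": report.mean_sensitivity,
                }
            )
    return pd.DataFrame(rows)
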