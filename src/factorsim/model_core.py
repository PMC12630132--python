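"""Generative linear factor model for multi-omics simulation.

Each omics layer is assembled as

    X_I = Λ_Iᵀ Γ + E_I

where Γ (k × n) holds factor scores shared by every layer, Λ_I (k × m_I)
holds the layer's feature loadings, and E_I is i.i.d. Gaussian noise with
layer-specific variance σ²_I.  Entrywise, x_ij = λ_iᵀ γ_j + ε_ij.  The
full ground truth (Γ, Λ_I, E_I, resolved config, seed) is retained in the
returned bundle so any downstream factorization can be scored against the
injected signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from ._rng import substream
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ScoreMatrix",
    "LoadingMatrix",
    "NoiseMatrix",
    "OmicLayer",
    "SimulatedDataset",
    "assemble_layer",
    "draw_noise",
    "simulate",
]


def _as_matrix(values, name: str) -> np.ndarray:
    # C-contiguity matters: BLAS products differ at the ulp level across
    # memory layouts, which would break bitwise report reproducibility
    arr = np.ascontiguousarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass
class ScoreMatrix:
    """Factor scores Γ: k factors × n samples, shared across all layers."""

    values: np.ndarray
    factor_ids: List[str]
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.values = _as_matrix(self.values, "scores")
        k, n = self.values.shape
        if n < 2:
            raise ValidationError(f"scores need n >= 2 samples, got n={n}")
        # k = 0 is legal: a factor-free config yields pure-noise layers
        if len(self.factor_ids) != k:
            raise ValidationError(f"{len(self.factor_ids)} factor_ids for {k} score rows")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample_ids for {n} score columns")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class LoadingMatrix:
    """Feature loadings Λ_I: k factors × m_I features for one layer.

    Rows of factors inactive on the layer are exactly zero.
    """

    values: np.ndarray
    layer_id: str
    factor_ids: List[str]
    feature_ids: List[str]

    def __post_init__(self) -> None:
        self.values = _as_matrix(self.values, f"loadings[{self.layer_id}]")
        k, m = self.values.shape
        if len(self.factor_ids) != k:
            raise ValidationError(f"{len(self.factor_ids)} factor_ids for {k} loading rows")
        if len(self.feature_ids) != m:
            raise ValidationError(f"{len(self.feature_ids)} feature_ids for {m} loading columns")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class NoiseMatrix:
    """Gaussian background noise E_I: m_I × n, i.i.d. N(0, sigma2)."""

    values: np.ndarray
    sigma2: float
    layer_id: str

    def __post_init__(self) -> None:
        self.values = _as_matrix(self.values, f"noise[{self.layer_id}]")
        if self.sigma2 < 0:
            raise ValidationError(f"noise variance must be >= 0, got {self.sigma2}")


@dataclass
class OmicLayer:
    """One observed data matrix X_I (features × samples)."""

    layer_id: str
    data: np.ndarray
    feature_ids: List[str]
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.data = _as_matrix(self.data, f"layer[{self.layer_id}]")
        m, n = self.data.shape
        if len(self.feature_ids) != m:
            raise ValidationError(f"{len(self.feature_ids)} feature_ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample_ids for {n} columns")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SimulatedDataset:
    """The emitted bundle: data plus complete ground truth.

    Regenerating with the same resolved config and seed reproduces every
    matrix exactly.
    """

    layers: List[OmicLayer]
    scores: ScoreMatrix
    loadings: Dict[str, LoadingMatrix]
    noises: Dict[str, NoiseMatrix]
    config: "signal_design.SimulationConfig" = None  # type: ignore[name-defined]
    seed: int = 0

    def layer(self, layer_id: str) -> OmicLayer:
        for lay in self.layers:
            if lay.layer_id == layer_id:
                return lay
        raise KeyError(layer_id)

    @property
    def layer_ids(self) -> List[str]:
        return [lay.layer_id for lay in self.layers]

    def signal(self, layer_id: str) -> np.ndarray:
        """Noiseless signal matrix S_I = Λ_Iᵀ Γ for one layer."""
        return self.loadings[layer_id].values.T @ self.scores.values

    def reconstruct(self, layer_id: str) -> np.ndarray:
        """Reassemble X_I from stored ground truth (Λᵀ Γ + E, plus any offset)."""
        x = self.signal(layer_id) + self.noises[layer_id].values
        offsets = getattr(self.config, "feature_offsets", None) or {}
        if layer_id in offsets:
            x = x + np.asarray(offsets[layer_id], dtype=float)[:, None]
        return x


def assemble_layer(loadings: LoadingMatrix, scores: ScoreMatrix, noise: NoiseMatrix) -> OmicLayer:
    """Assemble X = Λᵀ Γ + E for one layer.

    The output owns its memory: mutating the inputs afterwards does not
    change the returned layer.
    """
    if loadings.k != scores.k:
        raise ConfigurationError(
            f"loading matrix has k={loadings.k} factors but score matrix has "
            f"k={scores.k} (shapes {loadings.values.shape} vs {scores.values.shape})"
        )
    if loadings.factor_ids != scores.factor_ids:
        raise ConfigurationError(
            f"factor ordering mismatch: {loadings.factor_ids} vs {scores.factor_ids}"
        )
    expected = (loadings.m, scores.n)
    if noise.values.shape != expected:
        raise ConfigurationError(
            f"noise matrix shape {noise.values.shape} does not match "
            f"(m, n) = {expected} implied by loadings/scores"
        )
    data = loadings.values.T @ scores.values + noise.values
    return OmicLayer(
        layer_id=loadings.layer_id,
        data=data,
        feature_ids=list(loadings.feature_ids),
        sample_ids=list(scores.sample_ids),
    )


def draw_noise(m: int, n: int, sigma2: float, rng: np.random.Generator, layer_id: str = "") -> NoiseMatrix:
    """Draw an m × n noise matrix with i.i.d. N(0, sigma2) entries.

    ``sigma2 = 0`` returns the all-zero matrix; the same generator state
    always yields the same matrix.
    """
    if m < 1 or n < 1:
        raise ValidationError(f"noise dimensions must be positive, got {m} x {n}")
    if sigma2 < 0:
        raise ValidationError(f"noise variance must be >= 0, got {sigma2}")
    if sigma2 == 0:
        values = np.zeros((m, n))
    else:
        values = rng.normal(0.0, np.sqrt(sigma2), size=(m, n))
    return NoiseMatrix(values=values, sigma2=float(sigma2), layer_id=layer_id)


def simulate(config) -> SimulatedDataset:
    """Run the full generative model for a :class:`SimulationConfig`.

    One score matrix Γ is drawn once and shared by every layer; per-layer
    loadings are realized from the factor specs; per-layer noise comes
    from independent substreams.  Layers whose noise is given as a target
    SNR have σ²_I resolved from the realized signal variance.
    """
    from . import signal_design  # local import: signal_design depends on these types

    config = signal_design.validate_config(config)
    seed = config.seed
    n = config.n_samples
    sample_ids = [f"sample_{j}" for j in range(n)]

    scores = signal_design.realize_scores(config.factors, n, seed, sample_ids=sample_ids)

    layers: List[OmicLayer] = []
    loadings: Dict[str, LoadingMatrix] = {}
    noises: Dict[str, NoiseMatrix] = {}
    resolved_sigma2: Dict[str, float] = {}
    for layer_spec in config.layers:
        lid = layer_spec.layer_id
        lam = signal_design.realize_loadings(
            config.factors, lid, layer_spec.m, seed, feature_prefix=layer_spec.feature_prefix
        )
        noise_spec = config.noise[lid]
        if noise_spec.sigma2 is not None:
            sigma2 = float(noise_spec.sigma2)
        else:
            signal = lam.values.T @ scores.values
            sigma2 = signal_design.resolve_snr(signal, noise_spec.snr, layer_id=lid)
        resolved_sigma2[lid] = sigma2
        noise = draw_noise(layer_spec.m, n, sigma2, substream(seed, "noise", lid), layer_id=lid)
        layer = assemble_layer(lam, scores, noise)
        offsets = (config.feature_offsets or {}).get(lid)
        if offsets is not None:
            layer.data = layer.data + np.asarray(offsets, dtype=float)[:, None]
        layers.append(layer)
        loadings[lid] = lam
        noises[lid] = noise

    dataset = SimulatedDataset(
        layers=layers, scores=scores, loadings=loadings, noises=noises, config=config, seed=seed
    )
    dataset.resolved_sigma2 = resolved_sigma2  # type: ignore[attr-defined]
    return dataset
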