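"""Translate user intent into a concrete, reproducible signal design.

A factor is *unique* when it loads on exactly one omics layer, *shared*
when it spans two or more; a simulation mixing both is a *mixed*
structure.  Under the default ``disjoint`` overlap policy, the feature
supports of different factors within a layer never overlap, so every
feature is attributable to at most one factor — the crisp ground-truth
label used for sensitivity/specificity scoring.

Noise can be given directly as a per-layer variance σ²_I or indirectly
as a target signal-to-noise ratio, defined here as the ratio of the
empirical entry variance of the noiseless signal matrix Λ_Iᵀ Γ to σ²_I.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from ._rng import substream
from .errors import ConfigurationError, ValidationError
from .laws import DEFAULT_LOADING_LAW, DEFAULT_SCORE_LAW, sample_loadings, sample_score_row, validate_law
from .model_core import LoadingMatrix, OmicLayer, ScoreMatrix

__all__ = [
    "FactorSpec",
    "LayerSpec",
    "NoiseSpec",
    "SimulationConfig",
    "validate_config",
    "realize_loadings",
    "realize_scores",
    "resolve_snr",
    "permute_signal",
    "config_to_dict",
    "config_from_dict",
]

Support = Union[int, Sequence[int]]


@dataclass
class FactorSpec:
    """One latent factor: where it loads and how its values are drawn.

    ``activity`` maps layer_id → feature support, given either as an
    explicit index list or as a count to be placed by ``validate_config``.
    ``sample_support``, when given, restricts the factor's scores to a
    subset of samples (zero elsewhere).
    """

    factor_id: str
    activity: Dict[str, Support]
    score_law: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_LAW))
    loading_law: dict = field(default_factory=lambda: dict(DEFAULT_LOADING_LAW))
    sample_support: Optional[Sequence[int]] = None

    @property
    def is_resolved(self) -> bool:
        return all(not isinstance(s, (int, np.integer)) for s in self.activity.values())

    @property
    def layer_ids(self) -> List[str]:
        return list(self.activity)

    @property
    def label(self) -> str:
        """Derived 'shared' / 'unique' label from the number of active layers."""
        return "shared" if len(self.activity) >= 2 else "unique"


@dataclass
class LayerSpec:
    layer_id: str
    m: int
    feature_prefix: Optional[str] = None


@dataclass
class NoiseSpec:
    """Exactly one of ``sigma2`` (variance, data units²) or ``snr``
    (dimensionless variance ratio, > 0) per layer."""

    sigma2: Optional[float] = None
    snr: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.sigma2 is None) == (self.snr is None):
            raise ConfigurationError(
                f"give exactly one of sigma2 / snr per layer, got sigma2={self.sigma2}, snr={self.snr}"
            )
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValidationError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.snr is not None and self.snr <= 0:
            raise ValidationError(f"target SNR must be > 0, got {self.snr}")


@dataclass
class SimulationConfig:
    layers: List[LayerSpec]
    n_samples: int
    factors: List[FactorSpec]
    noise: Dict[str, NoiseSpec]
    overlap_policy: str = "disjoint"
    seed: Optional[int] = None
    feature_offsets: Optional[Dict[str, Sequence[float]]] = None

    @property
    def k(self) -> int:
        return len(self.factors)

    def layer(self, layer_id: str) -> LayerSpec:
        for spec in self.layers:
            if spec.layer_id == layer_id:
                return spec
        raise KeyError(layer_id)


def validate_config(config: SimulationConfig) -> SimulationConfig:
    """Validate a configuration and resolve it to explicit form.

    Count-style supports are placed by sampling without replacement from
    the layer's remaining free indices, in factor declaration order, using
    the seed's per-layer "placement" substream — so resolution is a pure
    function of (config, seed).  Under the ``disjoint`` policy an overlap
    among explicit supports, or an infeasible count, is an error naming
    the colliding factors.  The returned config is fully explicit and
    re-simulates bit-exactly.
    """
    if config.seed is None:
        raise ConfigurationError("config.seed is required: reproducibility is mandatory, no clock seeding")
    if config.n_samples < 2:
        raise ConfigurationError(f"n_samples must be >= 2, got {config.n_samples}")
    if config.overlap_policy not in ("disjoint", "free"):
        raise ConfigurationError(f"overlap_policy must be 'disjoint' or 'free', got {config.overlap_policy!r}")
    if not config.layers:
        raise ConfigurationError("at least one layer is required")

    layer_ids = [l.layer_id for l in config.layers]
    if len(set(layer_ids)) != len(layer_ids):
        raise ConfigurationError(f"duplicate layer ids: {layer_ids}")
    for spec in config.layers:
        if spec.m < 1:
            raise ConfigurationError(f"layer {spec.layer_id!r} needs m >= 1 features, got {spec.m}")
    if set(config.noise) != set(layer_ids):
        raise ConfigurationError(
            f"noise must be specified for exactly the layers {layer_ids}, got {sorted(config.noise)}"
        )

    factor_ids = [f.factor_id for f in config.factors]
    if len(set(factor_ids)) != len(factor_ids):
        dupes = sorted({fid for fid in factor_ids if factor_ids.count(fid) > 1})
        raise ConfigurationError(f"duplicate factor ids: {dupes}")

    for f in config.factors:
        if not f.activity:
            raise ConfigurationError(f"factor {f.factor_id!r} has empty activity (must load on >= 1 layer)")
        for lid in f.activity:
            if lid not in layer_ids:
                raise ConfigurationError(f"factor {f.factor_id!r} references unknown layer {lid!r}")
        validate_law(f.score_law, "score")
        validate_law(f.loading_law, "loading")
        if f.sample_support is not None:
            ss = np.asarray(list(f.sample_support), dtype=int)
            if ss.size and (ss.min() < 0 or ss.max() >= config.n_samples):
                raise ValidationError(
                    f"factor {f.factor_id!r} sample_support index out of range [0, {config.n_samples})"
                )

    # resolve feature supports per layer
    resolved: Dict[str, Dict[str, List[int]]] = {lid: {} for lid in layer_ids}
    for layer_spec in config.layers:
        lid, m = layer_spec.layer_id, layer_spec.m
        taken: Dict[int, str] = {}

        def claim(fid: str, idx: Sequence[int]) -> None:
            for i in idx:
                if config.overlap_policy == "disjoint" and i in taken:
                    raise ConfigurationError(
                        f"layer {lid!r}: factors {taken[i]!r} and {fid!r} overlap on feature "
                        f"index {i} under the disjoint policy"
                    )
                taken[i] = fid

        # explicit supports first: they are fixed by the user
        for f in config.factors:
            support = f.activity.get(lid)
            if support is None or isinstance(support, (int, np.integer)):
                continue
            idx = sorted(int(i) for i in support)
            if len(set(idx)) != len(idx):
                raise ConfigurationError(f"factor {f.factor_id!r} has duplicate feature indices on {lid!r}")
            if idx and (idx[0] < 0 or idx[-1] >= m):
                raise ConfigurationError(
                    f"factor {f.factor_id!r} support on layer {lid!r} outside [0, {m})"
                )
            claim(f.factor_id, idx)
            resolved[lid][f.factor_id] = idx

        # then count-style supports, in declaration order, from the placement substream
        rng = substream(config.seed, "placement", lid)
        for f in config.factors:
            support = f.activity.get(lid)
            if not isinstance(support, (int, np.integer)):
                continue
            count = int(support)
            if count < 1:
                raise ConfigurationError(f"factor {f.factor_id!r} requests {count} features on {lid!r}")
            pool = (
                [i for i in range(m) if i not in taken]
                if config.overlap_policy == "disjoint"
                else list(range(m))
            )
            if count > len(pool):
                raise ConfigurationError(
                    f"layer {lid!r}: factor {f.factor_id!r} requests {count} features but only "
                    f"{len(pool)} of {m} are free under the {config.overlap_policy} policy"
                )
            idx = sorted(int(i) for i in rng.choice(pool, size=count, replace=False))
            claim(f.factor_id, idx)
            resolved[lid][f.factor_id] = idx

    new_factors = [
        replace(
            f,
            activity={lid: list(resolved[lid][f.factor_id]) for lid in f.activity},
            score_law=validate_law(f.score_law, "score"),
            loading_law=validate_law(f.loading_law, "loading"),
            sample_support=None if f.sample_support is None else sorted(int(i) for i in f.sample_support),
        )
        for f in config.factors
    ]

    if config.feature_offsets is not None:
        for lid, vec in config.feature_offsets.items():
            if lid not in layer_ids:
                raise ConfigurationError(f"feature_offsets references unknown layer {lid!r}")
            if len(vec) != config.layer(lid).m:
                raise ConfigurationError(
                    f"feature_offsets for layer {lid!r} has length {len(vec)}, expected {config.layer(lid).m}"
                )

    return replace(config, factors=new_factors)


def realize_loadings(
    spec_list: Sequence[FactorSpec],
    layer_id: str,
    m: int,
    seed: int,
    feature_prefix: Optional[str] = None,
) -> LoadingMatrix:
    """Build the k × m loading matrix Λ_I for one layer.

    Row i carries draws from factor i's loading law exactly on its
    resolved support in this layer; all other entries — including the
    whole row of any factor inactive here — are exactly zero.
    """
    values = np.zeros((len(spec_list), m))
    for i, f in enumerate(spec_list):
        support = f.activity.get(layer_id)
        if support is None:
            continue
        if isinstance(support, (int, np.integer)):
            raise ConfigurationError(
                f"factor {f.factor_id!r} has an unresolved count-style support; run validate_config first"
            )
        idx = np.asarray(list(support), dtype=int)
        if idx.size:
            rng = substream(seed, "loadings", layer_id, f.factor_id)
            values[i, idx] = sample_loadings(f.loading_law, idx.size, rng)
    prefix = feature_prefix or f"{layer_id}_feature"
    return LoadingMatrix(
        values=values,
        layer_id=layer_id,
        factor_ids=[f.factor_id for f in spec_list],
        feature_ids=[f"{prefix}_{j}" for j in range(m)],
    )


def realize_scores(
    spec_list: Sequence[FactorSpec],
    n: int,
    seed: int,
    sample_ids: Optional[List[str]] = None,
) -> ScoreMatrix:
    """Draw the shared k × n score matrix Γ, one row per factor.

    Entries outside a factor's ``sample_support`` (when given) are set to
    the baseline 0.
    """
    values = np.zeros((len(spec_list), n))
    for i, f in enumerate(spec_list):
        rng = substream(seed, "scores", f.factor_id)
        row = sample_score_row(f.score_law, n, rng)
        if f.sample_support is not None:
            idx = np.asarray(list(f.sample_support), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValidationError(
                    f"factor {f.factor_id!r} sample_support index out of range [0, {n})"
                )
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            row = np.where(mask, row, 0.0)
        values[i] = row
    return ScoreMatrix(
        values=values,
        factor_ids=[f.factor_id for f in spec_list],
        sample_ids=sample_ids or [f"sample_{j}" for j in range(n)],
    )


def resolve_snr(signal: np.ndarray, target_snr: float, layer_id: str = "") -> float:
    """Convert a target SNR into a noise variance for one layer.

    SNR is defined as Var(signal entries) / σ², so σ² = Var(S) / SNR.
    """
    if target_snr is None or target_snr <= 0:
        raise ValidationError(f"target SNR must be > 0, got {target_snr}")
    var = float(np.var(np.asarray(signal, dtype=float)))
    if var == 0.0:
        raise ConfigurationError(
            f"layer {layer_id!r}: signal matrix is all-zero, SNR is undefined; give sigma2 directly"
        )
    return var / float(target_snr)


def permute_signal(layer: OmicLayer, rng: np.random.Generator) -> OmicLayer:
    """Independently permute each feature row across samples.

    Preserves every feature's marginal value multiset while destroying
    cross-feature (sample-level) structure — the standard factor-analysis
    null used to contrast structured and permuted signal patterns.
    """
    data = layer.data.copy()
    for i in range(data.shape[0]):
        data[i] = data[i, rng.permutation(data.shape[1])]
    return OmicLayer(
        layer_id=layer.layer_id,
        data=data,
        feature_ids=list(layer.feature_ids),
        sample_ids=list(layer.sample_ids),
    )


# ---------------------------------------------------------------------------
# config (de)serialization — plain dicts for YAML/JSON files

def config_to_dict(config: SimulationConfig) -> dict:
    out = {
        "layers": [
            {"id": l.layer_id, "m": l.m, **({"feature_prefix": l.feature_prefix} if l.feature_prefix else {})}
            for l in config.layers
        ],
        "n_samples": config.n_samples,
        "factors": [],
        "noise": {},
        "overlap_policy": config.overlap_policy,
        "seed": config.seed,
    }
    for f in config.factors:
        entry: dict = {"id": f.factor_id, "active_on": {}}
        for lid, support in f.activity.items():
            if isinstance(support, (int, np.integer)):
                entry["active_on"][lid] = {"n_features": int(support)}
            else:
                entry["active_on"][lid] = {"features": [int(i) for i in support]}
        entry["score_law"] = dict(f.score_law)
        entry["loading_law"] = dict(f.loading_law)
        if f.sample_support is not None:
            entry["sample_support"] = [int(i) for i in f.sample_support]
        out["factors"].append(entry)
    for lid, ns in config.noise.items():
        out["noise"][lid] = {"sigma2": ns.sigma2} if ns.sigma2 is not None else {"snr": ns.snr}
    if config.feature_offsets:
        out["feature_offsets"] = {lid: [float(v) for v in vec] for lid, vec in config.feature_offsets.items()}
    return out


def config_from_dict(data: Mapping) -> SimulationConfig:
    try:
        layers = [
            LayerSpec(layer_id=str(l["id"]), m=int(l["m"]), feature_prefix=l.get("feature_prefix"))
            for l in data["layers"]
        ]
        factors = []
        for f in data.get("factors", []):
            activity: Dict[str, Support] = {}
            for lid, spec in f["active_on"].items():
                if "features" in spec:
                    activity[lid] = [int(i) for i in spec["features"]]
                elif "n_features" in spec:
                    activity[lid] = int(spec["n_features"])
                else:
                    raise ConfigurationError(
                        f"factor {f.get('id')!r} active_on[{lid!r}] needs 'features' or 'n_features'"
                    )
            factors.append(
                FactorSpec(
                    factor_id=str(f["id"]),
                    activity=activity,
                    score_law=dict(f.get("score_law", DEFAULT_SCORE_LAW)),
                    loading_law=dict(f.get("loading_law", DEFAULT_LOADING_LAW)),
                    sample_support=f.get("sample_support"),
                )
            )
        noise = {}
        for lid, spec in data["noise"].items():
            noise[str(lid)] = NoiseSpec(sigma2=spec.get("sigma2"), snr=spec.get("snr"))
        return SimulationConfig(
            layers=layers,
            n_samples=int(data["n_samples"]),
            factors=factors,
            noise=noise,
            overlap_policy=data.get("overlap_policy", "disjoint"),
            seed=None if data.get("seed") is None else int(data["seed"]),
            feature_offsets=data.get("feature_offsets"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"config is missing required key: {exc}") from exc
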