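import numpy as np
import pytest

import factorsim as fs


def make_mixed_config(
    seed: int,
    n: int = 100,
    noise=None,
    m_rna: int = 150,
    m_prot: int = 100,
) -> fs.SimulationConfig:
    """Two-layer mixed design: one shared factor, one unique to the first
    layer — the canonical shared/unique benchmark structure.  Support
    sizes are deliberately unequal so the factors have well-separated
    singular values."""
    if noise is None:
        noise = {"rna": fs.NoiseSpec(sigma2=1.0), "prot": fs.NoiseSpec(sigma2=1.0)}
    return fs.SimulationConfig(
        layers=[fs.LayerSpec("rna", m_rna), fs.LayerSpec("prot", m_prot)],
        n_samples=n,
        factors=[
            fs.FactorSpec(
                "f1", {"rna": 60, "prot": 45}, loading_law={"family": "normal", "mean": 5, "sd": 1}
            ),
            fs.FactorSpec(
                "f2", {"rna": 20}, loading_law={"family": "normal", "mean": 4, "sd": 0.8}
            ),
        ],
        noise=noise,
        seed=seed,
    )


@pytest.fixture
def mixed_config():
    return make_mixed_config(seed=7)


@pytest.fixture
def mixed_dataset(mixed_config):
    return fs.simulate(mixed_config)


def random_config(rng: np.random.Generator) -> fs.SimulationConfig:
    """A small randomized but always-feasible configuration."""
    n_layers = int(rng.integers(1, 4))
    layers = [fs.LayerSpec(f"L{i}", int(rng.integers(5, 40))) for i in range(n_layers)]
    n = int(rng.integers(4, 30))
    k = int(rng.integers(0, 4))
    factors = []
    budget = {l.layer_id: l.m for l in layers}
    for i in range(k):
        active = {}
        for l in layers:
            if rng.random() < 0.6 and budget[l.layer_id] >= 2:
                take = int(rng.integers(1, max(2, budget[l.layer_id] // 2)))
                active[l.layer_id] = take
                budget[l.layer_id] -= take
        if not active:
            lid = layers[0].layer_id
            if budget[lid] < 1:
                continue
            active = {lid: 1}
            budget[lid] -= 1
        factors.append(fs.FactorSpec(f"f{i}", active))
    noise = {}
    for l in layers:
        has_signal = any(l.layer_id in f.activity for f in factors)
        if has_signal and rng.random() < 0.3:
            noise[l.layer_id] = fs.NoiseSpec(snr=float(rng.uniform(0.1, 50)))
        else:
            noise[l.layer_id] = fs.NoiseSpec(sigma2=float(rng.uniform(0, 4)))
    return fs.SimulationConfig(
        layers=layers, n_samples=n, factors=factors, noise=noise, seed=int(rng.integers(2**31))
    )
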