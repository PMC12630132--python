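"""File interfaces: TSV matrices, JSON manifest, config files.

Layout (all tab-separated, UTF-8, '.' decimal, no quoting):

* ``<layer>.tsv`` — data matrix, header row = sample IDs, first column
  ``feature_id``.
* ``scores.tsv`` — ground-truth Γ, factors × samples, first column
  ``factor_id``.
* ``loadings_<layer>.tsv`` — Λ_I, factors × features, first column
  ``factor_id``.
* ``noise_<layer>.tsv`` — E_I, same layout as the data matrix.
* ``manifest.json`` — resolved config, seed, per-layer σ² (and target
  SNR where given), file paths, tool version, creation timestamp.

Values round-trip bit-exactly (shortest-repr float serialization), so
``read_dataset(write_dataset(d))`` reproduces every matrix.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, IntegrityError, ValidationError
from .evaluation import Factorization, RecoveryReport
from .model_core import LoadingMatrix, NoiseMatrix, OmicLayer, ScoreMatrix, SimulatedDataset
from .signal_design import SimulationConfig, config_from_dict, config_to_dict

__all__ = [
    "write_dataset",
    "read_dataset",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_factorization",
    "write_factorization",
    "load_config",
    "save_config",
    "write_report",
    "write_layer_mtx",
]

MANIFEST_NAME = "manifest.json"


def write_matrix_tsv(path, values: np.ndarray, row_ids, col_ids, index_label: str) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float), index=row_ids, columns=col_ids)
    # %.17g is lossless for float64, so written matrices round-trip bit-exactly
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


def read_matrix_tsv(path, index_label: Optional[str] = None, allow_nan: bool = False) -> pd.DataFrame:
    """Strict TSV matrix reader: numeric cells only, no locale leniency.

    Anything that does not parse as a '.'-decimal float (e.g. a
    decimal-comma locale export) is a hard parse error, never silent
    corruption.
    """
    path = Path(path)
    if not path.exists():
        raise IntegrityError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValidationError(
            f"{path}: non-numeric values in column(s) {bad[:3]} — expected '.'-decimal TSV"
        )
    if df.isna().to_numpy().any() and not allow_nan:
        raise ValidationError(f"{path}: missing/unparseable cells found")
    if index_label is not None and df.index.name != index_label:
        raise IntegrityError(
            f"{path}: first column header is {df.index.name!r}, expected {index_label!r}"
        )
    return df


def write_dataset(dataset: SimulatedDataset, out_dir, overwrite: bool = False) -> dict:
    """Write the full ground-truth bundle and return the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True (CLI: --overwrite) to replace it"
        )

    files: Dict[str, object] = {"layers": {}, "loadings": {}, "noises": {}}
    scores = dataset.scores
    write_matrix_tsv(out_dir / "scores.tsv", scores.values, scores.factor_ids, scores.sample_ids, "factor_id")
    files["scores"] = "scores.tsv"
    for lay in dataset.layers:
        lid = lay.layer_id
        write_matrix_tsv(out_dir / f"{lid}.tsv", lay.data, lay.feature_ids, lay.sample_ids, "feature_id")
        files["layers"][lid] = f"{lid}.tsv"
        lam = dataset.loadings[lid]
        write_matrix_tsv(
            out_dir / f"loadings_{lid}.tsv", lam.values, lam.factor_ids, lam.feature_ids, "factor_id"
        )
        files["loadings"][lid] = f"loadings_{lid}.tsv"
        noi = dataset.noises[lid]
        write_matrix_tsv(
            out_dir / f"noise_{lid}.tsv", noi.values, lay.feature_ids, lay.sample_ids, "feature_id"
        )
        files["noises"][lid] = f"noise_{lid}.tsv"

    sigma2 = {lid: float(dataset.noises[lid].sigma2) for lid in dataset.layer_ids}
    snr_target = {
        lid: (None if ns.snr is None else float(ns.snr)) for lid, ns in dataset.config.noise.items()
    }
    manifest = {
        "tool": "factorsim",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": int(dataset.seed),
        "snr_definition": "var(signal entries) / sigma2",
        "sigma2": sigma2,
        "snr_target": snr_target,
        "config": config_to_dict(dataset.config),
        "files": files,
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(manifest_path) -> SimulatedDataset:
    """Inverse of :func:`write_dataset`; verifies dimensions against the manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IntegrityError(f"missing file: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    config = config_from_dict(manifest["config"])
    n = config.n_samples

    scores_df = read_matrix_tsv(base / manifest["files"]["scores"], "factor_id")
    if scores_df.shape != (len(config.factors), n):
        raise IntegrityError(
            f"scores.tsv has shape {scores_df.shape}, manifest implies {(len(config.factors), n)}"
        )
    scores = ScoreMatrix(
        values=scores_df.to_numpy(),
        factor_ids=[str(i) for i in scores_df.index],
        sample_ids=[str(c) for c in scores_df.columns],
    )

    layers, loadings, noises = [], {}, {}
    for layer_spec in config.layers:
        lid, m = layer_spec.layer_id, layer_spec.m
        lay_df = read_matrix_tsv(base / manifest["files"]["layers"][lid], "feature_id")
        if lay_df.shape != (m, n):
            raise IntegrityError(f"layer {lid!r} matrix has shape {lay_df.shape}, expected {(m, n)}")
        lam_df = read_matrix_tsv(base / manifest["files"]["loadings"][lid], "factor_id")
        if lam_df.shape != (len(config.factors), m):
            raise IntegrityError(
                f"loadings for {lid!r} have shape {lam_df.shape}, expected {(len(config.factors), m)}"
            )
        noi_df = read_matrix_tsv(base / manifest["files"]["noises"][lid], "feature_id")
        if noi_df.shape != (m, n):
            raise IntegrityError(f"noise for {lid!r} has shape {noi_df.shape}, expected {(m, n)}")
        feature_ids = [str(i) for i in lay_df.index]
        sample_ids = [str(c) for c in lay_df.columns]
        layers.append(OmicLayer(layer_id=lid, data=lay_df.to_numpy(), feature_ids=feature_ids, sample_ids=sample_ids))
        loadings[lid] = LoadingMatrix(
            values=lam_df.to_numpy(), layer_id=lid,
            factor_ids=[str(i) for i in lam_df.index], feature_ids=[str(c) for c in lam_df.columns],
        )
        noises[lid] = NoiseMatrix(values=noi_df.to_numpy(), sigma2=float(manifest["sigma2"][lid]), layer_id=lid)

    return SimulatedDataset(
        layers=layers, scores=scores, loadings=loadings, noises=noises,
        config=config, seed=int(manifest["seed"]),
    )


def write_factorization(fac: Factorization, out_dir, prefix: str = "inferred") -> Dict[str, str]:
    """Write an inferred factorization in the ground-truth TSV layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k_hat, n = fac.scores_hat.shape
    factor_ids = [f"factor_{i}" for i in range(k_hat)]
    paths = {}
    scores_path = out_dir / f"{prefix}_scores.tsv"
    write_matrix_tsv(scores_path, fac.scores_hat, factor_ids, [f"sample_{j}" for j in range(n)], "factor_id")
    paths["scores"] = str(scores_path)
    for lid, lam in fac.loadings_hat.items():
        p = out_dir / f"{prefix}_loadings_{lid}.tsv"
        write_matrix_tsv(p, lam, factor_ids, [f"feature_{j}" for j in range(lam.shape[1])], "factor_id")
        paths[f"loadings:{lid}"] = str(p)
    return paths


def read_factorization(
    scores_path, loadings_paths: Dict[str, Union[str, Path]], method_label: str = "external"
) -> Factorization:
    """Read an inferred factorization (any method) from TSV files."""
    scores_df = read_matrix_tsv(scores_path, "factor_id")
    loadings = {lid: read_matrix_tsv(p, "factor_id").to_numpy() for lid, p in loadings_paths.items()}
    return Factorization(scores_hat=scores_df.to_numpy(), loadings_hat=loadings, method_label=method_label)


def load_config(path) -> SimulationConfig:
    """Load a simulation config from YAML (JSON is a YAML subset)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_report(report: RecoveryReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_layer_mtx(layer: OmicLayer, path) -> None:
    """Optional Matrix Market export for sparse-format interop."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(str(path), sparse.csr_matrix(layer.data))
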