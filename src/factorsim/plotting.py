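"""Inspection plots for simulated datasets.

Per layer: a heatmap of the structured data, a heatmap of the same data
with within-feature permuted samples (the factor-analysis null, for
visual contrast), and per factor a loading scatter + histogram panel.
Globally: factor-score scatter plots (factor i vs j, or factor vs sample
index when k = 1).  Individual plotting failures are logged and skipped,
never fatal.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from ._rng import substream
from .model_core import SimulatedDataset
from .signal_design import permute_signal

__all__ = ["plot_suite"]

logger = logging.getLogger(__name__)


def _save(fig, path: Path, out: List[str]) -> None:
    fig.savefig(path, dpi=100)
    plt.close(fig)
    out.append(str(path))


def plot_suite(dataset: SimulatedDataset, out_dir) -> List[str]:
    """Emit the inspection plot set; returns the list of written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[str] = []
    scores = dataset.scores

    for lay in dataset.layers:
        lid = lay.layer_id
        try:
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(lay.data, aspect="auto", cmap="viridis", interpolation="nearest")
            ax.set(title=f"{lid}: structured signal", xlabel="sample", ylabel="feature")
            fig.colorbar(im, ax=ax)
            _save(fig, out_dir / f"{lid}_heatmap.png", written)
        except Exception:
            logger.exception("structured heatmap failed for layer %s", lid)
        try:
            permuted = permute_signal(lay, substream(dataset.seed, "plot-permute", lid))
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(permuted.data, aspect="auto", cmap="viridis", interpolation="nearest")
            ax.set(title=f"{lid}: permuted signal", xlabel="sample", ylabel="feature")
            fig.colorbar(im, ax=ax)
            _save(fig, out_dir / f"{lid}_heatmap_permuted.png", written)
        except Exception:
            logger.exception("permuted heatmap failed for layer %s", lid)

        lam = dataset.loadings[lid]
        for i, fid in enumerate(lam.factor_ids):
            try:
                row = lam.values[i]
                fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
                ax1.scatter(range(len(row)), row, s=6)
                ax1.set(title=f"{lid} / {fid}: loadings", xlabel="feature index", ylabel="loading")
                ax2.hist(row, bins=40)
                ax2.set(title="loading distribution", xlabel="loading", ylabel="count")
                fig.tight_layout()
                _save(fig, out_dir / f"{lid}_loadings_{fid}.png", written)
            except Exception:
                logger.exception("loading plot failed for %s/%s", lid, fid)

    try:
        if scores.k >= 2:
            for i, j in itertools.combinations(range(scores.k), 2):
                fig, ax = plt.subplots(figsize=(4, 4))
                ax.scatter(scores.values[i], scores.values[j], s=10)
                ax.set(
                    title="factor scores",
                    xlabel=scores.factor_ids[i],
                    ylabel=scores.factor_ids[j],
                )
                fig.tight_layout()
                _save(fig, out_dir / f"scores_{scores.factor_ids[i]}_vs_{scores.factor_ids[j]}.png", written)
        elif scores.k == 1:
            # degenerate k: fall back to factor vs sample index
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.scatter(range(scores.n), scores.values[0], s=10)
            ax.set(title="factor scores", xlabel="sample index", ylabel=scores.factor_ids[0])
            fig.tight_layout()
            _save(fig, out_dir / f"scores_{scores.factor_ids[0]}_vs_index.png", written)
    except Exception:
        logger.exception("score scatter failed")

    return written
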