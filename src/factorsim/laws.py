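"""Distribution descriptors for factor scores and feature loadings.

A *law* is a plain mapping with a ``family`` key, so it serializes
directly to YAML/JSON configuration files:

``{"family": "normal", "mean": 0.0, "sd": 1.0}``
    i.i.d. Gaussian draws.
``{"family": "constant", "value": c}``
    every entry equals ``c``.
``{"family": "two_group", "means": [a, b], "sd": s, "split": j}``
    score law only: samples ``0..split-1`` get mean ``a``, the rest mean
    ``b`` (default split: half the samples).  Mimics a factor that
    separates two sample groups.

Loading laws additionally accept ``min_abs`` (magnitudes below the floor
are pushed out to it, sign preserved) and ``random_sign`` (multiply each
draw by an independent ±1), which guarantee visibly active features.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .errors import ValidationError

__all__ = [
    "DEFAULT_SCORE_LAW",
    "DEFAULT_LOADING_LAW",
    "validate_law",
    "sample_score_row",
    "sample_loadings",
]

DEFAULT_SCORE_LAW: dict = {"family": "normal", "mean": 0.0, "sd": 1.0}
DEFAULT_LOADING_LAW: dict = {"family": "normal", "mean": 3.0, "sd": 1.0}

_SCORE_FAMILIES = {"normal", "constant", "two_group"}
_LOADING_FAMILIES = {"normal", "constant"}


def validate_law(law: Mapping, kind: str) -> dict:
    """Check a law descriptor and return it with defaults filled in."""
    if not isinstance(law, Mapping) or "family" not in law:
        raise ValidationError(f"{kind} law must be a mapping with a 'family' key, got {law!r}")
    family = law["family"]
    allowed = _SCORE_FAMILIES if kind == "score" else _LOADING_FAMILIES
    if family not in allowed:
        raise ValidationError(f"unknown {kind} law family {family!r}; allowed: {sorted(allowed)}")
    out = dict(law)
    if family == "normal":
        out.setdefault("mean", 0.0)
        out.setdefault("sd", 1.0)
        if out["sd"] < 0:
            raise ValidationError(f"{kind} law sd must be >= 0, got {out['sd']}")
        if kind == "loading":
            out.setdefault("min_abs", 0.0)
            out.setdefault("random_sign", False)
            if out["min_abs"] < 0:
                raise ValidationError(f"min_abs must be >= 0, got {out['min_abs']}")
    elif family == "constant":
        if "value" not in out:
            raise ValidationError(f"constant {kind} law requires a 'value' key")
    elif family == "two_group":
        means = out.get("means")
        if means is None or len(means) != 2:
            raise ValidationError("two_group law requires 'means': [group1, group2]")
        out.setdefault("sd", 1.0)
        out.setdefault("split", None)  # resolved to n // 2 at sampling time
        if out["sd"] < 0:
            raise ValidationError(f"two_group sd must be >= 0, got {out['sd']}")
    return out


def sample_score_row(law: Mapping, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one factor's scores across ``n`` samples."""
    law = validate_law(law, "score")
    family = law["family"]
    if family == "constant":
        return np.full(n, float(law["value"]))
    if family == "normal":
        return rng.normal(law["mean"], law["sd"], size=n)
    # two_group
    split = law["split"] if law["split"] is not None else n // 2
    if not 0 <= split <= n:
        raise ValidationError(f"two_group split {split} outside [0, {n}]")
    means = np.where(np.arange(n) < split, float(law["means"][0]), float(law["means"][1]))
    return means + rng.normal(0.0, law["sd"], size=n)


def sample_loadings(law: Mapping, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw loading values for the active features of one factor."""
    law = validate_law(law, "loading")
    if law["family"] == "constant":
        return np.full(size, float(law["value"]))
    vals = rng.normal(law["mean"], law["sd"], size=size)
    floor = law.get("min_abs", 0.0)
    if floor > 0:
        small = np.abs(vals) < floor
        # push sub-floor magnitudes out to the floor, keeping sign (0 -> +floor)
        vals[small] = np.where(vals[small] >= 0, floor, -floor)
    if law.get("random_sign", False):
        vals = vals * rng.choice([-1.0, 1.0], size=size)
    return vals
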