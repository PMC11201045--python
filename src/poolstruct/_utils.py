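"""Shared numerical helpers."""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("poolstruct")

#: clipping bound for logit transforms of boundary frequencies / FIR values
LOGIT_EPS = 1e-6


def logit(x, eps: float = LOGIT_EPS):
    x = np.clip(np.asarray(x, dtype=float), eps, 1.0 - eps)
    return np.log(x / (1.0 - x))


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


def check_unit_interval(arr, name: str) -> None:
    a = np.asarray(arr, dtype=float)
    finite = a[np.isfinite(a)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError(f"{name} must lie in [0, 1]")


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
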