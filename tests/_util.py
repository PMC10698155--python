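"""Shared test helpers: dataset builders and brute-force likelihood oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from pafcc import CodedDataset


def dataset_from_table(a: int, b: int, c: int, d: int) -> CodedDataset:
    """Expand 2x2 counts into a row-level coded dataset."""
    status = [1] * (a + b) + [0] * (c + d)
    exposure = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
    return CodedDataset(pd.DataFrame({"status": status, "exposure": exposure}))


def bernoulli_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def firth_penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (p * (1 - p))[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return bernoulli_loglik(X, y, beta) + 0.5 * logdet


def grid_maximize_2d(fn, center=(0.0, 0.0), width=8.0, levels=14, points=21
                     ) -> np.ndarray:
    """Maximize a smooth concave-ish 2-argument function by refining grids.

    Independent of any gradient-based fitting route: pure evaluation on
    successively zoomed lattices.  Final spacing ~ width / 10 / 4**levels.
    """
    c = np.asarray(center, dtype=float)
    w = width
    for _ in range(levels):
        g0 = np.linspace(c[0] - w, c[0] + w, points)
        g1 = np.linspace(c[1] - w, c[1] + w, points)
        best, arg = -np.inf, c
        for b0 in g0:
            for b1 in g1:
                v = fn(np.array([b0, b1]))
                if v > best:
                    best, arg = v, np.array([b0, b1])
        c = arg
        w /= 4.0
    return c
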