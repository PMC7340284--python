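"""Small numerical helpers shared by the force kernels.

``bincount``-based scatter-adds replace ``np.ufunc.at`` (an order of
magnitude faster for the pair counts this model produces) and keep the
deterministic, parallelism-independent reduction order the engine
promises.
"""

from __future__ import annotations

import numpy as np


def scatter_add_vec(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """out[idx] += vals for (n, 3) value rows, accumulated deterministically."""
    n = out.shape[0]
    for d in range(3):
        out[:, d] += np.bincount(idx, weights=vals[:, d], minlength=n)


def scatter_add_scalar(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    out += np.bincount(idx, weights=vals, minlength=out.shape[0])


def row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product (faster than np.cross for 2-D stacks)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out
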