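"""Shared numerical helpers: seeding, map matching, correlation."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a master seed out into *n* independent generators.

    Uses ``SeedSequence.spawn`` so streams are statistically independent and
    reproducible from the single master seed.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def child_seed(seed: int, index: int) -> int:
    """Deterministic child integer seed (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence([seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of ``a`` (m x v) and rows of ``b`` (n x v)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    an[an == 0] = np.nan
    bn[bn == 0] = np.nan
    return (ac @ bc.T) / np.outer(an, bn)


def match_maps(reference: np.ndarray, estimated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated maps to reference maps by maximal absolute correlation.

    Resolves the permutation/sign indeterminacy of ICA with a Hungarian
    assignment on ``1 - |r|``.  Returns ``(indices, r)`` where
    ``estimated[indices[i]]`` is the match for ``reference[i]`` and ``r[i]``
    the signed correlation of that pair.
    """
    c = corr_matrix(reference, estimated)
    cost = 1.0 - np.abs(np.nan_to_num(c))
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows)
    idx = cols[order]
    r = c[np.arange(len(rows)), idx]
    return idx, r


def amari_index(P: np.ndarray) -> float:
    """Amari separation index of a permutation-like matrix, in [0, 1].

    Zero iff ``P`` is a scaled permutation; used to score how well an
    unmixing matrix inverts a known mixing.
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    row = (P.sum(axis=1) / P.max(axis=1) - 1).sum() / (n - 1)
    col = (P.sum(axis=0) / P.max(axis=0) - 1).sum() / (n - 1)
    return float((row + col) / (2 * n))


def vec_upper(mat: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix."""
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def unvec_upper(vec: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vec_upper`: symmetric matrix with unit diagonal."""
    out = np.eye(p)
    iu = np.triu_indices(p, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out
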