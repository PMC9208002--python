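"""Group spatial ICA at multiple model orders.

Pipeline per model order N: subject-level spatial PCA (retaining > 99.99%
variance by default) -> concatenation of subject principal-component images
along the time/component dimension -> group-level spatial PCA to N
whitened components -> Infomax ICA, repeated with different initial
conditions and aggregated with ICASSO stability clustering -> the run
closest to the cluster centrotypes is kept as the best run -> subject time
courses by spatial multiple regression on the group maps.

Infomax is the natural-gradient algorithm (sign-adaptive by default, with
the classic logistic update available) with an annealed learning rate;
ICASSO pools components from all runs, clusters
them by absolute spatial correlation with average linkage, and scores each
cluster with the stability (quality) index: mean intra-cluster similarity
minus mean extra-cluster similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from ._utils import child_seed, corr_matrix
from .dataset import MaskedDataset

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA stages
# ---------------------------------------------------------------------------

def subject_pca(
    data: np.ndarray | MaskedDataset, var_retained: float = 0.9999
) -> tuple[np.ndarray, int]:
    """Subject-level spatial PCA and whitening.

    ``data`` is the subject's z-scored voxels x time matrix.  Returns the
    whitened principal-component images (d x voxels, orthogonal rows of
    unit variance over voxels) and the retained dimension d: the smallest
    number of components whose cumulative explained variance reaches
    ``var_retained``.
    """
    if isinstance(data, MaskedDataset):
        data = data.data
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a voxels x time matrix with time >= 2")
    if not np.any(X):
        raise ValueError("zero-variance input")
    # spatial PCA: voxels are the variables, so remove each time point's
    # spatial mean before the decomposition
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        raise ValueError("zero-variance input")
    ratio = np.cumsum(ev) / total
    d = int(np.searchsorted(ratio, var_retained - 1e-12) + 1)
    d = min(d, np.sum(ev > total * 1e-12))
    Y = U[:, :d].T * np.sqrt(X.shape[0])
    return Y, d


def explained_variance_ratio(data: np.ndarray) -> np.ndarray:
    """Per-component explained-variance fractions of the sample covariance."""
    X = np.asarray(data, dtype=float)
    s = np.linalg.svd(X, compute_uv=False)
    ev = s**2
    return ev / ev.sum()


def group_pca(subject_whitened: list[np.ndarray], n_components: int) -> np.ndarray:
    """Group-level spatial PCA of concatenated subject components.

    Stacks the subjects' whitened component images along the component
    (time) dimension and returns the ``n_components`` whitened directions
    of maximal variance (n_components x voxels), the input to spatial ICA.
    """
    C = np.vstack(subject_whitened)
    C = C - C.mean(axis=1, keepdims=True)  # zero spatial mean per component image
    if n_components > C.shape[0]:
        raise ValueError(
            f"model order {n_components} exceeds the {C.shape[0]} concatenated "
            "subject components"
        )
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    if s[n_components - 1] <= s[0] * 1e-12:
        raise ValueError(
            f"model order {n_components} exceeds the effective rank of the data"
        )
    return Vt[:n_components] * np.sqrt(C.shape[1])


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------

@dataclass
class InfomaxResult:
    unmixing: np.ndarray  # W, components x components
    sources: np.ndarray  # S = W X, unit-variance rows, peak positive
    converged: bool
    n_iter: int


def _fix_scale_sign(W: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S = S / sd
    W = W / sd
    peak = S[np.arange(S.shape[0]), np.argmax(np.abs(S), axis=1)]
    sign = np.where(peak < 0, -1.0, 1.0)[:, None]
    return W * sign, S * sign


def infomax_ica(
    X: np.ndarray,
    seed: int = 0,
    lr: float | None = None,
    max_iter: int = 512,
    tol: float = 1e-6,
    block: int | None = None,
    anneal: float = 0.90,
    extended: bool = True,
) -> InfomaxResult:
    """Natural-gradient Infomax ICA.

    ``X`` must be whitened (n x samples).  By default the sign-adaptive
    (extended) form is used, which estimates per-component source kurtosis
    signs and therefore separates sub-Gaussian as well as super-Gaussian
    sources; ``extended=False`` selects the classic logistic-nonlinearity
    update (super-Gaussian prior), which is what sparse fMRI spatial maps
    need.  The learning rate anneals by ``anneal`` when the update
    direction turns sharply between passes; iteration stops when the
    relative weight-change norm
    drops below ``tol``.  Non-convergence is flagged on the result, not
    raised.  Source rows are scaled to unit variance with the
    maximum-magnitude sample positive.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(seed)
    if lr is None:
        lr = 0.01 / np.log(max(n, 3))
    if block is None:
        # moderately large blocks: enough averaging for a stable natural
        # gradient, small enough to escape shallow local optima
        block = int(np.clip(m // 16, 64, 1024))
    W = np.eye(n) + 0.01 * rng.standard_normal((n, n))
    I = np.eye(n)
    signs = np.ones(n)  # +1 super-Gaussian, -1 sub-Gaussian
    prev_step: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        perm = rng.permutation(m)
        W_old = W.copy()
        if extended:
            # kurtosis-sign estimate on the full pass (Lee et al. switching)
            U = W @ X
            k = np.mean(1.0 / np.cosh(U) ** 2, axis=1) * np.mean(
                U**2, axis=1
            ) - np.mean(U * np.tanh(U), axis=1)
            signs = np.where(k >= 0, 1.0, -1.0)
        for start in range(0, m - block + 1, block):
            xb = X[:, perm[start : start + block]]
            u = W @ xb
            if extended:
                grad = I - (signs[:, None] * np.tanh(u)) @ u.T / xb.shape[1] - (
                    u @ u.T
                ) / xb.shape[1]
            else:
                y = 1.0 / (1.0 + np.exp(-u))
                grad = I + (1.0 - 2.0 * y) @ u.T / xb.shape[1]
            W = W + lr * (grad @ W)
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                # blow-up: restart from identity with a smaller rate
                lr *= 0.5
                W = np.eye(n) + 0.01 * rng.standard_normal((n, n))
                break
        step = W - W_old
        delta = np.linalg.norm(step) / max(np.linalg.norm(W_old), 1e-12)
        if delta < tol:
            converged = True
            break
        # anneal only when the update direction turns sharply (> 60 deg),
        # the classic runica schedule; stochastic fluctuation alone must
        # not collapse the learning rate
        if prev_step is not None:
            denom = np.linalg.norm(step) * np.linalg.norm(prev_step)
            if denom > 0 and (step * prev_step).sum() / denom < 0.5:
                lr *= anneal
        prev_step = step
    if not converged:
        log.warning("infomax did not converge in %d iterations (delta=%.2e)", it, delta)
    S = W @ X
    W, S = _fix_scale_sign(W, S)
    return InfomaxResult(unmixing=W, sources=S, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# ICASSO
# ---------------------------------------------------------------------------

@dataclass
class IcassoResult:
    stability: np.ndarray  # per selected cluster, descending
    centrotypes: np.ndarray  # n x voxels
    best_run: int
    best_run_maps: np.ndarray  # best run's components aligned to centrotypes
    cluster_labels: np.ndarray  # per pooled component
    run_converged: np.ndarray


def icasso(
    X: np.ndarray,
    n_runs: int = 100,
    seed: int = 0,
    bootstrap: bool = False,
    **ica_kwargs,
) -> IcassoResult:
    """Multi-run ICA stability analysis.

    Runs Infomax ``n_runs`` times from distinct initial conditions (and,
    optionally, bootstrap-resampled voxels), pools all components, clusters
    them by ``1 - |spatial correlation|`` with average linkage into as many
    clusters as the model order, and scores each cluster with the
    stability index (mean intra-cluster minus mean extra-cluster
    similarity).  The best run minimizes the summed matched distance of its
    components to the cluster centrotypes.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    pooled = []
    converged = []
    for r in range(n_runs):
        run_seed = child_seed(seed, r)
        if bootstrap:
            rng = np.random.default_rng(child_seed(seed, 10_000 + r))
            Xr = X[:, rng.integers(0, m, size=m)]
        else:
            Xr = X
        res = infomax_ica(Xr, seed=run_seed, **ica_kwargs)
        if bootstrap:
            # express sources on the original voxels
            S = res.unmixing @ X
            _, S = _fix_scale_sign(res.unmixing.copy(), S)
        else:
            S = res.sources
        pooled.append(S)
        converged.append(res.converged)
    pool = np.vstack(pooled)  # (n_runs*n) x voxels
    sim = np.abs(corr_matrix(pool, pool))
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(np.nan_to_num(sim), 0.0, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n, criterion="maxclust") - 1

    stability = np.empty(n)
    centro_idx = np.empty(n, dtype=int)
    for c in range(n):
        members = np.flatnonzero(labels == c)
        others = np.flatnonzero(labels != c)
        block = sim[np.ix_(members, members)]
        if len(members) > 1:
            intra = (block.sum() - len(members)) / (len(members) * (len(members) - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(members, others)].mean() if len(others) else 0.0
        stability[c] = intra - extra
        centro_idx[c] = members[np.argmax(sim[np.ix_(members, members)].sum(axis=1))]

    order = np.argsort(-stability)
    stability = stability[order]
    centrotypes = pool[centro_idx[order]]

    # best run: Hungarian match of each run's components to the centrotypes
    best_run, best_cost, best_aligned = 0, np.inf, None
    for r in range(n_runs):
        rows = slice(r * n, (r + 1) * n)
        d = 1.0 - np.abs(corr_matrix(centrotypes, pool[rows]))
        ri, ci = linear_sum_assignment(np.nan_to_num(d, nan=1.0))
        cost = d[ri, ci].sum()
        if cost < best_cost:
            best_cost = cost
            best_run = r
            aligned = pool[rows][ci[np.argsort(ri)]]
            # orient to the centrotypes
            signs = np.sign(
                np.sum(centrotypes * aligned, axis=1, keepdims=True)
            )
            signs[signs == 0] = 1.0
            best_aligned = aligned * signs
    return IcassoResult(
        stability=stability,
        centrotypes=centrotypes,
        best_run=best_run,
        best_run_maps=best_aligned,
        cluster_labels=labels,
        run_converged=np.asarray(converged),
    )


# ---------------------------------------------------------------------------
# Back-reconstruction
# ---------------------------------------------------------------------------

def back_reconstruct(
    ds: MaskedDataset | np.ndarray, group_maps: np.ndarray
) -> np.ndarray:
    """Subject time courses by spatial multiple regression.

    At each time point the subject volume is regressed on all group maps
    jointly; the OLS coefficients are the component time-course values.
    Returns a time x components matrix.
    """
    data = ds.data if isinstance(ds, MaskedDataset) else np.asarray(ds, dtype=float)
    A = np.asarray(group_maps, dtype=float).T  # voxels x components
    if A.shape[0] != data.shape[0]:
        raise ValueError("group maps and data have different voxel counts")
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] <= s[0] * 1e-10:
        c = np.abs(corr_matrix(group_maps, group_maps))
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        raise ValueError(
            f"group maps rank deficient; most collinear pair: ({i}, {j}) "
            f"with |r| = {c[i, j]:.3f}"
        )
    tc, *_ = np.linalg.lstsq(A, data, rcond=None)
    return tc.T


def subject_maps(data: np.ndarray, timecourses: np.ndarray) -> np.ndarray:
    """Subject spatial maps: regression of voxel data on the time courses."""
    B, *_ = np.linalg.lstsq(timecourses, np.asarray(data, dtype=float).T, rcond=None)
    return B


# ---------------------------------------------------------------------------
# Multi-order driver
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    """Group ICA result at one model order."""

    model_order: int
    group_maps: np.ndarray  # components x voxels (best run, centrotype-aligned)
    stability: np.ndarray  # per component
    best_run: int
    subject_timecourses: list[np.ndarray] = field(default_factory=list)  # time x comp
    subject_maps: list[np.ndarray] = field(default_factory=list)  # comp x voxels
    subject_ids: list[str] = field(default_factory=list)
    tr_seconds: float = 2.0


def run_multiscale(
    datasets: list[MaskedDataset],
    orders: list[int] = (25, 50, 75, 100),
    n_runs: int = 100,
    var_retained: float = 0.9999,
    seed: int = 0,
    zscore: bool = True,
    compute_subject_maps: bool = True,
    **ica_kwargs,
) -> dict[int, Decomposition]:
    """Run the full group-ICA chain independently at every model order.

    Subject PCA is shared across orders; each order then gets its own group
    PCA, ICASSO-aggregated Infomax, and back-reconstruction.  Deterministic
    under the master ``seed`` (per-order seeds are derived from it).
    """
    orders = list(orders)
    if len(set(orders)) != len(orders) or any(o <= 0 for o in orders):
        raise ValueError("orders must be distinct positive integers")
    prepared = [ds.zscore() if zscore else ds for ds in datasets]
    whitened = [subject_pca(ds, var_retained)[0] for ds in prepared]
    out: dict[int, Decomposition] = {}
    for oi, order in enumerate(orders):
        try:
            G = group_pca(whitened, order)
            ic = icasso(G, n_runs=n_runs, seed=child_seed(seed, oi), **ica_kwargs)
            maps = ic.best_run_maps
            dec = Decomposition(
                model_order=order,
                group_maps=maps,
                stability=ic.stability,
                best_run=ic.best_run,
                tr_seconds=datasets[0].tr_seconds,
            )
            for ds, prep in zip(datasets, prepared):
                tc = back_reconstruct(prep, maps)
                dec.subject_timecourses.append(tc)
                if compute_subject_maps:
                    dec.subject_maps.append(subject_maps(prep.data, tc))
                dec.subject_ids.append(ds.subject_id)
            out[order] = dec
        except Exception as exc:
            raise RuntimeError(f"model order {order} failed: {exc}") from exc
    return out
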