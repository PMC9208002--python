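"""Dynamic connectivity states from windowed-FNC series.

States are recurring windowed-FNC patterns found by k-means.  The primary
procedure is two-stage: per-subject exemplar windows (local maxima of the
across-pair variance) are clustered first, and the resulting centroids
initialize a single full pass over all windows.  City-block distance with
a component-wise median centroid update is the default, following the
usual practice for high-dimensional connectivity vectors; Euclidean and
correlation distances and two alternative strategies (subject-level
clustering first, or direct clustering of all windows) are available as
robustness checks.  The number of states is chosen with the elbow
criterion on the within/between cluster-variance ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._utils import child_seed
from .fnc import WindowedFncSeries

log = logging.getLogger(__name__)

STRATEGIES = ("exemplar_two_stage", "subject_then_group", "direct")
DISTANCES = ("cityblock", "euclidean", "correlation")


# ---------------------------------------------------------------------------
# Exemplars
# ---------------------------------------------------------------------------

def exemplar_indices(windows: np.ndarray) -> np.ndarray:
    """Indices of windows at strict local maxima of the across-pair
    variance (endpoints excluded)."""
    var = windows.var(axis=1)
    if len(var) < 3:
        raise ValueError("need at least 3 windows")
    interior = np.arange(1, len(var) - 1)
    hits = interior[(var[1:-1] > var[:-2]) & (var[1:-1] > var[2:])]
    return hits


def select_exemplars(series: WindowedFncSeries) -> np.ndarray:
    """Exemplar windows for one subject; falls back to the first window
    (with a warning) when the variance profile has no interior maximum."""
    idx = exemplar_indices(series.windows)
    idx = idx[series.valid[idx]] if len(idx) else idx
    if len(idx) == 0:
        warnings.warn(
            f"subject {series.subject_id}: no local variance maxima; "
            "falling back to the first window",
            stacklevel=2,
        )
        idx = np.array([0])
    return series.windows[idx]


# ---------------------------------------------------------------------------
# k-means with pluggable distance
# ---------------------------------------------------------------------------

def _distances(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, C, metric=metric)


def _update(X: np.ndarray, labels: np.ndarray, k: int, metric: str,
            old: np.ndarray) -> np.ndarray:
    C = old.copy()
    for c in range(k):
        members = X[labels == c]
        if len(members) == 0:
            continue
        C[c] = np.median(members, axis=0) if metric == "cityblock" else members.mean(axis=0)
    return C


def _kmeanspp(X: np.ndarray, k: int, metric: str, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d = _distances(X, np.asarray(centroids), metric).min(axis=1) ** 2
        tot = d.sum()
        if tot == 0:
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d / tot)])
    return np.asarray(centroids)


def kmeans_custom(
    X: np.ndarray,
    k: int,
    distance: str = "cityblock",
    n_rep: int = 100,
    seed: int = 0,
    max_iter: int = 200,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means with k-means++ seeding and a configurable distance.

    The centroid update is the component-wise median for city-block
    distance (the within-cluster optimizer for L1) and the mean otherwise;
    for correlation distance rows are standardized once up front.  Empty
    clusters are re-seeded at the point farthest from its centroid.  The
    best of ``n_rep`` replicates by total assignment distance is returned
    as ``(centroids, labels, objective)``.  Passing ``init`` skips seeding
    and runs a single replicate from the given centroids.
    """
    X = np.asarray(X, dtype=float)
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} samples")
    if distance == "correlation":
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("correlation distance undefined for constant rows")
    best = (None, None, np.inf)
    reps = 1 if init is not None else n_rep
    for rep in range(reps):
        rng = np.random.default_rng(child_seed(seed, rep))
        C = np.asarray(init, dtype=float) if init is not None else _kmeanspp(X, k, distance, rng)
        labels = np.full(X.shape[0], -1)
        obj = np.inf
        for _ in range(max_iter):
            D = _distances(X, C, distance)
            new_labels = D.argmin(axis=1)
            # re-seed empty clusters at the farthest point
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(D[np.arange(len(new_labels)), new_labels].argmax())
                    C[c] = X[far]
                    new_labels[far] = c
            new_obj = _distances(X, C, distance)[
                np.arange(len(new_labels)), new_labels
            ].sum()
            if np.array_equal(new_labels, labels) or new_obj >= obj - 1e-12:
                labels, obj = new_labels, min(obj, new_obj)
                break
            labels, obj = new_labels, new_obj
            C = _update(X, labels, k, distance, C)
        if obj < best[2]:
            best = (C.copy(), labels.copy(), float(obj))
    return best


# ---------------------------------------------------------------------------
# Elbow criterion
# ---------------------------------------------------------------------------

@dataclass
class ElbowResult:
    k: int
    k_range: np.ndarray
    ratio: np.ndarray  # within/between variance ratio per k (inf for k=1)
    low_confidence: bool


def cluster_variance_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Within- over between-cluster sum of squared (Euclidean) deviations
    about the cluster means / grand mean."""
    X = np.asarray(X, dtype=float)
    grand = X.mean(axis=0)
    wss = 0.0
    bss = 0.0
    for c in np.unique(labels):
        members = X[labels == c]
        mu = members.mean(axis=0)
        wss += ((members - mu) ** 2).sum()
        bss += len(members) * ((mu - grand) ** 2).sum()
    if bss == 0:
        return np.inf
    return wss / bss


def elbow_k(
    X: np.ndarray,
    k_range: range = range(1, 16),
    distance: str = "cityblock",
    seed: int = 0,
    n_rep: int = 10,
    sharpness_floor: float = 0.5,
) -> ElbowResult:
    """Pick the number of states at the knee of the within/between
    variance-ratio curve.

    The ratio at k = 1 is infinite (no between-cluster variance) and is
    excluded.  The knee is the point of maximum deviation below the chord
    joining the first and last finite curve points, computed on the log
    ratio — the log scale makes the transition to the flat regime (the
    elbow) dominate, instead of the largest absolute drop.  Knee sharpness
    (deviation divided by the total log-curve drop) below
    ``sharpness_floor`` means the curve has no pronounced bend; the result
    then falls back to k = 2 and is flagged low-confidence.
    """
    ks = np.asarray(list(k_range))
    if ks.max() > X.shape[0]:
        raise ValueError("k range exceeds the number of samples")
    ratios = np.empty(len(ks))
    for i, k in enumerate(ks):
        if k == 1:
            ratios[i] = np.inf
            continue
        _, labels, _ = kmeans_custom(
            X, int(k), distance=distance, n_rep=n_rep, seed=child_seed(seed, int(k))
        )
        ratios[i] = cluster_variance_ratio(X, labels)
    finite = np.flatnonzero(np.isfinite(ratios))
    if len(finite) < 3:
        return ElbowResult(2, ks, ratios, True)
    logr = np.log(np.maximum(ratios[finite], 1e-12))
    i0, i1 = finite[0], finite[-1]
    drop = logr[0] - logr[-1]
    if drop <= 0:
        return ElbowResult(2, ks, ratios, True)
    # signed vertical deviation below the chord, on the log curve
    chord = logr[0] + (logr[-1] - logr[0]) * (
        (ks[finite] - ks[i0]) / (ks[i1] - ks[i0])
    )
    deviation = chord - logr
    jbest = int(np.argmax(deviation))
    sharpness = deviation[jbest] / drop
    if sharpness < sharpness_floor:
        return ElbowResult(2, ks, ratios, True)
    return ElbowResult(int(ks[finite][jbest]), ks, ratios, False)


# ---------------------------------------------------------------------------
# State model
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """Fitted dynamic-connectivity states.

    ``subject_state_means[s][k]`` is subject s's average windowed FNC in
    state k, or ``None`` when the subject never visits the state (absent,
    not imputed).  ``poc`` is the percentage of all windows assigned to
    each state and sums to 100.
    """

    k: int
    centroids: np.ndarray  # k x pairs
    assignments: list[np.ndarray]  # per subject, per window
    subject_state_means: list[list[np.ndarray | None]]
    poc: np.ndarray
    strategy: str
    distance: str
    subject_ids: list[str]


def fit_states(
    all_series: list[WindowedFncSeries],
    k: int,
    strategy: str = "exemplar_two_stage",
    distance: str = "cityblock",
    seed: int = 0,
    n_rep: int = 100,
) -> StateModel:
    """Identify k dynamic states over all subjects' windowed FNC.

    Strategies: ``exemplar_two_stage`` clusters per-subject exemplar
    windows, then runs one full k-means pass over all windows initialized
    at those centroids; ``subject_then_group`` clusters each subject,
    concatenates subject centroids, clusters those, then assigns all
    windows; ``direct`` clusters all windows outright.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    stacked = np.vstack([s.windows[s.valid] for s in all_series])
    counts = [int(s.valid.sum()) for s in all_series]

    if strategy == "exemplar_two_stage":
        exemplars = np.vstack([select_exemplars(s) for s in all_series])
        C0, _, _ = kmeans_custom(
            exemplars, k, distance=distance, n_rep=n_rep, seed=child_seed(seed, 1)
        )
        centroids, labels_all, _ = kmeans_custom(
            stacked, k, distance=distance, seed=child_seed(seed, 2), init=C0
        )
    elif strategy == "subject_then_group":
        sub_centroids = []
        for i, s in enumerate(all_series):
            kk = min(k, int(s.valid.sum()))
            C, _, _ = kmeans_custom(
                s.windows[s.valid], kk, distance=distance,
                n_rep=max(5, n_rep // 10), seed=child_seed(seed, 100 + i),
            )
            sub_centroids.append(C)
        pool = np.vstack(sub_centroids)
        centroids, _, _ = kmeans_custom(
            pool, k, distance=distance, n_rep=n_rep, seed=child_seed(seed, 3)
        )
        labels_all = _distances(stacked, centroids, distance).argmin(axis=1)
    else:  # direct
        centroids, labels_all, _ = kmeans_custom(
            stacked, k, distance=distance, n_rep=n_rep, seed=child_seed(seed, 4)
        )

    assignments = []
    state_means: list[list[np.ndarray | None]] = []
    pos = 0
    for s, c in zip(all_series, counts):
        lab = labels_all[pos : pos + c]
        pos += c
        assignments.append(lab)
        means: list[np.ndarray | None] = []
        w = s.windows[s.valid]
        for st in range(k):
            means.append(w[lab == st].mean(axis=0) if np.any(lab == st) else None)
        state_means.append(means)
    poc = np.array(
        [100.0 * np.mean(labels_all == st) for st in range(k)]
    )
    return StateModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        subject_state_means=state_means,
        poc=poc,
        strategy=strategy,
        distance=distance,
        subject_ids=[s.subject_id for s in all_series],
    )
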