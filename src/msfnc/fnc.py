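"""Static and dynamic functional network connectivity (FNC).

FNC is the Pearson correlation between ICN time courses.  Static FNC uses
the whole scan; dynamic FNC slides a tapered window (rectangle convolved
with a Gaussian) across the scan at a one-sample step and computes a
weighted correlation matrix per window.  All ICNs from all model orders
enter a single P x P structure, so within- and between-scale pairs are
treated identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import vec_upper, unvec_upper


@dataclass
class FncMatrix:
    """Symmetric P x P correlation matrix over the ordered ICN set."""

    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FNC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FNC matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def vectorized(self) -> np.ndarray:
        return vec_upper(self.values)


def static_fnc(tcs: np.ndarray, labels: list[str] | None = None) -> FncMatrix:
    """Full-scan Pearson correlation between all ICN pairs."""
    tcs = np.asarray(tcs, dtype=float)
    if tcs.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = tcs.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant time course for ICN index {bad.tolist()}")
    c = np.corrcoef(tcs.T)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return FncMatrix(c, labels)


# ---------------------------------------------------------------------------
# Tapered window
# ---------------------------------------------------------------------------

@dataclass
class TaperWindow:
    """Tapered sliding window: rectangle convolved with a Gaussian.

    ``weights`` has length ``rect_len + 2 * half``; index ``half`` aligns
    with the first rectangle sample.  With TR = 2 s the canonical window is
    a 22-sample rectangle (44 s) tapered by a sigma = 3 sample (6 s)
    Gaussian, sliding at a 1-sample (2 s) step.
    """

    weights: np.ndarray
    rect_len: int
    sigma_samples: float
    half: int
    step: int = 1


def make_taper(
    tr_seconds: float, rect_seconds: float = 44.0, sigma_seconds: float = 6.0
) -> TaperWindow:
    """Build the tapered window for a given TR.

    The Gaussian kernel is truncated at +-3 sigma and renormalized to unit
    sum, so the taper weights sum to ``rect_len`` exactly (convolution with
    a unit-sum kernel preserves the sum).
    """
    ratio = rect_seconds / tr_seconds
    rect_len = int(round(ratio))
    if abs(ratio - rect_len) > 1e-9:
        warnings.warn(
            f"window of {rect_seconds} s is not an integer number of TRs "
            f"({tr_seconds} s); rounding to {rect_len} samples",
            stacklevel=2,
        )
    if rect_len < 1:
        raise ValueError("window shorter than one TR")
    sigma = sigma_seconds / tr_seconds
    if sigma <= 0:
        warnings.warn("sigma <= 0; returning an untapered rectangle", stacklevel=2)
        return TaperWindow(
            weights=np.ones(rect_len), rect_len=rect_len, sigma_samples=0.0, half=0
        )
    half = int(np.ceil(3.0 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    weights = np.convolve(np.ones(rect_len), kernel, mode="full")
    return TaperWindow(
        weights=weights, rect_len=rect_len, sigma_samples=sigma, half=half
    )


# ---------------------------------------------------------------------------
# Windowed FNC
# ---------------------------------------------------------------------------

@dataclass
class WindowedFncSeries:
    """Time-ordered vectorized windowed-FNC matrices for one subject."""

    subject_id: str
    windows: np.ndarray  # W x P*(P-1)/2
    onsets: np.ndarray  # rectangle-start sample indices
    n_components: int
    valid: np.ndarray  # per-window flag (False: zero-variance window)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def matrix(self, w: int) -> np.ndarray:
        return unvec_upper(self.windows[w], self.n_components)


def _weighted_corr(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Weighted Pearson correlation of columns of X; weights sum to 1."""
    m = w @ X
    Xc = X - m
    cov = (Xc * w[:, None]).T @ Xc
    var = np.diag(cov).copy()
    ok = bool(np.all(var > 1e-14))
    var[var <= 1e-14] = np.nan
    d = np.sqrt(var)
    c = cov / np.outer(d, d)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c, ok


def windowed_fnc(
    tcs: np.ndarray, taper: TaperWindow, subject_id: str = ""
) -> WindowedFncSeries:
    """Tapered sliding-window FNC series.

    The rectangle slides one sample at a time over the scan, giving
    ``W = T - rect_len`` windows; the Gaussian-tapered tails extend past
    the rectangle and are truncated (and the weights renormalized) at the
    scan edges.  Windows with a zero weighted variance are flagged invalid
    and excluded downstream.
    """
    tcs = np.asarray(tcs, dtype=float)
    T, P = tcs.shape
    n_win = T - taper.rect_len
    if n_win < 1:
        raise ValueError(f"scan of {T} samples shorter than the window support")
    iu = np.triu_indices(P, k=1)
    out = np.empty((n_win, len(iu[0])))
    valid = np.ones(n_win, dtype=bool)
    onsets = np.arange(n_win)
    for wdx, onset in enumerate(onsets):
        start = onset - taper.half
        stop = onset + taper.rect_len + taper.half
        w_lo = max(0, -start)
        w_hi = len(taper.weights) - max(0, stop - T)
        sl = slice(max(0, start), min(T, stop))
        w = taper.weights[w_lo:w_hi]
        w = w / w.sum()
        c, ok = _weighted_corr(tcs[sl], w)
        out[wdx] = c[iu]
        valid[wdx] = ok
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} windows with zero variance flagged invalid",
            stacklevel=2,
        )
        out = np.nan_to_num(out)
    return WindowedFncSeries(
        subject_id=subject_id, windows=out, onsets=onsets, n_components=P, valid=valid
    )


def window_count(T: int, taper: TaperWindow) -> int:
    """Number of windows a scan of length ``T`` yields (W = T - rect_len)."""
    return T - taper.rect_len


def pooled_window_count(lengths: list[int], taper: TaperWindow) -> int:
    """Total windowed-FNC matrices pooled over subjects."""
    return sum(window_count(T, taper) for T in lengths)
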