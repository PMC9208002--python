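"""Post-hoc cleaning of ICN time courses before connectivity estimation.

Cleaning order is fixed: polynomial detrending (up to cubic), regression of
the six rigid-body motion parameters plus their first derivatives, MAD
despiking with cubic-spline replacement, and a fifth-order Butterworth
band-pass (0.01-0.15 Hz) applied forward-backward for zero phase.  Time
courses acquired at a different sampling rate are cubic-spline interpolated
onto a common TR before windowed connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

log = logging.getLogger(__name__)


@dataclass
class CleanConfig:
    """Parameters of the cleaning pipeline.

    ``band`` must lie strictly inside (0, Nyquist) at the target TR; the
    MAD threshold is in robust-sigma units (1.4826 x MAD).
    """

    detrend_order: int = 3
    motion_regression: bool = True
    mad_threshold: float = 4.0
    spline_order: int = 3
    band: tuple[float, float] = (0.01, 0.15)
    filter_order: int = 5
    target_tr: float = 2.0

    def __post_init__(self) -> None:
        low, high = self.band
        nyq = 0.5 / self.target_tr
        if not (0.0 < low < high < nyq):
            raise ValueError(f"band {self.band} must lie inside (0, {nyq}) Hz")
        if self.spline_order != 3:
            raise ValueError("only cubic spline replacement is supported")


def detrend_poly(tc: np.ndarray, order: int = 3) -> np.ndarray:
    """Remove polynomial trends up to ``order`` (mean included) by OLS
    projection.  Works on 1-D series or time x components matrices."""
    tc = np.asarray(tc, dtype=float)
    n = tc.shape[0]
    if n <= order + 1:
        raise ValueError(f"series of length {n} too short for order-{order} detrend")
    t = np.linspace(-1.0, 1.0, n)
    basis = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    return tc - q @ (q.T @ tc)


def regress_nuisance(tc: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """Regress out the six motion parameters and their first differences.

    The derivative is a backward difference with the first sample zero, so
    length is preserved.  Near-collinear regressors are dropped with a
    warning rather than failing.
    """
    tc = np.asarray(tc, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != tc.shape[0]:
        raise ValueError("time course and motion have different lengths")
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    X = np.column_stack([np.ones(tc.shape[0]), motion, deriv])
    # drop collinear columns (keep earliest)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} collinear nuisance regressors",
            stacklevel=2,
        )
        X = X[:, keep]
        q, _ = np.linalg.qr(X)
    return tc - q @ (q.T @ tc)


def despike(
    tc: np.ndarray, mad_threshold: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """MAD-based outlier replacement with a cubic spline.

    Samples with ``|x - median| > mad_threshold * 1.4826 * MAD`` are
    flagged and replaced by a cubic spline fitted through the clean
    samples.  A zero MAD (constant stretches) is floored at a small
    fraction of the data scale so isolated spikes are still caught.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1:
        raise ValueError("despike operates on a single time course")
    med = np.median(tc)
    mad = np.median(np.abs(tc - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = 1e-6 * max(np.abs(tc).max(), 1.0)
    mask = np.abs(tc - med) > mad_threshold * scale
    if mask.sum() > 0.5 * len(tc):
        raise ValueError(f"{mask.sum()} of {len(tc)} samples flagged; signal unusable")
    if (~mask).sum() < 8:
        raise ValueError("fewer than 8 clean samples")
    if not mask.any():
        return tc.copy(), mask
    t = np.arange(len(tc), dtype=float)
    spline = CubicSpline(t[~mask], tc[~mask])
    out = tc.copy()
    out[mask] = spline(t[mask])
    return out, mask


def bandpass(
    tc: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.15),
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward application)."""
    tc = np.asarray(tc, dtype=float)
    nyq = 0.5 / tr_seconds
    low, high = band
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band {band} outside (0, {nyq:.4f}) Hz at TR {tr_seconds}")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, tc, axis=0)


def resample_to_tr(
    tc: np.ndarray, src_tr: float, target_tr: float = 2.0
) -> np.ndarray:
    """Cubic-spline interpolation onto a grid with spacing ``target_tr``
    over the same time span; no-op when the TRs already match."""
    if src_tr <= 0:
        raise ValueError("src_tr must be positive")
    tc = np.asarray(tc, dtype=float)
    if src_tr == target_tr:
        return tc.copy()
    n = tc.shape[0]
    t_src = np.arange(n) * src_tr
    t_new = np.arange(0.0, t_src[-1] + 1e-9, target_tr)
    return CubicSpline(t_src, tc, axis=0)(t_new)


def clean_timecourses(
    tcs: np.ndarray,
    tr_seconds: float,
    motion: np.ndarray | None = None,
    config: CleanConfig | None = None,
) -> np.ndarray:
    """Full cleaning chain on a time x components matrix.

    Order: detrend -> motion regression -> despike -> band-pass ->
    resample to the target TR (only if it differs).
    """
    config = config or CleanConfig()
    out = detrend_poly(np.asarray(tcs, dtype=float), config.detrend_order)
    if config.motion_regression and motion is not None:
        out = regress_nuisance(out, motion)
    for j in range(out.shape[1] if out.ndim == 2 else 1):
        col = out[:, j] if out.ndim == 2 else out
        cleaned, mask = despike(col, config.mad_threshold)
        if mask.any():
            log.info("despiked %d samples in component %d", int(mask.sum()), j)
        if out.ndim == 2:
            out[:, j] = cleaned
        else:
            out = cleaned
    out = bandpass(out, tr_seconds, config.band, config.filter_order)
    if tr_seconds != config.target_tr:
        out = resample_to_tr(out, tr_seconds, config.target_tr)
    return out
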