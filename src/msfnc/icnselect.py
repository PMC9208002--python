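"""Selection of intrinsic connectivity networks from ICA components.

A component is kept as an ICN when it is stable across ICA runs
(stability index > 0.8) and looks like a resting-state network: its time
course is dominated by low-frequency power (dynamic range and
low-to-high-frequency power ratio), its above-threshold voxels fall in
gray matter, and it has low spatial similarity with known artifact
patterns.  Functional-domain labels (CC, CR, DM, SB, SM, TP, VS) come
from user-supplied rules — explicit (order, component) labels or template
matching — since domain assignment is expert knowledge, not an algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sig

from ._utils import corr_matrix
from .decompose import Decomposition

log = logging.getLogger(__name__)

DOMAINS = ("CC", "CR", "DM", "SB", "SM", "TP", "VS")


@dataclass
class IcnThresholds:
    """Selection criteria.  Only the stability bar (0.8) is canonical; the
    spatial/spectral cutoffs encode common practice and are configurable."""

    stability: float = 0.8
    gm_overlap: float = 0.5
    artifact_similarity: float = 0.5
    freq_ratio: float = 2.0


# ---------------------------------------------------------------------------
# Per-component scores
# ---------------------------------------------------------------------------

def spectrum_features(
    tc: np.ndarray,
    tr_seconds: float,
    low_band: tuple[float, float] = (0.01, 0.10),
    high_low_edge: float = 0.15,
) -> tuple[float, float]:
    """Spectral low-frequency dominance features of one time course.

    The power spectrum is the mean of windowed periodograms (Welch).
    ``dynamic_range`` is the drop from the spectral peak to the lowest
    power at frequencies above the peak; ``freq_ratio`` is integrated
    power in the low band divided by integrated power between
    ``high_low_edge`` and Nyquist.
    """
    tc = np.asarray(tc, dtype=float)
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if tc.size < 64:
        raise ValueError("need at least 64 samples for spectral features")
    if tc.std() == 0:
        raise ValueError("constant time course has no spectrum")
    fs = 1.0 / tr_seconds
    nper = min(128, tc.size)
    f, p = sig.welch(tc, fs=fs, nperseg=nper)
    peak = int(np.argmax(p))
    dynamic_range = float(p[peak] - p[peak:].min())
    lo = (f >= low_band[0]) & (f <= low_band[1])
    hi = f >= high_low_edge
    if not lo.any() or not hi.any():
        raise ValueError("frequency bands empty at this TR/length")
    low_power = np.trapezoid(p[lo], f[lo])
    high_power = np.trapezoid(p[hi], f[hi])
    freq_ratio = float(low_power / max(high_power, 1e-300))
    return dynamic_range, freq_ratio


def spatial_scores(
    component_map: np.ndarray,
    gm_mask: np.ndarray | None,
    artifact_maps: np.ndarray | None,
    z_threshold: float = 1.96,
) -> tuple[float, float]:
    """Gray-matter overlap and artifact similarity of one spatial map.

    The map is z-scaled; ``gm_overlap`` is the fraction of
    ``|Z| > z_threshold`` voxels inside the gray-matter mask (0 when no
    voxel survives), ``artifact_similarity`` the maximum absolute
    correlation with the artifact templates (0 when none given).
    """
    m = np.asarray(component_map, dtype=float)
    gm_overlap = 1.0
    if gm_mask is not None:
        gm = np.asarray(gm_mask).astype(bool).ravel()
        if gm.shape != m.shape:
            raise ValueError("component map and gray-matter mask size mismatch")
        z = (m - m.mean()) / m.std()
        supra = np.abs(z) > z_threshold
        gm_overlap = float(supra[gm].sum() / supra.sum()) if supra.any() else 0.0
    artifact_similarity = 0.0
    if artifact_maps is not None and len(artifact_maps):
        am = np.atleast_2d(np.asarray(artifact_maps, dtype=float))
        if am.shape[1] != m.size:
            raise ValueError("artifact templates and map size mismatch")
        artifact_similarity = float(np.nanmax(np.abs(corr_matrix(m[None, :], am))))
    return gm_overlap, artifact_similarity


# ---------------------------------------------------------------------------
# Domain rules
# ---------------------------------------------------------------------------

def assign_domains(
    maps: np.ndarray,
    order: int,
    domain_rules: dict | None,
    min_template_r: float = 0.4,
) -> list[str | None]:
    """Domain label per component.

    ``domain_rules`` is either ``{"labels": {(order, idx): domain}}`` or
    ``{"templates": {domain: map_vector}}`` (matched by maximum absolute
    correlation, requiring ``min_template_r``).  Missing rules yield None.
    """
    n = maps.shape[0]
    out: list[str | None] = [None] * n
    if not domain_rules:
        return out
    labels = domain_rules.get("labels")
    if labels:
        for i in range(n):
            out[i] = labels.get((order, i))
        return out
    templates = domain_rules.get("templates")
    if templates:
        names = list(templates)
        tmpl = np.vstack([templates[d] for d in names])
        r = np.abs(corr_matrix(maps, tmpl))
        for i in range(n):
            j = int(np.argmax(r[i]))
            if r[i, j] >= min_template_r:
                out[i] = names[j]
    return out


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_icns(
    decomps: dict[int, Decomposition],
    gm_mask: np.ndarray | None = None,
    artifact_maps: np.ndarray | None = None,
    domain_rules: dict | None = None,
    thresholds: IcnThresholds | None = None,
    report_only: bool = False,
) -> pd.DataFrame:
    """Score every component of every model order and flag the ICNs.

    Returns the ICN table: one row per (order, component) with stability,
    spectral and spatial scores, the ``is_icn`` flag (conjunction of all
    thresholds; always False in ``report_only`` mode so an analyst can set
    cutoffs afterwards), and the domain label for selected ICNs.  Row
    order — domain-major within order-major — defines the FNC ordering.
    """
    thresholds = thresholds or IcnThresholds()
    rows = []
    for order in sorted(decomps):
        dec = decomps[order]
        tcs = dec.subject_timecourses
        for i in range(dec.model_order):
            dr_vals, fr_vals = [], []
            for tc in tcs:
                dr, fr = spectrum_features(tc[:, i], dec.tr_seconds)
                dr_vals.append(dr)
                fr_vals.append(fr)
            gm, art = spatial_scores(dec.group_maps[i], gm_mask, artifact_maps)
            rows.append(
                {
                    "order": order,
                    "component": i,
                    "stability": float(dec.stability[i]),
                    "dynamic_range": float(np.mean(dr_vals)),
                    "freq_ratio": float(np.mean(fr_vals)),
                    "gm_overlap": gm,
                    "artifact_similarity": art,
                }
            )
    table = pd.DataFrame(rows)
    passed = (
        (table["stability"] > thresholds.stability)
        & (table["gm_overlap"] >= thresholds.gm_overlap)
        & (table["artifact_similarity"] <= thresholds.artifact_similarity)
        & (table["freq_ratio"] >= thresholds.freq_ratio)
    )
    table["is_icn"] = False if report_only else passed
    domains: list[str | None] = [None] * len(table)
    for order in sorted(decomps):
        dec = decomps[order]
        labels = assign_domains(dec.group_maps, order, domain_rules)
        sel = table.index[table["order"] == order]
        for i, ridx in enumerate(sel):
            if table.loc[ridx, "is_icn"]:
                if labels[i] is None:
                    warnings.warn(
                        f"no domain rule for ICN (order {order}, component {i})",
                        stacklevel=2,
                    )
                domains[ridx] = labels[i]
    table["domain"] = domains
    return table


def icn_ordering(table: pd.DataFrame, sort: str = "block") -> pd.DataFrame:
    """Selected ICNs in display order.

    ``"block"`` sorts by functional domain then model order (domain-major);
    ``"finger"`` sorts by model order then domain (order-major).
    """
    icns = table[table["is_icn"]].copy()
    icns["domain"] = icns["domain"].fillna("~none")
    keys = (
        ["domain", "order", "component"]
        if sort == "block"
        else ["order", "domain", "component"]
    )
    if sort not in ("block", "finger"):
        raise ValueError("sort must be 'block' or 'finger'")
    return icns.sort_values(keys).reset_index(drop=True)


def domain_counts(table: pd.DataFrame) -> pd.DataFrame:
    """ICN counts per (order, domain) with row totals — the standard
    summary layout for multi-order ICN selections."""
    icns = table[table["is_icn"]]
    counts = (
        icns.pivot_table(
            index="order", columns="domain", values="component", aggfunc="count"
        )
        .fillna(0)
        .astype(int)
    )
    counts["Total"] = counts.sum(axis=1)
    return counts
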