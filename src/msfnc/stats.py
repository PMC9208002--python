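"""Group-difference statistics for multiscale FNC features.

Diagnosis contrasts are fitted separately in the male and female cohorts
with a GLM controlling for age, acquisition site (reference-coded
dummies), and mean framewise displacement.  Sex-specific differences are
tested by comparing the difference of the two cohorts' diagnosis t-values
against a permutation null that shuffles sex labels *within* each
diagnostic group (group sizes preserved exactly).  All p-values — static
and dynamic features, both cohorts, and the interaction tests — are pooled
into a single Benjamini-Hochberg FDR correction.  Domain-level summaries
average FNC over all ICN pairs within and between (domain x model-order)
blocks, e.g. a 28 x 28 matrix for 7 domains x 4 orders.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._utils import child_seed

log = logging.getLogger(__name__)

REQUIRED_PHENO = ("subject_id", "diagnosis", "sex", "age", "site", "mean_fd")


# ---------------------------------------------------------------------------
# Framewise displacement
# ---------------------------------------------------------------------------

def framewise_displacement(
    motion: np.ndarray, rotation_radius_mm: float | None = None
) -> tuple[np.ndarray, float]:
    """Per-frame head motion: sum of absolute first differences of the six
    rigid-body parameters; fd(0) = 0.

    By default rotations contribute in their native angular units (the
    literal six-term sum); ``rotation_radius_mm`` converts them to arc
    length on a sphere of that radius (commonly 50 mm) first.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be time x 6 with >= 2 time points")
    m = motion.copy()
    if rotation_radius_mm is not None:
        m[:, 3:] *= rotation_radius_mm
    fd = np.zeros(m.shape[0])
    fd[1:] = np.abs(np.diff(m, axis=0)).sum(axis=1)
    return fd, float(fd.mean())


# ---------------------------------------------------------------------------
# GLM diagnosis contrast
# ---------------------------------------------------------------------------

def _design(pheno: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Design matrix [intercept, SZ indicator, age, site dummies, mean_fd];
    returns it with the column index of the diagnosis term."""
    n = len(pheno)
    dx = (pheno["diagnosis"].to_numpy() == "SZ").astype(float)
    cols = [np.ones(n), dx]
    names = ["intercept", "diagnosis"]

    def add_covariate(cname, v):
        if v.std() > 1e-12 * (np.abs(v).mean() + 1.0):
            cols.append(v)
            names.append(cname)
        else:  # constant covariates carry no information
            log.info("covariate %s constant in cohort; dropped", cname)

    add_covariate("age", pheno["age"].to_numpy(dtype=float))
    sites = sorted(pheno["site"].unique())
    for s in sites[1:]:  # reference level: lexicographically first
        add_covariate(f"site_{s}", (pheno["site"].to_numpy() == s).astype(float))
    add_covariate("mean_fd", pheno["mean_fd"].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"collinear design matrix; involved columns: {bad}")
    return X, 1


def glm_contrast(
    features: np.ndarray, pheno: pd.DataFrame, cohort_sex: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Diagnosis t- and two-sided p-values per feature within one sex cohort.

    ``features`` is subjects x F aligned with ``pheno`` rows.  The GLM is
    OLS of each feature on [intercept, diagnosis, age, site dummies,
    mean_fd]; all features share the design, so the fit is vectorized.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != len(pheno):
        raise ValueError("features and phenotype rows do not align")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if cohort_sex is not None:
        keep = (pheno["sex"] == cohort_sex).to_numpy()
        pheno = pheno.loc[keep].reset_index(drop=True)
        features = features[keep]
    counts = pheno["diagnosis"].value_counts()
    if counts.get("CT", 0) < 2 or counts.get("SZ", 0) < 2:
        raise ValueError("need >= 2 subjects per diagnosis in the cohort")
    if pheno["site"].nunique() == 1:
        log.info("single-site cohort; site dummies dropped")
    X, j = _design(pheno)
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ features)
    resid = features - X @ beta
    rss = (resid**2).sum(axis=0)
    dof = n - p
    sigma2 = rss / dof
    scale = np.mean(features**2, axis=0) + 1e-30
    if np.any(sigma2 <= 1e-12 * scale):
        bad = np.flatnonzero(sigma2 <= 1e-12 * scale)
        raise ValueError(f"zero residual variance for features {bad.tolist()}")
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    t = beta[j] / se
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    return t, pvals


# ---------------------------------------------------------------------------
# Sex-permutation null for the t-difference
# ---------------------------------------------------------------------------

def sex_permutation_null(
    features: np.ndarray,
    pheno: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    return_null: bool = False,
):
    """Permutation p-values for sex-specific diagnosis effects.

    The statistic is the difference between the male-cohort and the
    female-cohort diagnosis t-values.  Each permutation shuffles sex
    labels within CT and within SZ separately (sex counts per diagnosis
    are preserved exactly and asserted per draw), recomputes both cohort
    GLMs, and records the null difference.  Two-sided add-one p-values:
    ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pheno = pheno.reset_index(drop=True)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    for dx in ("CT", "SZ"):
        sub = pheno.loc[pheno["diagnosis"] == dx, "sex"]
        if sub.nunique() < 2:
            raise ValueError(f"both sexes must be present in diagnosis {dx}")
    t_m, _ = glm_contrast(features, pheno, "male")
    t_f, _ = glm_contrast(features, pheno, "female")
    obs = t_m - t_f

    base_counts = pheno.groupby(["diagnosis", "sex"]).size()
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, features.shape[1]))
    done = 0
    attempts = 0
    while done < n_perm:
        attempts += 1
        if attempts > 20 * n_perm:
            raise RuntimeError("too many degenerate permutations")
        perm_sex = pheno["sex"].to_numpy().copy()
        for dx in ("CT", "SZ"):
            idx = np.flatnonzero(pheno["diagnosis"].to_numpy() == dx)
            perm_sex[idx] = perm_sex[idx][rng.permutation(len(idx))]
        pp = pheno.copy()
        pp["sex"] = perm_sex
        new_counts = pp.groupby(["diagnosis", "sex"]).size()
        assert new_counts.sort_index().equals(base_counts.sort_index()), (
            "permutation changed group sizes"
        )
        try:
            tm, _ = glm_contrast(features, pp, "male")
            tf, _ = glm_contrast(features, pp, "female")
        except ValueError as exc:
            log.info("redrawing degenerate permutation: %s", exc)
            continue
        null[done] = tm - tf
        done += 1
    p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)) / (n_perm + 1.0)
    if return_null:
        return p, obs, null
    return p, obs


def pooled_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over the pooled p-value vector."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# Domain-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class DomainMatrix:
    """Block-mean FNC over (domain x model order) groups, e.g. 28 x 28."""

    values: np.ndarray  # block means; NaN where a block pair has no ICN pair
    labels: list[str]  # e.g. "CC25", "CR50"


def domain_aggregate(fnc_matrix: np.ndarray, icns: pd.DataFrame) -> DomainMatrix:
    """Average FNC within and between (domain, order) blocks.

    ``icns`` must have one row per ICN in FNC order, with ``domain`` and
    ``order`` columns.  Entry (a, b) is the mean over all ICN pairs with
    one member in block a and the other in block b; within-block entries
    average over distinct pairs only (diagonal excluded) and are NaN for
    singleton blocks.  Block labels are sorted by domain then order.
    """
    fnc_matrix = np.asarray(fnc_matrix, dtype=float)
    if len(icns) != fnc_matrix.shape[0]:
        raise ValueError("ICN table and FNC matrix size mismatch")
    blocks = sorted(
        {(d, int(o)) for d, o in zip(icns["domain"], icns["order"])},
        key=lambda b: (b[0], b[1]),
    )
    labels = [f"{d}{o}" for d, o in blocks]
    members = {
        b: np.flatnonzero((icns["domain"] == b[0]) & (icns["order"] == b[1]))
        for b in blocks
    }
    n = len(blocks)
    out = np.full((n, n), np.nan)
    for a in range(n):
        ia = members[blocks[a]]
        for b in range(a, n):
            ib = members[blocks[b]]
            if a == b:
                if len(ia) > 1:
                    sub = fnc_matrix[np.ix_(ia, ia)]
                    iu = np.triu_indices(len(ia), k=1)
                    out[a, a] = sub[iu].mean()
            else:
                out[a, b] = out[b, a] = fnc_matrix[np.ix_(ia, ib)].mean()
    return DomainMatrix(values=out, labels=labels)


# ---------------------------------------------------------------------------
# Symptom correlation
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def symptom_correlation(
    feature: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    min_n: int = 10,
) -> tuple[float, float, int]:
    """Covariate-adjusted Pearson correlation of a feature with a symptom
    score.

    Both variables are residualized on the covariates (age, site dummies,
    mean FD in the standard pipeline) before correlating; subjects with
    missing scores are dropped pairwise.  Returns ``(r, p, n_used)``.
    """
    feature = np.asarray(feature, dtype=float)
    scores = np.asarray(scores, dtype=float)
    keep = np.isfinite(feature) & np.isfinite(scores)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(feature):
            covariates = covariates.T
        keep &= np.all(np.isfinite(covariates), axis=1)
    n_used = int(keep.sum())
    if n_used < min_n:
        raise ValueError(f"only {n_used} subjects with scores (need >= {min_n})")
    if n_used < len(feature):
        log.info("dropped %d subjects with missing scores", len(feature) - n_used)
    f = feature[keep]
    s = scores[keep]
    if covariates is not None:
        c = covariates[keep]
        f = _residualize(f, c)
        s = _residualize(s, c)
    r, p = sps.pearsonr(f, s)
    return float(r), float(p), n_used


def bprs_to_panss(
    bprs_total: np.ndarray | float, mapping_table: np.ndarray
) -> np.ndarray | float:
    """Convert BPRS total scores to PANSS totals via a monotone lookup
    table with linear interpolation; out-of-range inputs are clamped with
    a warning."""
    table = np.asarray(mapping_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("mapping table must be (bprs, panss) rows")
    b, p = table[:, 0], table[:, 1]
    order = np.argsort(b)
    b, p = b[order], p[order]
    if np.any(np.diff(b) <= 0) or np.any(np.diff(p) < 0):
        raise ValueError("mapping table must be strictly monotone in BPRS")
    x = np.asarray(bprs_total, dtype=float)
    if np.any(x < b[0]) or np.any(x > b[-1]):
        warnings.warn("BPRS values outside the mapping range were clamped",
                      stacklevel=2)
    out = np.interp(x, b, p)
    return float(out) if np.isscalar(bprs_total) else out


# ---------------------------------------------------------------------------
# Contrast table
# ---------------------------------------------------------------------------

def contrast_table(
    feature_sets: dict[str, np.ndarray],
    pheno: pd.DataFrame,
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full sex-specific contrast analysis over named feature sets.

    ``feature_sets`` maps a source name (e.g. ``"sfnc"``, ``"state1"``) to
    a subjects x F matrix.  Per feature: male and female diagnosis
    t-values, their difference, the sex-permutation p-value, and
    significance flags from one pooled BH correction across *all* sources
    and tests (both cohorts' parametric p-values and the permutation
    p-values together).
    """
    rows = []
    pooled_p = []
    for si, (name, feats) in enumerate(feature_sets.items()):
        t_m, p_m = glm_contrast(feats, pheno, "male")
        t_f, p_f = glm_contrast(feats, pheno, "female")
        p_perm, diff = sex_permutation_null(
            feats, pheno, n_perm=n_perm, seed=child_seed(seed, si)
        )
        for j in range(feats.shape[1]):
            rows.append(
                {
                    "source": name,
                    "feature": j,
                    "t_male": t_m[j],
                    "t_female": t_f[j],
                    "p_male": p_m[j],
                    "p_female": p_f[j],
                    "diff_t": diff[j],
                    "p_perm": p_perm[j],
                }
            )
            pooled_p.extend([p_m[j], p_f[j], p_perm[j]])
    table = pd.DataFrame(rows)
    reject = pooled_fdr(np.asarray(pooled_p), q=q)
    table["sig_male"] = reject[0::3]
    table["sig_female"] = reject[1::3]
    table["sig_sex_specific"] = reject[2::3]
    return table
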