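"""Synthetic multiscale resting-state fMRI with known ground truth.

The generator emulates the multiscale premise directly: a set of coarse
blob sources each subdivides into fine sources whose supports lie
mostly, but not exactly, inside the parent (a coarse source is *not* a
simple union of its children).  Rendered voxel data are generated from the
finest-scale maps; the coarse scale enters through parent-shared signal in
the fine-source covariance (:func:`hierarchical_covariance`).  Because
spatial ICA treats maps as sources and time courses as mixing, a low model
order merges sibling sources into their parent-union pattern while a high
order resolves the fine maps — giving exact ground truth at both scales.

Source connectivity switches between a small number of states following a
first-order Markov chain with geometric dwell times; diagnosis x sex cells
of the cohort can receive covariance offsets on chosen source pairs so the
group-difference statistics have planted effects.  Motion enters the data
as a rank-1 spatial pattern times a motion-derived time course, so the
nuisance-regression stage has a true positive to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import spawn_rngs
from .dataset import MaskedDataset

CELLS = [("CT", "male"), ("CT", "female"), ("SZ", "male"), ("SZ", "female")]


# ---------------------------------------------------------------------------
# Source atlas
# ---------------------------------------------------------------------------

@dataclass
class SourceAtlas:
    """Hierarchical spatial sources on a voxel grid.

    ``maps`` holds one voxels x sources matrix per scale, coarse first;
    every map is unit L2 norm with a nonnegative peak.  ``hierarchy`` maps
    each fine source index to its parent coarse source.
    """

    grid_shape: tuple[int, int, int]
    maps: list[np.ndarray]
    hierarchy: np.ndarray  # fine index -> parent coarse index

    @property
    def coarse_maps(self) -> np.ndarray:
        """sources x voxels at the coarse scale."""
        return self.maps[0].T

    @property
    def fine_maps(self) -> np.ndarray:
        """sources x voxels at the finest scale (the generating scale)."""
        return self.maps[-1].T

    @property
    def n_fine(self) -> int:
        return self.maps[-1].shape[1]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def _gaussian_blob(grid_shape, center, sigma) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in grid_shape]
    zz = [(ax - c) ** 2 for ax, c in zip(axes, center)]
    d2 = (
        zz[0][:, None, None] + zz[1][None, :, None] + zz[2][None, None, :]
    )
    blob = np.exp(-d2 / (2.0 * sigma**2))
    flat = blob.ravel()
    return flat / np.linalg.norm(flat)


def _plateau_blob(grid_shape, center, radius, edge_sigma=0.7) -> np.ndarray:
    """Flat-top blob: a ball of ones smoothed at the edge, unit L2 norm.

    Flat-top sources keep their shape under per-voxel variance
    normalization (a monotone pointwise rescaling maps a plateau onto a
    plateau), unlike sharply peaked Gaussians whose peaks saturate.
    """
    from scipy.ndimage import gaussian_filter

    axes = [np.arange(n, dtype=float) for n in grid_shape]
    zz = [(ax - c) ** 2 for ax, c in zip(axes, center)]
    d2 = zz[0][:, None, None] + zz[1][None, :, None] + zz[2][None, None, :]
    ball = (d2 <= radius**2).astype(float)
    sm = gaussian_filter(ball, sigma=edge_sigma, mode="constant")
    flat = sm.ravel()
    return flat / np.linalg.norm(flat)


def _smooth3d(flat: np.ndarray, grid_shape, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    vol = flat.reshape(grid_shape)
    sm = gaussian_filter(vol, sigma=sigma, mode="constant")
    out = sm.ravel()
    return out / np.linalg.norm(out)


def make_hierarchical_sources(
    grid_shape: tuple[int, int, int],
    n_coarse: int,
    split_factor: int,
    seed: int,
    child_radius_frac: float = 0.14,
    child_radius: float | None = None,
    sep_ratio: float = 2.6,
    edge_sigma: float = 0.7,
    smooth_ratio: float = 0.9,
    max_tries: int = 200,
) -> SourceAtlas:
    """Generate hierarchical blob sources: fine flat-top blobs grouped
    under coarse parents.

    For each parent, ``split_factor`` child blobs of radius
    ``child_radius_frac * min(grid)`` are placed ``sep_ratio * radius``
    apart around the parent center (low mutual overlap, so fine-scale ICA
    can separate them).  The parent map is the Gaussian-smoothed union of
    its children, renormalized — a single coarse blob that is highly
    similar to, but not identical with, the union: >= 80% of each child's
    mass lies inside the parent's 10%-of-peak support while >= 10% lies
    outside the parent's half-max contour (a coarse source is not a simple
    split).

    Raises
    ------
    ValueError
        If the grid cannot host ``n_coarse`` sufficiently separated source
        groups.
    """
    if n_coarse < 2:
        raise ValueError("n_coarse must be >= 2")
    if split_factor < 1:
        raise ValueError("split_factor must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    rng = np.random.default_rng(seed)
    r_c = child_radius if child_radius is not None else child_radius_frac * min(grid_shape)
    radius = 0.5 * sep_ratio * r_c  # child center distance from parent center
    blob_margin = r_c + edge_sigma + 0.5  # child blob containment
    min_blob_sep = 2.0 * r_c + 3.0 * edge_sigma  # between blobs of different parents

    # an axis is "free" for dumbbell orientation only if the parent center
    # can move radius away from the blob margin on that side
    lo_child = np.array([blob_margin] * 3)
    hi_child = np.array([g - 1 - blob_margin for g in grid_shape], dtype=float)
    if np.any(hi_child <= lo_child):
        raise ValueError(
            f"grid {grid_shape} too small for blobs of radius {r_c + edge_sigma:.2f}"
        )
    free = (hi_child - lo_child) >= 2.0 * radius
    lo_par = np.where(free, lo_child + radius, (lo_child + hi_child) / 2.0)
    hi_par = np.where(free, hi_child - radius, (lo_child + hi_child) / 2.0)
    if not np.any(free) and split_factor > 1:
        raise ValueError(f"grid {grid_shape} too small to separate sibling sources")

    def _directions() -> np.ndarray:
        v = rng.standard_normal(3) * free  # confine to free axes
        v /= np.linalg.norm(v)
        if split_factor == 2:
            return np.stack([v, -v])
        d = rng.standard_normal((split_factor, 3)) * free
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    last_err: Exception | None = None
    for _ in range(max_tries):
        # greedy max-min placement of parent centers from a candidate pool
        pool = np.column_stack(
            [rng.uniform(l, h, size=256) for l, h in zip(lo_par, hi_par)]
        )
        chosen = [pool[rng.integers(len(pool))]]
        for _ in range(n_coarse - 1):
            d = np.min(
                np.linalg.norm(pool[:, None, :] - np.asarray(chosen)[None, :, :], axis=-1),
                axis=1,
            )
            chosen.append(pool[int(np.argmax(d))])
        centers = np.asarray(chosen)

        fine_cols = []
        coarse_cols = []
        hierarchy = []
        child_centers = []
        for k, c in enumerate(centers):
            if split_factor == 1:
                child = _plateau_blob(grid_shape, c, r_c, edge_sigma)
                fine_cols.append(child)
                child_centers.append((k, c))
                hierarchy.append(k)
                coarse_cols.append(_smooth3d(child, grid_shape, 0.4 * edge_sigma))
                continue
            dirs = _directions()
            children = []
            for j in range(split_factor):
                cc = np.clip(c + radius * dirs[j], lo_child, hi_child)
                children.append(_plateau_blob(grid_shape, cc, r_c, edge_sigma))
                child_centers.append((k, cc))
                hierarchy.append(k)
            fine_cols.extend(children)
            coarse_cols.append(
                _smooth3d(np.sum(children, axis=0), grid_shape, smooth_ratio * r_c)
            )
        # geometric acceptance: blobs of different parents keep their distance
        ok = True
        for a in range(len(child_centers)):
            for b in range(a + 1, len(child_centers)):
                if child_centers[a][0] != child_centers[b][0]:
                    if (
                        np.linalg.norm(child_centers[a][1] - child_centers[b][1])
                        < min_blob_sep
                    ):
                        ok = False
        if not ok:
            continue
        atlas = SourceAtlas(
            grid_shape,
            [np.column_stack(coarse_cols), np.column_stack(fine_cols)],
            np.asarray(hierarchy),
        )
        try:
            _check_atlas(atlas)
            return atlas
        except ValueError as exc:
            last_err = exc
            continue
    raise ValueError(
        f"grid {grid_shape} too small to place {n_coarse} x {split_factor} "
        f"separated sources" + (f" ({last_err})" if last_err else "")
    )


def _check_atlas(atlas: SourceAtlas) -> None:
    coarse, fine = atlas.maps
    hierarchy = atlas.hierarchy
    for scale in atlas.maps:
        c = np.corrcoef(scale.T)
        np.fill_diagonal(c, 0.0)
        if np.abs(c).max() >= 0.5:
            raise ValueError(
                "within-scale source maps too similar "
                f"(max |r| = {np.abs(c).max():.2f}); enlarge the grid"
            )
    for j in range(fine.shape[1]):
        parent = coarse[:, hierarchy[j]]
        child = fine[:, j]
        support10 = parent > 0.10 * parent.max()
        halfmax = parent > 0.5 * parent.max()
        mass = child.sum()
        inside = child[support10].sum() / mass
        outside_hm = child[~halfmax].sum() / mass
        if inside < 0.80:
            raise ValueError(f"fine source {j}: only {inside:.0%} mass inside parent")
        if outside_hm < 0.10:
            raise ValueError(
                f"fine source {j}: only {outside_hm:.0%} mass outside parent half-max"
            )


def union_map(atlas: SourceAtlas, parent: int) -> np.ndarray:
    """Unnormalized sum of the fine maps belonging to one parent."""
    members = np.flatnonzero(atlas.hierarchy == parent)
    return atlas.maps[-1][:, members].sum(axis=1)


# ---------------------------------------------------------------------------
# Connectivity states
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """Ground-truth connectivity states for the fine sources.

    Each state is a source x source covariance with unit diagonal; the state
    sequence is a first-order Markov chain (geometric dwell).  If
    ``transition`` is omitted it is built from ``dwell_mean``: stay
    probability ``1 - 1/dwell_mean``, uniform exits.
    """

    covariances: list[np.ndarray]
    dwell_mean: float = 20.0
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariances = [np.asarray(c, dtype=float) for c in self.covariances]
        for idx, c in enumerate(self.covariances):
            if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"state {idx}: covariance not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-8):
                raise ValueError(f"state {idx}: covariance diagonal must be 1")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError(f"state {idx}: covariance not positive semidefinite")
        k = len(self.covariances)
        if self.transition is None:
            if self.dwell_mean < 1:
                raise ValueError("dwell_mean must be >= 1 TR")
            stay = 1.0 - 1.0 / self.dwell_mean
            if k == 1:
                self.transition = np.ones((1, 1))
            else:
                off = (1.0 - stay) / (k - 1)
                self.transition = np.full((k, k), off)
                np.fill_diagonal(self.transition, stay)
        else:
            self.transition = np.asarray(self.transition, dtype=float)
            if self.transition.shape != (k, k):
                raise ValueError("transition must be K x K")
            if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.covariances)

    @property
    def n_sources(self) -> int:
        return self.covariances[0].shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the state chain."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def hierarchical_covariance(
    hierarchy: np.ndarray, rho: float = 0.6, base: np.ndarray | None = None
) -> np.ndarray:
    """Fine-source covariance with parent-shared signal.

    Siblings (same parent) correlate at ``rho``; different parents are
    uncorrelated unless ``base`` supplies additional structure.  This is the
    construction that makes the coarse scale emerge at low ICA model order.
    """
    hierarchy = np.asarray(hierarchy)
    n = len(hierarchy)
    c = np.where(hierarchy[:, None] == hierarchy[None, :], rho, 0.0)
    np.fill_diagonal(c, 1.0)
    if base is not None:
        c = c + np.asarray(base, dtype=float)
        np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise ValueError("hierarchical covariance not positive semidefinite")
    return c


def perturbed_covariance(
    base: np.ndarray, contrast: float, rng: np.random.Generator
) -> np.ndarray:
    """A distinct state covariance derived from ``base``.

    Mixes the base with a random sign-pattern rank-one correlation matrix
    ``v v^T`` (v in {-1, +1}^n): the result is PSD with unit diagonal by
    construction and differs from the base by about ``contrast`` on
    off-diagonal entries.
    """
    base = np.asarray(base, dtype=float)
    v = rng.choice([-1.0, 1.0], size=base.shape[0])
    return (1.0 - contrast) * base + contrast * np.outer(v, v)


def simulate_state_timecourses(
    states: StateSpec,
    T: int,
    tr_seconds: float = 2.0,
    seed: int = 0,
    atlas: SourceAtlas | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample source time courses under the state-switching covariance model.

    Within each dwell segment, samples are zero-mean multivariate normal
    with that state's covariance.  Returns ``(tc, labels)`` with ``tc`` of
    shape T x sources and one state label per TR.
    """
    if atlas is not None and states.n_sources != atlas.n_fine:
        raise ValueError(
            f"state covariance is {states.n_sources} sources but atlas has "
            f"{atlas.n_fine} fine sources"
        )
    rng = np.random.default_rng(seed)
    k = states.n_states
    labels = np.empty(T, dtype=int)
    labels[0] = rng.choice(k, p=states.stationary())
    for t in range(1, T):
        labels[t] = rng.choice(k, p=states.transition[labels[t - 1]])
    chols = []
    for c in states.covariances:
        # eigenvalue-floored factor: tolerate semidefinite states
        vals, vecs = np.linalg.eigh(c)
        vals = np.clip(vals, 0.0, None)
        chols.append(vecs * np.sqrt(vals))
    z = rng.standard_normal((T, states.n_sources))
    tc = np.empty_like(z)
    for s in range(k):
        idx = labels == s
        tc[idx] = z[idx] @ chols[s].T
    return tc, labels


# ---------------------------------------------------------------------------
# Cohort rendering
# ---------------------------------------------------------------------------

@dataclass
class EffectPair:
    """Planted group effect: covariance offset on one source pair per cell.

    ``offsets`` maps a ``"DX:sex"`` cell key (e.g. ``"SZ:female"``) to the
    additive offset applied to covariance entry ``(i, j)``; ``states`` names
    the states affected (``None`` = all).
    """

    i: int
    j: int
    offsets: dict[str, float]
    states: list[int] | None = None


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults are the desk-scale study conditions used throughout the tests:
    moderate voxel noise relative to the unit-variance source signal and a
    small random-walk head motion coupled into the data as a rank-1
    pattern.
    """

    n_per_cell: int
    effect_pairs: list[EffectPair] = field(default_factory=list)
    noise_sd: float = 0.1
    motion_amp: float = 0.02
    seed: int = 0
    source_amplitude: float = 1.0
    motion_coupling: float = 0.5
    site_names: tuple[str, ...] = ("siteA", "siteB", "siteC")
    site_offset: float = 0.0
    tr_seconds: float = 2.0
    lowpass_hz: float | None = 0.1  # slow source dynamics; None = white

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")


def _lowpass_preserving_scale(tc: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass of each source, rescaled back to unit variance.

    The same filter on every column preserves the zero-lag correlation
    structure in expectation while giving the sources the slow dynamics
    resting-state signals have (so the low-frequency ICN criterion is
    meaningful on simulated data).
    """
    from scipy import signal as sig

    nyq = 0.5 / tr
    sos = sig.butter(4, min(cutoff_hz / nyq, 0.99), btype="lowpass", output="sos")
    out = sig.sosfiltfilt(sos, tc, axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd * tc.std(axis=0)


def _cell_states(states: StateSpec, spec: CohortSpec, cell_key: str) -> StateSpec:
    covs = [c.copy() for c in states.covariances]
    for ep in spec.effect_pairs:
        delta = ep.offsets.get(cell_key, 0.0)
        if delta == 0.0:
            continue
        target = range(len(covs)) if ep.states is None else ep.states
        for s in target:
            covs[s][ep.i, ep.j] += delta
            covs[s][ep.j, ep.i] += delta
    try:
        return StateSpec(covs, dwell_mean=states.dwell_mean, transition=states.transition)
    except ValueError as exc:
        raise ValueError(f"effect offsets for cell {cell_key} break PSD: {exc}") from exc


def render_cohort(
    atlas: SourceAtlas,
    states: StateSpec,
    cohort: CohortSpec,
    T: int,
    tr_seconds: float | None = None,
) -> tuple[list[MaskedDataset], dict]:
    """Render a diagnosis x sex cohort of subjects plus a ground-truth record.

    Each subject's data is ``amplitude * fine_maps @ tc.T`` plus Gaussian
    voxel noise, an optional per-site additive offset, and a rank-1 motion
    nuisance term.  Cells listed in ``cohort.effect_pairs`` receive their
    covariance offsets.  Deterministic under ``cohort.seed``.
    """
    tr = cohort.tr_seconds if tr_seconds is None else tr_seconds
    mask = np.ones(atlas.grid_shape, dtype=bool)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    n_sub = 4 * cohort.n_per_cell
    rngs = spawn_rngs(cohort.seed, n_sub + 1)
    meta_rng = rngs[-1]

    # fixed motion nuisance pattern shared across subjects
    center = np.array(atlas.grid_shape) / 2.0
    motion_pattern = _gaussian_blob(atlas.grid_shape, center, 0.25 * min(atlas.grid_shape))

    maps = atlas.maps[-1]  # voxels x fine sources
    datasets: list[MaskedDataset] = []
    truth_subjects = []
    idx = 0
    for dx, sex in CELLS:
        cell_key = f"{dx}:{sex}"
        cell_states = _cell_states(states, cohort, cell_key)
        for _ in range(cohort.n_per_cell):
            rng = rngs[idx]
            sub_seed = int(rng.integers(2**31))
            tc, labels = simulate_state_timecourses(cell_states, T, tr, seed=sub_seed)
            if cohort.lowpass_hz is not None:
                tc = _lowpass_preserving_scale(tc, tr, cohort.lowpass_hz)
            data = cohort.source_amplitude * (maps @ tc.T)
            motion = np.cumsum(
                rng.normal(0.0, cohort.motion_amp, size=(T, 6)), axis=0
            ) if cohort.motion_amp > 0 else np.zeros((T, 6))
            if cohort.motion_amp > 0 and cohort.motion_coupling != 0:
                m = motion[:, 0]
                msd = m.std()
                if msd > 0:
                    data = data + cohort.motion_coupling * np.outer(
                        motion_pattern, (m - m.mean()) / msd
                    )
            if cohort.noise_sd > 0:
                data = data + rng.normal(0.0, cohort.noise_sd, size=data.shape)
            site = cohort.site_names[idx % len(cohort.site_names)]
            if cohort.site_offset:
                data = data + cohort.site_offset * cohort.site_names.index(site)
            age = float(np.clip(meta_rng.normal(38.0, 12.0), 18.0, 65.0))
            sid = f"sub-{idx:04d}"
            datasets.append(
                MaskedDataset(
                    subject_id=sid,
                    data=data,
                    tr_seconds=tr,
                    mask=mask,
                    affine=affine,
                    motion=motion,
                    site=site,
                    diagnosis=dx,
                    sex=sex,
                    age=age,
                )
            )
            truth_subjects.append(
                {
                    "subject_id": sid,
                    "cell": cell_key,
                    "state_labels": labels,
                    "timecourses": tc,
                    "seed": sub_seed,
                }
            )
            idx += 1
    truth = {
        "atlas": atlas,
        "states": states,
        "cohort": cohort,
        "subjects": truth_subjects,
    }
    return datasets, truth


def phenotype_table(datasets: list[MaskedDataset]) -> pd.DataFrame:
    """Assemble the subject phenotype table (TSV layout) from datasets."""
    rows = [
        {
            "subject_id": ds.subject_id,
            "diagnosis": ds.diagnosis,
            "sex": ds.sex,
            "age": ds.age,
            "site": ds.site,
        }
        for ds in datasets
    ]
    return pd.DataFrame(rows)


def write_cohort(
    datasets: list[MaskedDataset], truth: dict, directory: str | Path
) -> None:
    """Write NIfTI volumes, motion files, phenotype TSV, and a JSON
    ground-truth sidecar (state labels and cell membership)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.write(directory)
    phenotype_table(datasets).to_csv(directory / "phenotype.tsv", sep="\t", index=False)
    sidecar = {
        "seed": truth["cohort"].seed,
        "subjects": [
            {
                "subject_id": s["subject_id"],
                "cell": s["cell"],
                "state_labels": np.asarray(s["state_labels"]).tolist(),
            }
            for s in truth["subjects"]
        ],
    }
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh)
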