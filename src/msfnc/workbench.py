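"""I/O, configuration, and end-to-end orchestration.

A run is driven by a :class:`RunConfig` (YAML-serializable, unknown keys
rejected) and produces a persistent output tree::

    out_dir/
      config.yaml            resolved configuration + master seed
      data/                  simulated NIfTI volumes, motion, phenotype TSV
      decompose/             group maps (4-D NIfTI per order) + stability TSV
                             + per-subject time-course TSVs
      icn/icn_table.tsv      component scores, ICN flags, domains
      clean/                 cleaned, concatenated ICN time courses
      fnc/                   static FNC TSVs + windowed series (HDF5)
      states/                centroids, occupancy, assignments
      stats/                 contrast and domain-level tables

Every stage is deterministic under the master seed; rerunning a stage with
the same config regenerates identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import fnc as fnc_mod
from . import icnselect, simulate, stats, states as states_mod, tcclean
from ._utils import child_seed
from .dataset import MaskedDataset, read_motion
from .decompose import run_multiscale

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NIfTI helpers
# ---------------------------------------------------------------------------

def load_masked(nifti_path: str | Path, mask_path: str | Path, **meta) -> MaskedDataset:
    """Load a 4-D NIfTI and mask into a z-scored voxels x time matrix."""
    img = nib.load(str(nifti_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4-D image, got {data.ndim}-D")
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"grid mismatch: image {data.shape[:3]} vs mask {mask.shape}"
        )
    matrix = data[mask, :]
    if not np.all(np.isfinite(matrix)):
        raise ValueError(f"{nifti_path}: non-finite voxels inside the mask")
    tr = float(meta.pop("tr_seconds", img.header.get_zooms()[3] or 2.0))
    sid = meta.pop("subject_id", Path(nifti_path).stem.replace("_bold", ""))
    ds = MaskedDataset(
        subject_id=sid,
        data=matrix,
        tr_seconds=tr,
        mask=mask,
        affine=img.affine,
        **meta,
    )
    return ds.zscore()


def write_maps(
    maps: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    z_threshold: float | None = None,
) -> Path:
    """Write component maps as a 4-D NIfTI (component = 4th axis).

    With ``z_threshold`` the maps are z-scaled and values below the
    threshold zeroed — the composite-overlay convention (|Z| > 1.96).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[1] != int(mask.sum()):
        raise ValueError("maps do not match the mask voxel count")
    out = maps
    if z_threshold is not None:
        z = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        out = np.where(np.abs(z) > z_threshold, z, 0.0)
    vol = np.zeros(mask.shape + (maps.shape[0],), dtype=np.float32)
    vol[mask, :] = out.T
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(vol, affine).to_filename(str(path))
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SimulateConfig:
    grid_shape: tuple[int, int, int] = (26, 26, 10)
    n_coarse: int = 4
    split_factor: int = 2
    n_per_cell: int = 4
    n_timepoints: int = 250
    tr_seconds: float = 2.0
    n_states: int = 1
    dwell_mean: float = 20.0
    state_rho: float = 0.35
    noise_sd: float = 0.05
    motion_amp: float = 0.02
    source_amplitude: float = 1.0
    child_radius: float | None = 2.2
    sep_ratio: float = 2.8
    smooth_ratio: float = 0.5
    state_contrast: float = 0.35


@dataclass
class DecomposeConfig:
    orders: tuple[int, ...] = (5, 10)
    n_runs: int = 10
    var_retained: float = 0.9999


@dataclass
class StatesConfig:
    k: int | None = None  # None: choose by elbow
    k_range: tuple[int, int] = (1, 15)
    strategy: str = "exemplar_two_stage"
    distance: str = "cityblock"
    n_rep: int = 20


@dataclass
class StatsConfig:
    n_perm: int = 500
    q: float = 0.05


@dataclass
class RunConfig:
    out_dir: str = "msfnc_run"
    master_seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    decompose: DecomposeConfig = field(default_factory=DecomposeConfig)
    clean: tcclean.CleanConfig = field(default_factory=tcclean.CleanConfig)
    rect_seconds: float = 44.0
    sigma_seconds: float = 6.0
    states: StatesConfig = field(default_factory=StatesConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "simulate": SimulateConfig,
            "decompose": DecomposeConfig,
            "clean": tcclean.CleanConfig,
            "states": StatesConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, scls in sub.items():
            if key in d:
                v = d.pop(key)
                kwargs[key] = _from_dict(scls, v) if isinstance(v, dict) else v
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        for k in ("grid_shape",):
            pass
        cfg = cls(**{**d, **kwargs})
        cfg.simulate.grid_shape = tuple(cfg.simulate.grid_shape)
        cfg.decompose.orders = tuple(cfg.decompose.orders)
        cfg.clean.band = tuple(cfg.clean.band)
        cfg.states.k_range = tuple(cfg.states.k_range)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _simulate_stage(cfg: RunConfig, out: Path):
    sc = cfg.simulate
    seed = child_seed(cfg.master_seed, 0)
    atlas = simulate.make_hierarchical_sources(
        sc.grid_shape,
        sc.n_coarse,
        sc.split_factor,
        seed=seed,
        child_radius=sc.child_radius,
        sep_ratio=sc.sep_ratio,
        smooth_ratio=sc.smooth_ratio,
    )
    base = simulate.hierarchical_covariance(atlas.hierarchy, rho=sc.state_rho)
    covs = [base]
    rng = np.random.default_rng(child_seed(cfg.master_seed, 1))
    for _ in range(sc.n_states - 1):
        covs.append(
            simulate.perturbed_covariance(base, sc.state_contrast, rng)
        )
    states = simulate.StateSpec(covs, dwell_mean=sc.dwell_mean)
    cohort = simulate.CohortSpec(
        n_per_cell=sc.n_per_cell,
        noise_sd=sc.noise_sd,
        motion_amp=sc.motion_amp,
        source_amplitude=sc.source_amplitude,
        seed=child_seed(cfg.master_seed, 2),
        tr_seconds=sc.tr_seconds,
    )
    datasets, truth = simulate.render_cohort(atlas, states, cohort, T=sc.n_timepoints)
    simulate.write_cohort(datasets, truth, out / "data")
    return datasets, truth


def load_cohort(data_dir: str | Path) -> list[MaskedDataset]:
    """Load every subject in a data directory written by the simulator (or
    following the same layout: *_bold.nii[.gz], *_mask.nii[.gz],
    rp_*.txt, phenotype.tsv)."""
    data_dir = Path(data_dir)
    pheno = pd.read_csv(data_dir / "phenotype.tsv", sep="\t")
    datasets = []
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        bold = next(data_dir.glob(f"{sid}_bold.nii*"))
        mask = next(data_dir.glob(f"{sid}_mask.nii*"))
        motion_path = data_dir / f"rp_{sid}.txt"
        ds = load_masked(
            bold,
            mask,
            subject_id=sid,
            motion=read_motion(motion_path) if motion_path.exists() else None,
            site=row["site"],
            diagnosis=row["diagnosis"],
            sex=row["sex"],
            age=float(row["age"]),
        )
        datasets.append(ds)
    return datasets


def _decompose_stage(cfg: RunConfig, datasets, out: Path):
    dc = cfg.decompose
    decomps = run_multiscale(
        datasets,
        orders=list(dc.orders),
        n_runs=dc.n_runs,
        var_retained=dc.var_retained,
        seed=child_seed(cfg.master_seed, 3),
        zscore=False,  # datasets are already z-scored on load
        compute_subject_maps=False,
    )
    ddir = out / "decompose"
    ddir.mkdir(parents=True, exist_ok=True)
    for order, dec in decomps.items():
        write_maps(
            dec.group_maps, datasets[0].mask, datasets[0].affine,
            ddir / f"order-{order:03d}_maps.nii",
        )
        pd.DataFrame(
            {"component": np.arange(dec.model_order), "stability": dec.stability}
        ).to_csv(ddir / f"order-{order:03d}_stability.tsv", sep="\t", index=False)
        for sid, tc in zip(dec.subject_ids, dec.subject_timecourses):
            np.savetxt(ddir / f"tc_{sid}_order-{order:03d}.tsv", tc, delimiter="\t")
    return decomps


def _select_stage(cfg: RunConfig, decomps, truth, out: Path):
    domain_rules = None
    if truth is not None:
        atlas = truth["atlas"]
        names = [icnselect.DOMAINS[k % len(icnselect.DOMAINS)] for k in
                 range(atlas.maps[0].shape[1])]
        templates = {}
        for k, name in enumerate(names):
            u = simulate.union_map(atlas, k)
            templates.setdefault(name, np.zeros_like(u))
            templates[name] = templates[name] + u
        domain_rules = {"templates": templates}
    table = icnselect.select_icns(decomps, domain_rules=domain_rules)
    idir = out / "icn"
    idir.mkdir(parents=True, exist_ok=True)
    table.to_csv(idir / "icn_table.tsv", sep="\t", index=False)
    return table


def _clean_stage(cfg: RunConfig, decomps, icn_table, datasets, out: Path):
    """Concatenate selected ICN time courses across orders (order-major)
    and clean them per subject."""
    ordering = icnselect.icn_ordering(icn_table, sort="finger")
    if ordering.empty:
        raise ValueError(
            "no components passed ICN selection; relax the thresholds or "
            "inspect icn/icn_table.tsv"
        )
    cdir = out / "clean"
    cdir.mkdir(parents=True, exist_ok=True)
    cleaned = []
    for i, ds in enumerate(datasets):
        cols = []
        names = []
        for _, row in ordering.iterrows():
            tc = decomps[row["order"]].subject_timecourses[i][:, row["component"]]
            cols.append(tc)
            names.append(f"{row['domain'] or 'NA'}{row['order']}c{row['component']}")
        tcs = np.column_stack(cols)
        tcs = tcclean.clean_timecourses(
            tcs, ds.tr_seconds, motion=ds.motion, config=cfg.clean
        )
        cleaned.append(tcs)
        df = pd.DataFrame(tcs, columns=names)
        df.to_csv(cdir / f"{ds.subject_id}_icn_tcs.tsv", sep="\t", index=False)
    return cleaned, ordering


def _fnc_stage(cfg: RunConfig, cleaned, datasets, out: Path):
    taper = fnc_mod.make_taper(cfg.clean.target_tr, cfg.rect_seconds, cfg.sigma_seconds)
    fdir = out / "fnc"
    fdir.mkdir(parents=True, exist_ok=True)
    sfnc = []
    series = []
    for ds, tcs in zip(datasets, cleaned):
        sf = fnc_mod.static_fnc(tcs)
        sfnc.append(sf)
        series.append(fnc_mod.windowed_fnc(tcs, taper, subject_id=ds.subject_id))
    np.savetxt(
        fdir / "sfnc_mean.tsv",
        np.mean([sf.values for sf in sfnc], axis=0),
        delimiter="\t",
    )
    sub_rows = np.vstack([sf.vectorized() for sf in sfnc])
    pd.DataFrame(sub_rows, index=[ds.subject_id for ds in datasets]).to_csv(
        fdir / "sfnc_subjects.tsv", sep="\t", header=False
    )
    with h5py.File(fdir / "windows.h5", "w") as fh:
        for s in series:
            g = fh.create_group(s.subject_id)
            g.create_dataset("windows", data=s.windows)
            g.create_dataset("onsets", data=s.onsets)
            g.create_dataset("valid", data=s.valid)
            g.attrs["n_components"] = s.n_components
    return sfnc, series


def load_decompositions(
    out_dir: str | Path, datasets: list[MaskedDataset]
) -> dict[int, "Decomposition"]:
    """Reload persisted decompositions (maps, stability, time courses)."""
    from .decompose import Decomposition

    ddir = Path(out_dir) / "decompose"
    decomps: dict[int, Decomposition] = {}
    mask = datasets[0].mask
    for maps_path in sorted(ddir.glob("order-*_maps.nii*")):
        order = int(maps_path.name.split("-")[1].split("_")[0])
        vol = np.asarray(nib.load(str(maps_path)).dataobj, dtype=float)
        maps = vol[mask, :].T
        stab = pd.read_csv(
            ddir / f"order-{order:03d}_stability.tsv", sep="\t"
        )["stability"].to_numpy()
        dec = Decomposition(
            model_order=maps.shape[0],
            group_maps=maps,
            stability=stab,
            best_run=-1,
            tr_seconds=datasets[0].tr_seconds,
        )
        for ds in datasets:
            tc = np.loadtxt(
                ddir / f"tc_{ds.subject_id}_order-{order:03d}.tsv", delimiter="\t"
            )
            dec.subject_timecourses.append(np.atleast_2d(tc))
            dec.subject_ids.append(ds.subject_id)
        decomps[order] = dec
    if not decomps:
        raise FileNotFoundError(f"no decomposition outputs under {ddir}")
    return decomps


def load_window_series(path: str | Path) -> list[fnc_mod.WindowedFncSeries]:
    out = []
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh):
            g = fh[sid]
            out.append(
                fnc_mod.WindowedFncSeries(
                    subject_id=sid,
                    windows=g["windows"][()],
                    onsets=g["onsets"][()],
                    valid=g["valid"][()].astype(bool),
                    n_components=int(g.attrs["n_components"]),
                )
            )
    return out


def fnc_stage_from_files(cfg: RunConfig, out_dir: str | Path) -> int:
    """File-based FNC stage: read cleaned time-course TSVs, write static
    FNC tables and the windowed-series container.  Returns the number of
    subjects processed."""
    out = Path(out_dir)
    cdir = out / "clean"
    paths = sorted(cdir.glob("*_icn_tcs.tsv"))
    if not paths:
        raise FileNotFoundError(f"no cleaned time courses under {cdir}")
    taper = fnc_mod.make_taper(cfg.clean.target_tr, cfg.rect_seconds, cfg.sigma_seconds)
    fdir = out / "fnc"
    fdir.mkdir(parents=True, exist_ok=True)
    mats, rows, ids = [], [], []
    with h5py.File(fdir / "windows.h5", "w") as fh:
        for p in paths:
            sid = p.name.replace("_icn_tcs.tsv", "")
            tcs = pd.read_csv(p, sep="\t").to_numpy()
            sf = fnc_mod.static_fnc(tcs)
            mats.append(sf.values)
            rows.append(sf.vectorized())
            ids.append(sid)
            s = fnc_mod.windowed_fnc(tcs, taper, subject_id=sid)
            g = fh.create_group(sid)
            g.create_dataset("windows", data=s.windows)
            g.create_dataset("onsets", data=s.onsets)
            g.create_dataset("valid", data=s.valid)
            g.attrs["n_components"] = s.n_components
    np.savetxt(fdir / "sfnc_mean.tsv", np.mean(mats, axis=0), delimiter="\t")
    pd.DataFrame(np.vstack(rows), index=ids).to_csv(
        fdir / "sfnc_subjects.tsv", sep="\t", header=False
    )
    return len(paths)


def load_sfnc(out_dir: str | Path) -> tuple[list[fnc_mod.FncMatrix], list[str]]:
    """Reload per-subject static FNC matrices written by the FNC stage."""
    from ._utils import unvec_upper

    path = Path(out_dir) / "fnc" / "sfnc_subjects.tsv"
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    n_pairs = df.shape[1]
    p = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    mats = [fnc_mod.FncMatrix(unvec_upper(row.to_numpy(), p)) for _, row in df.iterrows()]
    return mats, list(df.index)


def load_state_model(out_dir: str | Path, distance: str = "cityblock"):
    """Rebuild a StateModel from persisted centroids, assignments and
    windows."""
    from .states import StateModel

    out_dir = Path(out_dir)
    centroids = np.atleast_2d(np.loadtxt(out_dir / "states" / "centroids.tsv",
                                         delimiter="\t"))
    series = load_window_series(out_dir / "fnc" / "windows.h5")
    k = centroids.shape[0]
    assignments, state_means, ids = [], [], []
    with h5py.File(out_dir / "states" / "assignments.h5", "r") as fh:
        for s in series:
            lab = fh[s.subject_id][()]
            assignments.append(lab)
            w = s.windows[s.valid]
            means = [
                w[lab == st].mean(axis=0) if np.any(lab == st) else None
                for st in range(k)
            ]
            state_means.append(means)
            ids.append(s.subject_id)
    all_lab = np.concatenate(assignments)
    poc = np.array([100.0 * np.mean(all_lab == st) for st in range(k)])
    return StateModel(
        k=k, centroids=centroids, assignments=assignments,
        subject_state_means=state_means, poc=poc,
        strategy="loaded", distance=distance, subject_ids=ids,
    )


def _states_stage(cfg: RunConfig, series, out: Path):
    stc = cfg.states
    sdir = out / "states"
    sdir.mkdir(parents=True, exist_ok=True)
    seed = child_seed(cfg.master_seed, 4)
    k = stc.k
    elbow = None
    if k is None:
        stacked = np.vstack([s.windows[s.valid] for s in series])
        elbow = states_mod.elbow_k(
            stacked,
            range(stc.k_range[0], stc.k_range[1] + 1),
            distance=stc.distance,
            seed=seed,
            n_rep=max(2, stc.n_rep // 4),
        )
        k = elbow.k
        pd.DataFrame({"k": elbow.k_range, "ratio": elbow.ratio}).to_csv(
            sdir / "elbow.tsv", sep="\t", index=False
        )
    model = states_mod.fit_states(
        series, k, strategy=stc.strategy, distance=stc.distance,
        seed=seed, n_rep=stc.n_rep,
    )
    np.savetxt(sdir / "centroids.tsv", model.centroids, delimiter="\t")
    pd.DataFrame({"state": np.arange(k), "poc": model.poc}).to_csv(
        sdir / "poc.tsv", sep="\t", index=False
    )
    with h5py.File(sdir / "assignments.h5", "w") as fh:
        for sid, lab in zip(model.subject_ids, model.assignments):
            fh.create_dataset(sid, data=lab)
    return model, elbow


def _stats_stage(cfg: RunConfig, sfnc, model, icn_order, datasets, out: Path):
    tdir = out / "stats"
    tdir.mkdir(parents=True, exist_ok=True)
    pheno = simulate.phenotype_table(datasets)
    pheno["mean_fd"] = [
        stats.framewise_displacement(ds.motion)[1] if ds.motion is not None else 0.0
        for ds in datasets
    ]
    feature_sets = {"sfnc": np.vstack([sf.vectorized() for sf in sfnc])}
    for st in range(model.k):
        rows = []
        for means in model.subject_state_means:
            rows.append(means[st])
        # subjects who never visit a state are excluded from that state's
        # contrast by imputing the subject's static FNC? No — keep absent:
        # represent as NaN and drop feature-wise inside the GLM caller.
        valid = [r is not None for r in rows]
        if all(valid):
            feature_sets[f"state{st + 1}"] = np.vstack(rows)
        else:
            log.info(
                "state %d skipped in stats: %d subjects never visit it",
                st + 1, int(len(rows) - sum(valid)),
            )
    table = stats.contrast_table(
        feature_sets, pheno,
        n_perm=cfg.stats.n_perm, q=cfg.stats.q,
        seed=child_seed(cfg.master_seed, 5),
    )
    table.to_csv(tdir / "contrasts.tsv", sep="\t", index=False)

    icns = icn_order.rename(columns={"domain": "domain"})
    mean_sfnc = np.mean([sf.values for sf in sfnc], axis=0)
    dm = stats.domain_aggregate(mean_sfnc, icns)
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
        tdir / "domain_sfnc.tsv", sep="\t"
    )
    return table, dm


def run_pipeline(cfg: RunConfig):
    """Execute the full chain: simulate -> decompose -> select -> clean ->
    FNC -> states -> group statistics.  Returns a results dict; every
    stage also persists its outputs under ``cfg.out_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    stage = "simulate"
    try:
        datasets, truth = _simulate_stage(cfg, out)
        prepared = [ds.zscore() for ds in datasets]
        stage = "decompose"
        decomps = _decompose_stage(cfg, prepared, out)
        stage = "icnselect"
        icn_table = _select_stage(cfg, decomps, truth, out)
        stage = "tcclean"
        cleaned, ordering = _clean_stage(cfg, decomps, icn_table, datasets, out)
        stage = "fnc"
        sfnc, series = _fnc_stage(cfg, cleaned, datasets, out)
        stage = "states"
        model, elbow = _states_stage(cfg, series, out)
        stage = "stats"
        contrasts, domain_matrix = _stats_stage(
            cfg, sfnc, model, ordering, datasets, out
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return {
        "datasets": datasets,
        "truth": truth,
        "decompositions": decomps,
        "icn_table": icn_table,
        "cleaned": cleaned,
        "ordering": ordering,
        "sfnc": sfnc,
        "series": series,
        "state_model": model,
        "elbow": elbow,
        "contrasts": contrasts,
        "domain_matrix": domain_matrix,
    }
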