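"""End-to-end orchestration: synth -> relax -> conn -> stats.

Each stage reads its inputs from the run directory and writes its outputs
there, so a later stage can be rerun alone against cached upstream files.
All randomness flows from the single cohort seed through stable per-subject,
per-stage substreams, making every output deterministic for a given config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rotorelax import connectivity as conn
from rotorelax import group_stats as gs
from rotorelax import io as rio
from rotorelax import relaxometry as rx
from rotorelax.synth import (
    CohortSpec,
    FMRISpec,
    PhantomSpec,
    ROIDef,
    default_phantom_spec,
    demographics_table,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "demo_config",
    "default_config",
    "save_config",
    "load_config",
    "run_pipeline",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("synth", "relax", "conn", "stats")

MODALITY_METRIC = {"t1rho": "T1rho", "t2rho": "T2rho", "raff4": "RAFF4"}


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage and subject."""


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=default_phantom_spec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fmri: FMRISpec = field(default_factory=FMRISpec)
    schedules: tuple = (rx.T1RHO_SCHEDULE, rx.T2RHO_SCHEDULE, rx.RAFF4_SCHEDULE)
    drop_initial_volumes: int = 10
    censor_threshold_mm: float = 0.33
    min_dof: int = 20
    target_fwhm_mm: float = 4.0
    network_alpha: float = 0.0005
    min_cluster: int = 20
    seed_rois: tuple = (
        "accumbens", "amygdala", "caudate", "hippocampus", "pallidum",
        "putamen", "thalamus", "midbrain", "pons", "SNc", "SNr",
    )


def default_config(seed: int = 0) -> PipelineConfig:
    cfg = PipelineConfig()
    return replace(cfg, cohort=replace(cfg.cohort, seed=seed))


def demo_phantom_spec() -> PhantomSpec:
    """Compact 32 x 32 x 20 phantom for demonstrations and quick runs."""
    b = dict(radii=(2.5, 2.5, 2.2), bilateral=True)
    rois = (
        ROIDef("accumbens", 1, (8, 6, 5), **b),
        ROIDef("amygdala", 2, (8, 6, 10), **b),
        ROIDef("caudate", 3, (8, 6, 15), **b),
        ROIDef("hippocampus", 4, (8, 14, 5), **b),
        ROIDef("pallidum", 5, (8, 14, 10), **b),
        ROIDef("putamen", 6, (8, 14, 15), **b),
        ROIDef("thalamus", 7, (8, 22, 5), **b),
        ROIDef("SNc", 8, (8, 22, 10), **b),
        ROIDef("SNr", 9, (8, 22, 15), **b),
        ROIDef("midbrain", 10, (16, 28, 6), (3.0, 3.0, 2.5), bilateral=False),
        ROIDef("pons", 11, (16, 28, 14), (3.0, 3.0, 2.5), bilateral=False),
    )
    return PhantomSpec(grid_shape=(32, 32, 20), roi_defs=rois)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Scaled-down end-to-end configuration: a compact grid and 3/3/3
    subjects.  The BOLD run keeps its full 502-volume length because the
    out-of-band spectral regressors scale with run length — much shorter
    runs cannot retain 20 DOF after censoring."""
    fmri = FMRISpec(
        wm_box=((1, 12), (26, 31), (1, 12)),
        csf_box=((20, 31), (26, 31), (1, 10)),
    )
    # 10 controls are kept so the control-group network definition
    # (one-sample t at p < 0.0005) has its intended degrees of freedom;
    # the patient groups are trimmed to 3 each.
    cohort = CohortSpec(n_per_group=(10, 3, 3), seed=seed)
    return PipelineConfig(phantom=demo_phantom_spec(), cohort=cohort, fmri=fmri)


# ---------------------------------------------------------------------------
# config (de)serialization — round-trips losslessly through YAML

def _spec_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _spec_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_spec_to_dict(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _spec_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = _spec_to_dict(cfg)
    # tuple-keyed effect dicts are flattened for YAML
    d["cohort"]["group_effects"] = [
        {"group": g, "roi": r, "metric": m, "shift": float(v)}
        for (g, r, m), v in cfg.cohort.group_effects.items()
    ]
    return d


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    ph = dict(d["phantom"])
    ph["grid_shape"] = _tuplify(ph["grid_shape"])
    ph["voxel_size_mm"] = _tuplify(ph["voxel_size_mm"])
    ph["roi_defs"] = tuple(
        ROIDef(r["name"], r["label"], _tuplify(r["center"]),
               _tuplify(r["radii"]), r["bilateral"])
        for r in ph["roi_defs"]
    )
    co = dict(d["cohort"])
    co["n_per_group"] = _tuplify(co["n_per_group"])
    co["group_effects"] = {
        (e["group"], e["roi"], e["metric"]): e["shift"]
        for e in co["group_effects"]
    }
    co["age_dist"] = {k: _tuplify(v) for k, v in co["age_dist"].items()}
    co["fd_dist"] = {k: _tuplify(v) for k, v in co["fd_dist"].items()}
    fm = dict(d["fmri"])
    fm["networks"] = tuple(
        (n[0], _tuplify(n[1]), n[2]) for n in fm["networks"]
    )
    fm["band"] = _tuplify(fm["band"])
    fm["wm_box"] = _tuplify(fm["wm_box"])
    fm["csf_box"] = _tuplify(fm["csf_box"])
    schedules = tuple(
        rx.AcquisitionSchedule(s["modality"], s["unit_duration_ms"],
                               _tuplify(s["counts"]), s["tr_s"])
        for s in d["schedules"]
    )
    return PipelineConfig(
        phantom=PhantomSpec(**ph),
        cohort=CohortSpec(**co),
        fmri=FMRISpec(**fm),
        schedules=schedules,
        drop_initial_volumes=d["drop_initial_volumes"],
        censor_threshold_mm=d["censor_threshold_mm"],
        min_dof=d["min_dof"],
        target_fwhm_mm=d["target_fwhm_mm"],
        network_alpha=d["network_alpha"],
        min_cluster=d["min_cluster"],
        seed_rois=_tuplify(d["seed_rois"]),
    )


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# stages

def _subject_dir(out: Path, subject_id: str) -> Path:
    return rio.ensure_dir(out / "subjects" / subject_id)


def _hash_file(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _provenance(out: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    rec = {
        "stage": stage,
        "params": params,
        "inputs": {str(p.relative_to(out)): _hash_file(p) for p in inputs},
    }
    path = out / "provenance.json"
    log = json.loads(path.read_text()) if path.exists() else []
    log = [r for r in log if r["stage"] != stage] + [rec]
    path.write_text(json.dumps(log, indent=1, sort_keys=True))


def stage_synth(cfg: PipelineConfig, out: Path) -> None:
    vox = cfg.phantom.voxel_size_mm
    demo = demographics_table(cfg.cohort)
    demo.to_csv(out / "demographics.csv", index=False)
    truth_rows = []
    for bundle in generate_cohort(cfg.cohort, cfg.phantom, cfg.fmri):
        sdir = _subject_dir(out, bundle.subject_id)
        rio.save_nifti(sdir / "labels.nii", bundle.labels, vox)
        for modality, series in bundle.relax_series.items():
            if modality == "raff4":
                rio.save_nifti(sdir / "raff4_decay.nii",
                               series[0].astype(np.float32), vox)
                rio.save_nifti(sdir / "raff4_recovery.nii",
                               series[1].astype(np.float32), vox)
            else:
                rio.save_nifti(sdir / f"{modality}.nii",
                               series.astype(np.float32), vox)
        rio.save_nifti(sdir / "bold.nii", bundle.bold.bold, vox)
        rio.save_motion(sdir / "motion.txt", bundle.bold.motion)
        rio.save_nifti(sdir / "wm_mask.nii",
                       bundle.bold.wm_mask.astype(np.uint8), vox)
        rio.save_nifti(sdir / "csf_mask.nii",
                       bundle.bold.csf_mask.astype(np.uint8), vox)
        truth_rows.append(bundle.truth.roi_means)
    truth = pd.concat(truth_rows, ignore_index=True)
    truth.to_csv(out / "truth_roi_means.csv", index=False)
    _provenance(out, "synth", {"seed": cfg.cohort.seed,
                               "n_per_group": list(cfg.cohort.n_per_group)},
                [out / "demographics.csv"])


def stage_relax(cfg: PipelineConfig, out: Path) -> None:
    vox = cfg.phantom.voxel_size_mm
    demo = pd.read_csv(out / "demographics.csv")
    lookup = cfg.phantom.label_lookup()
    rows = []
    schedules = {s.modality: s for s in cfg.schedules}
    for _, row in demo.iterrows():
        sid = row["subject_id"]
        sdir = out / "subjects" / sid
        try:
            labels, _ = rio.load_nifti(sdir / "labels.nii")
            mask = labels > 0
            for modality, sched in schedules.items():
                if modality == "raff4":
                    decay, _ = rio.load_nifti(sdir / "raff4_decay.nii")
                    rec, _ = rio.load_nifti(sdir / "raff4_recovery.nii")
                    pmap = rx.fit_parameter_map(decay, sched, mask, recovery=rec)
                else:
                    series, _ = rio.load_nifti(sdir / f"{modality}.nii")
                    pmap = rx.fit_parameter_map(series, sched, mask)
                rio.save_nifti(sdir / f"{modality}_map.nii",
                               pmap.values.astype(np.float32), vox)
                rows.append(rx.roi_summarize(
                    pmap, labels, lookup, MODALITY_METRIC[modality], sid))
        except FileNotFoundError as e:
            raise PipelineError(f"stage relax, subject {sid}: missing input "
                                f"{e.filename}") from e
        except Exception as e:
            raise PipelineError(f"stage relax failed for {sid}: {e}") from e
    pd.concat(rows, ignore_index=True).to_csv(out / "relax_metrics.csv",
                                              index=False)
    _provenance(out, "relax",
                {"schedules": [s.modality for s in cfg.schedules]},
                [out / "relax_metrics.csv"])


def stage_conn(cfg: PipelineConfig, out: Path) -> None:
    vox = cfg.phantom.voxel_size_mm
    demo = pd.read_csv(out / "demographics.csv")
    lookup = cfg.phantom.label_lookup()
    drop = cfg.drop_initial_volumes
    z_maps: dict[str, dict[str, np.ndarray]] = {r: {} for r in cfg.seed_rois}
    reho_rows, summary_rows = [], []
    for _, row in demo.iterrows():
        sid = row["subject_id"]
        sdir = out / "subjects" / sid
        try:
            bold, _ = rio.load_nifti(sdir / "bold.nii")
            motion = rio.load_motion(sdir / "motion.txt")
            labels, _ = rio.load_nifti(sdir / "labels.nii")
            wm, _ = rio.load_nifti(sdir / "wm_mask.nii")
            csf, _ = rio.load_nifti(sdir / "csf_mask.nii")
            bold = np.asarray(bold, dtype=np.float32)[..., drop:]
            motion = motion[drop:]
            design = conn.nuisance_design(
                motion, bold, wm.astype(bool), csf.astype(bool), cfg.fmri.tr)
            cm = conn.censor_mask(motion, cfg.censor_threshold_mm, design,
                                  min_dof=cfg.min_dof)
            rio.save_censor(sdir / "censor.txt", cm.keep)
            fd = conn.framewise_displacement(motion)
            summary_rows.append({
                "subject_id": sid, "group": row["group"],
                "n_kept": cm.n_kept, "dof": cm.dof_remaining,
                "fd_mean": float(fd.mean()), "excluded": cm.excluded,
            })
            if cm.excluded:
                logger.warning("subject %s excluded: DOF %s < %d",
                               sid, cm.dof_remaining, cfg.min_dof)
                continue
            resid, dof = conn.denoise(bold, design, cm)
            resid = conn.smooth_to_fwhm(resid, cfg.target_fwhm_mm, vox)
            brain = np.ones(labels.shape, dtype=bool)
            for roi in cfg.seed_rois:
                fc = conn.seed_fc(resid, labels, lookup[roi], dof, roi)
                rio.save_nifti(sdir / f"fc_{roi}.nii",
                               fc.z.astype(np.float32), vox)
                z_maps[roi][sid] = fc.z
            rmap = conn.reho(resid, brain)
            rio.save_nifti(sdir / "reho_z.nii", rmap.z.astype(np.float32), vox)
            reho_rows.append(rx.roi_summarize(rmap.z, labels, lookup,
                                              "ReHo", sid))
        except FileNotFoundError as e:
            raise PipelineError(f"stage conn, subject {sid}: missing input "
                                f"{e.filename}") from e
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage conn failed for {sid}: {e}") from e

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "conn_summary.csv", index=False)
    controls = demo[demo["group"] == "control"]["subject_id"].tolist()
    strength_rows = []
    for roi in cfg.seed_rois:
        ctrl_maps = [z_maps[roi][s] for s in controls if s in z_maps[roi]]
        net = conn.define_network(ctrl_maps, cfg.network_alpha,
                                  cfg.min_cluster, seed_name=roi)
        rio.save_nifti(out / f"network_{roi}.nii",
                       net.mask.astype(np.uint8), vox)
        for sid, z in z_maps[roi].items():
            strength_rows.append({
                "subject_id": sid, "roi_name": roi,
                "metric_name": "network_strength",
                "value": conn.network_strength(z, net),
                "n_voxels": int(net.mask.sum()),
                "missing": not net.mask.any(),
            })
    func = pd.concat(
        [pd.DataFrame(strength_rows)] + reho_rows, ignore_index=True)
    func.to_csv(out / "functional_metrics.csv", index=False)
    _provenance(out, "conn",
                {"censor_threshold_mm": cfg.censor_threshold_mm,
                 "min_dof": cfg.min_dof, "target_fwhm_mm": cfg.target_fwhm_mm,
                 "alpha": cfg.network_alpha, "min_cluster": cfg.min_cluster},
                [out / "conn_summary.csv", out / "functional_metrics.csv"])


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    demo = pd.read_csv(out / "demographics.csv")
    relax = pd.read_csv(out / "relax_metrics.csv")
    func = pd.read_csv(out / "functional_metrics.csv")
    truth = pd.read_csv(out / "truth_roi_means.csv")
    summary = pd.read_csv(out / "conn_summary.csv")

    # FA/MD ROI values come from the table-level generator (tensor fitting
    # is out of scope); relaxation + functional metrics come from images.
    diffusion = truth[truth["metric_name"].isin(["FA", "MD"])][
        ["subject_id", "roi_name", "metric_name", "value"]
    ]
    measured = pd.concat(
        [relax[["subject_id", "roi_name", "metric_name", "value"]],
         func[["subject_id", "roi_name", "metric_name", "value"]],
         diffusion],
        ignore_index=True,
    )
    table = measured.merge(demo, on="subject_id", how="left").merge(
        summary[["subject_id", "fd_mean"]], on="subject_id", how="left"
    ).rename(columns={"fd_mean": "FD"})
    excluded = summary[summary["excluded"]]["subject_id"].tolist()
    if excluded:
        logger.warning("subjects excluded by the DOF rule: %s", excluded)
    table.to_csv(out / "cohort_metrics.csv", index=False)

    results = gs.analyze_cohort(table)
    results.to_csv(out / "results.csv", index=False)
    gs.summarize_cohort(table).to_csv(out / "group_summary.csv", index=False)
    gs.control_cv_table(table).to_csv(out / "cv_by_metric.csv", index=False)
    kept = summary[~summary["excluded"]]
    if kept["group"].nunique() > 1 and (kept.groupby("group").size() >= 2).all():
        f, p = gs.anova_oneway(kept["dof"].to_numpy(), kept["group"].to_numpy())
    else:
        f, p = float("nan"), float("nan")
    (out / "dof_anova.json").write_text(json.dumps(
        {"F": f, "p": p, "excluded_subjects": excluded}, indent=1))
    _provenance(out, "stats", {"contrasts": ["PD-control", "iRBD-control"]},
                [out / "results.csv"])


_STAGE_FUNCS = {
    "synth": stage_synth,
    "relax": stage_relax,
    "conn": stage_conn,
    "stats": stage_stats,
}


def run_pipeline(cfg: PipelineConfig, out_dir, stages=STAGES) -> Path:
    """Run the requested stages in order, writing into ``out_dir``.

    The resolved configuration is snapshotted into the run directory so a
    run is fully described by its own files.
    """
    out = rio.ensure_dir(out_dir)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("rotorelax")
    root.addHandler(handler)
    old_level = root.level
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        save_config(cfg, out / "config.yaml")
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise PipelineError(f"unknown stage {stage!r}; "
                                    f"expected one of {STAGES}")
            logger.info("running stage %s", stage)
            try:
                _STAGE_FUNCS[stage](cfg, out)
            except PipelineError:
                raise
            except FileNotFoundError as e:
                raise PipelineError(
                    f"stage {stage}: missing input {e.filename}") from e
            except Exception as e:
                raise PipelineError(f"stage {stage} failed: {e}") from e
    finally:
        root.setLevel(old_level)
        root.removeHandler(handler)
        handler.close()
    return out
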