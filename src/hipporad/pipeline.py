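"""End-to-end pipeline: simulate/load -> QC -> ALFF -> extract -> evaluate.

Each stage writes standard-format artifacts (NIfTI, CSV, JSON) under the
configured output directory; every CSV starts with a commented provenance
header (config hash, seed, package version) and every JSON embeds the same
provenance object, so re-running with an identical config reproduces
identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluation import EvaluationReport, run_experiment
from .features import extract_feature_vector, save_roster_manifest
from .images import ROIMask, TimeSeriesImage, VolumeImage
from .preproc import MotionTrace, alff_pipeline, qc_exclude
from .roi import combine_bilateral
from .synthetic import Cohort, CohortSpec, default_study_spec, generate_cohort, save_cohort

logger = logging.getLogger("hipporad")

__all__ = ["run_pipeline", "load_cohort_dir", "cohort_spec_from_config"]


def _write_csv(df: pd.DataFrame, path: Path, provenance: dict, index: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index)


def read_provenance_csv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def cohort_spec_from_config(cfg: PipelineConfig) -> CohortSpec:
    base = default_study_spec(seed=cfg.seed)
    groups = {
        name: (dataclasses.replace(base.groups[name], n=n) if name in base.groups else None)
        for name, n in cfg.cohort.n_per_group.items()
    }
    if any(v is None for v in groups.values()):
        bad = [k for k, v in groups.items() if v is None]
        raise ValueError(f"cohort.n_per_group: unknown group label(s) {bad}")
    shape = tuple(cfg.cohort.image_shape)
    # scale the default hippocampus-like ellipsoids with the grid
    scale = np.array(shape) / np.array(base.image_shape)
    rois = {}
    for side, roi in (("roi_left", base.roi_left), ("roi_right", base.roi_right)):
        rois[side] = type(roi)(
            tuple(np.array(roi.center) * scale),
            tuple(np.maximum(np.array(roi.radii) * scale, 1.5)),
        )
    return CohortSpec(
        groups=groups,
        image_shape=shape,
        n_volumes=cfg.cohort.n_volumes,
        tr_seconds=cfg.cohort.tr_seconds,
        texture_effect=cfg.cohort.texture_effect,
        alff_effect=cfg.cohort.alff_effect,
        noise_sd=cfg.cohort.noise_sd,
        seed=cfg.seed,
        **rois,
    )


def load_cohort_dir(path: str | Path, tr: float | None = None):
    """Load an on-disk cohort written by :func:`hipporad.synthetic.save_cohort`.

    Returns (table, subjects) where each subject is a dict with the images,
    masks, and motion trace.
    """
    path = Path(path)
    table = pd.read_csv(path / "subjects.csv")
    subjects = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        subjects.append(
            {
                "subject_id": sid,
                "group": row["group"],
                "score": row["score"],
                "structural": VolumeImage.load(path / f"{sid}_T1w.nii.gz"),
                "functional": TimeSeriesImage.load(path / f"{sid}_bold.nii.gz", tr=tr),
                "mask_left": ROIMask.load(path / f"{sid}_mask-left.nii.gz"),
                "mask_right": ROIMask.load(path / f"{sid}_mask-right.nii.gz"),
                "motion": MotionTrace.load(path / row["motion_path"]),
            }
        )
    return table, subjects


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(
    cfg: PipelineConfig,
    cohort: Cohort | None = None,
    write_images: bool = False,
) -> EvaluationReport:
    """Run every stage in flow order and write the output tree.

    ``cohort`` may be passed to reuse an in-memory cohort (e.g. in tests);
    otherwise it is simulated or loaded according to the config.
    ``write_images`` additionally saves per-subject NIfTI volumes (cohort
    images and ALFF maps), which the numeric results do not depend on.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance()
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    try:
        return _run(cfg, cohort, out, prov, write_images)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(cfg, cohort, out, prov, write_images) -> EvaluationReport:
    # --- cohort
    t0 = _stage("cohort")
    if cohort is None:
        if cfg.cohort.simulate:
            cohort = generate_cohort(cohort_spec_from_config(cfg))
        else:
            table, raw = load_cohort_dir(cfg.cohort.path)
            cohort = _cohort_from_records(table, raw, cfg)
    subjects = cohort.subjects
    if write_images:
        save_cohort(cohort, out / "cohort")
    _done("cohort", t0)

    # --- QC
    t0 = _stage("qc")
    motions = {s.subject_id: s.motion for s in subjects}
    kept_ids, excluded, qc_report = qc_exclude(motions, cfg.qc)
    _write_csv(qc_report, out / "qc_report.csv", prov)
    if excluded:
        logger.info("qc excluded %d subject(s): %s", len(excluded), excluded)
    subjects = [s for s in subjects if s.subject_id in set(kept_ids)]
    _done("qc", t0)

    # --- ALFF
    t0 = _stage("alff")
    alff_maps = {}
    for s in subjects:
        analysis_mask = combine_bilateral(s.mask_left, s.mask_right)
        amap = alff_pipeline(s.functional, analysis_mask, s.motion, cfg.band)
        alff_maps[s.subject_id] = amap
        if write_images:
            (out / "alff").mkdir(exist_ok=True)
            amap.volume.save(out / "alff" / f"{s.subject_id}_alff.nii.gz")
    _done("alff", t0)

    # --- features
    t0 = _stage("extract")
    (out / "features").mkdir(exist_ok=True)
    save_roster_manifest(out / "features" / "roster.json")
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for roi_name in cfg.rois:
        for modality in ("T1-w", "ALFF"):
            rows = {}
            for s in subjects:
                mask = _roi_mask(s, roi_name)
                img = s.structural if modality == "T1-w" else alff_maps[s.subject_id].volume
                rows[s.subject_id] = extract_feature_vector(
                    img, mask, n_bins=cfg.n_bins, modality=modality
                )
            df = pd.DataFrame.from_dict(rows, orient="index")
            df.index.name = "subject_id"
            tables[(roi_name, modality)] = df
            _write_csv(df, out / "features" / f"{roi_name}_{modality}.csv", prov, index=True)
    _done("extract", t0)

    # --- evaluation
    t0 = _stage("evaluate")
    groups = pd.Series({s.subject_id: s.group for s in subjects})
    clinical = pd.Series({s.subject_id: s.score for s in subjects})
    report = run_experiment(
        tables,
        groups,
        clinical,
        contrasts=cfg.contrasts,
        rois=cfg.rois,
        modalities=cfg.modalities,
        scheme=cfg.split,
        mrmr_k=cfg.mrmr_k,
        folds=cfg.folds,
        keep_models=True,
    )
    (out / "models").mkdir(exist_ok=True)
    for cell in report.cells:
        models = cell.pop("models", None)
        if models:
            name = f"{cell['contrast']}_{cell['roi']}_{cell['modality']}".replace("/", "-")
            models[0].meta["provenance"] = prov
            models[0].to_json(out / "models" / f"{name}_rep0.json")
    report.to_json(out / "report.json", provenance=prov)
    _write_csv(report.cell_frame(), out / "report_cells.csv", prov)
    _write_csv(report.summary_frame(), out / "report_summary.csv", prov)
    _done("evaluate", t0)
    failed = [c for c in report.cells if c["failed"]]
    if failed:
        logger.error("%d cell(s) failed", len(failed))
        raise RuntimeError(
            "pipeline cells failed: "
            + "; ".join(f"{c['contrast']}/{c['roi']}/{c['modality']}: {c['error']}" for c in failed)
        )
    return report


def _roi_mask(s, roi_name: str) -> ROIMask:
    if roi_name == "left":
        return s.mask_left
    if roi_name == "right":
        return s.mask_right
    if roi_name == "bilateral":
        return combine_bilateral(s.mask_left, s.mask_right)
    raise ValueError(f"unknown ROI {roi_name!r}")


def _cohort_from_records(table, raw, cfg) -> Cohort:
    from .synthetic import SyntheticSubject

    subjects = [
        SyntheticSubject(
            subject_id=r["subject_id"], group=r["group"],
            structural=r["structural"], functional=r["functional"],
            mask_left=r["mask_left"], mask_right=r["mask_right"],
            motion=r["motion"], score=float(r["score"]),
        )
        for r in raw
    ]
    spec = cohort_spec_from_config(cfg)
    return Cohort(spec, subjects, table[["subject_id", "group", "score"]].copy())
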