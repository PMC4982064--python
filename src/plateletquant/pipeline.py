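"""End-to-end pipeline: images -> platelets -> granule counts -> statistics.

Per acquisition batch, a granule threshold is derived from that batch's
control images (mean of per-image moment-preserving thresholds); control
images are segmented with their own threshold and patient images with the
batch reference, reproducing the same-day threshold-transfer scheme of the
clinical workflow.  All outputs are plain CSV/JSON and deterministic for a
fixed manifest + config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, granules, io, radial, segmentation, stats
from .granules import CountTable, GranuleSegConfig
from .imops import ImagePlane
from .io import RunConfig

logger = logging.getLogger("plateletquant")


@dataclass
class RunResult:
    """In-memory pipeline outputs (what the CSV/JSON artifacts serialize)."""

    platelet_table: pd.DataFrame
    granule_table: pd.DataFrame
    count_table: CountTable
    profile_table: pd.DataFrame
    subject_curves: pd.DataFrame
    group_curves: pd.DataFrame
    stats_report: dict
    batch_thresholds: dict[str, float]
    errors: list[dict] = field(default_factory=list)


def _project_pair(row: pd.Series, cfg: RunConfig) -> tuple[ImagePlane, ImagePlane]:
    tub_stack, cd_stack = io.read_image(
        row["image_path"], pixel_size_nm=cfg.pixel_size_nm_override
    )
    return segmentation.project_z(tub_stack), segmentation.project_z(cd_stack)


def compute_batch_thresholds(
    manifest: pd.DataFrame, cfg: RunConfig
) -> tuple[dict[str, float], list[dict]]:
    """Reference granule threshold per batch from that batch's control images."""
    thresholds: dict[str, float] = {}
    errors: list[dict] = []
    for batch, rows in manifest.groupby("batch_id"):
        imgs: list[ImagePlane] = []
        for _, row in rows[rows["group"] == "control"].iterrows():
            try:
                _, cd = _project_pair(row, cfg)
                imgs.append(cd)
            except Exception as exc:  # noqa: BLE001 - record and continue
                errors.append({"image": row["image_path"], "stage": "reference",
                               "error": str(exc)})
        if imgs:
            thresholds[batch] = granules.compute_reference_threshold(
                imgs, cfg.granule.rolling_ball_radius_px,
                cfg.granule.blur_sigma_px)
            logger.info("batch %s: reference threshold %.3f from %d control "
                        "image(s)", batch, thresholds[batch], len(imgs))
        else:
            logger.warning("batch %s has no readable control images; patient "
                           "images in it cannot be thresholded", batch)
    return thresholds, errors


def run_pipeline(manifest: pd.DataFrame, cfg: RunConfig,
                 outdir: str | Path | None = None) -> RunResult:
    """Run every stage over a manifest; optionally write artifacts to outdir."""
    logging.basicConfig()
    logger.setLevel(cfg.log_level)

    batch_thr, errors = compute_batch_thresholds(manifest, cfg)

    plat_rows: list[dict] = []
    gran_rows: list[dict] = []
    count_frames: list[pd.DataFrame] = []
    n_unassigned = 0
    profiles: list[radial.RadialProfile] = []
    prof_rows: list[dict] = []
    group_of: dict[str, str] = {}

    for _, row in manifest.iterrows():
        sid, grp, batch = row["subject_id"], row["group"], row["batch_id"]
        image_id = Path(row["image_path"]).stem
        group_of[sid] = grp
        try:
            tubulin, cd63 = _project_pair(row, cfg)
        except Exception as exc:  # noqa: BLE001
            errors.append({"image": row["image_path"], "stage": "read",
                           "error": str(exc)})
            continue
        try:
            platelets = segmentation.segment_platelets(
                tubulin, cd63, cfg.platelet, subject_id=sid, image_id=image_id
            )
            if grp == "patient":
                if batch not in batch_thr:
                    raise ValueError(f"no control reference threshold for "
                                     f"batch {batch}")
                gcfg = replace(cfg.granule, threshold_mode="reference",
                               reference_threshold=batch_thr[batch])
            else:
                gcfg = replace(cfg.granule, threshold_mode="self",
                               reference_threshold=None)
            grains = granules.segment_granules(cd63, platelets, gcfg,
                                               subject_id=sid, image_id=image_id)
            table = granules.count_granules(grains, platelets, group=grp)
        except Exception as exc:  # noqa: BLE001
            errors.append({"image": row["image_path"], "stage": "segment",
                           "error": str(exc)})
            continue

        count_frames.append(table.rows)
        n_unassigned += table.n_unassigned
        for p in platelets:
            plat_rows.append({
                "subject_id": sid, "image_id": image_id,
                "platelet_id": p.platelet_id,
                "area_um2": p.metrics.area_um2,
                "perimeter_um": p.metrics.perimeter_um,
                "circularity": p.metrics.circularity,
                "centroid_row": p.metrics.centroid_px[0],
                "centroid_col": p.metrics.centroid_px[1],
            })
        for g in grains:
            gran_rows.append({
                "subject_id": sid, "image_id": image_id,
                "granule_id": g.granule_id, "platelet_id": g.platelet_id,
                "area_um2": g.area_um2,
                "centroid_row": g.centroid_px[0],
                "centroid_col": g.centroid_px[1],
            })
        for p in radial.select_circular(platelets, cfg.distribution):
            try:
                prof = radial.profile_platelet(p, tubulin, cd63, cfg.distribution)
            except radial.DegenerateProfileError:
                continue
            profiles.append(prof["cd63"])
            for channel in ("cd63", "tubulin"):
                pr = prof[channel]
                for i in range(pr.n_rings):
                    prof_rows.append({
                        "subject_id": sid, "image_id": image_id,
                        "platelet_id": p.platelet_id, "channel": channel,
                        "ring": i,
                        "norm_radius": pr.norm_radius[i],
                        "norm_density": pr.norm_density[i],
                    })

    count_rows = pd.concat(count_frames, ignore_index=True) if count_frames \
        else pd.DataFrame(columns=["subject_id", "group", "image_id",
                                   "platelet_id", "n_granules"])
    count_table = CountTable(rows=count_rows, n_unassigned=n_unassigned)

    # ---- cohort statistics ------------------------------------------------
    subjects: list[stats.SubjectCounts] = []
    for sid, sub in count_rows.groupby("subject_id"):
        if len(sub) == 0:
            continue
        subjects.append(stats.SubjectCounts(
            subject_id=str(sid), group=group_of[str(sid)],
            counts=sub["n_granules"].to_numpy()))
    missing = sorted(set(group_of) - {s.subject_id for s in subjects})
    for sid in missing:
        logger.warning("subject %s yielded no usable platelets; excluded "
                       "from statistics", sid)

    report: dict = {"n_subjects": len(subjects),
                    "excluded_subjects": missing,
                    "n_unassigned_granules": n_unassigned}
    if subjects:
        report["per_subject"] = {
            s.subject_id: {"group": s.group, "n_platelets": int(s.counts.size),
                           "mean_count": s.mean}
            for s in subjects
        }
        pct = granules.fraction_at_or_above(count_table, cfg.readout_k)
        for sid, v in pct.items():
            report["per_subject"][str(sid)][f"pct_ge_{cfg.readout_k}"] = float(v)
        report["group_summary"] = stats.group_summary(subjects)
        if len(subjects) >= 2:
            kw = stats.kw_multiple_comparison(subjects, alpha=cfg.stats_alpha)
            for s in subjects:
                report["per_subject"][s.subject_id]["mean_rank"] = \
                    kw.mean_rank[s.subject_id]
            report["kruskal_wallis"] = {"H": kw.H, "dof": kw.dof,
                                        "p_value": kw.p_value}
            report["pairwise"] = [asdict(p) for p in kw.pairwise]
            ctrl = [s for s in subjects if s.group == "control"]
            pat = [s for s in subjects if s.group == "patient"]
            if ctrl and pat:
                gkw = stats.kruskal_wallis([
                    np.concatenate([s.counts for s in ctrl]),
                    np.concatenate([s.counts for s in pat]),
                ])
                report["group_kruskal_wallis"] = {
                    "H": gkw.H, "dof": gkw.dof, "p_value": gkw.p_value,
                    "confidence_pct": 100.0 * (1.0 - gkw.p_value),
                }

    subject_curves, group_curves = radial.aggregate_group_profiles(
        profiles, group_of, cfg.distribution)

    result = RunResult(
        platelet_table=pd.DataFrame(plat_rows),
        granule_table=pd.DataFrame(gran_rows),
        count_table=count_table,
        profile_table=pd.DataFrame(prof_rows),
        subject_curves=subject_curves,
        group_curves=group_curves,
        stats_report=report,
        batch_thresholds=batch_thr,
        errors=errors,
    )
    if outdir is not None:
        write_artifacts(result, cfg, outdir)
    return result


def write_artifacts(result: RunResult, cfg: RunConfig, outdir: str | Path) -> None:
    """Serialize a RunResult to CSV/JSON files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.platelet_table.to_csv(out / "platelets.csv", index=False)
    result.granule_table.to_csv(out / "granules.csv", index=False)
    result.count_table.rows.to_csv(out / "counts.csv", index=False)
    result.profile_table.to_csv(out / "profiles.csv", index=False)
    result.subject_curves.to_csv(out / "subject_curves.csv", index=False)
    result.group_curves.to_csv(out / "group_curves.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(result.stats_report, fh, indent=2)
    provenance = {
        "package": "plateletquant",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            "platelet": asdict(cfg.platelet),
            "granule": asdict(cfg.granule),
            "distribution": asdict(cfg.distribution),
            "stats_alpha": cfg.stats_alpha,
            "readout_k": cfg.readout_k,
            "pixel_size_nm_override": cfg.pixel_size_nm_override,
        },
        "interior_erosion_px": cfg.platelet.interior_erosion_px,
        "batch_thresholds": result.batch_thresholds,
        "errors": result.errors,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
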