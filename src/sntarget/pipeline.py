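"""End-to-end analysis pipeline over synthetic anatomy and cohorts.

Stages hand artifacts off through files in the output directory so each
stage can also be run on its own (see the command-line interface):

    simulate -> features -> engage -> train -> rulemap -> depth

Every artifact is written deterministically (fixed float formatting,
sorted JSON keys), and the run manifest records the configuration hash,
seed, library versions and a sha256 per artifact, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .engagement import (
    build_ct,
    classify_lead_contacts,
    cohort_summary,
    depth_profile,
    engagement_from_contacts,
)
from .geometry import depth_along_trajectory, extend_virtual, extract_features, find_max_rn_plane
from .io import (
    read_atlas,
    read_features,
    read_frame,
    read_leads,
    write_atlas,
    write_features,
    write_frame,
    write_leads,
)
from .rules import (
    GpcConfig,
    GridSpec,
    cross_validate,
    extract_rules,
    fit_depth_rule,
    on_track,
    probability_map,
    train_gpc,
)
from .synthetic import AnatomyParams, CohortParams, make_atlas, make_frame, sample_cohort

__all__ = ["run_pipeline", "STAGES"]


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _stamp(obj: dict, config: PipelineConfig) -> dict:
    obj["config_hash"] = config_hash(config)
    obj["seed"] = config.seed
    return obj


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    anatomy = AnatomyParams(voxel_size_mm=config.voxel_size_mm, seed=config.seed)
    atlas = make_atlas(anatomy)
    frame = make_frame(anatomy)
    cohort = CohortParams(n_leads=config.n_leads, seed=config.seed)
    leads, record = sample_cohort(atlas, cohort, frame)
    leads = [extend_virtual(lead, tuple(config.extensions_mm)) for lead in leads]
    write_atlas(atlas, outdir / "atlas.nii")
    write_frame(frame, outdir / "frame.json")
    write_leads(leads, outdir / "leads.csv")
    record.to_csv(outdir / "cohort_record.csv", index=False, float_format="%.6f")


def stage_features(config: PipelineConfig, outdir: Path) -> None:
    atlas = read_atlas(outdir / "atlas.nii")
    frame = read_frame(outdir / "frame.json")
    leads = read_leads(outdir / "leads.csv")
    rows = []
    for lead in leads:
        f = extract_features(lead, atlas, frame)
        rows.append(
            {
                "lead_id": lead.lead_id,
                "hemisphere": lead.hemisphere,
                "x_mm": f.x_mm,
                "y_mm": f.y_mm,
                "ms_angle_deg": f.ms_angle,
                "acpc_angle_deg": f.acpc_angle,
            }
        )
    write_features(pd.DataFrame.from_records(rows), outdir / "features.csv")


def stage_engage(config: PipelineConfig, outdir: Path) -> None:
    atlas = build_ct(read_atlas(outdir / "atlas.nii"))
    frame = read_frame(outdir / "frame.json")
    leads = read_leads(outdir / "leads.csv")
    record = pd.read_csv(outdir / "cohort_record.csv")
    design = dict(zip(record["lead_id"], record["design_class"]))

    contact_rows = []
    engagements = []
    traj_rows = []
    for lead in leads:
        ces = classify_lead_contacts(lead, atlas)
        for ce in ces:
            row = {
                "lead_id": lead.lead_id,
                "contact_index": ce.contact_index,
                "is_virtual": ce.is_virtual,
                "sn_class": ce.sn_class,
            }
            row.update({f"overlap_{r}_mm3": v for r, v in sorted(ce.overlaps_mm3.items())})
            contact_rows.append(row)
        for scenario in config.scenarios:
            te = engagement_from_contacts(lead, ces, scenario)
            engagements.append(te)
            traj_rows.append(
                {
                    "lead_id": te.lead_id,
                    "scenario": scenario,
                    "engaged_regions": "|".join(sorted(te.engaged_regions)),
                }
            )
    pd.DataFrame.from_records(contact_rows).to_csv(
        outdir / "contact_engagements.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame.from_records(traj_rows).to_csv(
        outdir / "trajectory_engagements.csv", index=False
    )
    summary = cohort_summary(engagements, design)
    summary.to_csv(outdir / "engagement_summary.csv", index=False, float_format="%.6f")
    _write_json(
        _stamp({"summary": summary.to_dict(orient="records")}, config),
        outdir / "engagement_summary.json",
    )
    profiles = {
        region: depth_profile(leads, atlas, frame, region, scenario="plus6mm",
                              radius_mm=config.vat_radius_mm).table.to_dict(orient="records")
        for region in ("SNr", "SNc")
    }
    _write_json(_stamp({"profiles": profiles}, config), outdir / "depth_profiles.json")


def _labels_for(outdir: Path, config: PipelineConfig) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    features = read_features(outdir / "features.csv")
    traj = pd.read_csv(outdir / "trajectory_engagements.csv")
    traj = traj[traj["scenario"] == config.label_scenario]
    traj = traj.set_index("lead_id")["engaged_regions"].fillna("")
    labels = {}
    for region in ("SNr", "SNc"):
        labels[region] = np.array(
            [region in str(traj.get(lid, "")).split("|") for lid in features["lead_id"]],
            dtype=int,
        )
    return features, labels


def stage_train(config: PipelineConfig, outdir: Path) -> None:
    features, labels = _labels_for(outdir, config)
    X = features[["x_mm", "y_mm", "ms_angle_deg", "acpc_angle_deg"]]
    gcfg = GpcConfig(seed=config.seed, n_restarts=config.gpc_restarts)
    report = {}
    for region in ("SNr", "SNc"):
        cv = cross_validate(
            X, labels[region], k=config.cv_folds,
            confidence_threshold=config.confidence_threshold,
            seed=config.seed, config=gcfg,
        )
        model = train_gpc(X, labels[region], region=region, config=gcfg)
        report[region] = {
            "n": cv.n,
            "positives": int(labels[region].sum()),
            "cv_accuracy": cv.overall_accuracy,
            "confident_accuracy": cv.confident_accuracy,
            "confident_fraction": cv.confident_fraction,
            "kernel": str(model.gpc.kernel_),
            "lengthscales": model.lengthscales.tolist(),
        }
    _write_json(_stamp({"cv": report}, config), outdir / "cv_report.json")


def stage_rulemap(config: PipelineConfig, outdir: Path) -> None:
    features, labels = _labels_for(outdir, config)
    X = features[["x_mm", "y_mm", "ms_angle_deg", "acpc_angle_deg"]]
    g = config.grid
    grid = GridSpec(tuple(g["x"]), tuple(g["y"]), tuple(g["ms"]), tuple(g["acpc"]))
    gcfg = GpcConfig(seed=config.seed, n_restarts=config.gpc_restarts)
    rules_out = {}
    for region in ("SNr", "SNc"):
        model = train_gpc(X, labels[region], region=region, config=gcfg)
        rmap = probability_map(model, grid, threshold=config.confidence_threshold)
        _write_json(_stamp(rmap.to_dict(), config), outdir / f"rulemap_{region}.json")
        panels = []
        for x in rmap.axes["x"]:
            for y in rmap.axes["y"]:
                panel = extract_rules(rmap, float(x), float(y))
                panels.append(
                    {
                        "x": float(x),
                        "y": float(y),
                        "n_cells": len(panel.cells),
                        "bounds": panel.bounds,
                        "summary": panel.summary,
                    }
                )
        rules_out[region] = panels
    _write_json(_stamp({"rules": rules_out}, config), outdir / "rules.json")


def stage_depth(config: PipelineConfig, outdir: Path) -> None:
    atlas = read_atlas(outdir / "atlas.nii")
    frame = read_frame(outdir / "frame.json")
    leads = read_leads(outdir / "leads.csv")
    contact_df = pd.read_csv(outdir / "contact_engagements.csv")
    sn_class = {
        (r.lead_id, r.contact_index): r.sn_class
        for r in contact_df.itertuples()
    }
    planes = {}
    depths, in_sn = [], []
    for lead in leads:
        if not on_track(lead, atlas):
            continue
        if lead.hemisphere not in planes:
            planes[lead.hemisphere] = find_max_rn_plane(atlas, frame, lead.hemisphere)
        # contact 0 = deepest implanted contact; virtual contacts enter only
        # through the on-track inclusion of the trajectory itself
        idx = int(np.flatnonzero(~lead.virtual_flags)[0])
        depths.append(depth_along_trajectory(lead.contacts[idx], lead, planes[lead.hemisphere]))
        in_sn.append(sn_class[(lead.lead_id, idx)] != "none")
    rule = fit_depth_rule(depths, in_sn)
    _write_json(
        _stamp(
            {
                "n_on_track": len(depths),
                "intercept": rule.intercept,
                "slope_per_mm": rule.slope,
                "min_depth_95_mm": rule.min_depth_95,
                "min_depth_95_lower_border_mm": rule.min_depth_95_lower_border,
                "separation_penalized": rule.penalized,
            },
            config,
        ),
        outdir / "depth_rule.json",
    )


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "engage": stage_engage,
    "train": stage_train,
    "rulemap": stage_rulemap,
    "depth": stage_depth,
}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the run manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, stage in STAGES.items():
        try:
            stage(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    import sklearn

    artifacts = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        artifacts[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "sntarget": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "artifacts": artifacts,
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
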