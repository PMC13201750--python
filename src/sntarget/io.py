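"""File formats: NIfTI atlases, CSV lead/feature tables, JSON frames.

Conventions: coordinates are always mm, RAS; CSV floats are written with
6-decimal fixed formatting so repeated runs are byte-identical; every atlas
NIfTI travels with a JSON label sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import BASE_STRUCTURES, LabelAtlas
from .geometry import NativeFrame
from .models import Lead, get_lead_model

__all__ = [
    "write_atlas",
    "read_atlas",
    "write_leads",
    "read_leads",
    "write_frame",
    "read_frame",
    "write_features",
    "read_features",
]

FLOAT_FMT = "%.6f"


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_atlas(atlas: LabelAtlas, path: str | Path) -> Path:
    """Write the label volume plus a JSON label sidecar (and overlay volumes)."""
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, path)
    sidecar = {
        "labels": dict(sorted(atlas.label_table.items())),
        "overlays": sorted(atlas.overlays),
    }
    sidecar_path = _sidecar_path(path)
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    for name in sorted(atlas.overlays):
        ov_img = nib.Nifti1Image(atlas.overlays[name].astype(np.uint8), atlas.affine)
        nib.save(ov_img, path.with_name(path.stem.split(".")[0] + f"_{name}.nii"))
    return sidecar_path


def read_atlas(path: str | Path) -> LabelAtlas:
    """Read a label NIfTI with its JSON sidecar, validating the contract."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: atlas voxel data is not integer-valued")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: atlas affine is singular")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing label sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    table = {str(k): int(v) for k, v in sidecar["labels"].items()}
    for base in BASE_STRUCTURES:
        for suf in ("_R", "_L"):
            if base + suf not in table:
                raise ValueError(f"{sidecar_path}: label table is missing {base + suf!r}")
    overlays = {}
    for name in sidecar.get("overlays", []):
        ov_path = path.with_name(path.stem.split(".")[0] + f"_{name}.nii")
        overlays[name] = np.asanyarray(nib.load(ov_path).dataobj).astype(bool)
    return LabelAtlas(np.round(data).astype(np.int16), affine, table, overlays)


LEAD_COLUMNS = ["lead_id", "hemisphere", "model", "contact_index", "is_virtual",
                "x_mm", "y_mm", "z_mm"]


def write_leads(leads: list[Lead], path: str | Path) -> None:
    """One CSV row per contact, ventralmost first within each lead."""
    rows = []
    for lead in leads:
        for idx, (pt, virt) in enumerate(zip(lead.contacts, lead.virtual_flags)):
            rows.append(
                {
                    "lead_id": lead.lead_id,
                    "hemisphere": lead.hemisphere,
                    "model": lead.model.name,
                    "contact_index": idx,
                    "is_virtual": bool(virt),
                    "x_mm": pt[0],
                    "y_mm": pt[1],
                    "z_mm": pt[2],
                }
            )
    pd.DataFrame.from_records(rows, columns=LEAD_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_leads(path: str | Path) -> list[Lead]:
    df = pd.read_csv(path)
    missing = set(LEAD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: lead table is missing columns {sorted(missing)}")
    leads = []
    for lead_id, g in df.groupby("lead_id", sort=False):
        g = g.sort_values("contact_index")
        leads.append(
            Lead(
                str(lead_id),
                str(g["hemisphere"].iloc[0]),
                get_lead_model(str(g["model"].iloc[0])),
                g[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                g["is_virtual"].to_numpy(dtype=bool),
            )
        )
    return leads


def write_frame(frame: NativeFrame, path: str | Path) -> None:
    payload = {
        "ac": [round(float(v), 6) for v in frame.ac],
        "pc": [round(float(v), 6) for v in frame.pc],
        "midline_vertex": [round(float(v), 6) for v in frame.midline_vertex],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_frame(path: str | Path) -> NativeFrame:
    d = json.loads(Path(path).read_text())
    return NativeFrame(d["ac"], d["pc"], d["midline_vertex"])


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
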