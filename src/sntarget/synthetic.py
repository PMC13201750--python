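"""Synthetic subcortical anatomy and electrode cohorts.

The generator builds a label atlas from analytic ellipsoids (subthalamic
nucleus, substantia nigra, red nucleus) rasterized on a regular mm grid,
and samples electrode cohorts whose trajectory-feature distributions mirror
the per-class means and spreads observed in clinical dual STN-SN targeting
cohorts.  It exists so every downstream stage - feature extraction,
engagement scoring, rule learning - can be exercised end-to-end with known
ground truth.

Topology emulated (right hemisphere; the left is its mirror image):

* STN: ellipsoid, partitioned into a posterodorsal motor compartment (MC)
  and an associative remainder by a quantile cut along a posterodorsal
  axis, so the MC holds a configurable fraction of STN voxels exactly.
* SN: ellipsoid ventral-posterior-medial to the STN, split by an oblique
  plane into a dorsomedial SNc strip and the SNr remainder - disjoint by
  construction.
* RN: sphere medial-posterior to the STN; its widest axial slice defines
  the max-RN reference plane.

Voxels claimed by more than one ellipsoid are resolved by priority
RN > STN > SN, so all labels are pairwise disjoint.

Cohort classes are "snr" (SNr-aimed), "snc" (SNc-aimed) and "off"
(off-target); each lead's generating intent is recorded, but ground-truth
engagement labels always come from the engagement module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .atlas import LabelAtlas
from .geometry import (
    NativeFrame,
    PlaneSpec,
    bejjani_origin,
    find_max_rn_plane,
    line_plane_intersection,
)
from .models import LEAD_MODELS, Lead, LeadModel, get_lead_model

logger = logging.getLogger(__name__)

__all__ = [
    "EllipsoidSpec",
    "AnatomyParams",
    "CohortParams",
    "make_atlas",
    "make_frame",
    "make_lead",
    "sample_cohort",
]

COHORT_CLASSES = ("snr", "snc", "off")


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned or rotated ellipsoid: center, semi-axes (mm), z-y-x Euler angles (deg)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation(self) -> np.ndarray:
        return Rotation.from_euler("zyx", self.euler_deg, degrees=True).as_matrix()

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 3) mm points."""
        local = (np.atleast_2d(points) - np.asarray(self.center)) @ self.rotation()
        return (local / np.asarray(self.semi_axes)) ** 2 @ np.ones(3) <= 1.0

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.rotation()
        extent = np.sqrt((r * np.asarray(self.semi_axes)) ** 2 @ np.ones(3))
        c = np.asarray(self.center)
        return c - extent, c + extent

    def mirrored(self) -> "EllipsoidSpec":
        cx, cy, cz = self.center
        ez, ey, ex = self.euler_deg
        return replace(self, center=(-cx, cy, cz), euler_deg=(-ez, -ey, ex))


@dataclass(frozen=True)
class AnatomyParams:
    """Right-hemisphere ellipsoid specs and frame landmarks (mm, RAS, mid-commissural origin).

    Default geometry places the STN ~12 mm lateral and ~4 mm ventral to the
    mid-commissural point, the SN ventral-posterior-medial to it, and the RN
    medially with its equator (the max-RN plane) at z = -3.  The SNc split
    plane normal points dorsomedially and is tilted so that the SNr/SNc
    boundary runs roughly parallel to typical implantation trajectories.
    """

    voxel_size_mm: float = 0.25
    stn_spec: EllipsoidSpec = EllipsoidSpec((12.0, -2.0, -4.0), (5.0, 3.5, 3.0))
    mc_fraction: float = 0.5
    mc_axis: tuple[float, float, float] = (0.0, -1.0, 1.0)  # posterodorsal
    sn_spec: EllipsoidSpec = EllipsoidSpec((9.5, -7.0, -8.0), (5.5, 4.0, 2.5))
    snc_split_normal: tuple[float, float, float] = (-1.0, -1.0, 1.17)  # dorsomedial
    snc_split_offset_mm: float = 1.4  # signed distance of split plane from SN center
    rn_spec: EllipsoidSpec = EllipsoidSpec((5.0, -8.0, -3.0), (3.5, 3.5, 3.5))
    ac: tuple[float, float, float] = (0.0, 12.5, 0.0)
    pc: tuple[float, float, float] = (0.0, -12.5, 0.0)
    midline_vertex: tuple[float, float, float] = (0.0, 0.0, 60.0)
    margin_mm: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not 0.0 < self.mc_fraction < 1.0:
            raise ValueError("mc_fraction must be in (0, 1)")
        if abs(self.rn_spec.center[0]) >= abs(self.stn_spec.center[0]):
            raise ValueError("red nucleus must be strictly medial to the STN center")
        if self.sn_spec.center[2] >= self.stn_spec.center[2]:
            raise ValueError("SN centroid must be strictly ventral to the STN centroid")


def make_frame(params: AnatomyParams) -> NativeFrame:
    return NativeFrame(params.ac, params.pc, params.midline_vertex)


def _grid(params: AnatomyParams) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric voxel grid (affine, shape) covering all structures plus margin.

    Voxel centers are symmetric under x -> -x so the left hemisphere is an
    exact voxelwise mirror of the right.
    """
    vs = params.voxel_size_mm
    specs = [params.stn_spec, params.sn_spec, params.rn_spec]
    los, his = zip(*(s.bbox() for s in specs))
    lo = np.min(los, axis=0) - params.margin_mm
    hi = np.max(his, axis=0) + params.margin_mm
    half_x = max(abs(lo[0]), abs(hi[0]))
    nx_half = int(math.ceil(half_x / vs))
    x0 = -nx_half * vs
    nx = 2 * nx_half + 1
    ny = int(math.ceil((hi[1] - lo[1]) / vs)) + 1
    nz = int(math.ceil((hi[2] - lo[2]) / vs)) + 1
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = vs
    affine[:3, 3] = (x0, lo[1], lo[2])
    return affine, np.array([nx, ny, nz])


#: label integers for the right hemisphere; left = value + 5
_RIGHT_LABELS = {"STN_MC_R": 1, "STN_assoc_R": 2, "SNr_R": 3, "SNc_R": 4, "RN_R": 5}


def make_atlas(params: AnatomyParams | None = None) -> LabelAtlas:
    """Rasterize the anatomy into an integer label volume.

    Deterministic given ``params``.  Raises if the SNc split plane leaves
    either SN compartment empty or the topology invariants are violated.
    """
    params = params or AnatomyParams()
    params.validate()
    affine, shape = _grid(params)
    ni, nj, nk = (int(s) for s in shape)
    xs = affine[0, 3] + np.arange(ni) * affine[0, 0]
    ys = affine[1, 3] + np.arange(nj) * affine[1, 1]
    zs = affine[2, 3] + np.arange(nk) * affine[2, 2]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    def mask_of(spec: EllipsoidSpec) -> np.ndarray:
        return spec.contains(points).reshape(ni, nj, nk)

    stn = mask_of(params.stn_spec)
    sn = mask_of(params.sn_spec)
    rn = mask_of(params.rn_spec)
    # priority RN > STN > SN keeps labels pairwise disjoint where ellipsoids abut
    stn &= ~rn
    sn &= ~rn & ~stn
    for name, m in (("STN", stn), ("SN", sn), ("RN", rn)):
        if not m.any():
            raise ValueError(f"{name} ellipsoid rasterizes to zero voxels")

    centers = points.reshape(ni, nj, nk, 3)

    # STN -> motor (posterodorsal fraction) + associative, by exact quantile
    mc_axis = np.asarray(params.mc_axis, dtype=float)
    mc_axis /= np.linalg.norm(mc_axis)
    stn_idx = np.argwhere(stn)
    proj = (centers[stn] - np.asarray(params.stn_spec.center)) @ mc_axis
    order = np.argsort(proj, kind="stable")
    n_mc = int(round(params.mc_fraction * len(order)))
    mc = np.zeros_like(stn)
    mc_sel = stn_idx[order[len(order) - n_mc:]]
    mc[tuple(mc_sel.T)] = True
    assoc = stn & ~mc

    # SN -> SNc (positive side of oblique split plane) + SNr
    n_split = np.asarray(params.snc_split_normal, dtype=float)
    n_split /= np.linalg.norm(n_split)
    s = (centers[sn] - np.asarray(params.sn_spec.center)) @ n_split
    snc_sel = s >= params.snc_split_offset_mm
    if not snc_sel.any() or snc_sel.all():
        raise ValueError(
            "SNc split plane leaves a compartment empty: SNr and SNc must both "
            "contain voxels (adjust snc_split_offset_mm / snc_split_normal)"
        )
    sn_idx = np.argwhere(sn)
    snc = np.zeros_like(sn)
    snc[tuple(sn_idx[snc_sel].T)] = True
    snr = sn & ~snc

    labels = np.zeros((ni, nj, nk), dtype=np.int16)
    right = {"STN_MC_R": mc, "STN_assoc_R": assoc, "SNr_R": snr, "SNc_R": snc, "RN_R": rn}
    table: dict[str, int] = {}
    for name, m in right.items():
        val = _RIGHT_LABELS[name]
        labels[m] = val
        table[name] = val
    # left hemisphere: exact mirror across the midsagittal plane (x -> -x)
    mirrored = np.flip(labels, axis=0)
    for name, val in _RIGHT_LABELS.items():
        lname = name[:-2] + "_L"
        table[lname] = val + 5
        labels[mirrored == val] = val + 5

    atlas = LabelAtlas(labels, affine, table)
    assert not (atlas.mask("SNr") & atlas.mask("SNc")).any()
    return atlas


# ------------------------------------------------------------------- cohorts


def _sind(deg: float) -> float:
    return math.sin(math.radians(deg))


def make_lead(
    model: LeadModel | str,
    target_point: np.ndarray,
    ms_angle: float,
    acpc_angle: float,
    depth_mm: float,
    frame: NativeFrame,
    lead_id: str = "lead",
    atlas: LabelAtlas | None = None,
) -> Lead:
    """Construct a lead crossing ``target_point`` at the requested plane angles.

    ``target_point`` is the (mm, world) point where the trajectory crosses
    the max-RN plane; the deepest contact center lies ``depth_mm`` of arc
    length ventral to it.  The trajectory leans laterally and anteriorly
    going dorsal, as in a standard frontal approach.  If ``atlas`` is given,
    contacts outside its volume raise an error naming the contact.
    """
    if isinstance(model, str):
        model = get_lead_model(model)
    if not (0.0 < ms_angle < 90.0 and 0.0 < acpc_angle < 90.0):
        raise ValueError("angles must lie strictly inside (0, 90) degrees")
    sx = _sind(ms_angle)
    sz = _sind(acpc_angle)
    rest = 1.0 - sx * sx - sz * sz
    if rest <= 1e-12:
        raise ValueError(
            f"angle pair (MS={ms_angle}, AC-PC={acpc_angle}) is degenerate: "
            "no anterior-leaning direction has both plane angles"
        )
    target_point = np.asarray(target_point, dtype=float)
    hemisphere = frame.hemisphere_of(target_point)
    lat = 1.0 if hemisphere == "right" else -1.0
    direction = lat * sx * frame.ex + math.sqrt(rest) * frame.ey + sz * frame.ez
    deepest = target_point - depth_mm * direction
    offsets = np.arange(model.n_levels)[:, None] * model.inter_level_spacing
    contacts = deepest + offsets * direction
    if atlas is not None:
        lo, hi = atlas.world_bounds()
        inside = np.all((contacts >= lo) & (contacts <= hi), axis=1)
        if not inside.all():
            bad = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"lead {lead_id!r}: contact {bad} at {np.round(contacts[bad], 2)} "
                "falls outside the atlas volume"
            )
    return Lead(lead_id, hemisphere, model, contacts)


def _default_feature_means() -> dict[str, tuple[float, float, float, float]]:
    # (X lateral mm, Y anterior mm, MS deg, AC-PC deg) per generating class
    return {
        "snr": (2.0, 0.45, 22.3, 50.1),
        "snc": (0.97, -0.66, 22.5, 49.2),
        "off": (-1.0, 1.5, 22.0, 50.0),
    }


def _default_feature_sds() -> dict[str, tuple[float, float, float, float]]:
    # spreads consistent with reported per-class standard errors at cohort scale
    return {
        "snr": (1.35, 1.35, 4.4, 6.4),
        "snc": (1.05, 1.05, 3.8, 5.5),
        "off": (1.2, 1.2, 4.0, 6.0),
    }


@dataclass(frozen=True)
class CohortParams:
    """Sampling distribution of a simulated implantation cohort.

    ``class_mix`` gives proportions of SNr-aimed / SNc-aimed / off-target
    leads; per-class ``feature_means`` / ``feature_sds`` parameterize the
    4-feature Gaussian (an optional 4x4 ``feature_corr`` correlation matrix
    applies to all classes).  ``implantation_depth_*`` is the arc-length
    depth (mm) of the deepest implanted contact below the max-RN plane.
    """

    n_leads: int = 612
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"snr": 0.55, "snc": 0.30, "off": 0.15}
    )
    feature_means: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_feature_means
    )
    feature_sds: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_feature_sds
    )
    feature_corr: np.ndarray | None = None
    lead_model_mix: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 / len(LEAD_MODELS) for name in LEAD_MODELS}
    )
    implantation_depth_mean: float = 4.5
    implantation_depth_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")
        for name, mix in (("class_mix", self.class_mix), ("lead_model_mix", self.lead_model_mix)):
            vals = np.array(list(mix.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} proportions must be non-negative and sum to 1")
        if set(self.class_mix) - set(COHORT_CLASSES):
            raise ValueError(f"class_mix keys must be among {COHORT_CLASSES}")
        for cls in self.class_mix:
            if cls not in self.feature_means or cls not in self.feature_sds:
                raise ValueError(f"missing feature means/sds for class {cls!r}")
            if any(s < 0 for s in self.feature_sds[cls]):
                raise ValueError("feature sds must be >= 0")
        for name in self.lead_model_mix:
            get_lead_model(name)
        if self.implantation_depth_sd < 0:
            raise ValueError("implantation_depth_sd must be >= 0")


_MAX_RESAMPLE = 200


def sample_cohort(
    atlas: LabelAtlas,
    params: CohortParams,
    frame: NativeFrame,
) -> tuple[list[Lead], pd.DataFrame]:
    """Sample a cohort of leads; returns leads plus the generating record.

    Per lead: a generating class, a lead model, a hemisphere (balanced via
    the RNG), features drawn from the class Gaussian, and an implantation
    depth.  Feature draws producing degenerate directions (trajectory
    parallel to the max-RN plane or angles outside (1, 89) degrees) are
    rejected and resampled; rejections are logged.  Deterministic given
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    classes = sorted(params.class_mix)
    class_p = np.array([params.class_mix[c] for c in classes])
    model_names = sorted(params.lead_model_mix)
    model_p = np.array([params.lead_model_mix[m] for m in model_names])

    planes: dict[str, PlaneSpec] = {}
    origins: dict[str, np.ndarray] = {}
    for hemi in ("right", "left"):
        planes[hemi] = find_max_rn_plane(atlas, frame, hemi)
        origins[hemi] = bejjani_origin(atlas, frame, hemi)

    corr = np.eye(4) if params.feature_corr is None else np.asarray(params.feature_corr)

    leads: list[Lead] = []
    records: list[dict] = []
    n_rejected = 0
    for i in range(params.n_leads):
        cls = classes[rng.choice(len(classes), p=class_p)]
        model = get_lead_model(model_names[rng.choice(len(model_names), p=model_p)])
        hemi = "right" if rng.random() < 0.5 else "left"
        mean = np.asarray(params.feature_means[cls], dtype=float)
        sd = np.asarray(params.feature_sds[cls], dtype=float)
        cov = corr * np.outer(sd, sd)
        for _ in range(_MAX_RESAMPLE):
            feats = rng.multivariate_normal(mean, cov)
            depth = rng.normal(params.implantation_depth_mean, params.implantation_depth_sd)
            x, y, ms, acpc = (float(v) for v in feats)
            if not (1.0 < ms < 89.0 and 1.0 < acpc < 89.0):
                n_rejected += 1
                continue
            if _sind(ms) ** 2 + _sind(acpc) ** 2 >= 1.0 - 1e-9:
                n_rejected += 1
                continue
            lat = 1.0 if hemi == "right" else -1.0
            target = origins[hemi] + lat * x * frame.ex + y * frame.ey
            try:
                lead = make_lead(
                    model, target, ms, acpc, depth, frame,
                    lead_id=f"lead{i:04d}", atlas=atlas,
                )
            except ValueError:
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError(
                f"could not sample a valid lead for class {cls!r} after "
                f"{_MAX_RESAMPLE} attempts; check cohort parameters"
            )
        leads.append(lead)
        records.append(
            {
                "lead_id": lead.lead_id,
                "generating_class": cls,
                "hemisphere": hemi,
                "model": model.name,
                "design_class": model.design_class,
                "x_mm": x,
                "y_mm": y,
                "ms_angle_deg": ms,
                "acpc_angle_deg": acpc,
                "implantation_depth_mm": depth,
            }
        )
    if n_rejected:
        logger.info("sample_cohort: resampled %d degenerate draws", n_rejected)
    return leads, pd.DataFrame.from_records(records)
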