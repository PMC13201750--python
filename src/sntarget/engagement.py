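"""Contact- and trajectory-level target engagement against a label atlas.

A contact *engages* a region if a 1 mm-radius sphere centered on it
intersects the region; a trajectory engages a region if any of its
(scenario-eligible) contacts does.  A contact overlapping both substantia
nigra compartments is assigned to the one with the greater overlap, so a
single contact is SNr or SNc but never both, while a trajectory may engage
both through different contacts.

Graded engagement uses the volume of activated tissue (VAT) for 1 mA
stimulation, approximated as a 2 mm-radius sphere, reported as the percent
of VAT volume overlapping the target.  Overlap volumes are estimated by
voxel-center inclusion at the atlas resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import LabelAtlas
from .geometry import NativeFrame, PlaneSpec, depth_along_trajectory, find_max_rn_plane
from .models import Lead

__all__ = [
    "SCENARIOS",
    "ContactEngagement",
    "TrajectoryEngagement",
    "VatOverlap",
    "DepthProfile",
    "sphere_mask_overlap",
    "classify_contact",
    "classify_lead_contacts",
    "engagement_from_contacts",
    "classify_trajectory",
    "build_ct",
    "vat_overlap",
    "depth_profile",
    "cohort_summary",
]

#: scenario name -> maximum virtual-extension arc length (mm) whose
#: virtual contacts count toward engagement
SCENARIOS: dict[str, float] = {
    "implanted_only": 0.0,
    "plus2mm": 2.0,
    "plus4mm": 4.0,
    "plus6mm": 6.0,
}

CONTACT_SPHERE_RADIUS_MM = 1.0
VAT_RADIUS_MM = 2.0


@dataclass(frozen=True)
class ContactEngagement:
    contact_index: int
    overlaps_mm3: dict[str, float]  # region -> sphere-overlap volume
    sn_class: str  # "SNr" | "SNc" | "none"
    is_virtual: bool


@dataclass(frozen=True)
class TrajectoryEngagement:
    lead_id: str
    scenario: str
    engaged_regions: frozenset[str]  # subset of {"SNr", "SNc", "MC", "CT"}
    contacts: tuple[ContactEngagement, ...] = ()


@dataclass(frozen=True)
class VatOverlap:
    contact_index: int
    region: str
    percent: float  # [0, 100] of VAT volume inside the region
    depth_mm: float | None = None  # arc-length depth below the max-RN plane


@dataclass(frozen=True)
class DepthProfile:
    """Per-2 mm-bin mean and SEM of VAT percent overlap for one region."""

    region: str
    table: pd.DataFrame = field(repr=False)  # bin_center, mean, sem, n


def sphere_mask_overlap(
    center: np.ndarray,
    radius_mm: float,
    atlas: LabelAtlas,
    region: str,
    hemisphere: str | None = None,
) -> float:
    """Volume (mm3) of sphere-region intersection by voxel-center inclusion."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    mask = atlas.mask(region, hemisphere)  # KeyError for unknown regions
    center = np.asarray(center, dtype=float)
    # restrict to the voxel bounding box of the sphere
    vs = atlas.voxel_size
    cijk = atlas.world_to_ijk(center)[0]
    pad = radius_mm / vs + 1.0
    lo = np.maximum(np.floor(cijk - pad).astype(int), 0)
    hi = np.minimum(np.ceil(cijk + pad).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return 0.0
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if not sub.any():
        return 0.0
    ijk = np.argwhere(sub) + lo
    centers = atlas.ijk_to_world(ijk)
    d2 = ((centers - center) ** 2).sum(axis=1)
    n_in = int((d2 <= radius_mm**2).sum())
    return n_in * atlas.voxel_volume_mm3


def classify_contact(
    contact: np.ndarray,
    atlas: LabelAtlas,
    contact_index: int = 0,
    is_virtual: bool = False,
    radius_mm: float = CONTACT_SPHERE_RADIUS_MM,
) -> ContactEngagement:
    """Sphere-rule engagement of one contact, with SNr/SNc exclusivity.

    The contact is assigned to the SN compartment with the greater sphere
    overlap; an exact nonzero tie goes to SNr with a warning.
    """
    regions = ["SNr", "SNc"]
    for optional in ("STN_MC", "CT"):
        if atlas.has_region(optional):
            regions.append(optional)
    overlaps = {r: sphere_mask_overlap(contact, radius_mm, atlas, r) for r in regions}
    snr, snc = overlaps["SNr"], overlaps["SNc"]
    if snr == 0.0 and snc == 0.0:
        sn_class = "none"
    elif snr >= snc:
        if snr == snc:
            warnings.warn(
                f"contact {contact_index}: exact SNr/SNc overlap tie "
                f"({snr:.3f} mm3); assigning SNr",
                stacklevel=2,
            )
        sn_class = "SNr"
    else:
        sn_class = "SNc"
    return ContactEngagement(contact_index, overlaps, sn_class, is_virtual)


def _eligible(lead: Lead, scenario: str) -> np.ndarray:
    """Boolean eligibility of each contact under the scenario."""
    try:
        limit = SCENARIOS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}") from None
    eligible = ~lead.virtual_flags
    if limit > 0 and lead.virtual_flags.any():
        ventral_implanted = lead.implanted_contacts[0]
        ext = np.linalg.norm(lead.contacts - ventral_implanted, axis=1)
        eligible |= lead.virtual_flags & (ext <= limit + 1e-9)
    return eligible


def classify_lead_contacts(lead: Lead, atlas: LabelAtlas) -> tuple[ContactEngagement, ...]:
    """Classify every contact of a lead (virtual contacts included)."""
    return tuple(
        classify_contact(
            lead.contacts[idx], atlas, contact_index=int(idx),
            is_virtual=bool(lead.virtual_flags[idx]),
        )
        for idx in range(lead.n_contacts)
    )


def engagement_from_contacts(
    lead: Lead, contacts: tuple[ContactEngagement, ...], scenario: str
) -> TrajectoryEngagement:
    """Union of already-classified contact engagements under a scenario."""
    eligible = _eligible(lead, scenario)
    engaged: set[str] = set()
    kept = []
    for ce in contacts:
        if not eligible[ce.contact_index]:
            continue
        kept.append(ce)
        if ce.sn_class != "none":
            engaged.add(ce.sn_class)
        if ce.overlaps_mm3.get("STN_MC", 0.0) > 0:
            engaged.add("MC")
        if ce.overlaps_mm3.get("CT", 0.0) > 0:
            engaged.add("CT")
    return TrajectoryEngagement(lead.lead_id, scenario, frozenset(engaged), tuple(kept))


def classify_trajectory(lead: Lead, atlas: LabelAtlas, scenario: str = "implanted_only") -> TrajectoryEngagement:
    """Union of contact engagements over scenario-eligible contacts."""
    _eligible(lead, scenario)  # validate the scenario name up front
    return engagement_from_contacts(lead, classify_lead_contacts(lead, atlas), scenario)


# ------------------------------------------------------------------ central target


def build_ct(atlas: LabelAtlas, band_mm: float = 0.75) -> LabelAtlas:
    """Add the central-target (CT) overlay near the MC-associative boundary.

    Per hemisphere: STN voxels whose center lies within ``band_mm`` of any
    voxel-face boundary between the motor and associative compartments form
    a band; the most ventral 50% of the band (by voxel-center z rank, ties
    at the median retained dorsally) is excluded.  The CT overlaps the STN
    compartments, so it is stored as an overlay mask, not an integer label.
    """
    out = atlas
    for hemi, suffix in (("right", "_R"), ("left", "_L")):
        mc = atlas.mask("STN_MC", hemi)
        assoc = atlas.mask("STN_assoc", hemi)
        if not mc.any() or not assoc.any():
            raise ValueError(f"hemisphere {hemi}: needs both STN_MC and STN_assoc labels")
        boundary_pts = _boundary_face_centers(atlas, mc, assoc)
        if len(boundary_pts) == 0:
            raise ValueError(f"hemisphere {hemi}: no MC-associative boundary found")
        stn = mc | assoc
        stn_ijk = np.argwhere(stn)
        stn_xyz = atlas.ijk_to_world(stn_ijk)
        dist, _ = cKDTree(boundary_pts).query(stn_xyz, k=1)
        band_sel = dist <= band_mm
        band_ijk = stn_ijk[band_sel]
        band_z = stn_xyz[band_sel][:, 2]
        n_keep = math.ceil(0.5 * len(band_ijk))
        order = np.argsort(-band_z, kind="stable")  # dorsal first
        keep = band_ijk[order[:n_keep]]
        ct = np.zeros(atlas.labels.shape, dtype=bool)
        ct[tuple(keep.T)] = True
        out = out.with_overlay("CT" + suffix, ct)
    return out


def _boundary_face_centers(atlas: LabelAtlas, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Midpoints (mm) of shared faces between voxels of masks ``a`` and ``b``."""
    pts = []
    for axis in range(3):
        # a-voxels with a b-neighbour one step along +/- axis
        for shift in (1, -1):
            shifted = np.roll(b, -shift, axis=axis)
            # voxels rolled across the array edge are not neighbours
            edge = [slice(None)] * 3
            edge[axis] = slice(-1, None) if shift == 1 else slice(0, 1)
            shifted[tuple(edge)] = False
            ijk = np.argwhere(a & shifted).astype(float)
            if len(ijk):
                ijk[:, axis] += 0.5 * shift
                pts.append(atlas.ijk_to_world(ijk))
    if not pts:
        return np.empty((0, 3))
    return np.unique(np.vstack(pts), axis=0)


# ------------------------------------------------------------------ graded (VAT)


def vat_overlap(
    contact: np.ndarray,
    atlas: LabelAtlas,
    region: str,
    radius_mm: float = VAT_RADIUS_MM,
    contact_index: int = 0,
    depth_mm: float | None = None,
) -> VatOverlap:
    """Percent of the spherical VAT volume overlapping ``region``."""
    vol = sphere_mask_overlap(contact, radius_mm, atlas, region)
    full = 4.0 / 3.0 * math.pi * radius_mm**3
    percent = float(np.clip(100.0 * vol / full, 0.0, 100.0))
    return VatOverlap(contact_index, region, percent, depth_mm)


def depth_bin_center(depth_mm: float, bin_width: float = 2.0) -> float:
    """Center of the half-open depth bin [c - w/2, c + w/2) containing ``depth_mm``."""
    return bin_width * math.floor(depth_mm / bin_width + 0.5)


def depth_profile(
    leads: list[Lead],
    atlas: LabelAtlas,
    frame: NativeFrame,
    region: str,
    scenario: str = "plus6mm",
    radius_mm: float = VAT_RADIUS_MM,
    bin_width: float = 2.0,
) -> DepthProfile:
    """Mean (+/- SEM) VAT percent overlap per 2 mm depth bin across contacts.

    Depth is arc length along each trajectory below the ipsilateral max-RN
    plane, ventral-positive.  Bins with no contacts are absent from the
    table, not reported as zero.
    """
    planes: dict[str, PlaneSpec] = {}
    rows = []
    for lead in leads:
        if lead.hemisphere not in planes:
            planes[lead.hemisphere] = find_max_rn_plane(atlas, frame, lead.hemisphere)
        plane = planes[lead.hemisphere]
        for idx in np.flatnonzero(_eligible(lead, scenario)):
            contact = lead.contacts[idx]
            d = depth_along_trajectory(contact, lead, plane)
            ov = vat_overlap(contact, atlas, region, radius_mm, int(idx), d)
            rows.append({"bin_center": depth_bin_center(d, bin_width), "percent": ov.percent})
    df = pd.DataFrame.from_records(rows)
    grouped = (
        df.groupby("bin_center")["percent"]
        .agg(mean="mean", sem=lambda s: float(s.sem(ddof=1)) if len(s) > 1 else 0.0, n="size")
        .reset_index()
    )
    return DepthProfile(region, grouped)


# ------------------------------------------------------------------- summaries

SUMMARY_REGIONS = ("SNr", "SNc", "MC", "CT")


def cohort_summary(
    engagements: list[TrajectoryEngagement],
    design_by_lead: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Engagement-rate table stratified by scenario and lead design class.

    One row per (scenario, design stratum); design strata are "all" plus
    any design classes provided via ``design_by_lead``.  Rates are simple
    fractions of trajectories; counts are reported alongside.
    """
    if not engagements:
        raise ValueError("need at least one trajectory engagement")
    recs = []
    for te in engagements:
        design = design_by_lead.get(te.lead_id, "unknown") if design_by_lead else "all"
        recs.append(
            {
                "scenario": te.scenario,
                "design_class": design,
                "SNr": "SNr" in te.engaged_regions,
                "SNc": "SNc" in te.engaged_regions,
                "MC": "MC" in te.engaged_regions,
                "CT": "CT" in te.engaged_regions,
            }
        )
    df = pd.DataFrame.from_records(recs)
    df["both"] = df["SNr"] & df["SNc"]
    df["none_sn"] = ~df["SNr"] & ~df["SNc"]

    out_rows = []
    for scenario, sdf in df.groupby("scenario", sort=True):
        strata = [("all", sdf)]
        if design_by_lead:
            strata += [(d, g) for d, g in sdf.groupby("design_class", sort=True)]
        for stratum, g in strata:
            row = {"scenario": scenario, "design_class": stratum, "n": len(g)}
            for col in ("SNr", "SNc", "both", "none_sn", "MC", "CT"):
                row[f"{col}_count"] = int(g[col].sum())
                row[f"{col}_rate"] = float(g[col].mean())
            out_rows.append(row)
    return pd.DataFrame.from_records(out_rows)
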