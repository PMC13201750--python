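"""Coordinate frames and trajectory geometry.

All coordinates are mm, RAS (x right+, y anterior+, z dorsal+).  The
stereotactic frame is defined by the anterior commissure (AC), posterior
commissure (PC) and a midline vertex point: the midsagittal plane contains
all three landmarks, the AC-PC plane contains the AC-PC line and the
frame's left-right axis, and axial planes are constant-z planes of the
frame basis.

The per-hemisphere reference objects are the *max-RN plane* (the axial
slice where the ipsilateral red nucleus cross-section is largest) and the
*Bejjani origin* (the intersection, in that slice, of Bejjani's line - the
line parallel to the midsagittal plane tangent to the anterior border of
the red nucleus - with the medial border of the STN).  Trajectory features
are the in-plane offsets (X lateral+, Y anterior+) of the trajectory's
crossing of the max-RN plane from the Bejjani origin, plus the angles of
the trajectory to the midsagittal and AC-PC planes.

Angle convention: the angle between a line l and a plane with unit normal
n is 90 deg minus the angle between l and n, folded into [0, 90]; this is
the acute angle the line makes with the plane itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import LabelAtlas
from .models import Lead

__all__ = [
    "PlaneSpec",
    "NativeFrame",
    "TrajectoryFeatures",
    "trajectory_norm",
    "angle_to_plane",
    "extend_virtual",
    "find_max_rn_plane",
    "bejjani_origin",
    "extract_features",
    "depth_along_trajectory",
    "line_plane_intersection",
]


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError(f"{what} must be non-zero and finite")
    return v / n


@dataclass(frozen=True)
class PlaneSpec:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.point) @ self.normal


@dataclass
class NativeFrame:
    """AC/PC/midline landmarks and the planes they induce.

    The orthonormal basis (ex, ey, ez) has ey along PC->AC (anterior+),
    ex along the midsagittal normal with a positive rightward component,
    and ez = ex x ey (dorsal+).
    """

    ac: np.ndarray
    pc: np.ndarray
    midline_vertex: np.ndarray
    _basis: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        self.midline_vertex = np.asarray(self.midline_vertex, dtype=float)
        acpc = self.ac - self.pc
        if np.linalg.norm(acpc) < 1e-9:
            raise ValueError("AC and PC coincide")
        ey = _unit(acpc)
        off_line = self.midline_vertex - self.ac
        ms_normal = np.cross(-acpc, off_line)
        if np.linalg.norm(ms_normal) < 1e-9:
            raise ValueError("midline vertex lies on the AC-PC line")
        ex = _unit(ms_normal)
        if ex[0] < 0:  # orient left->right so +x is the anatomical right
            ex = -ex
        ez = np.cross(ex, ey)
        self._basis = np.stack([ex, ey, ez])

    @property
    def ex(self) -> np.ndarray:
        return self._basis[0]

    @property
    def ey(self) -> np.ndarray:
        return self._basis[1]

    @property
    def ez(self) -> np.ndarray:
        return self._basis[2]

    @property
    def midsagittal_plane(self) -> PlaneSpec:
        return PlaneSpec(self.ac, self.ex)

    @property
    def acpc_plane(self) -> PlaneSpec:
        return PlaneSpec(self.ac, self.ez)

    def hemisphere_of(self, point: np.ndarray) -> str:
        d = float(self.midsagittal_plane.signed_distance(point)[0])
        return "right" if d >= 0 else "left"


@dataclass(frozen=True)
class TrajectoryFeatures:
    """The 4-feature description of a trajectory.

    X/Y are mm offsets of the trajectory's max-RN-plane crossing from the
    Bejjani origin, with lateral and anterior positive (left-hemisphere X
    is reflected so lateral is positive in both hemispheres).  Angles are
    line-to-plane angles in degrees, in [0, 90].
    """

    x_mm: float
    y_mm: float
    ms_angle: float
    acpc_angle: float

    def __post_init__(self) -> None:
        for name in ("x_mm", "y_mm", "ms_angle", "acpc_angle"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"feature {name} is not finite")
        for name in ("ms_angle", "acpc_angle"):
            a = getattr(self, name)
            if not 0.0 <= a <= 90.0:
                raise ValueError(f"{name}={a} outside [0, 90] degrees")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm, self.ms_angle, self.acpc_angle])


# --------------------------------------------------------------------- lines


def trajectory_norm(lead: Lead) -> np.ndarray:
    """Unit direction of the implantation path, ventralmost toward dorsalmost."""
    d = lead.dorsalmost - lead.ventralmost
    return _unit(d, "trajectory (ventralmost and dorsalmost contacts coincide)")


def angle_to_plane(l: np.ndarray, plane: PlaneSpec) -> float:
    """Acute angle (degrees) between the line along ``l`` and ``plane``.

    Computed as 90 deg minus the angle between the line and the plane
    normal; symmetric under flipping either vector.
    """
    l = _unit(l, "direction")
    cos_to_normal = min(1.0, abs(float(l @ plane.normal)))
    return 90.0 - math.degrees(math.acos(cos_to_normal))


def line_plane_intersection(point: np.ndarray, direction: np.ndarray, plane: PlaneSpec) -> np.ndarray:
    """Intersection of the line through ``point`` along ``direction`` with ``plane``."""
    direction = np.asarray(direction, dtype=float)
    denom = float(direction @ plane.normal)
    if abs(denom) < 1e-12:
        raise ValueError("trajectory is parallel to the plane")
    t = float((plane.point - point) @ plane.normal) / denom
    return np.asarray(point, dtype=float) + t * direction


def extend_virtual(lead: Lead, extensions_mm: tuple[float, ...] = (2.0, 4.0, 6.0)) -> Lead:
    """Add virtual contacts ``extensions_mm`` beyond the ventralmost contact.

    Virtual contacts simulate deeper implantation or longer contact arrays:
    each lies the stated arc length past the ventralmost implanted contact
    along the ventral continuation of the trajectory.  Returned contacts
    stay ordered ventralmost first (deepest virtual contact at index 0).
    """
    ext = [float(e) for e in extensions_mm]
    if any(e <= 0 for e in ext) or any(b <= a for a, b in zip(ext, ext[1:])):
        raise ValueError("extensions must be positive and strictly increasing")
    direction = trajectory_norm(lead)
    ventral = lead.ventralmost
    new_contacts = [ventral - e * direction for e in reversed(ext)]
    contacts = np.vstack([new_contacts, lead.contacts])
    flags = np.concatenate([np.ones(len(ext), dtype=bool), lead.virtual_flags])
    return Lead(lead.lead_id, lead.hemisphere, lead.model, contacts, flags)


# --------------------------------------------------------------- atlas planes


def _axial_axis(atlas: LabelAtlas, frame: NativeFrame) -> int:
    """Voxel axis aligned with the frame's z (axial) direction.

    The atlas grid must have one voxel axis parallel to the frame z-axis
    within ~0.5 deg so that axial slices coincide with voxel slabs.
    """
    cols = atlas.affine[:3, :3] / np.linalg.norm(atlas.affine[:3, :3], axis=0)
    dots = np.abs(cols.T @ frame.ez)
    axis = int(np.argmax(dots))
    if dots[axis] < 0.99996:
        raise ValueError("atlas grid is not aligned with the frame's axial direction")
    return axis


def _frame_key(frame: NativeFrame) -> bytes:
    return frame.ac.tobytes() + frame.pc.tobytes() + frame.midline_vertex.tobytes()


def find_max_rn_plane(atlas: LabelAtlas, frame: NativeFrame, hemisphere: str) -> PlaneSpec:
    """Axial plane of the largest ipsilateral red-nucleus cross-section.

    Ties are broken toward the more ventral slice.
    """
    cache_key = ("max_rn_plane", hemisphere, _frame_key(frame))
    if cache_key in atlas._mask_cache:
        return atlas._mask_cache[cache_key]
    rn = atlas.mask("RN", hemisphere)
    if not rn.any():
        raise ValueError(f"no red-nucleus voxels for hemisphere {hemisphere!r}")
    axis = _axial_axis(atlas, frame)
    counts = rn.sum(axis=tuple(i for i in range(3) if i != axis))
    # slice z (frame coordinates) for each voxel index along the axial axis
    idx_grid = np.zeros((len(counts), 3))
    idx_grid[:, axis] = np.arange(len(counts))
    slice_z = (atlas.ijk_to_world(idx_grid) - frame.ac) @ frame.ez
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    k = tied[np.argmin(slice_z[tied])]  # ventral tie-break
    ijk = np.zeros(3)
    ijk[axis] = k
    point = atlas.ijk_to_world(ijk)[0]
    plane = PlaneSpec(point, frame.ez)
    atlas._mask_cache[cache_key] = plane
    return plane


def bejjani_origin(
    atlas: LabelAtlas,
    frame: NativeFrame,
    hemisphere: str,
    y_band_mm: float = 0.5,
) -> np.ndarray:
    """Intersection of Bejjani's line with the medial STN border.

    In the max-RN axial slice, Bejjani's line runs parallel to the
    midsagittal plane through the anterior-most ipsilateral RN voxel
    center.  The medial STN border is operationalized as the most medial
    STN voxel center whose frame-y coordinate lies within ``y_band_mm`` of
    the line.
    """
    cache_key = ("bejjani_origin", hemisphere, y_band_mm, _frame_key(frame))
    if cache_key in atlas._mask_cache:
        return atlas._mask_cache[cache_key]
    plane = find_max_rn_plane(atlas, frame, hemisphere)
    axis = _axial_axis(atlas, frame)
    # voxel index of the max-RN slab
    k = int(np.round(atlas.world_to_ijk(plane.point)[0][axis]))

    def slice_centers(region: str) -> np.ndarray:
        mask = atlas.mask(region, hemisphere)
        sl = [slice(None)] * 3
        sl[axis] = slice(k, k + 1)
        sub = np.zeros_like(mask)
        sub[tuple(sl)] = mask[tuple(sl)]
        return atlas.voxel_centers(sub)

    rn_pts = slice_centers("RN")
    if len(rn_pts) == 0:
        raise ValueError("red nucleus absent from its own max-RN slice")
    stn_pts = slice_centers("STN")
    if len(stn_pts) == 0:
        raise ValueError(f"no STN voxels in the max-RN slice for {hemisphere!r}")

    rn_y = (rn_pts - frame.ac) @ frame.ey
    line_y = float(rn_y.max())  # anterior tangent of the RN

    stn_y = (stn_pts - frame.ac) @ frame.ey
    in_band = np.abs(stn_y - line_y) <= y_band_mm
    if not in_band.any():
        gap = float(np.min(np.abs(stn_y - line_y)))
        raise ValueError(
            f"Bejjani's line misses the STN in the max-RN slice for {hemisphere!r}: "
            f"closest STN voxel is {gap:.2f} mm from the line (band {y_band_mm} mm)"
        )
    stn_x = (stn_pts - frame.ac) @ frame.ex
    sign = 1.0 if hemisphere == "right" else -1.0
    medial_idx = np.flatnonzero(in_band)[np.argmin(sign * stn_x[in_band])]
    x_med = float(stn_x[medial_idx])
    # origin sits at (medial STN x, Bejjani line y) within the max-RN plane
    z = float((plane.point - frame.ac) @ frame.ez)
    origin = frame.ac + x_med * frame.ex + line_y * frame.ey + z * frame.ez
    atlas._mask_cache[cache_key] = origin
    return origin


# ------------------------------------------------------------------ features


def extract_features(lead: Lead, atlas: LabelAtlas, frame: NativeFrame) -> TrajectoryFeatures:
    """Trajectory features: max-RN-plane crossing offsets and plane angles."""
    hemi = lead.hemisphere
    plane = find_max_rn_plane(atlas, frame, hemi)
    origin = bejjani_origin(atlas, frame, hemi)
    direction = trajectory_norm(lead)
    crossing = line_plane_intersection(lead.ventralmost, direction, plane)
    offset = crossing - origin
    lateral_sign = 1.0 if hemi == "right" else -1.0
    x = lateral_sign * float(offset @ frame.ex)
    y = float(offset @ frame.ey)
    ms = angle_to_plane(direction, frame.midsagittal_plane)
    acpc = angle_to_plane(direction, frame.acpc_plane)
    return TrajectoryFeatures(x, y, ms, acpc)


def depth_along_trajectory(contact: np.ndarray, lead: Lead, max_rn_plane: PlaneSpec) -> float:
    """Signed arc length from the plane crossing to ``contact``, ventral-positive.

    Depth is measured along the trajectory, not along the z-axis, so a
    contact 2 mm below the plane on an oblique trajectory is more than
    2 mm deep.
    """
    direction = trajectory_norm(lead)
    crossing = line_plane_intersection(lead.ventralmost, direction, max_rn_plane)
    # direction points ventral->dorsal; below the plane means against it
    return -float((np.asarray(contact, dtype=float) - crossing) @ direction)
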