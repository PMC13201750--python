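"""Integer label volumes of subcortical anatomy.

A :class:`LabelAtlas` holds a voxel grid of integer anatomical labels with a
mm<->voxel affine.  Labels are per structure and hemisphere (``STN_MC_R``,
``SNr_L``, ...).  The STN proper is the union of its motor (``STN_MC``) and
associative (``STN_assoc``) compartments, which partition it.  Regions that
overlap the base labels (the central target ``CT``) are stored as boolean
overlay masks rather than integer labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelAtlas", "REGION_BASES", "BASE_STRUCTURES"]

#: Structure base names that must be present (per hemisphere) in any atlas.
BASE_STRUCTURES = ("STN_MC", "STN_assoc", "SNr", "SNc", "RN")

#: Region name -> base labels whose union defines the region.
REGION_BASES: dict[str, tuple[str, ...]] = {
    "STN": ("STN_MC", "STN_assoc"),
    "STN_MC": ("STN_MC",),
    "MC": ("STN_MC",),
    "STN_assoc": ("STN_assoc",),
    "SN": ("SNr", "SNc"),
    "SNr": ("SNr",),
    "SNc": ("SNc",),
    "RN": ("RN",),
}

_HEMI_SUFFIX = {"right": "_R", "left": "_L"}


@dataclass
class LabelAtlas:
    """Voxel grid of integer anatomical labels with a mm<->voxel affine."""

    labels: np.ndarray  # (ni, nj, nk) integer array, 0 = background
    affine: np.ndarray  # 4x4 voxel -> mm (RAS)
    label_table: dict[str, int]  # e.g. {"STN_MC_R": 1, ...}
    overlays: dict[str, np.ndarray] = field(default_factory=dict)  # bool masks
    _mask_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("atlas data must be integer labels")
            self.labels = np.round(self.labels).astype(np.int16)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("atlas affine is singular")
        values = list(self.label_table.values())
        if len(set(values)) != len(values):
            raise ValueError("label_table assigns one integer to two names")

    # ------------------------------------------------------------------ geometry
    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def ijk_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_ijk(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) mm corners of the voxel-center grid."""
        shape = np.array(self.labels.shape) - 1
        corners = np.array(
            [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])],
            dtype=float,
        )
        world = self.ijk_to_world(corners)
        return world.min(axis=0), world.max(axis=0)

    # ------------------------------------------------------------------ regions
    def label_ids(self, region: str, hemisphere: str | None = None) -> list[int]:
        """Integer labels making up ``region``, optionally one hemisphere."""
        if region in REGION_BASES:
            bases = REGION_BASES[region]
        elif region in self.label_table or any(
            region + s in self.label_table for s in _HEMI_SUFFIX.values()
        ):
            bases = (region,)
        else:
            known = sorted(set(REGION_BASES) | set(self.label_table))
            raise KeyError(f"unknown region {region!r}; known: {known}")
        suffixes = [_HEMI_SUFFIX[hemisphere]] if hemisphere else list(_HEMI_SUFFIX.values())
        ids = [
            self.label_table[base + suf]
            for base in bases
            for suf in suffixes
            if base + suf in self.label_table
        ]
        if not ids and region not in self.overlays_region_names():
            raise KeyError(f"region {region!r} has no labels in this atlas")
        return ids

    def overlays_region_names(self) -> set[str]:
        return {name.rsplit("_", 1)[0] for name in self.overlays}

    def mask(self, region: str, hemisphere: str | None = None) -> np.ndarray:
        """Boolean voxel mask of ``region`` (union over hemispheres by default).

        Masks are cached per (region, hemisphere); treat them as read-only.
        """
        key = (region, hemisphere)
        if key in self._mask_cache:
            return self._mask_cache[key]
        out = self._compute_mask(region, hemisphere)
        self._mask_cache[key] = out
        return out

    def _compute_mask(self, region: str, hemisphere: str | None) -> np.ndarray:
        base = region
        suffixes = [_HEMI_SUFFIX[hemisphere]] if hemisphere else list(_HEMI_SUFFIX.values())
        overlay_names = [base + s for s in suffixes if base + s in self.overlays]
        if overlay_names:
            out = np.zeros(self.labels.shape, dtype=bool)
            for name in overlay_names:
                out |= self.overlays[name]
            return out
        ids = self.label_ids(region, hemisphere)
        return np.isin(self.labels, ids)

    def has_region(self, region: str, hemisphere: str | None = None) -> bool:
        try:
            return bool(self.mask(region, hemisphere).any())
        except KeyError:
            return False

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """World mm coordinates of the centers of voxels where ``mask`` is true."""
        ijk = np.argwhere(mask)
        if len(ijk) == 0:
            return np.empty((0, 3))
        return self.ijk_to_world(ijk)

    def with_overlay(self, name: str, mask: np.ndarray) -> "LabelAtlas":
        """Return a copy sharing the label volume, with ``mask`` added as overlay."""
        if mask.shape != self.labels.shape:
            raise ValueError("overlay shape must match label volume")
        overlays = dict(self.overlays)
        overlays[name] = np.asarray(mask, dtype=bool)
        return LabelAtlas(self.labels, self.affine, dict(self.label_table), overlays)
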