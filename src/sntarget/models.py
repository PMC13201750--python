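"""DBS lead models and the in-memory lead representation.

A *lead* is an implanted (or simulated) electrode described by the ordered
centers of its contact levels, ventralmost first.  Lead models are drawn
from a registry of commercially available electrodes; a model is classified
as ``extended`` if it has more than four contact levels or an inter-level
spacing greater than 0.5 mm, otherwise ``standard``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LeadModel", "Lead", "LEAD_MODELS", "get_lead_model"]

#: Maximum allowed perpendicular deviation (mm) of any contact from the
#: line fitted through all contacts.
COLLINEARITY_TOL_MM = 0.1


@dataclass(frozen=True)
class LeadModel:
    """An electrode model: contact-level count and spacing.

    ``design_class`` is derived, never passed: ``extended`` iff
    ``n_levels > 4`` or ``inter_level_spacing > 0.5`` mm.
    """

    name: str
    n_levels: int
    inter_level_spacing: float  # mm between adjacent contact levels

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"lead model {self.name!r}: n_levels must be >= 2")
        if self.inter_level_spacing <= 0:
            raise ValueError(f"lead model {self.name!r}: spacing must be > 0")

    @property
    def design_class(self) -> str:
        if self.n_levels > 4 or self.inter_level_spacing > 0.5:
            return "extended"
        return "standard"

    @property
    def array_span_mm(self) -> float:
        """Distance from ventralmost to dorsalmost contact level."""
        return (self.n_levels - 1) * self.inter_level_spacing


#: Registry of the electrode models supported by the cohort simulator.
LEAD_MODELS: dict[str, LeadModel] = {
    m.name: m
    for m in (
        LeadModel("Boston Scientific Vercise Cartesia X", 6, 0.5),
        LeadModel("Boston Scientific Vercise Directed", 4, 0.5),
        LeadModel("Medtronic 3387", 4, 1.5),
        LeadModel("Medtronic 3389", 4, 0.5),
        LeadModel("Medtronic B33005", 4, 0.5),
        LeadModel("Medtronic B33015", 4, 1.5),
        LeadModel("Abbott/St. Jude Directed 6172", 4, 0.5),
        LeadModel("Abbott/St. Jude Directed 6173", 4, 1.5),
    )
}


def get_lead_model(name: str) -> LeadModel:
    try:
        return LEAD_MODELS[name]
    except KeyError:
        known = ", ".join(sorted(LEAD_MODELS))
        raise KeyError(f"unknown lead model {name!r}; known models: {known}") from None


def _max_line_deviation(points: np.ndarray) -> float:
    """Max perpendicular distance of ``points`` from their least-squares line."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    perp = centered - np.outer(centered @ direction, direction)
    return float(np.linalg.norm(perp, axis=1).max())


@dataclass
class Lead:
    """An electrode trajectory: ordered contact centers, ventralmost first.

    ``contacts`` is an (n, 3) array of mm RAS coordinates; index 0 is the
    ventralmost (deepest) contact.  ``virtual_flags`` marks contacts created
    by virtual trajectory extension rather than physically implanted.
    """

    lead_id: str
    hemisphere: str  # "left" | "right"
    model: LeadModel
    contacts: np.ndarray
    virtual_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=float)
        if self.contacts.ndim != 2 or self.contacts.shape[1] != 3:
            raise ValueError("contacts must be an (n, 3) array of mm coordinates")
        if len(self.contacts) < 2:
            raise ValueError("a lead needs at least 2 contacts")
        if not np.all(np.isfinite(self.contacts)):
            raise ValueError("contact coordinates must be finite")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.virtual_flags is None:
            self.virtual_flags = np.zeros(len(self.contacts), dtype=bool)
        self.virtual_flags = np.asarray(self.virtual_flags, dtype=bool)
        if len(self.virtual_flags) != len(self.contacts):
            raise ValueError("virtual_flags length must match contacts")
        dev = _max_line_deviation(self.contacts)
        if dev > COLLINEARITY_TOL_MM:
            raise ValueError(
                f"lead {self.lead_id!r}: contacts deviate {dev:.3f} mm from a "
                f"straight line (tolerance {COLLINEARITY_TOL_MM} mm)"
            )

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def implanted_contacts(self) -> np.ndarray:
        return self.contacts[~self.virtual_flags]

    @property
    def ventralmost(self) -> np.ndarray:
        return self.contacts[0]

    @property
    def dorsalmost(self) -> np.ndarray:
        return self.contacts[-1]
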