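"""Regions of interest (ROIs) and the fixation-to-ROI assignment rules.

An ROI is an expert-annotated polygon with a semantic label on a stimulus
image.  A fixation centroid can fall inside zero, one or several (possibly
overlapping) ROI polygons; :func:`assign_roi` resolves every fixation to
exactly one label:

1. inside exactly one polygon -> that polygon's label;
2. inside several overlapping polygons -> the polygon with minimal area
   (the most specific region);
3. inside none -> the ROI whose boundary is closest (Euclidean
   point-to-boundary distance).

Ties are broken deterministically: rule 2 by lexicographically smaller
label; rule 1 by smaller polygon area, then label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from shapely.geometry import Point, Polygon

__all__ = ["Roi", "RoiSet", "assign_roi"]


@dataclass(frozen=True)
class Roi:
    """A labelled polygonal region of interest.

    Parameters
    ----------
    label
        Unique symbol within a :class:`RoiSet`.
    vertices
        Ordered polygon vertices in pixel coordinates (0-based, y grows
        downward).  Must form a simple polygon with >= 3 vertices.
    gap_penalty
        Non-negative penalty charged when this ROI is visited in one case
        but has no counterpart in the case it is compared against.
    ontology_class
        Optional semantic class used to match corresponding nodes across
        images (e.g. two rib ROIs on different stimuli).
    """

    label: str
    vertices: tuple[tuple[float, float], ...]
    gap_penalty: float = 1.0
    ontology_class: Optional[str] = None
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError(f"ROI {self.label!r}: polygon needs >= 3 vertices")
        if self.gap_penalty < 0:
            raise ValueError(f"ROI {self.label!r}: gap_penalty must be >= 0")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"ROI {self.label!r}: polygon must be simple and non-degenerate")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        return self._polygon.area

    def contains_point(self, x: float, y: float) -> bool:
        """Containment test; boundary points count as inside."""
        return self._polygon.covers(Point(x, y))

    def boundary_distance(self, x: float, y: float) -> float:
        """Euclidean distance from a point to the polygon boundary."""
        return self._polygon.exterior.distance(Point(x, y))


class RoiSet:
    """An ordered collection of ROIs over one image, unique by label."""

    def __init__(self, rois: Iterable[Roi]):
        rois = list(rois)
        labels = [r.label for r in rois]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels in RoiSet")
        self._rois: dict[str, Roi] = {r.label: r for r in rois}

    def __len__(self) -> int:
        return len(self._rois)

    def __iter__(self) -> Iterator[Roi]:
        return iter(self._rois.values())

    def __getitem__(self, label: str) -> Roi:
        return self._rois[label]

    def __contains__(self, label: str) -> bool:
        return label in self._rois

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._rois)

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        """Load a JSON array of ``{label, vertices, gap_penalty?, ontology_class?}``."""
        with open(path) as fh:
            records = json.load(fh)
        return cls(
            Roi(
                label=rec["label"],
                vertices=tuple(tuple(v) for v in rec["vertices"]),
                gap_penalty=rec.get("gap_penalty", 1.0),
                ontology_class=rec.get("ontology_class"),
            )
            for rec in records
        )

    def to_json(self, path: str | Path) -> None:
        records = []
        for roi in self:
            rec: dict = {"label": roi.label, "vertices": [list(v) for v in roi.vertices]}
            if roi.gap_penalty != 1.0:
                rec["gap_penalty"] = roi.gap_penalty
            if roi.ontology_class is not None:
                rec["ontology_class"] = roi.ontology_class
            records.append(rec)
        Path(path).write_text(json.dumps(records, indent=1))


def assign_roi(centroid: Sequence[float], rois: RoiSet) -> str:
    """Assign a fixation centroid to a unique ROI label.

    Applies the three assignment rules described in the module docstring.
    Raises ``ValueError`` on an empty :class:`RoiSet`.
    """
    if len(rois) == 0:
        raise ValueError("cannot assign fixations with an empty RoiSet")
    x, y = float(centroid[0]), float(centroid[1])
    containing = [r for r in rois if r.contains_point(x, y)]
    if len(containing) == 1:
        return containing[0].label
    if len(containing) > 1:
        return min(containing, key=lambda r: (r.area, r.label)).label
    return min(rois, key=lambda r: (r.boundary_distance(x, y), r.area, r.label)).label
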