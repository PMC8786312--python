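"""Non-numerical magnitudes of dot arrays and congruency coding.

The continuous magnitudes that covary with numerosity are: total dot area,
total perimeter, mean radius, convex-hull area, mean inter-dot distance,
density and sparsity.  The convex hull is taken over the dot *outlines*
(each centre buffered by its radius) rather than the bare centres, so that
hull area is well defined even for two-dot arrays.

Congruency coding follows the six-condition scheme: for each control
condition, every uncontrolled magnitude either increases with numerosity
(congruent, ``C``), decreases (incongruent, ``IC``) or is equated (``EQ``).
The congruency *level* of a condition is the number of congruent variables
(1-3 here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Point
from shapely.ops import unary_union

from .stimgen import ControlCondition, DotArray, Geometry, Spatial, StimulusPair

__all__ = [
    "MagnitudeVector",
    "CongruencyCode",
    "compute_magnitudes",
    "congruency_level",
    "congruency_direction",
    "disk_hull_area",
    "mean_nn_dist",
    "UndefinedMagnitudeError",
    "CONGRUENCY_TABLE",
]

#: shapely buffer resolution (segments per quarter circle) for disk outlines
_BUFFER_QUAD_SEGS = 64


class UndefinedMagnitudeError(ValueError):
    """A magnitude was requested that is undefined for this array."""


@dataclass(frozen=True)
class MagnitudeVector:
    """The non-numerical magnitudes of one dot array (mm-based units)."""

    numerosity: int
    total_area: float  # mm^2, sum of pi r^2
    total_perimeter: float  # mm, sum of 2 pi r
    mean_radius: float  # mm
    hull_area: float  # mm^2, convex hull of the dot outlines
    mean_nn_dist: float  # mm, mean nearest-neighbour centre distance (nan for n=1)
    density: float  # dots / mm^2 of hull
    sparsity: float  # mm^2 of hull / dot


@dataclass(frozen=True)
class CongruencyCode:
    """Table row for a control condition: per-variable C/IC/EQ and level."""

    condition: ControlCondition
    per_variable: dict  # {overall_area, overall_perimeter, convex_hull, inter_distance} -> C/IC/EQ
    level: int  # number of C entries, 1-3
    variant: str  # 'a' (convex hull equated) or 'b' (inter-distance equated)


def disk_hull_area(array: DotArray) -> float:
    """Area of the convex hull of the dot outlines (centres buffered by radii)."""
    disks = [
        Point(d.center_x, d.center_y).buffer(d.radius, quad_segs=_BUFFER_QUAD_SEGS)
        for d in array.dots
    ]
    return float(unary_union(disks).convex_hull.area)


def mean_nn_dist(array: DotArray) -> float:
    """Mean over dots of the nearest-neighbour centre distance (mm)."""
    if array.numerosity < 2:
        raise UndefinedMagnitudeError(
            "mean nearest-neighbour distance is undefined for a single dot"
        )
    dmat = squareform(pdist(array.centers))
    np.fill_diagonal(dmat, np.inf)
    return float(dmat.min(axis=1).mean())


def compute_magnitudes(array: DotArray) -> MagnitudeVector:
    """Compute all magnitudes of an array.

    Area, perimeter and mean radius are exact closed forms; hull area comes
    from the polygonised disk union; mean nearest-neighbour distance is NaN
    for single-dot arrays (it is undefined there, and callers that need it
    should use :func:`mean_nn_dist`, which raises instead).
    """
    if array.numerosity < 1:
        raise ValueError("array must contain at least one dot")
    r = array.radii
    hull = disk_hull_area(array)
    nn = mean_nn_dist(array) if array.numerosity >= 2 else float("nan")
    return MagnitudeVector(
        numerosity=array.numerosity,
        total_area=float(np.sum(np.pi * r**2)),
        total_perimeter=float(np.sum(2 * np.pi * r)),
        mean_radius=float(r.mean()),
        hull_area=hull,
        mean_nn_dist=nn,
        density=array.numerosity / hull,
        sparsity=hull / array.numerosity,
    )


# Congruency table: per condition, the C/IC/EQ status of the four coded
# variables.  The area and perimeter columns follow from the closed-form
# radius solutions (verified analytically in congruency_direction); the
# convex-hull and inter-distance columns are fixed by the coding scheme:
# the equated spatial variable is EQ, the free one is coded C.
CONGRUENCY_TABLE: dict[tuple[Geometry, Spatial], tuple[dict, int, str]] = {
    (Geometry.PERIM_EQ, Spatial.CH_EQ): (
        {"overall_area": "IC", "overall_perimeter": "EQ",
         "convex_hull": "EQ", "inter_distance": "C"},
        1, "a",
    ),
    (Geometry.PERIM_EQ, Spatial.ID_EQ): (
        {"overall_area": "IC", "overall_perimeter": "EQ",
         "convex_hull": "C", "inter_distance": "EQ"},
        1, "b",
    ),
    (Geometry.AREA_EQ, Spatial.CH_EQ): (
        {"overall_area": "EQ", "overall_perimeter": "C",
         "convex_hull": "EQ", "inter_distance": "C"},
        2, "a",
    ),
    (Geometry.AREA_EQ, Spatial.ID_EQ): (
        {"overall_area": "EQ", "overall_perimeter": "C",
         "convex_hull": "C", "inter_distance": "EQ"},
        2, "b",
    ),
    (Geometry.RADIUS_FIXED, Spatial.CH_EQ): (
        {"overall_area": "C", "overall_perimeter": "C",
         "convex_hull": "EQ", "inter_distance": "C"},
        3, "a",
    ),
    (Geometry.RADIUS_FIXED, Spatial.ID_EQ): (
        {"overall_area": "C", "overall_perimeter": "C",
         "convex_hull": "C", "inter_distance": "EQ"},
        3, "b",
    ),
}


def congruency_level(condition: ControlCondition) -> CongruencyCode:
    """Return the congruency code (per-variable C/IC/EQ, level, variant)."""
    per_var, level, variant = CONGRUENCY_TABLE[(condition.geometry, condition.spatial)]
    return CongruencyCode(
        condition=condition, per_variable=dict(per_var), level=level, variant=variant
    )


_VARIABLE_GETTERS = {
    "overall_area": lambda m: m.total_area,
    "overall_perimeter": lambda m: m.total_perimeter,
    "convex_hull": lambda m: m.hull_area,
    "inter_distance": lambda m: m.mean_nn_dist,
}


def congruency_direction(
    pair: StimulusPair | tuple[DotArray, DotArray],
    variable: str,
    rel_tol: float = 0.05,
) -> str:
    """Empirical congruency of one magnitude on a generated pair.

    ``C`` if the larger-numerosity array's value exceeds the smaller's by
    more than ``rel_tol`` (relative), ``IC`` if the smaller array's value is
    larger, ``EQ`` within tolerance.  ``pair`` may also be a plain
    ``(array_small, array_large)`` tuple.
    """
    if variable not in _VARIABLE_GETTERS:
        raise ValueError(f"unknown magnitude variable {variable!r}")
    get = _VARIABLE_GETTERS[variable]
    if isinstance(pair, StimulusPair):
        arr_s, arr_l = pair.array_small, pair.array_large
    else:
        arr_s, arr_l = pair
    v_small = get(compute_magnitudes(arr_s))
    v_large = get(compute_magnitudes(arr_l))
    if abs(v_large - v_small) <= rel_tol * abs(v_small):
        return "EQ"
    return "C" if v_large > v_small else "IC"
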