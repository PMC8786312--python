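"""Generation of paired dot-array stimuli under non-numerical magnitude controls.

Two-alternative numerosity experiments must ensure animals cannot solve the
task from continuous magnitudes (total area, total perimeter, convex hull,
inter-dot spacing) that normally covary with the number of elements.  This
module builds pairs of dot arrays that differ in numerosity while one
*geometry* magnitude (dot radius, total area, or total perimeter) and one
*spatial* magnitude (convex-hull area or mean nearest-neighbour distance) are
equated between the two arrays.  Crossing the three geometry controls with
the two spatial controls yields six control conditions; the magnitudes left
uncontrolled are free to covary with numerosity.

All geometry lives in continuous millimetres with the origin at the field
centre and y pointing up.  Rasterisation maps pixel centres onto this frame
without anti-aliasing so that analytic ink-area checks hold.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Geometry",
    "Spatial",
    "ControlCondition",
    "CONDITIONS",
    "Dot",
    "DotArray",
    "StimulusPair",
    "GenerationConfig",
    "StimulusError",
    "InfeasibleConditionError",
    "PlacementError",
    "AdjustmentError",
    "solve_geometry",
    "place_dots",
    "adjust_spatial",
    "generate_pair",
    "render_image",
    "visual_angle",
]


class StimulusError(RuntimeError):
    """Base class for stimulus-generation failures."""


class InfeasibleConditionError(StimulusError):
    """The requested geometry control cannot be satisfied in the size range."""


class PlacementError(StimulusError):
    """Dots could not be placed without violating overlap/containment."""


class AdjustmentError(StimulusError):
    """The spatial metric could not be driven to its target."""


class Geometry(str, enum.Enum):
    """Which geometric magnitude is equated between the two arrays."""

    RADIUS_FIXED = "radius_fixed"
    AREA_EQ = "area_eq"
    PERIM_EQ = "perim_eq"


class Spatial(str, enum.Enum):
    """Which spatial-arrangement magnitude is equated between the two arrays."""

    CH_EQ = "ch_eq"  # convex-hull area of the dot outlines
    ID_EQ = "id_eq"  # mean nearest-neighbour centre distance


@dataclass(frozen=True)
class ControlCondition:
    """One of the six crossed magnitude-control conditions."""

    geometry: Geometry
    spatial: Spatial

    def label(self) -> str:
        geo = {
            Geometry.RADIUS_FIXED: "radius-fixed",
            Geometry.AREA_EQ: "area",
            Geometry.PERIM_EQ: "perimeter",
        }[self.geometry]
        sp = {Spatial.CH_EQ: "ch", Spatial.ID_EQ: "id"}[self.spatial]
        return f"{geo}-{sp}"

    @staticmethod
    def from_label(label: str) -> "ControlCondition":
        geo_part, _, sp_part = label.rpartition("-")
        geo = {
            "radius-fixed": Geometry.RADIUS_FIXED,
            "radius_fixed": Geometry.RADIUS_FIXED,
            "rf": Geometry.RADIUS_FIXED,
            "area": Geometry.AREA_EQ,
            "perimeter": Geometry.PERIM_EQ,
            "perim": Geometry.PERIM_EQ,
        }.get(geo_part)
        sp = {"ch": Spatial.CH_EQ, "id": Spatial.ID_EQ}.get(sp_part)
        if geo is None or sp is None:
            raise ValueError(f"unknown condition label: {label!r}")
        return ControlCondition(geo, sp)


#: All six control conditions in Table-row order (perimeter, area, radius-fixed).
CONDITIONS: tuple[ControlCondition, ...] = (
    ControlCondition(Geometry.PERIM_EQ, Spatial.CH_EQ),
    ControlCondition(Geometry.PERIM_EQ, Spatial.ID_EQ),
    ControlCondition(Geometry.AREA_EQ, Spatial.CH_EQ),
    ControlCondition(Geometry.AREA_EQ, Spatial.ID_EQ),
    ControlCondition(Geometry.RADIUS_FIXED, Spatial.CH_EQ),
    ControlCondition(Geometry.RADIUS_FIXED, Spatial.ID_EQ),
)


@dataclass(frozen=True)
class Dot:
    """A filled circular dot: centre (mm, field-centred frame) and radius (mm)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("dot radius must be positive")


@dataclass(frozen=True)
class DotArray:
    """An ordered set of non-overlapping dots inside a circular field.

    The field is a disk of ``field_radius`` mm centred at ``field_center``
    (default the origin).  Numerosity is the number of dots.
    """

    dots: tuple[Dot, ...]
    field_radius: float = 30.0
    field_center: tuple[float, float] = (0.0, 0.0)

    @property
    def numerosity(self) -> int:
        return len(self.dots)

    @property
    def centers(self) -> np.ndarray:
        return np.array([(d.center_x, d.center_y) for d in self.dots], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([d.radius for d in self.dots], dtype=float)

    def validate(self, min_gap: float = 0.0, atol: float = 1e-9) -> None:
        """Raise if containment or pairwise non-overlap is violated."""
        if self.numerosity < 1:
            raise ValueError("array must contain at least one dot")
        c = self.centers - np.asarray(self.field_center)
        dist = np.hypot(c[:, 0], c[:, 1])
        if np.any(dist + self.radii > self.field_radius + atol):
            raise ValueError("a dot extends outside the field circle")
        if self.numerosity >= 2:
            from scipy.spatial.distance import pdist

            d = pdist(self.centers)
            rr = self.radii
            i, j = np.triu_indices(self.numerosity, k=1)
            if np.any(d + atol < rr[i] + rr[j] + min_gap):
                raise ValueError("two dot disks overlap (or violate min_gap)")

    def with_centers(self, centers: np.ndarray) -> "DotArray":
        dots = tuple(
            Dot(float(x), float(y), float(r))
            for (x, y), r in zip(centers, self.radii)
        )
        return DotArray(dots, self.field_radius, self.field_center)

    def to_dict(self) -> dict:
        return {
            "field_radius": self.field_radius,
            "field_center": list(self.field_center),
            "dots": [asdict(d) for d in self.dots],
        }


@dataclass
class GenerationConfig:
    """Tunable parameters of the stimulus generator.

    Dot sizes follow the study conditions: diameters between 3 and 12 mm.
    Base radii for the reference array are drawn uniformly from
    ``base_radius_range`` (a sub-range of 1.5-6 mm chosen so that every
    control condition stays feasible up to 9 dots inside a 30 mm field).
    """

    field_radius: float = 30.0
    base_radius_range: tuple[float, float] = (2.0, 3.5)
    radius_limits: tuple[float, float] = (1.5, 6.0)  # permitted solved radii, mm
    min_gap: float = 1.0  # minimum edge-to-edge distance, mm
    rel_tol: float = 0.05  # relative tolerance for spatial constraints
    max_attempts: int = 10_000  # per-dot rejection-sampling attempts
    max_restarts: int = 50  # full resamples of an array
    max_adjust_iter: int = 60  # spatial-adjustment iterations
    px_per_mm: float = 8.533  # ~512 px over a 60 mm field


@dataclass(frozen=True)
class StimulusPair:
    """Two arrays differing in numerosity under one control condition.

    ``constraint_report`` records the achieved relative deviation for each
    controlled magnitude so downstream checks can re-verify the pair.
    """

    array_small: DotArray
    array_large: DotArray
    condition: ControlCondition
    tolerances: dict
    seed: int
    constraint_report: dict

    def __post_init__(self) -> None:
        if self.array_small.numerosity >= self.array_large.numerosity:
            raise ValueError("array_small must have strictly fewer dots")

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition.label(),
                "seed": self.seed,
                "tolerances": self.tolerances,
                "constraint_report": self.constraint_report,
                "array_small": self.array_small.to_dict(),
                "array_large": self.array_large.to_dict(),
            },
            indent=2,
        )


def solve_geometry(
    n_ref: int,
    radii_ref: Sequence[float],
    n_other: int,
    mode: Geometry,
) -> np.ndarray:
    """Solve the other array's (uniform) radii for a geometry control.

    Given a reference array of ``n_ref`` dots with radii ``radii_ref``,
    return ``n_other`` radii such that the controlled magnitude is equated
    exactly:

    - ``RADIUS_FIXED``: every dot keeps the common reference radius,
    - ``AREA_EQ``: total disk area is preserved, r' = sqrt(sum(r^2)/n),
    - ``PERIM_EQ``: total circumference is preserved, r' = sum(r)/n.
    """
    radii_ref = np.asarray(radii_ref, dtype=float)
    if n_ref < 1 or n_other < 1:
        raise ValueError("numerosities must be >= 1")
    if radii_ref.shape != (n_ref,):
        raise ValueError("radii_ref length must equal n_ref")
    if np.any(radii_ref <= 0):
        raise ValueError("all radii must be positive")

    if mode is Geometry.RADIUS_FIXED:
        if not np.allclose(radii_ref, radii_ref[0]):
            raise InfeasibleConditionError(
                "RADIUS_FIXED requires a uniform reference radius"
            )
        r = float(radii_ref[0])
    elif mode is Geometry.AREA_EQ:
        r = math.sqrt(float(np.sum(radii_ref**2)) / n_other)
    elif mode is Geometry.PERIM_EQ:
        r = float(np.sum(radii_ref)) / n_other
    else:  # pragma: no cover - enum exhausts
        raise ValueError(f"unknown geometry mode {mode}")
    return np.full(n_other, r, dtype=float)


def _check_radius_limits(radii: np.ndarray, limits: tuple[float, float]) -> None:
    lo, hi = limits
    if np.any(radii < lo - 1e-12) or np.any(radii > hi + 1e-12):
        raise InfeasibleConditionError(
            f"solved radius outside permitted range [{lo}, {hi}] mm: "
            f"{float(radii.min()):.3f}-{float(radii.max()):.3f}"
        )


def place_dots(
    n: int,
    radii: Sequence[float],
    field_radius: float,
    rng: np.random.Generator,
    *,
    min_gap: float = 1.0,
    max_attempts: int = 10_000,
) -> DotArray:
    """Place ``n`` dots uniformly at random inside the field without overlap.

    Uniform rejection sampling: candidate centres are drawn uniformly over
    the disk of radius ``field_radius - r`` (containment built in) and
    rejected if the new disk comes within ``min_gap`` of an accepted one.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) != n:
        raise ValueError("radii length must equal n")
    if np.any(radii >= field_radius):
        raise PlacementError("a dot radius exceeds the field radius")

    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        rmax = field_radius - r
        for _ in range(max_attempts):
            # uniform over disk via sqrt transform
            rho = rmax * math.sqrt(rng.random())
            phi = 2.0 * math.pi * rng.random()
            x, y = rho * math.cos(phi), rho * math.sin(phi)
            ok = True
            for (px, py), pr in zip(centers, radii[: len(centers)]):
                if math.hypot(x - px, y - py) < r + pr + min_gap:
                    ok = False
                    break
            if ok:
                centers.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place dot {i + 1}/{n} (radius {r:.2f} mm) without "
                f"overlap after {max_attempts} attempts"
            )
    dots = tuple(Dot(x, y, float(r)) for (x, y), r in zip(centers, radii))
    return DotArray(dots, field_radius)


def _measure(array: DotArray, metric: str) -> float:
    from . import magnitudes

    if metric == "hull_area":
        return magnitudes.disk_hull_area(array)
    if metric == "mean_nn_dist":
        return magnitudes.mean_nn_dist(array)
    raise ValueError(f"unknown spatial metric {metric!r}")


def _repair(
    centers: np.ndarray,
    radii: np.ndarray,
    field_radius: float,
    min_gap: float,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> np.ndarray | None:
    """Nudge centres until containment and non-overlap hold; None on failure.

    Containment is fixed by radial clamping; overlaps by symmetrically pushing
    the offending pair apart.  Both moves are small and local so the spatial
    metric is minimally disturbed.
    """
    c = centers.copy()
    n = len(radii)
    for _ in range(max_iter):
        dirty = False
        # containment
        d = np.hypot(c[:, 0], c[:, 1])
        over = d + radii > field_radius
        if np.any(over):
            dirty = True
            for i in np.flatnonzero(over):
                if d[i] < 1e-12:
                    continue
                scale = (field_radius - radii[i]) / d[i]
                c[i] *= scale
        # overlap
        for i in range(n):
            for j in range(i + 1, n):
                delta = c[j] - c[i]
                dist = float(np.hypot(*delta))
                need = radii[i] + radii[j] + min_gap
                if dist < need:
                    dirty = True
                    if dist < 1e-9:
                        ang = 2 * math.pi * rng.random()
                        delta = np.array([math.cos(ang), math.sin(ang)])
                        dist = 1.0
                    push = (need - dist) / 2 + 1e-6
                    unit = delta / dist
                    c[i] -= unit * push
                    c[j] += unit * push
        if not dirty:
            return c
    return None


def adjust_spatial(
    array: DotArray,
    metric: str,
    target: float,
    rel_tol: float,
    rng: np.random.Generator,
    *,
    min_gap: float = 1.0,
    max_iter: int = 60,
) -> DotArray:
    """Rescale dot centres about their centroid until a spatial metric hits target.

    Uses the similarity-scaling identities: scaling all centres by k about
    the centroid multiplies mean nearest-neighbour distance by k and hull
    area by ~k^2 (exactly k^2 for the centre hull; nearly so for the
    disk-outline hull since radii are unchanged).  After each scaling step,
    containment and overlap violations are repaired locally; the loop exits
    once the re-measured metric is within ``rel_tol`` of ``target``.
    """
    if array.numerosity < 2:
        raise ValueError("spatial adjustment requires numerosity >= 2")
    if target <= 0:
        raise ValueError("target must be positive")
    exponent = 0.5 if metric == "hull_area" else 1.0

    current = array
    for _ in range(max_iter):
        value = _measure(current, metric)
        if abs(value - target) <= rel_tol * target:
            return current
        k = (target / value) ** exponent
        # damp large steps: repair after expansion can undo part of the move
        k = float(np.clip(k, 0.5, 2.0))
        centroid = current.centers.mean(axis=0)
        new_centers = centroid + (current.centers - centroid) * k
        repaired = _repair(
            new_centers, current.radii, current.field_radius, min_gap, rng
        )
        if repaired is None:
            raise AdjustmentError(
                f"could not repair overlaps while driving {metric} to {target:.3g}"
            )
        current = current.with_centers(repaired)
    value = _measure(current, metric)
    if abs(value - target) <= rel_tol * target:
        return current
    raise AdjustmentError(
        f"{metric} stuck at {value:.4g} after {max_iter} iterations "
        f"(target {target:.4g} ± {rel_tol:.0%})"
    )


def generate_pair(
    n_small: int,
    n_large: int,
    condition: ControlCondition,
    config: GenerationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> StimulusPair:
    """Generate a stimulus pair under one of the six control conditions.

    The geometry constraint is solved analytically (exact); the spatial
    constraint is satisfied iteratively within ``config.rel_tol``.  The
    returned pair carries a constraint report with the achieved relative
    deviations, re-measurable via :mod:`numfish.magnitudes`.
    """
    if not (1 <= n_small < n_large):
        raise ValueError("need 1 <= n_small < n_large")
    config = config or GenerationConfig()
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    else:
        seed = -1  # external generator; seed unknown

    metric = "hull_area" if condition.spatial is Spatial.CH_EQ else "mean_nn_dist"

    last_err: Exception | None = None
    for _ in range(config.max_restarts):
        try:
            if condition.geometry is Geometry.RADIUS_FIXED:
                base = float(rng.uniform(*config.base_radius_range))
                radii_small = np.full(n_small, base)
            else:
                radii_small = np.full(
                    n_small, float(rng.uniform(*config.base_radius_range))
                )
            radii_large = solve_geometry(
                n_small, radii_small, n_large, condition.geometry
            )
            _check_radius_limits(radii_large, config.radius_limits)

            arr_small = place_dots(
                n_small,
                radii_small,
                config.field_radius,
                rng,
                min_gap=config.min_gap,
                max_attempts=config.max_attempts,
            )
            arr_large = place_dots(
                n_large,
                radii_large,
                config.field_radius,
                rng,
                min_gap=config.min_gap,
                max_attempts=config.max_attempts,
            )
            if n_small >= 2:
                target = _measure(arr_small, metric)
                arr_large = adjust_spatial(
                    arr_large,
                    metric,
                    target,
                    config.rel_tol,
                    rng,
                    min_gap=config.min_gap,
                    max_iter=config.max_adjust_iter,
                )
            else:
                # a single dot has no spatial arrangement to equate
                target = float("nan")

            report = _constraint_report(arr_small, arr_large, condition, metric)
            return StimulusPair(
                array_small=arr_small,
                array_large=arr_large,
                condition=condition,
                tolerances={"geometry": 0.0, "spatial": config.rel_tol},
                seed=seed,
                constraint_report=report,
            )
        except (PlacementError, AdjustmentError, InfeasibleConditionError) as err:
            last_err = err
            continue
    raise StimulusError(
        f"failed to generate a {condition.label()} {n_small} vs {n_large} pair "
        f"after {config.max_restarts} restarts"
    ) from last_err


def _constraint_report(
    arr_small: DotArray,
    arr_large: DotArray,
    condition: ControlCondition,
    metric: str,
) -> dict:
    from . import magnitudes

    m_s = magnitudes.compute_magnitudes(arr_small)
    m_l = magnitudes.compute_magnitudes(arr_large)

    def rel(a: float, b: float) -> float:
        return abs(b - a) / a if a else float("nan")

    geo_dev = {
        Geometry.RADIUS_FIXED: rel(m_s.mean_radius, m_l.mean_radius),
        Geometry.AREA_EQ: rel(m_s.total_area, m_l.total_area),
        Geometry.PERIM_EQ: rel(m_s.total_perimeter, m_l.total_perimeter),
    }[condition.geometry]
    if arr_small.numerosity >= 2:
        if metric == "hull_area":
            sp_dev = rel(m_s.hull_area, m_l.hull_area)
        else:
            sp_dev = rel(m_s.mean_nn_dist, m_l.mean_nn_dist)
    else:
        sp_dev = float("nan")
    return {
        "geometry_control": condition.geometry.value,
        "geometry_rel_dev": geo_dev,
        "spatial_control": condition.spatial.value,
        "spatial_metric": metric,
        "spatial_rel_dev": sp_dev,
    }


def render_image(
    array: DotArray,
    px_per_mm: float,
    draw_outline: bool = True,
    outline_width_mm: float = 0.6,
) -> np.ndarray:
    """Rasterise a dot array to an 8-bit grayscale image.

    White background (255), black filled disks (0), and optionally the black
    outline ring marking the field boundary.  A pixel is painted black when
    its centre falls inside a disk (no anti-aliasing), which keeps the black
    pixel count close to the analytic ink area.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    side = math.ceil(2 * array.field_radius * px_per_mm)
    # pixel-centre coordinates in mm, field-centred, y up
    coords = (np.arange(side) + 0.5) / px_per_mm - array.field_radius
    xx, yy = np.meshgrid(coords, -coords)  # row 0 = top = +y
    img = np.full((side, side), 255, dtype=np.uint8)
    if draw_outline:
        rr = np.hypot(xx, yy)
        ring = np.abs(rr - array.field_radius) <= outline_width_mm / 2
        img[ring] = 0
    for d in array.dots:
        mask = (xx - d.center_x) ** 2 + (yy - d.center_y) ** 2 <= d.radius**2
        img[mask] = 0
    return img


def visual_angle(extent_mm: float, viewing_distance_mm: float) -> float:
    """Visual angle (degrees) subtended by an extent at a viewing distance."""
    if extent_mm <= 0 or viewing_distance_mm <= 0:
        raise ValueError("extent and distance must be positive")
    return math.degrees(2.0 * math.atan(extent_mm / (2.0 * viewing_distance_mm)))
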