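"""Screw-placement accuracy metrics and the perforation verdict.

The evaluation geometry of a navigated drilling:

* **MLD** (maximal lateral deviation): the largest orthogonal distance of
  any point of the drilled axis — evaluated over the inserted segment, from
  entry to screw tip — from the planned (infinite) axis. The distance to a
  line is convex along a segment, so the maximum is always attained at the
  base or the tip; the attaining end is reported alongside the value.
* **Entry deviation**: distance between planned and drilled entry points.
* **Central-aim deviation**: distance from the planned central aim point to
  the drilled screw *tip* — deliberately depth-dependent: stopping short or
  overshooting counts.
* **Angular deviation**: angle between the two axis directions, degrees.
* **Perforation**: the screw is a capsule of radius ``diameter/2`` along the
  drilled segment, the corridor a capsule of its own radius along its axis;
  the cortex is breached iff at some point of the insertion the screw
  capsule pokes out of the corridor capsule. Breach directions are named
  anatomically (anterior = small pelvis, posterior = spinal canal,
  superior/inferior = neuroforamina) by an 8-sector compass on the radial
  offset at the worst breach.

Correct placement is defined as the absence of perforation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    AnatomicalFrame,
    DegenerateGeometryError,
    Trajectory,
    point_to_line_distance,
)
from .phantom import Corridor

__all__ = [
    "PerforationFinding",
    "PlacementReport",
    "mld",
    "entry_deviation",
    "central_aim_deviation",
    "angular_deviation",
    "detect_perforation",
    "detect_perforation_mesh",
    "evaluate_placement",
    "REPORT_COLUMNS",
]

#: Stable column order of CSV placement reports.
REPORT_COLUMNS = (
    "screw_label",
    "mld_mm",
    "mld_location",
    "entry_dev_mm",
    "central_aim_dev_mm",
    "angular_dev_deg",
    "perforated",
    "directions",
    "correct",
)

#: Secondary compass component is included when it reaches tan(22.5 deg) of
#: the primary one (8-sector compass: 4 pure + 4 combined directions).
_COMBINE_RATIO = np.tan(np.deg2rad(22.5))


@dataclass(frozen=True)
class PerforationFinding:
    """Cortical breach verdict for one screw.

    ``directions`` is a frozenset drawn from {anterior, posterior, superior,
    inferior}: a singleton for a pure breach, an adjacent pair for a combined
    one, empty iff no perforation. ``breach_depth`` is how far the screw
    surface protrudes beyond the corridor surface at the worst point (mm);
    ``breach_location_t`` the normalised insertion position of that point.
    """

    perforated: bool
    directions: frozenset
    breach_depth: float
    breach_location_t: float

    def __post_init__(self):
        if self.perforated != bool(self.directions):
            raise ValueError("perforated must match directions being non-empty")
        if self.perforated != (self.breach_depth > 0):
            raise ValueError("breach_depth must be > 0 iff perforated")

    @property
    def directions_str(self) -> str:
        order = ("anterior", "posterior", "superior", "inferior")
        return "+".join(d for d in order if d in self.directions)


@dataclass(frozen=True)
class PlacementReport:
    """All accuracy metrics for one screw."""

    screw_label: str
    mld: float
    mld_location: str
    entry_deviation: float
    central_aim_deviation: float
    angular_deviation: float
    perforation: PerforationFinding
    correct: bool

    def __post_init__(self):
        if self.correct != (not self.perforation.perforated):
            raise ValueError("correct must equal absence of perforation")

    def to_row(self) -> dict:
        return {
            "screw_label": self.screw_label,
            "mld_mm": self.mld,
            "mld_location": self.mld_location,
            "entry_dev_mm": self.entry_deviation,
            "central_aim_dev_mm": self.central_aim_deviation,
            "angular_dev_deg": self.angular_deviation,
            "perforated": self.perforation.perforated,
            "directions": self.perforation.directions_str,
            "correct": self.correct,
        }


def mld(planned: Trajectory, drilled: Trajectory) -> tuple[float, str]:
    """Maximal lateral deviation of the drilled axis from the planned axis.

    Returns ``(distance_mm, location)`` where location is ``"base"`` or
    ``"tip"``. The drilled axis is evaluated over the inserted segment
    (entry to tip); the planned axis is treated as an infinite line. Ties
    report ``"tip"`` (the clinically riskier end).
    """
    if drilled.depth <= 0:
        raise DegenerateGeometryError("drilled segment has zero length")
    p0 = drilled.entry
    p1 = drilled.tip
    a = planned.entry
    d = planned.direction
    d_base = point_to_line_distance(p0, a, d)
    d_tip = point_to_line_distance(p1, a, d)
    if d_base > d_tip:
        return d_base, "base"
    return d_tip, "tip"


def entry_deviation(planned: Trajectory, drilled: Trajectory) -> float:
    """Distance between planned and drilled entry points, mm."""
    return float(np.linalg.norm(planned.entry - drilled.entry))


def central_aim_deviation(planned: Trajectory, drilled: Trajectory) -> float:
    """Distance from the planned central aim point to the drilled tip, mm.

    Uses the drilled screw tip, so drilling short of or past the aim point
    registers as deviation.
    """
    return float(np.linalg.norm(planned.central_aim - drilled.tip))


def angular_deviation(planned: Trajectory, drilled: Trajectory) -> float:
    """Angle between planned and drilled axis directions, degrees, in [0, 180].

    Computed as ``atan2(|d1 x d2|, d1 . d2)``, which stays accurate near
    0 and 180 degrees where ``arccos`` loses half the significant digits.
    """
    d1, d2 = planned.direction, drilled.direction
    return float(
        np.degrees(np.arctan2(np.linalg.norm(np.cross(d1, d2)), np.dot(d1, d2)))
    )


def _segment_closest_points(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    return a + t[:, None] * ab


def _classify_direction(offset: np.ndarray, frame: AnatomicalFrame) -> frozenset:
    """8-sector compass on the (anterior, superior) components of the offset."""
    a = float(np.dot(offset, frame.anterior))
    s = float(np.dot(offset, frame.superior))
    comps = []
    if abs(a) >= abs(s):
        primary, secondary = ("anterior" if a >= 0 else "posterior", abs(a)), (
            "superior" if s >= 0 else "inferior",
            abs(s),
        )
    else:
        primary, secondary = ("superior" if s >= 0 else "inferior", abs(s)), (
            "anterior" if a >= 0 else "posterior",
            abs(a),
        )
    comps.append(primary[0])
    if primary[1] > 0 and secondary[1] >= _COMBINE_RATIO * primary[1]:
        comps.append(secondary[0])
    if primary[1] == 0:
        # Radial offset has no component in the compass plane (a breach
        # straight out the corridor end); call it by the larger raw component
        # sign anyway — degenerate and practically unreachable.
        comps = ["anterior" if a >= 0 else "posterior"]
    return frozenset(comps)


def detect_perforation(
    drilled: Trajectory, corridor: Corridor, frame: AnatomicalFrame
) -> PerforationFinding:
    """Test the drilled screw capsule against the corridor capsule.

    The screw breaches the cortex iff at some normalised position ``t`` of
    the insertion the distance from the drilled axis to the corridor axis
    segment plus the screw radius exceeds the corridor radius. That excess
    is convex in ``t`` (distance to a convex set along an affine path), so
    its maximum sits at an endpoint; both are evaluated and the worse one is
    reported.
    """
    r_screw = drilled.radius
    a, b = corridor.axis_entry, corridor.axis_end
    ends = np.vstack([drilled.entry, drilled.tip])
    closest = _segment_closest_points(ends, a, b)
    dists = np.linalg.norm(ends - closest, axis=1)
    excess = dists + r_screw - corridor.radius
    i = int(np.argmax(excess))
    worst = float(excess[i])
    if worst <= 0:
        return PerforationFinding(
            perforated=False, directions=frozenset(), breach_depth=0.0, breach_location_t=0.0
        )
    offset = ends[i] - closest[i]
    directions = _classify_direction(offset, frame)
    return PerforationFinding(
        perforated=True,
        directions=directions,
        breach_depth=worst,
        breach_location_t=float(i),  # 0.0 = base, 1.0 = tip (endpoint argmax)
    )


def _sample_capsule_surface(traj: Trajectory, points_per_mm2: float) -> np.ndarray:
    """Quasi-uniform points on the screw capsule surface (cylinder + caps)."""
    r = traj.radius
    L = traj.depth
    d = traj.direction
    from .phantom import _perpendicular_basis

    e1, e2 = _perpendicular_basis(d)
    area = 2 * np.pi * r * L + 4 * np.pi * r**2
    n = max(64, int(area * points_per_mm2))
    # Fibonacci-style lattice over (t, phi) for the side plus two cap spheres
    n_side = int(n * (2 * np.pi * r * L) / area)
    k = np.arange(max(n_side, 1))
    t = (k + 0.5) / max(n_side, 1)
    phi = 2 * np.pi * ((k * 0.6180339887498949) % 1.0)
    side = (
        traj.entry[None, :]
        + (t * L)[:, None] * d
        + r * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    n_cap = max(n - n_side, 8)
    k = np.arange(n_cap)
    z = 1.0 - 2.0 * (k + 0.5) / n_cap
    theta = np.arccos(z)
    phi = 2 * np.pi * ((k * 0.6180339887498949) % 1.0)
    sph = r * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), z], axis=1
    )
    sph_world = sph @ np.vstack([e1, e2, d])
    caps = np.vstack(
        [traj.entry[None, :] + sph_world[sph_world @ d <= 0], traj.tip[None, :] + sph_world[sph_world @ d >= 0]]
    )
    return np.vstack([side, caps])


def _points_in_mesh(mesh, pts: np.ndarray) -> np.ndarray:
    """Ray-parity containment test (vectorised Moeller-Trumbore).

    Casts one fixed, irrationally oriented ray per point and counts triangle
    crossings; odd parity means inside. Assumes a watertight mesh.
    """
    tri = np.asarray(mesh.triangles)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    d = np.array([0.57735026918962584, 0.57735026918962562, 0.57735026918962629])
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    inside = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        tvec = p - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = np.einsum("ij,ij->i", qvec, e2) * inv
        hits = ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 1e-9)
        inside[i] = bool(np.count_nonzero(hits) % 2)
    return inside


def detect_perforation_mesh(
    drilled: Trajectory,
    mesh,
    frame: AnatomicalFrame,
    points_per_mm2: float = 1.0,
) -> PerforationFinding:
    """Perforation test against an arbitrary watertight bone/corridor mesh.

    The screw capsule surface is sampled (default 1 point/mm^2) and each
    sample point is tested for containment by ray parity; the breach depth
    is the largest unsigned distance of an outside sample from the mesh
    surface. Directions are classified from the offset of the worst sample
    to its nearest point on the mesh.
    """
    import trimesh  # mesh is a trimesh.Trimesh

    pts = _sample_capsule_surface(drilled, points_per_mm2)
    inside = _points_in_mesh(mesh, pts)
    if bool(np.all(inside)):
        return PerforationFinding(
            perforated=False, directions=frozenset(), breach_depth=0.0, breach_location_t=0.0
        )
    outside = pts[~inside]
    closest, dist, _ = trimesh.proximity.closest_point_naive(mesh, outside)
    i = int(np.argmax(dist))
    offset = outside[i] - closest[i]
    t = float(
        np.clip(np.dot(outside[i] - drilled.entry, drilled.direction) / drilled.depth, 0.0, 1.0)
    )
    return PerforationFinding(
        perforated=True,
        directions=_classify_direction(offset, frame),
        breach_depth=float(dist[i]),
        breach_location_t=t,
    )


def evaluate_placement(
    planned: Trajectory,
    drilled: Trajectory,
    corridor: Corridor,
    frame: AnatomicalFrame,
    screw_label: str = "",
) -> PlacementReport:
    """Assemble the full per-screw accuracy report."""
    mld_mm, mld_loc = mld(planned, drilled)
    finding = detect_perforation(drilled, corridor, frame)
    return PlacementReport(
        screw_label=screw_label or corridor.label,
        mld=mld_mm,
        mld_location=mld_loc,
        entry_deviation=entry_deviation(planned, drilled),
        central_aim_deviation=central_aim_deviation(planned, drilled),
        angular_deviation=angular_deviation(planned, drilled),
        perforation=finding,
        correct=not finding.perforated,
    )
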