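"""Shared 3-D geometry: landmarks, the anatomical frame, similarity transforms.

All lengths are millimetres, all public angles degrees (radians internally).
Points and vectors are plain ``numpy`` arrays of shape ``(3,)``; the container
types below are small frozen dataclasses so they can be hashed, compared and
serialised without surprises.

The anatomical frame is built from the three palpable registration landmarks
(left/right anterior superior iliac spine and the pubic symphysis): the
lateral axis joins the two ASIS, the inferior axis points from the inter-ASIS
midpoint towards the symphysis (orthogonalised), and the anterior axis
completes a right-handed triad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DegenerateGeometryError",
    "LandmarkSet",
    "AnatomicalFrame",
    "SimilarityTransform",
    "Trajectory",
    "build_frame",
    "point_to_line_distance",
    "point_to_segment_distance",
    "transform_point",
    "rotation_axis_angle",
    "MIN_TRIANGLE_AREA_MM2",
]

#: Landmark triangles with area below this are rejected as degenerate.
#: Palpated pelvic landmarks are centimetres apart in any real subject.
MIN_TRIANGLE_AREA_MM2 = 1.0

_UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when landmark or trajectory geometry is too degenerate to use."""


def _as_point(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must have shape (3,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


def _normalize(v: np.ndarray, name: str = "vector") -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError(f"cannot normalise near-zero {name}")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """The three registration fiducials, in one coordinate space.

    Parameters
    ----------
    left_asis, right_asis : array-like, shape (3,)
        Anterior superior iliac spines, mm.
    symphysis : array-like, shape (3,)
        Pubic symphysis, mm.
    """

    left_asis: np.ndarray
    right_asis: np.ndarray
    symphysis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "left_asis", _as_point(self.left_asis, "left_asis"))
        object.__setattr__(self, "right_asis", _as_point(self.right_asis, "right_asis"))
        object.__setattr__(self, "symphysis", _as_point(self.symphysis, "symphysis"))
        if self.triangle_area() < MIN_TRIANGLE_AREA_MM2:
            raise DegenerateGeometryError(
                f"landmark triangle area {self.triangle_area():.3g} mm^2 is below "
                f"{MIN_TRIANGLE_AREA_MM2} mm^2 (collinear or coincident landmarks)"
            )

    def triangle_area(self) -> float:
        """Area of the landmark triangle in mm^2."""
        u = self.right_asis - self.left_asis
        v = self.symphysis - self.left_asis
        return 0.5 * float(np.linalg.norm(np.cross(u, v)))

    def as_array(self) -> np.ndarray:
        """Rows ``[left_asis, right_asis, symphysis]``, shape (3, 3)."""
        return np.vstack([self.left_asis, self.right_asis, self.symphysis])

    @classmethod
    def from_array(cls, a) -> "LandmarkSet":
        a = np.asarray(a, dtype=float)
        if a.shape != (3, 3):
            raise ValueError(f"expected shape (3, 3), got {a.shape}")
        return cls(a[0], a[1], a[2])

    def to_dict(self) -> dict:
        return {
            "left_asis": self.left_asis.tolist(),
            "right_asis": self.right_asis.tolist(),
            "symphysis": self.symphysis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(d["left_asis"], d["right_asis"], d["symphysis"])


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal patient frame derived from the landmarks.

    ``origin`` is the inter-ASIS midpoint. ``lateral_right`` points from the
    left to the right ASIS, ``inferior`` towards the symphysis within the
    landmark plane, and ``anterior = lateral_right x inferior`` completes the
    triad. ``superior`` is stored for convenience as ``-inferior``.
    """

    origin: np.ndarray
    lateral_right: np.ndarray
    inferior: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin, "origin"))
        for name in ("lateral_right", "inferior", "anterior"):
            v = _as_point(getattr(self, name), name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} is not a unit vector")
            object.__setattr__(self, name, v)
        if self.superior is None:
            object.__setattr__(self, "superior", -self.inferior)

    def axes(self) -> np.ndarray:
        """Rows ``[lateral_right, anterior, superior]`` (a rotation matrix)."""
        return np.vstack([self.lateral_right, self.anterior, self.superior])


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Construct the anatomical frame from the three landmarks.

    The symphysis lies, by construction, in the plane spanned at the origin
    by ``lateral_right`` and ``inferior``.

    Raises
    ------
    DegenerateGeometryError
        If the landmarks are (near-)collinear.
    """
    origin = 0.5 * (landmarks.left_asis + landmarks.right_asis)
    lateral = _normalize(landmarks.right_asis - landmarks.left_asis, "inter-ASIS axis")
    v = landmarks.symphysis - origin
    v_perp = v - np.dot(v, lateral) * lateral
    inferior = _normalize(v_perp, "symphysis offset from the inter-ASIS axis")
    anterior = np.cross(lateral, inferior)
    return AnatomicalFrame(
        origin=origin,
        lateral_right=lateral,
        inferior=inferior,
        anterior=anterior,
        superior=-inferior,
    )


@dataclass(frozen=True)
class SimilarityTransform:
    """Isotropic similarity: ``p -> scale * R @ p + translation``.

    ``rotation`` must be a proper rotation (orthonormal, det = +1) and
    ``scale`` strictly positive.
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1); reflections rejected")
        t = _as_point(self.translation, "translation")
        s = float(self.scale)
        if not (np.isfinite(s) and s > 0):
            raise ValueError(f"scale must be a positive finite number, got {s}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", s)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points) -> np.ndarray:
        """Apply to one point (shape (3,)) or a stack (shape (n, 3))."""
        p = np.asarray(points, dtype=float)
        return self.scale * p @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def apply_landmarks(self, lms: LandmarkSet) -> LandmarkSet:
        return LandmarkSet.from_array(self.apply(lms.as_array()))

    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation": self.translation.tolist(),
            "scale": float(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(d["translation"], dtype=float),
            scale=float(d["scale"]),
        )


@dataclass(frozen=True)
class Trajectory:
    """A screw trajectory: entry point, central aim point, diameter, depth.

    ``depth`` is the insertion length measured from ``entry`` along the axis;
    the screw tip is ``entry + depth * direction``. Applies to both the
    planned corridor axis and the drilled result.
    """

    entry: np.ndarray
    central_aim: np.ndarray
    diameter: float
    depth: float

    def __post_init__(self):
        object.__setattr__(self, "entry", _as_point(self.entry, "entry"))
        object.__setattr__(self, "central_aim", _as_point(self.central_aim, "central_aim"))
        object.__setattr__(self, "diameter", float(self.diameter))
        object.__setattr__(self, "depth", float(self.depth))
        if np.linalg.norm(self.central_aim - self.entry) < 1e-9:
            raise DegenerateGeometryError("entry and central_aim coincide")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry towards the central aim point."""
        return _normalize(self.central_aim - self.entry)

    @property
    def tip(self) -> np.ndarray:
        """Screw tip: ``entry + depth * direction``."""
        return self.entry + self.depth * self.direction

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    def transformed(
        self, T: SimilarityTransform, preserve_physical: bool = True
    ) -> "Trajectory":
        """Map the trajectory through ``T``.

        With ``preserve_physical`` (default) the screw diameter and insertion
        depth are kept — the physical screw does not change size when the
        hologram is displaced. Otherwise both lengths scale with ``T.scale``.
        """
        k = 1.0 if preserve_physical else T.scale
        return Trajectory(
            entry=T.apply(self.entry),
            central_aim=T.apply(self.central_aim),
            diameter=self.diameter * k,
            depth=self.depth * k,
        )

    def to_dict(self) -> dict:
        return {
            "entry": self.entry.tolist(),
            "central_aim": self.central_aim.tolist(),
            "diameter": float(self.diameter),
            "depth": float(self.depth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(d["entry"], d["central_aim"], d["diameter"], d["depth"])


def point_to_line_distance(p, line_point, line_dir) -> float:
    """Orthogonal distance from ``p`` to the infinite line, mm.

    ``line_dir`` must be a unit vector.
    """
    p = _as_point(p, "p")
    a = _as_point(line_point, "line_point")
    d = _as_point(line_dir, "line_dir")
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("line_dir must be a unit vector")
    w = p - a
    return float(np.linalg.norm(w - np.dot(w, d) * d))


def point_to_segment_distance(p, a, b) -> float:
    """Distance from ``p`` to the closed segment ``[a, b]``, mm."""
    p = _as_point(p, "p")
    a = _as_point(a, "a")
    b = _as_point(b, "b")
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom < 1e-18:
        return float(np.linalg.norm(p - a))
    t = float(np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def transform_point(T: SimilarityTransform, p) -> np.ndarray:
    """Apply a similarity transform to a single point."""
    return T.apply(_as_point(p))


def rotation_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit) and angle (radians, >= 0) of a rotation matrix."""
    rv = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-15:
        return np.array([1.0, 0.0, 0.0]), 0.0
    return rv / angle, angle
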