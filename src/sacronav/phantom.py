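"""Parametric pelvis phantom and the simulated noise sources.

The phantom stands in for a physical pelvic model: three palpable landmarks
(both ASIS and the symphysis) and four transiliac screw corridors — S1 and
S2 on each side, with the S1 corridor wider than the S2 corridor, the
structural asymmetry that makes S2 screws harder to place safely.

Model space is the canonical anatomical frame: +x lateral-right, +y
anterior, +z superior, origin at the inter-ASIS midpoint, units mm. The
corridors run transversely (parallel to the inter-ASIS axis) into the
sacral vertebral bodies, which sit posterior and inferior to that axis; the
planned trajectory of each corridor is its axis, entering laterally and
aiming at the vertebral body centre.

The noise model captures the error sources of a landmark-probed AR
workflow: isotropic per-landmark probing noise, one systematic anterior
mis-marking of the symphysis (the hypothesised cause of tilt about the
inter-ASIS axis), and operator jitter at the drill.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    LandmarkSet,
    SimilarityTransform,
    Trajectory,
    build_frame,
)

__all__ = [
    "Corridor",
    "PhantomParams",
    "PhantomPelvis",
    "NoiseModel",
    "make_phantom",
    "probe_landmarks",
    "simulate_drilling",
    "DRILLING_ORDER",
]

#: Fixed drilling order of the trial protocol.
DRILLING_ORDER = ("S1_right", "S1_left", "S2_right", "S2_left")

#: Semantic names of the structures at risk in each breach direction.
FORBIDDEN_REGIONS = {
    "anterior": "small pelvis",
    "posterior": "spinal canal",
    "superior": "neuroforamina",
    "inferior": "neuroforamina",
}


@dataclass(frozen=True)
class Corridor:
    """An osseous safe channel, modelled as a capsule around an axis segment."""

    label: str
    axis_entry: np.ndarray
    axis_end: np.ndarray
    radius: float
    forbidden_regions: dict = field(default_factory=lambda: dict(FORBIDDEN_REGIONS))

    def __post_init__(self):
        object.__setattr__(self, "axis_entry", np.asarray(self.axis_entry, dtype=float))
        object.__setattr__(self, "axis_end", np.asarray(self.axis_end, dtype=float))
        if self.radius <= 0:
            raise ValueError("corridor radius must be > 0")
        if np.linalg.norm(self.axis_end - self.axis_entry) < 1e-9:
            raise ValueError("corridor axis is degenerate")

    def transformed(self, T: SimilarityTransform) -> "Corridor":
        """Map the corridor (a geometric object: radius scales with T)."""
        return Corridor(
            label=self.label,
            axis_entry=T.apply(self.axis_entry),
            axis_end=T.apply(self.axis_end),
            radius=self.radius * T.scale,
            forbidden_regions=dict(self.forbidden_regions),
        )


@dataclass(frozen=True)
class PhantomParams:
    """Generating parameters of the phantom, all in mm unless noted.

    The corridor centre offsets are measured from the inter-ASIS midpoint:
    positive ``posterior`` towards the sacrum (-y), positive ``inferior``
    towards the feet (-z). The defaults place S2 both further from the
    inter-ASIS axis than S1 (so registration tilt displaces it more) and
    predominantly inferior to that axis (so an anterior symphysis bias
    displaces it mostly anteriorly) — the regime of an adult pelvis in which
    the narrow S2 corridor fails anteriorly first.
    """

    asis_span: float = 240.0
    symphysis_drop: float = 90.0
    s1_radius: float = 7.5
    s2_radius: float = 5.5
    screw_diameter: float = 7.5
    s1_posterior: float = 50.0
    s1_inferior: float = 30.0
    s2_posterior: float = 55.0
    s2_inferior: float = 65.0
    entry_halfwidth: float = 80.0
    axis_overshoot: float = 10.0

    def __post_init__(self):
        for name in (
            "asis_span",
            "symphysis_drop",
            "s1_radius",
            "s2_radius",
            "screw_diameter",
            "entry_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.s1_radius <= self.s2_radius:
            raise ValueError("the S1 corridor must be wider than the S2 corridor")
        if self.axis_overshoot < 0:
            raise ValueError("axis_overshoot must be >= 0")
        if self.entry_halfwidth <= self.axis_overshoot:
            raise ValueError("entry_halfwidth must exceed axis_overshoot")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PhantomPelvis:
    """A generated phantom: landmarks, corridors, planned trajectories."""

    landmarks: LandmarkSet
    corridors: dict  # label -> Corridor
    planned: dict  # label -> Trajectory (corridor axis)
    params: PhantomParams
    mesh: object = None  # optional trimesh.Trimesh

    def planned_in_order(self) -> list:
        return [(label, self.planned[label]) for label in DRILLING_ORDER]


def _corridor_and_plan(label: str, center: np.ndarray, side: int, params: PhantomParams):
    """Build one corridor capsule and its planned axis trajectory.

    ``side`` is +1 for right, -1 for left. Entry is lateral, the aim point
    is the vertebral body centre (x = 0); the corridor axis overshoots the
    centre slightly so the capsule does not end exactly at the aim point.
    """
    radius = params.s1_radius if label.startswith("S1") else params.s2_radius
    entry = center + np.array([side * params.entry_halfwidth, 0.0, 0.0])
    end = center + np.array([-side * params.axis_overshoot, 0.0, 0.0])
    corridor = Corridor(label=label, axis_entry=entry, axis_end=end, radius=radius)
    plan = Trajectory(
        entry=entry,
        central_aim=center,
        diameter=params.screw_diameter,
        depth=params.entry_halfwidth,
    )
    return corridor, plan


def make_phantom(
    params: PhantomParams | None = None,
    seed: int = 0,
    with_mesh: bool = False,
) -> PhantomPelvis:
    """Generate the parametric phantom.

    The construction is deterministic for fixed parameters; ``seed`` is
    accepted for interface symmetry with the samplers and reserved for
    future stochastic shape variation.
    """
    params = params or PhantomParams()
    half = 0.5 * params.asis_span
    landmarks = LandmarkSet(
        left_asis=np.array([-half, 0.0, 0.0]),
        right_asis=np.array([half, 0.0, 0.0]),
        symphysis=np.array([0.0, 0.0, -params.symphysis_drop]),
    )
    centers = {
        "S1": np.array([0.0, -params.s1_posterior, -params.s1_inferior]),
        "S2": np.array([0.0, -params.s2_posterior, -params.s2_inferior]),
    }
    corridors: dict = {}
    planned: dict = {}
    for label in DRILLING_ORDER:
        level, side_name = label.split("_")
        side = 1 if side_name == "right" else -1
        corridor, plan = _corridor_and_plan(label, centers[level], side, params)
        corridors[label] = corridor
        planned[label] = plan

    mesh = _build_mesh(landmarks, corridors, params) if with_mesh else None
    return PhantomPelvis(
        landmarks=landmarks, corridors=corridors, planned=planned, params=params, mesh=mesh
    )


def _build_mesh(landmarks: LandmarkSet, corridors: dict, params: PhantomParams):
    """Stylised bone surface: corridor capsules plus landmark knobs.

    Intended for visualisation and file-format round-trips, not anatomy.
    """
    import trimesh

    parts = []
    for c in corridors.values():
        axis = c.axis_end - c.axis_entry
        length = float(np.linalg.norm(axis))
        cap = trimesh.creation.capsule(radius=c.radius, height=length)
        # capsule() is z-aligned and centred; move it onto the corridor axis
        z = np.array([0.0, 0.0, 1.0])
        T = trimesh.geometry.align_vectors(z, axis / length)
        T[:3, 3] = 0.5 * (c.axis_entry + c.axis_end)
        cap.apply_transform(T)
        parts.append(cap)
    for p in landmarks.as_array():
        knob = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        knob.apply_translation(p)
        parts.append(knob)
    return trimesh.util.concatenate(parts)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic error sources of the simulated workflow.

    Parameters
    ----------
    landmark_sigma : float
        Isotropic Gaussian SD per probed landmark coordinate, mm.
    symphysis_anterior_bias : float
        Systematic offset of the probed symphysis along the patient's
        anterior axis, mm (marking the symphysis "too far anteriorly").
    operator_entry_sigma : float
        Gaussian SD of the drill entry jitter, mm.
    operator_angle_sigma : float
        Gaussian SD of the drill axis angular jitter, degrees.
    seed : int
        Default seed for stand-alone sampling calls.
    """

    landmark_sigma: float = 2.0
    symphysis_anterior_bias: float = 0.0
    operator_entry_sigma: float = 1.0
    operator_angle_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("landmark_sigma", "operator_entry_sigma", "operator_angle_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def zeroed(self) -> "NoiseModel":
        """Copy with every noise term switched off."""
        return replace(
            self,
            landmark_sigma=0.0,
            symphysis_anterior_bias=0.0,
            operator_entry_sigma=0.0,
            operator_angle_sigma=0.0,
        )

    def to_dict(self) -> dict:
        return {
            "landmark_sigma": self.landmark_sigma,
            "symphysis_anterior_bias": self.symphysis_anterior_bias,
            "operator_entry_sigma": self.operator_entry_sigma,
            "operator_angle_sigma": self.operator_angle_sigma,
            "seed": self.seed,
        }


def probe_landmarks(
    phantom: PhantomPelvis,
    world_transform: SimilarityTransform,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> LandmarkSet:
    """Simulate probing the three landmarks on the positioned patient.

    The model landmarks are mapped through ``world_transform`` (the true
    patient pose), perturbed by isotropic Gaussian noise, and the symphysis
    is additionally offset by the systematic anterior bias along the world
    anterior axis.
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    world = world_transform.apply(phantom.landmarks.as_array())
    frame = build_frame(LandmarkSet.from_array(world))
    pts = world + rng.normal(0.0, noise.landmark_sigma, size=(3, 3)) if noise.landmark_sigma > 0 else world.copy()
    pts[2] = pts[2] + noise.symphysis_anterior_bias * frame.anterior
    return LandmarkSet.from_array(pts)


def _perpendicular_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def simulate_drilling(
    planned_world: Trajectory,
    guidance_error: SimilarityTransform,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one drilling guided by an imperfectly registered hologram.

    The drill follows the hologram, i.e. the planned trajectory mapped
    through ``guidance_error`` (the registration's target error,
    ``T_est o T_true^-1``). Operator imprecision then jitters the entry
    point (isotropic Gaussian) and tilts the axis (independent Gaussian
    angular components about two perpendicular axes). Screw diameter and
    insertion depth are physical properties and are preserved.
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    followed = planned_world.transformed(guidance_error, preserve_physical=True)
    entry = followed.entry
    direction = followed.direction
    if noise.operator_entry_sigma > 0:
        entry = entry + rng.normal(0.0, noise.operator_entry_sigma, size=3)
    if noise.operator_angle_sigma > 0:
        e1, e2 = _perpendicular_basis(direction)
        sd = np.tan(np.deg2rad(noise.operator_angle_sigma))
        a1, a2 = rng.normal(0.0, sd, size=2)
        direction = direction + a1 * e1 + a2 * e2
        direction = direction / np.linalg.norm(direction)
    aim_dist = float(np.linalg.norm(followed.central_aim - followed.entry))
    return Trajectory(
        entry=entry,
        central_aim=entry + aim_dist * direction,
        diameter=planned_world.diameter,
        depth=planned_world.depth,
    )
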