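"""Intraoperative guidance as a deterministic, replayable state machine.

Consumes a stream of tracked drill poses (tip + axis direction, the
"laser" the headset overlays on the drill) and emits the feedback events the
display surfaced: the entry marker turning green when the drill tip sits on
the planned entry point, the axis turning green when the drill ray
additionally passes the planned central aim point, and progression to the
next screw of the plan once the planned depth is reached. The screws are
worked through in the fixed protocol order S1 right, S1 left, S2 right,
S2 left.

The alignment flags are pure functions of the current pose, the active plan
and the monotone phase progression
``searching -> entry_captured -> aligned -> depth_reached`` per screw — no
other hidden state. Identical pose streams therefore always produce
identical event logs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .geometry import Trajectory
from .phantom import DRILLING_ORDER

__all__ = [
    "DrillPose",
    "GuidanceTolerances",
    "GuidancePhase",
    "GuidanceState",
    "GuidanceEvent",
    "GuidanceSession",
]


@dataclass(frozen=True)
class DrillPose:
    """One tracked drill sample: time (s), tip position (mm), unit direction."""

    timestamp: float
    tip: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))

    def direction_is_unit(self, tol: float = 1e-6) -> bool:
        return abs(float(np.linalg.norm(self.direction)) - 1.0) <= tol


@dataclass(frozen=True)
class GuidanceTolerances:
    """Alignment tolerances.

    ``entry_mm``: radius of the entry sphere around the planned entry point.
    ``aim_mm``: maximal distance of the drill ray from the planned central
    aim point for the axis to count as aligned. Defaults sit well below the
    default corridor radii, so satisfied guidance implies geometric safety.
    ``stale_after_s``: tracking-loss timeout; a pose gap longer than this
    emits a ``tracking_stale`` event (flags simply hold their last values).
    """

    entry_mm: float = 2.0
    aim_mm: float = 2.0
    stale_after_s: float = 1.0

    def __post_init__(self):
        if self.entry_mm <= 0 or self.aim_mm <= 0 or self.stale_after_s <= 0:
            raise ValueError("tolerances must be positive")


class GuidancePhase(str, Enum):
    SEARCHING = "searching"
    ENTRY_CAPTURED = "entry_captured"
    ALIGNED = "aligned"
    DEPTH_REACHED = "depth_reached"
    COMPLETE = "complete"


_PHASE_ORDER = {
    GuidancePhase.SEARCHING: 0,
    GuidancePhase.ENTRY_CAPTURED: 1,
    GuidancePhase.ALIGNED: 2,
    GuidancePhase.DEPTH_REACHED: 3,
    GuidancePhase.COMPLETE: 4,
}


@dataclass(frozen=True)
class GuidanceState:
    active_screw: str
    entry_ok: bool = False
    axis_ok: bool = False
    depth_progress: float = 0.0
    phase: GuidancePhase = GuidancePhase.SEARCHING


@dataclass(frozen=True)
class GuidanceEvent:
    timestamp: float
    event: str
    screw: str

    def to_dict(self) -> dict:
        return {"t": float(self.timestamp), "event": self.event, "screw": self.screw}


class GuidanceSession:
    """Replayable guidance over an ordered screw plan.

    Parameters
    ----------
    plan : dict
        Mapping screw label -> planned :class:`~sacronav.geometry.Trajectory`
        in patient/world space.
    order : sequence of str
        Drilling order; defaults to the protocol order.
    tolerances : GuidanceTolerances
    """

    def __init__(
        self,
        plan: dict,
        order=DRILLING_ORDER,
        tolerances: GuidanceTolerances | None = None,
    ):
        missing = [label for label in order if label not in plan]
        if missing:
            raise ValueError(f"plan is missing screws: {missing}")
        self.plan = dict(plan)
        self.order = tuple(order)
        self.tolerances = tolerances or GuidanceTolerances()
        self._index = 0
        self._last_t: float | None = None
        self.state = GuidanceState(active_screw=self.order[0])

    # -- pure pose predicates -------------------------------------------------

    def _entry_ok(self, pose: DrillPose, planned: Trajectory, drilling: bool) -> bool:
        # While positioning, the drill tip itself must sit on the entry
        # point; once drilling is underway the tip is inside the bone and it
        # is the shaft (the drill axis) that must keep passing through the
        # entry point.
        if drilling:
            w = planned.entry - pose.tip
            offset = w - float(np.dot(w, pose.direction)) * pose.direction
            return float(np.linalg.norm(offset)) <= self.tolerances.entry_mm
        return float(np.linalg.norm(pose.tip - planned.entry)) <= self.tolerances.entry_mm

    def _axis_ok(self, pose: DrillPose, planned: Trajectory) -> bool:
        # distance of the planned central aim point from the drill ray
        # (tip + s * direction, s >= 0)
        w = planned.central_aim - pose.tip
        s = max(0.0, float(np.dot(w, pose.direction)))
        closest = pose.tip + s * pose.direction
        return float(np.linalg.norm(planned.central_aim - closest)) <= self.tolerances.aim_mm

    # -- state machine --------------------------------------------------------

    def update(self, pose: DrillPose) -> list[GuidanceEvent]:
        """Consume one pose; return the events it triggers.

        A pose with a non-unit direction is rejected: an ``invalid_pose``
        event is emitted and the state is left untouched.
        """
        st = self.state
        if st.phase is GuidancePhase.COMPLETE:
            return []
        events: list[GuidanceEvent] = []
        if not pose.direction_is_unit():
            return [GuidanceEvent(pose.timestamp, "invalid_pose", st.active_screw)]
        if (
            self._last_t is not None
            and pose.timestamp - self._last_t > self.tolerances.stale_after_s
        ):
            events.append(GuidanceEvent(pose.timestamp, "tracking_stale", st.active_screw))
        self._last_t = pose.timestamp

        planned = self.plan[st.active_screw]
        drilling = _PHASE_ORDER[st.phase] >= _PHASE_ORDER[GuidancePhase.ALIGNED]
        entry_ok = self._entry_ok(pose, planned, drilling)
        axis_ok = entry_ok and self._axis_ok(pose, planned)
        depth = max(0.0, float(np.dot(pose.tip - planned.entry, planned.direction)))

        if entry_ok and not st.entry_ok:
            events.append(GuidanceEvent(pose.timestamp, "entry_captured", st.active_screw))
        if not entry_ok and st.entry_ok:
            events.append(GuidanceEvent(pose.timestamp, "entry_lost", st.active_screw))
        if axis_ok and not st.axis_ok:
            events.append(GuidanceEvent(pose.timestamp, "aligned", st.active_screw))
        if not axis_ok and st.axis_ok:
            events.append(GuidanceEvent(pose.timestamp, "alignment_lost", st.active_screw))

        phase = st.phase
        if entry_ok and _PHASE_ORDER[phase] < _PHASE_ORDER[GuidancePhase.ENTRY_CAPTURED]:
            phase = GuidancePhase.ENTRY_CAPTURED
        if axis_ok and _PHASE_ORDER[phase] < _PHASE_ORDER[GuidancePhase.ALIGNED]:
            phase = GuidancePhase.ALIGNED
        if (
            depth >= planned.depth
            and phase is GuidancePhase.ALIGNED
        ):
            phase = GuidancePhase.DEPTH_REACHED
            events.append(GuidanceEvent(pose.timestamp, "depth_reached", st.active_screw))

        self.state = GuidanceState(
            active_screw=st.active_screw,
            entry_ok=entry_ok,
            axis_ok=axis_ok,
            depth_progress=depth,
            phase=phase,
        )
        return events

    def advance(self, timestamp: float | None = None) -> list[GuidanceEvent]:
        """Move to the next screw of the plan.

        Only legal once the current screw has reached planned depth. After
        the last screw the session enters the terminal ``complete`` phase.
        """
        st = self.state
        if st.phase is GuidancePhase.COMPLETE:
            return []
        if st.phase is not GuidancePhase.DEPTH_REACHED:
            raise RuntimeError(
                f"cannot advance from phase {st.phase.value!r}; planned depth not reached"
            )
        t = self._last_t if timestamp is None else timestamp
        events = [GuidanceEvent(t if t is not None else 0.0, "advanced", st.active_screw)]
        self._index += 1
        if self._index >= len(self.order):
            self.state = replace(st, phase=GuidancePhase.COMPLETE)
        else:
            self.state = GuidanceState(active_screw=self.order[self._index])
            self._last_t = None
        return events

    def replay(self, poses, auto_advance: bool = True) -> list[GuidanceEvent]:
        """Run a whole pose stream; optionally auto-advance at depth."""
        events: list[GuidanceEvent] = []
        for pose in poses:
            events.extend(self.update(pose))
            if auto_advance and self.state.phase is GuidancePhase.DEPTH_REACHED:
                events.extend(self.advance())
        return events

    @property
    def complete(self) -> bool:
        return self.state.phase is GuidancePhase.COMPLETE
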