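"""Placement metrics: MLD, deviations, perforation verdict and direction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sacronav import (
    Corridor,
    LandmarkSet,
    Trajectory,
    angular_deviation,
    build_frame,
    central_aim_deviation,
    detect_perforation,
    entry_deviation,
    evaluate_placement,
    mld,
)
from sacronav.metrics import detect_perforation_mesh

from conftest import random_trajectory

# canonical frame: +x lateral, +y anterior, +z superior
FRAME = build_frame(LandmarkSet([-120, 0, 0], [120, 0, 0], [0, 0, -90]))


def z_axis_trajectory(entry, tip_offset, diameter=7.5, depth=100.0):
    entry = np.asarray(entry, float)
    tip = entry + np.asarray(tip_offset, float)
    return Trajectory(entry, tip, diameter, depth)


class TestMLD:
    def test_zero_for_identical_trajectories(self):
        t = Trajectory([0, 0, 0], [0, 0, 100], 7.5, 100.0)
        value, loc = mld(t, t)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert loc == "tip"  # tie reported at the riskier end

    def test_tip_deviation_example(self):
        planned = Trajectory([0, 0, 0], [0, 0, 100], 7.5, 100.0)
        # drilled from the same base, tip displaced 10 mm laterally at depth 100
        drilled = Trajectory([0, 0, 0], [10, 0, 100], 7.5, np.hypot(10, 100))
        value, loc = mld(planned, drilled)
        assert value == pytest.approx(10.0, abs=1e-9)
        assert loc == "tip"

    def test_base_deviation(self):
        planned = Trajectory([0, 0, 0], [0, 0, 100], 7.5, 100.0)
        drilled = Trajectory([8, 0, 0], [0, 0, 100], 7.5, np.hypot(8, 100))
        value, loc = mld(planned, drilled)
        assert value == pytest.approx(8.0, abs=1e-9)
        assert loc == "base"

    def test_matches_dense_sampling_oracle(self, rng):
        """Endpoint evaluation equals the max over 1e4 sampled axis points."""
        for _ in range(200):
            planned = random_trajectory(rng)
            drilled = random_trajectory(rng)
            value, loc = mld(planned, drilled)
            t = np.linspace(0.0, 1.0, 10_000)
            pts = drilled.entry + t[:, None] * (drilled.tip - drilled.entry)
            w = pts - planned.entry
            d = planned.direction
            dists = np.linalg.norm(w - np.outer(w @ d, d), axis=1)
            assert value == pytest.approx(float(dists.max()), abs=1e-3)
            expected_loc = "base" if int(np.argmax(dists)) == 0 else "tip"
            assert loc == expected_loc


class TestDeviations:
    def test_entry_345(self):
        planned = z_axis_trajectory([0, 0, 0], [0, 0, 100])
        drilled = z_axis_trajectory([3, 4, 0], [0, 0, 100])
        assert entry_deviation(planned, drilled) == pytest.approx(5.0)

    def test_entry_invariant_under_shared_rigid_motion(self, rng):
        planned, drilled = random_trajectory(rng), random_trajectory(rng)
        base = entry_deviation(planned, drilled)
        Q = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-100, 100, size=3)

        def move(traj):
            return Trajectory(Q @ traj.entry + t, Q @ traj.central_aim + t,
                              traj.diameter, traj.depth)

        assert entry_deviation(move(planned), move(drilled)) == pytest.approx(base, abs=1e-9)

    def test_central_aim_zero_when_tip_hits_aim(self):
        planned = Trajectory([0, 0, 0], [0, 0, 80], 7.5, 80.0)
        assert central_aim_deviation(planned, planned) == pytest.approx(0.0, abs=1e-12)

    def test_central_aim_counts_drilling_short(self):
        planned = Trajectory([0, 0, 0], [0, 0, 80], 7.5, 80.0)
        short = Trajectory([0, 0, 0], [0, 0, 80], 7.5, 70.0)
        assert central_aim_deviation(planned, short) == pytest.approx(10.0, abs=1e-12)

    def test_central_aim_matches_vector_oracle(self, rng):
        for _ in range(50):
            planned, drilled = random_trajectory(rng), random_trajectory(rng)
            tip = drilled.entry + drilled.depth * drilled.direction
            expected = float(np.linalg.norm(planned.central_aim - tip))
            assert central_aim_deviation(planned, drilled) == pytest.approx(expected, abs=1e-12)

    def test_angular_examples(self):
        p = Trajectory([0, 0, 0], [0, 0, 100], 7.5, 100.0)
        assert angular_deviation(p, p) == pytest.approx(0.0, abs=1e-9)
        five = Trajectory([0, 0, 0], [np.sin(np.deg2rad(5)), 0, np.cos(np.deg2rad(5))], 7.5, 100.0)
        assert angular_deviation(p, five) == pytest.approx(5.0, abs=1e-9)
        anti = Trajectory([0, 0, 0], [0, 0, -100], 7.5, 100.0)
        assert angular_deviation(p, anti) == pytest.approx(180.0, abs=1e-9)

    def test_pure_orthogonal_translation_relation(self):
        """Translation orthogonal to the axis: MLD equals the entry deviation
        and the angular deviation vanishes."""
        planned = Trajectory([0, 0, 0], [0, 0, 100], 7.5, 100.0)
        drilled = Trajectory([2, 1, 0], [2, 1, 100], 7.5, 100.0)
        value, _ = mld(planned, drilled)
        assert value == pytest.approx(entry_deviation(planned, drilled), abs=1e-9)
        assert angular_deviation(planned, drilled) == pytest.approx(0.0, abs=1e-9)


def corridor_x(radius=7.5):
    """Transverse corridor along the lateral (x) axis, like a real SI channel."""
    return Corridor("S1_right", [90, 0, 0], [-20, 0, 0], radius)


def offset_screw(dy, dz, diameter=7.5):
    """Screw parallel to the corridor, axis offset (anterior, superior) = (dy, dz)."""
    return Trajectory([80, dy, dz], [0, dy, dz], diameter, 80.0)


class TestPerforation:
    def test_centered_screw_inside_wide_corridor(self):
        finding = detect_perforation(offset_screw(0, 0), corridor_x(7.5), FRAME)
        assert not finding.perforated
        assert finding.directions == frozenset()
        assert finding.breach_depth == 0.0

    def test_anterior_offset_breach_arithmetic(self):
        # parallel axis offset 4.0 mm toward anterior (+y): 4.0 + 3.75 > 7.5
        finding = detect_perforation(offset_screw(4.0, 0), corridor_x(7.5), FRAME)
        assert finding.perforated
        assert finding.directions == frozenset({"anterior"})
        assert finding.breach_depth == pytest.approx(0.25, abs=1e-9)

    def test_combined_direction_labels(self):
        # equal anterior and superior offset components: combined label
        off = 4.0 / np.sqrt(2)
        finding = detect_perforation(offset_screw(off, off), corridor_x(7.5), FRAME)
        assert finding.perforated
        assert finding.directions == frozenset({"anterior", "superior"})

    def test_pure_direction_classification(self):
        c = corridor_x(7.5)
        assert detect_perforation(offset_screw(-5.0, 0), c, FRAME).directions == frozenset(
            {"posterior"}
        )
        assert detect_perforation(offset_screw(0, 5.0), c, FRAME).directions == frozenset(
            {"superior"}
        )
        assert detect_perforation(offset_screw(0, -5.0), c, FRAME).directions == frozenset(
            {"inferior"}
        )

    def test_weak_secondary_component_stays_pure(self):
        # secondary below tan(22.5 deg) of primary: single label
        finding = detect_perforation(offset_screw(5.0, 1.0), corridor_x(7.5), FRAME)
        assert finding.directions == frozenset({"anterior"})

    def test_verdict_monotone_in_radius_and_offset(self, rng):
        """Growing the screw or the offset never turns a breach safe."""
        for _ in range(100):
            corridor = Corridor("S1_left", rng.uniform(-50, 50, 3),
                                rng.uniform(-50, 50, 3) + [0, 0, 100],
                                rng.uniform(4.0, 10.0))
            screw = random_trajectory(rng, box=60.0)
            f1 = detect_perforation(screw, corridor, FRAME)
            fatter = Trajectory(screw.entry, screw.central_aim,
                                screw.diameter + 2.0, screw.depth)
            f2 = detect_perforation(fatter, corridor, FRAME)
            if f1.perforated:
                assert f2.perforated
                assert f2.breach_depth >= f1.breach_depth - 1e-12

    def test_matches_capsule_surface_sampling_oracle(self, rng):
        """Analytic verdict vs brute-force sampling of the screw capsule
        surface against the corridor capsule (small-n version)."""
        agree = 0
        n = 100
        for _ in range(n):
            corridor = Corridor("S2_right", rng.uniform(-40, 40, 3),
                                rng.uniform(-40, 40, 3) + [60, 0, 0],
                                rng.uniform(4.0, 9.0))
            screw = random_trajectory(rng, box=50.0, depth_range=(30.0, 90.0))
            analytic = detect_perforation(screw, corridor, FRAME)

            # oracle: per axial slice, the surface point farthest from the
            # corridor axis; outside iff its distance exceeds the radius
            t = np.linspace(0.0, 1.0, 1000)
            pts = screw.entry + t[:, None] * (screw.tip - screw.entry)
            a, b = corridor.axis_entry, corridor.axis_end
            ab = b - a
            s = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
            closest = a + s[:, None] * ab
            w = pts - closest
            d = np.linalg.norm(w, axis=1)
            safe = d > 1e-12
            what = np.zeros_like(w)
            what[safe] = w[safe] / d[safe, None]
            what[~safe] = np.array([1.0, 0.0, 0.0])
            surface = pts + screw.radius * what
            ds = np.linalg.norm(
                surface - (a + np.clip((surface - a) @ ab / (ab @ ab), 0, 1)[:, None] * ab),
                axis=1,
            )
            brute = bool(np.any(ds > corridor.radius))
            agree += analytic.perforated == brute
        assert agree >= n - 1

    def test_mesh_based_detector_agrees_with_analytic_on_capsule_mesh(self):
        import trimesh

        corridor = corridor_x(7.5)
        mesh = trimesh.creation.capsule(radius=7.5, height=110.0)
        # capsule() is z-aligned and centred; rotate onto the x axis and
        # move the centre to x=35 so the axis runs from x=90 to x=-20
        mesh.apply_transform(
            trimesh.geometry.align_vectors([0, 0, 1.0], [-1.0, 0, 0])
        )
        mesh.apply_translation([35.0, 0, 0])
        inside = offset_screw(2.0, 0)
        outside = offset_screw(5.0, 0)
        assert not detect_perforation_mesh(inside, mesh, FRAME).perforated
        assert not detect_perforation(inside, corridor, FRAME).perforated
        f_mesh = detect_perforation_mesh(outside, mesh, FRAME)
        f_analytic = detect_perforation(outside, corridor, FRAME)
        assert f_mesh.perforated and f_analytic.perforated
        assert "anterior" in f_mesh.directions
        assert f_mesh.breach_depth == pytest.approx(f_analytic.breach_depth, abs=0.1)


class TestEvaluatePlacement:
    def test_perfect_placement_all_zero(self):
        planned = offset_screw(0, 0)
        report = evaluate_placement(planned, planned, corridor_x(7.5), FRAME, "S1_right")
        assert report.correct
        assert report.mld == pytest.approx(0.0, abs=1e-12)
        assert report.entry_deviation == pytest.approx(0.0, abs=1e-12)
        assert report.central_aim_deviation == pytest.approx(0.0, abs=1e-12)
        assert report.angular_deviation == pytest.approx(0.0, abs=1e-9)

    def test_anterior_breach_marked_incorrect(self):
        planned = offset_screw(0, 0)
        drilled = offset_screw(4.0, 0)
        report = evaluate_placement(planned, drilled, corridor_x(7.5), FRAME)
        assert not report.correct
        assert report.perforation.directions == frozenset({"anterior"})

    def test_batch_matches_independent_recomputation(self, rng):
        """Per-row agreement with a directly scripted recomputation."""
        for _ in range(50):
            planned = random_trajectory(rng)
            drilled = random_trajectory(rng)
            corridor = Corridor("S1_left", planned.entry, planned.tip, 7.5)
            report = evaluate_placement(planned, drilled, corridor, FRAME)

            d = planned.direction
            ends = [drilled.entry, drilled.entry + drilled.depth * drilled.direction]
            dists = [
                np.linalg.norm((e - planned.entry) - ((e - planned.entry) @ d) * d)
                for e in ends
            ]
            assert report.mld == pytest.approx(max(dists), abs=1e-9)
            assert report.entry_deviation == pytest.approx(
                np.linalg.norm(planned.entry - drilled.entry), abs=1e-9
            )
            assert report.angular_deviation == pytest.approx(
                np.degrees(
                    np.arccos(np.clip(np.dot(planned.direction, drilled.direction), -1, 1))
                ),
                abs=1e-9,
            )
            assert report.correct == (not report.perforation.perforated)

    def test_metrics_invariant_under_shared_rigid_motion(self, rng):
        planned, drilled = random_trajectory(rng), random_trajectory(rng)
        corridor = Corridor("S2_left", planned.entry, planned.tip, 6.0)
        r1 = evaluate_placement(planned, drilled, corridor, FRAME)
        Q = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-100, 100, size=3)

        def move_t(traj):
            return Trajectory(Q @ traj.entry + t, Q @ traj.central_aim + t,
                              traj.diameter, traj.depth)

        corridor2 = Corridor("S2_left", Q @ corridor.axis_entry + t,
                             Q @ corridor.axis_end + t, corridor.radius)
        lm = LandmarkSet.from_array(
            np.array([[-120, 0, 0], [120, 0, 0], [0, 0, -90]]) @ Q.T + t
        )
        r2 = evaluate_placement(move_t(planned), move_t(drilled), corridor2, build_frame(lm))
        assert r2.mld == pytest.approx(r1.mld, abs=1e-9)
        assert r2.entry_deviation == pytest.approx(r1.entry_deviation, abs=1e-9)
        assert r2.central_aim_deviation == pytest.approx(r1.central_aim_deviation, abs=1e-9)
        assert r2.angular_deviation == pytest.approx(r1.angular_deviation, abs=1e-6)
        assert r2.perforation.perforated == r1.perforation.perforated
        assert r2.perforation.directions == r1.perforation.directions
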