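"""Gate construction, Boolean selection, splitting and the full dissection."""

import numpy as np
import pytest

from smtract.gating import (
    Gate,
    GateExtents,
    GateProtocol,
    apply_protocol,
    build_sm_protocol,
    midplane_crossings,
    not_templates,
    split_between_gates,
    streamline_crosses_gate,
)
from smtract.phantom import Landmarks
from smtract.space import AffineGrid
from smtract.tracking import Streamline, Tractogram


def _gate(role="AND", plane="axial", slab=(9.5, 10.5), rect=((0.0, 10.0), (0.0, 10.0)),
          label="g"):
    return Gate(role=role, plane=plane, slab=slab, rect=rect, label=label)


def _tg(point_arrays, grid=None):
    grid = grid or AffineGrid((64, 64, 64), np.eye(4))
    return Tractogram(
        [Streamline(points=np.asarray(p, float), seed_index=0) for p in point_arrays],
        grid,
    )


def dense_membership(points, gate, h=0.01):
    """Brute-force oracle: membership of the densely resampled polyline."""
    p = np.asarray(points, dtype=float)
    samples = [p[:1]]
    for a, b in zip(p[:-1], p[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / h)) + 1)
        t = np.linspace(0.0, 1.0, n)[1:]
        samples.append(a + t[:, None] * (b - a))
    return bool(gate.contains(np.vstack(samples)).any())


class TestGateMembership:
    def test_perpendicular_pass_through_centre(self):
        g = _gate()
        pts = [(5.0, 5.0, 0.0), (5.0, 5.0, 20.0)]
        assert streamline_crosses_gate(np.array(pts), g)

    def test_laterally_disjoint(self):
        g = _gate()
        pts = np.array([(11.0, 5.0, 0.0), (11.0, 5.0, 20.0)])
        assert not streamline_crosses_gate(pts, g)

    def test_vertex_inside_slab(self):
        g = _gate()
        pts = np.array([(5.0, 5.0, 10.0), (5.0, 5.0, 10.2)])
        assert streamline_crosses_gate(pts, g)

    def test_oracle_equivalence_1000_random_polylines(self):
        """Exact segment-box verdicts match dense resampling membership."""
        g = _gate(slab=(9.5, 10.5), rect=((3.0, 9.0), (2.0, 8.0)))
        rng = np.random.default_rng(2024)
        mismatches = 0
        for _ in range(1000):
            n = rng.integers(2, 8)
            pts = rng.uniform(0, 14, size=(n, 3))
            fast = streamline_crosses_gate(pts, g)
            slow = dense_membership(pts, g)
            mismatches += fast != slow
        assert mismatches == 0

    def test_invalid_gate_geometry_rejected(self):
        with pytest.raises(ValueError):
            _gate(slab=(10.5, 9.5))
        with pytest.raises(ValueError):
            _gate(rect=((0.0, 0.0), (0.0, 1.0)))


def _phantom_landmarks():
    return Landmarks(
        ac_apex=np.array([32.0, 41.6, 27.0]),
        pineal_apex=np.array([32.0, 22.4, 26.0]),
        thalamus_mid=np.array([32.0, 32.0, 34.6]),
    )


class TestProtocolConstruction:
    def test_gates_contain_arc_ends_and_apex(self, phantom_bundle):
        _, _, _, truth = phantom_bundle
        proto = build_sm_protocol(truth.landmarks, truth.grid)
        anterior, posterior = proto.or_gates
        mid = proto.and_gates[0]
        cl = truth.centerline
        assert streamline_crosses_gate(cl[:20], anterior)
        assert streamline_crosses_gate(cl[-20:], posterior)
        apex = cl[len(cl) // 2 - 20 : len(cl) // 2 + 20]
        assert streamline_crosses_gate(apex, mid)

    def test_translation_equivariance(self):
        grid = AffineGrid((64, 64, 64), np.eye(4))
        lm = _phantom_landmarks()
        delta = np.array([1.5, -2.0, 3.0])
        lm2 = Landmarks(
            ac_apex=lm.ac_apex + delta,
            pineal_apex=lm.pineal_apex + delta,
            thalamus_mid=lm.thalamus_mid + delta,
        )
        p1 = build_sm_protocol(lm, grid)
        p2 = build_sm_protocol(lm2, grid)
        for g1, g2 in zip(p1.all_gates(), p2.all_gates()):
            n = g1.normal_axis
            assert np.allclose(np.asarray(g2.slab) - np.asarray(g1.slab), delta[n])
            u, v = g1.plane_axes
            assert np.allclose(np.asarray(g2.rect[0]) - np.asarray(g1.rect[0]), delta[u])
            assert np.allclose(np.asarray(g2.rect[1]) - np.asarray(g1.rect[1]), delta[v])

    def test_landmark_ordering_violation_raises(self):
        with pytest.raises(ValueError, match="ordering"):
            Landmarks(
                ac_apex=np.array([32.0, 22.0, 27.0]),
                pineal_apex=np.array([32.0, 41.0, 26.0]),  # pineal anterior: wrong
                thalamus_mid=np.array([32.0, 32.0, 34.6]),
            )

    def test_gate_outside_grid_rejected(self):
        grid = AffineGrid((16, 16, 16), np.eye(4))
        lm = _phantom_landmarks()  # landmarks sized for a 64-voxel grid
        with pytest.raises(ValueError, match="outside"):
            build_sm_protocol(lm, grid)

    def test_not_gate_overlapping_selection_gate_rejected(self):
        g_or = _gate(role="SEED_OR", label="or")
        g_not = _gate(role="NOT", slab=(10.0, 11.0), label="no")
        with pytest.raises(ValueError, match="overlaps"):
            GateProtocol(or_gates=[g_or], not_gates=[g_not])


class TestApplyProtocol:
    def test_no_gates_is_identity(self):
        t = _tg([np.random.default_rng(0).uniform(0, 60, (5, 3)) for _ in range(10)])
        out = apply_protocol(t, GateProtocol(or_gates=[]))
        assert len(out) == len(t)

    def test_universal_not_gate_empties_tractogram(self):
        t = _tg([np.random.default_rng(1).uniform(5, 55, (5, 3)) for _ in range(10)])
        whole = _gate(role="NOT", plane="axial", slab=(-1.0, 65.0),
                      rect=((-1.0, 65.0), (-1.0, 65.0)), label="all")
        out = apply_protocol(t, GateProtocol(or_gates=[], not_gates=[whole]))
        assert len(out) == 0
        assert out.provenance["selection"]["empty_warning"]

    def test_adding_not_gate_never_adds_streamlines(self):
        rng = np.random.default_rng(5)
        t = _tg([rng.uniform(0, 20, (6, 3)) for _ in range(60)])
        g_or = _gate(role="SEED_OR", slab=(8.0, 12.0),
                     rect=((0.0, 20.0), (0.0, 20.0)), label="or")
        g_not = _gate(role="NOT", plane="coronal", slab=(2.0, 4.0),
                      rect=((0.0, 20.0), (13.0, 20.0)), label="not")
        base = apply_protocol(t, GateProtocol(or_gates=[g_or]))
        cut = apply_protocol(t, GateProtocol(or_gates=[g_or], not_gates=[g_not]))
        kept = {id(s) for s in cut.streamlines}
        assert kept <= {id(s) for s in base.streamlines}


class TestSplit:
    def _spanning_streamline(self):
        # crosses z=27 upward at y=41.6, arcs, crosses down at y=22.4
        theta = np.linspace(-0.05, np.pi + 0.05, 100)
        R = 9.6
        return np.column_stack(
            [np.full_like(theta, 32.0), 32.0 + R * np.cos(theta), 27.0 + R * np.sin(theta)]
        )

    def _gates(self):
        lm = _phantom_landmarks()
        proto = build_sm_protocol(lm, AffineGrid((64, 64, 64), np.eye(4)))
        return proto.gate("anterior_or"), proto.gate("posterior_or")

    def test_endpoints_exactly_on_planes(self):
        a, p = self._gates()
        t = _tg([self._spanning_streamline()])
        out, info = split_between_gates(t, a, p)
        assert info["n_split"] == 1
        s = out.streamlines[0].points
        assert abs(s[0, 2] - a.midplane) < 1e-6
        assert abs(s[-1, 2] - p.midplane) < 1e-6

    def test_idempotence(self):
        a, p = self._gates()
        once, _ = split_between_gates(_tg([self._spanning_streamline()]), a, p)
        twice, _ = split_between_gates(once, a, p)
        assert np.allclose(
            once.streamlines[0].points, twice.streamlines[0].points, atol=1e-9
        )

    def test_orientation_normalized(self):
        a, p = self._gates()
        rev = self._spanning_streamline()[::-1]
        out, info = split_between_gates(_tg([rev]), a, p)
        s = out.streamlines[0].points
        assert s[0, 1] > s[-1, 1]  # runs anterior -> posterior after split

    def test_non_crossing_streamlines_dropped_and_counted(self):
        a, p = self._gates()
        stray = np.column_stack(
            [np.full(10, 5.0), np.linspace(5, 15, 10), np.full(10, 50.0)]
        )
        out, info = split_between_gates(_tg([self._spanning_streamline(), stray]), a, p)
        assert info["n_split"] == 1 and info["n_dropped"] == 1


class TestPipeline:
    def test_tract_nonempty_and_near_centerline(self, phantom_bundle, pipeline_result):
        _, _, _, truth = phantom_bundle
        res = pipeline_result
        assert not res.empty
        assert res.stats.n_streamlines > 20
        for s in res.tract:
            d = np.linalg.norm(
                s.points[:, None, :] - truth.centerline[None, :, :], axis=2
            ).min(axis=1)
            assert d.max() < 2.0

    def test_mean_clipped_length_matches_arc(self, phantom_bundle, pipeline_result):
        _, _, _, truth = phantom_bundle
        assert abs(pipeline_result.stats.mean_length - truth.arc_length) <= 0.5

    def test_not_templates_remove_distractors(self, phantom_bundle, pipeline_result):
        """>= 95% of distractor-labelled streamlines are excluded."""
        from tests.conftest import streamline_label_fraction

        _, _, _, truth = phantom_bundle
        dmask = np.zeros(truth.grid.shape, bool)
        for m in truth.distractor_masks.values():
            dmask |= m
        n_bad = sum(
            1 for s in pipeline_result.tract
            if streamline_label_fraction(s.points, dmask, truth.grid) > 0.5
        )
        assert n_bad <= 0.05 * max(1, len(pipeline_result.tract))

    def test_cleanup_robust_to_distractors(
        self, pipeline_result, pipeline_result_nodistr
    ):
        """Final streamline count unchanged (<= 5%) by adding distractors."""
        n_with = pipeline_result.stats.n_streamlines
        n_without = pipeline_result_nodistr.stats.n_streamlines
        assert abs(n_with - n_without) <= 0.05 * n_without

    def test_counts_logged(self, pipeline_result):
        c = pipeline_result.counts
        assert c["low_fidelity"]["n_whole_brain"] > 0
        assert c["high_fidelity"]["n_span_retained"] == pipeline_result.stats.n_streamlines


def test_coronal_not_gates_catch_fornix_like_arc(phantom_bundle):
    """The coronal NOT pair alone removes dorsal-arc distractor streamlines."""
    _, _, _, truth = phantom_bundle
    nots = [g for g in not_templates(truth.landmarks, truth.grid)
            if g.plane == "coronal"]
    # synthetic streamline along the fornix-body arc centerline
    theta = np.linspace(np.radians(-25), np.radians(205), 200)
    rho = truth.arc_radius + 3.5
    c = truth.arc_center
    pts = np.column_stack(
        [np.full_like(theta, c[0]), c[1] + rho * np.cos(theta), c[2] + rho * np.sin(theta)]
    )
    assert any(streamline_crosses_gate(pts, g) for g in nots)
    # while the tract centerline is untouched
    assert not any(streamline_crosses_gate(truth.centerline, g) for g in nots)


def test_crus_not_gates_catch_lateral_tubes(phantom_bundle):
    _, _, _, truth = phantom_bundle
    nots = [g for g in not_templates(truth.landmarks, truth.grid)
            if g.plane == "axial"]
    c = truth.arc_center
    t = np.linspace(0, 1, 100)[:, None]
    a = np.array([c[0] + 4.5, c[1] - 10.6, c[2] - 6.0])
    b = np.array([c[0] + 4.5, c[1] + 1.0, c[2] + 14.0])
    pts = a + t * (b - a)
    assert any(streamline_crosses_gate(pts, g) for g in nots)
    assert not any(streamline_crosses_gate(truth.centerline, g) for g in nots)
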