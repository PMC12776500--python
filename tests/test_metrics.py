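"""Axial difference, GOA, neighbor graph and LMS against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from misalign import (
    Cell,
    FieldSpec,
    LmsConfig,
    TissueAxis,
    angular_difference,
    build_neighbor_graph,
    fold_to_lms,
    generate_field,
    goa,
    goa_scores,
    lms_scores,
)
from conftest import axial_diff, ellipse


def make_cell(cid, x, y, theta, cls=None):
    """A tiny elongated cell at (x, y) whose orientation is forced to theta."""
    cell = Cell.from_polygon(cid, ellipse(x, y, 4, 1.5, theta), class_label=cls)
    cell.orientation_deg = theta  # exact values, free of polygon discretization
    cell.centroid = (float(x), float(y))
    return cell


def lms_brute_force(cells, radius, min_neighbors=1, fold=True):
    """Double-loop oracle: all-pairs distances, then per-cell mean fold."""
    out = {}
    for c in cells:
        diffs = []
        for o in cells:
            if o.id == c.id:
                continue
            d = np.hypot(c.centroid[0] - o.centroid[0], c.centroid[1] - o.centroid[1])
            if 0 < d <= radius:
                diffs.append(axial_diff(c.orientation_deg, o.orientation_deg))
        if len(diffs) >= min_neighbors:
            m = float(np.mean(diffs))
            out[c.id] = (45.0 - abs(45.0 - m)) if fold else m
        else:
            out[c.id] = np.nan
    return out


class TestAngularDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10, 170, 20),  # wraps across the 180° boundary
            (0, 90, 90),  # maximal axial separation
            (30, 30, 0),
            (170, 0, 10),
            (25, 25, 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert angular_difference(a, b) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            angular_difference(np.nan, 10.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.floats(-720, 720), b=st.floats(-720, 720))
    def test_range_symmetry_and_periodicity(self, a, b):
        d = angular_difference(a, b)
        assert 0.0 <= d <= 90.0
        assert d == pytest.approx(angular_difference(b, a))
        assert d == pytest.approx(angular_difference(a + 180.0, b), abs=1e-6)


class TestGoa:
    def test_perpendicular_is_90(self):
        assert goa(90.0, TissueAxis("a", 0.0)) == 90.0

    def test_axial_folding(self):
        assert goa(170.0, 0.0) == pytest.approx(10.0)

    def test_joint_rotation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            theta, axis, delta = rng.uniform(0, 180, 3)
            assert goa(theta + delta, axis + delta) == pytest.approx(
                goa(theta, axis), abs=1e-9
            )

    def test_missing_axis_names_annotation(self):
        cell = make_cell("c1", 0, 0, 10)
        cell.annotation_id = "tibia-1"
        with pytest.raises(KeyError, match="tibia-1"):
            goa_scores([cell], {"femur-1": 0.0})


class TestNeighborGraph:
    def test_inclusive_boundary(self):
        a, b = make_cell("a", 0, 0, 0), make_cell("b", 30.0, 0, 0)
        g = build_neighbor_graph([a, b], radius=30.0)
        assert g.adjacency["a"] == ["b"]

    def test_beyond_radius_not_adjacent(self):
        a, b = make_cell("a", 0, 0, 0), make_cell("b", 30.5, 0, 0)
        g = build_neighbor_graph([a, b], radius=30.0)
        assert g.adjacency["a"] == []

    def test_matches_brute_force_on_random_cells(self):
        rng = np.random.default_rng(5)
        cells = [
            make_cell(f"c{k}", *rng.uniform(0, 200, 2), rng.uniform(0, 180))
            for k in range(200)
        ]
        g = build_neighbor_graph(cells, radius=25.0)
        for c in cells:
            expected = {
                o.id
                for o in cells
                if o.id != c.id
                and 0
                < np.hypot(c.centroid[0] - o.centroid[0], c.centroid[1] - o.centroid[1])
                <= 25.0
            }
            assert set(g.adjacency[c.id]) == expected

    def test_symmetric_no_self_loops(self):
        rng = np.random.default_rng(9)
        cells = [
            make_cell(f"c{k}", *rng.uniform(0, 100, 2), 0.0) for k in range(60)
        ]
        g = build_neighbor_graph(cells, radius=20.0)
        for cid, nbrs in g.adjacency.items():
            assert cid not in nbrs
            for n in nbrs:
                assert cid in g.adjacency[n]

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            build_neighbor_graph([make_cell("a", 0, 0, 0)], radius=0.0)


class TestFold:
    @pytest.mark.parametrize("x,expected", [(45, 45), (0, 0), (90, 0), (60, 30)])
    def test_folded(self, x, expected):
        assert fold_to_lms(x) == pytest.approx(expected)

    def test_raw_passthrough(self):
        assert fold_to_lms(60.0, mode="raw") == 60.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fold_to_lms(90.1)


class TestLms:
    def test_hand_example(self):
        """Center at 0° with neighbors {30,60,90,120}: raw 60 → LMS 30."""
        cells = [make_cell("z", 0, 0, 0)] + [
            make_cell(f"n{k}", 5 * (k + 1), 0, t)
            for k, t in enumerate([30, 60, 90, 120])
        ]
        cfg = LmsConfig(radius=30.0)
        table = lms_scores(cells, cfg)
        assert table.loc["z", "raw_mean_diff_deg"] == pytest.approx(60.0)
        assert table.loc["z", "lms_deg"] == pytest.approx(30.0)

    def test_aligned_field_scores_zero(self, aligned_field):
        cells, _ = aligned_field
        table = lms_scores(cells, LmsConfig(radius=60.0))
        defined = table["lms_deg"].dropna()
        assert len(defined) > 0
        assert np.allclose(defined, 0.0, atol=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        cells = [
            make_cell(f"c{k:03d}", *rng.uniform(0, 250, 2), rng.uniform(0, 180))
            for k in range(300)
        ]
        table = lms_scores(cells, LmsConfig(radius=30.0))
        oracle = lms_brute_force(cells, 30.0)
        for cid, expected in oracle.items():
            got = table.loc[cid, "lms_deg"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_graph_and_fast_paths_agree(self, uniform_field):
        cells, _ = uniform_field
        cfg = LmsConfig(radius=40.0)
        fast = lms_scores(cells, cfg)
        from misalign import build_neighbor_graph

        slow = lms_scores(cells, cfg, build_neighbor_graph(cells, 40.0))
        pd.testing.assert_frame_equal(fast, slow)

    def test_zero_neighbor_cells_undefined_not_zero(self):
        far = [make_cell("a", 0, 0, 10), make_cell("b", 500, 500, 20)]
        table = lms_scores(far, LmsConfig(radius=30.0))
        assert table["lms_deg"].isna().all()
        assert (table["neighbor_count"] == 0).all()

    def test_global_rotation_reflection_and_reference_invariance(self, uniform_field):
        cells, _ = uniform_field
        cfg = LmsConfig(radius=40.0)
        base = lms_scores(cells, cfg)["lms_deg"]
        for transform in (
            lambda t: (t + 77.3) % 180.0,  # global rotation
            lambda t: (-t) % 180.0,  # reflection
            lambda t: (t + 90.0) % 180.0,  # different reference axis
        ):
            shifted = []
            for c in cells:
                c2 = Cell(**{**c.__dict__})
                c2.orientation_deg = transform(c.orientation_deg)
                shifted.append(c2)
            got = lms_scores(shifted, cfg)["lms_deg"]
            assert np.allclose(base.fillna(-1), got.fillna(-1), atol=1e-9)

    def test_scores_bounded(self, uniform_scores):
        defined = uniform_scores["lms_deg"].dropna()
        assert ((0 <= defined) & (defined <= 45)).all()
        raw = uniform_scores["raw_mean_diff_deg"].dropna()
        assert ((0 <= raw) & (raw <= 90)).all()

    def test_class_restriction_excludes_cross_class_neighbors(self):
        chondro = [make_cell(f"c{k}", 10 * k, 0, 0.0, cls="chondro-PZ") for k in range(3)]
        noise = [make_cell(f"m{k}", 10 * k + 5, 0, 90.0, cls="myocyte") for k in range(3)]
        cfg = LmsConfig(radius=30.0, classes=("chondro-PZ",))
        table = lms_scores(chondro + noise, cfg)
        assert set(table.index) == {c.id for c in chondro}
        assert np.allclose(table["lms_deg"], 0.0)  # myocytes never contaminate

    def test_monotone_in_orientation_noise(self):
        """Mean LMS is non-decreasing in wrapped-normal σ (the detection axis)."""
        sigmas = [0.0, 5.0, 10.0, 20.0, 40.0]
        means = []
        for sigma in sigmas:
            per_seed = []
            for seed in range(20):
                spec = FieldSpec(
                    n_cells=250, width=450, height=450,
                    noise_model="wrapped_normal" if sigma > 0 else "none",
                    sigma_deg=sigma, mean_orientation_deg=90.0, seed=100 + seed,
                )
                cells, _ = generate_field(spec)
                per_seed.append(
                    lms_scores(cells, LmsConfig(radius=60.0))["lms_deg"].mean()
                )
            means.append(np.mean(per_seed))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_uniform_neighborhood_mean_approaches_45(self):
        """Law of large numbers: huge uniform neighborhoods give raw mean ≈ 45."""
        rng = np.random.default_rng(23)
        theta = rng.uniform(0, 180, 4000)
        diffs = angular_difference(theta[0], theta[1:])
        assert np.mean(diffs) == pytest.approx(45.0, abs=1.5)
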