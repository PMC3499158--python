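"""Gate geometry, bit-mask hierarchy, population statistics and matching."""

import math

import numpy as np
import pytest

from flowqa.errors import GatingError, TemplateError
from flowqa.gating import (
    GateDef,
    GatingSet,
    GatingTemplate,
    apply_template,
    boundary_event_fraction,
    in_gate,
    match_populations,
    population_stats,
)
from flowqa.fcs import Sample
from flowqa.transforms import LinearTransform, QuantizedTransform


def brute_point_in_polygon(px, py, verts):
    """Independent per-point even-odd ray caster (on-edge counts inside)."""
    inside = False
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        # on-segment check
        cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
        if (abs(cross) < 1e-11 * (1 + abs(px) + abs(py))
                and min(x0, x1) <= px <= max(x0, x1)
                and min(y0, y1) <= py <= max(y0, y1)):
            return True
        if (y0 > py) != (y1 > py):
            x_at = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if px < x_at:
                inside = not inside
    return inside


class TestGeometry:
    def test_rect_half_open_convention(self):
        g = GateDef("r", None, "rect", ("x", "y"), ((0.0, 1.0), (0.0, 1.0)))
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [0.999, 0.999]])
        np.testing.assert_array_equal(in_gate(pts, g), [True, False, False, True])

    def test_interval_half_open(self):
        g = GateDef("i", None, "interval", ("x",), (2.0, 4.0))
        np.testing.assert_array_equal(
            in_gate(np.array([1.9, 2.0, 3.0, 4.0]), g),
            [False, True, True, False])

    def test_triangle_hand_geometry(self):
        g = GateDef("t", None, "polygon", ("x", "y"),
                    ((0.0, 0.0), (4.0, 0.0), (0.0, 4.0)))
        pts = np.array([[1.0, 1.0], [3.0, 3.0]])
        np.testing.assert_array_equal(in_gate(pts, g), [True, False])

    def test_polygon_edges_count_inside(self):
        g = GateDef("sq", None, "polygon", ("x", "y"),
                    ((0, 0), (2, 0), (2, 2), (0, 2)))
        pts = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 0.0], [1.0, 2.0], [0, 0]])
        assert in_gate(pts, g).all()

    def test_vertical_edge_no_crossing_flicker(self):
        verts = ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.5, 0.5), (0.0, 1.0))
        g = GateDef("p", None, "polygon", ("x", "y"), verts)
        rng = np.random.default_rng(5)
        pts = rng.uniform(-0.2, 1.2, (500, 2))
        base = in_gate(pts, g)
        shifted = GateDef("p", None, "polygon", ("x", "y"),
                          tuple((x + 1e-9, y) for x, y in verts))
        moved = in_gate(pts, shifted)
        # identical except possibly points within 1e-9 of an edge
        disagree = base != moved
        assert disagree.sum() <= 1

    def test_matches_bruteforce_on_random_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(3, 9))
            verts = tuple(map(tuple, rng.uniform(0, 10, (k, 2))))
            g = GateDef("p", None, "polygon", ("x", "y"), verts)
            pts = rng.uniform(-1, 11, (400, 2))
            mine = in_gate(pts, g)
            ref = np.array([brute_point_in_polygon(x, y, verts) for x, y in pts])
            np.testing.assert_array_equal(mine, ref)

    def test_matches_shapely_on_convex_polygons(self):
        shapely = pytest.importorskip("shapely")
        rng = np.random.default_rng(8)
        for _ in range(10):
            pts_poly = rng.uniform(0, 10, (12, 2))
            hull = shapely.MultiPoint(pts_poly).convex_hull
            verts = tuple(hull.exterior.coords)[:-1]
            g = GateDef("p", None, "polygon", ("x", "y"), verts)
            pts = rng.uniform(-1, 11, (300, 2))
            mine = in_gate(pts, g)
            ref = shapely.covers(hull, shapely.points(pts[:, 0], pts[:, 1]))
            np.testing.assert_array_equal(mine, np.asarray(ref))

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(TemplateError, match=">= 3 vertices"):
            GateDef("p", None, "polygon", ("x", "y"), ((0, 0), (1, 1)))


def two_channel_template(gates):
    return GatingTemplate(
        channels=["x", "y"], gates=gates,
        transforms={"x": LinearTransform(T=10), "y": LinearTransform(T=10)})


class TestHierarchy:
    def test_universal_rect_child_equals_parent(self):
        rng = np.random.default_rng(0)
        s = Sample("s", rng.uniform(0, 2, (500, 2)), ["x", "y"], ["", ""])
        tpl = two_channel_template([
            GateDef("A", None, "rect", ("x", "y"), ((0.5, 2.0), (-math.inf, math.inf))),
            GateDef("B", "A", "rect", ("x", "y"),
                    ((-math.inf, math.inf), (-math.inf, math.inf))),
        ])
        h = apply_template(s, tpl)
        np.testing.assert_array_equal(h.node("/A/B").mask, h.node("/A").mask)

    def test_unit_square_popcount_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        ev = rng.uniform(0, 2, (1000, 2))
        s = Sample("s", ev, ["x", "y"], ["", ""])
        verts = ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0))
        tpl = two_channel_template([GateDef("sq", None, "polygon", ("x", "y"), verts)])
        h = apply_template(s, tpl)
        brute = sum(brute_point_in_polygon(x, y, verts) for x, y in ev)
        count = h.node("/sq").count
        assert count == brute
        assert count == pytest.approx(250, abs=50)

    def test_not_gate_boolean_identity(self):
        rng = np.random.default_rng(2)
        s = Sample("s", rng.uniform(0, 2, (400, 2)), ["x", "y"], ["", ""])
        tpl = two_channel_template([
            GateDef("P", None, "rect", ("x", "y"), ((0.0, 1.5), (0.0, 2.0))),
            GateDef("Q", "P", "rect", ("x", "y"), ((0.0, 0.7), (0.0, 2.0))),
            GateDef("notQ", "P", "bool", bool_op="NOT", operands=("Q",)),
        ])
        h = apply_template(s, tpl)
        p, q, notq = (h.node(f"/P{x}").mask for x in ("", "/Q", "/notQ"))
        np.testing.assert_array_equal(notq, p & ~q)

    def test_child_mask_subset_of_parent_everywhere(self, small_gated):
        for h in small_gated:
            for node in h.walk():
                if node.parent is not None:
                    assert not np.any(node.mask & ~node.parent.mask)

    def test_counts_equal_chain_recomputation_oracle(self, small_gated):
        """Per-event re-evaluation of the full gate chain, no mask reuse."""
        for h in list(small_gated)[:4]:
            s = h.sample
            for node in h.walk():
                if node.gate is None:
                    continue
                chain = []
                cur = node
                while cur.gate is not None:
                    chain.append(cur.gate)
                    cur = cur.parent
                member = np.ones(s.n_events, dtype=bool)
                for g in chain:
                    if g.kind == "bool":
                        member = None
                        break
                    cols = [s.channel_index(d) for d in g.dims]
                    member &= in_gate(h.transformed[:, cols], g)
                if member is not None:
                    assert node.count == int(member.sum()), node.path

    def test_stats_invariant_to_event_permutation(self, small_study):
        s = small_study.samples[0]
        tpl = small_study.template
        h1 = apply_template(s, tpl)
        rng = np.random.default_rng(9)
        perm = rng.permutation(s.n_events)
        # joint shuffle keeps the time column sorted by re-sorting afterwards
        ev = s.events[perm]
        order = np.argsort(ev[:, s.time_channel], kind="stable")
        s2 = Sample(s.sample_id, ev[order], s.channel_names, s.stain_names)
        h2 = apply_template(s2, tpl)
        r1 = {r["population"]: (r["count"], r["proportion"]) for r in population_stats(h1)}
        r2 = {r["population"]: (r["count"], r["proportion"]) for r in population_stats(h2)}
        assert r1 == r2

    def test_missing_channel_error_names_it(self):
        s = Sample("s", np.ones((5, 1)), ["x"], [""])
        tpl = two_channel_template([
            GateDef("A", None, "rect", ("x", "y"), ((0.0, 2.0), (0.0, 2.0)))])
        with pytest.raises(GatingError, match="y"):
            apply_template(s, tpl)


class TestPopulationStats:
    def test_root_proportion_exactly_one(self, small_gated):
        h = next(iter(small_gated))
        recs = {r["population"]: r for r in population_stats(h)}
        assert recs["/"]["proportion"] == 1.0

    def test_empty_population_has_missing_mfi(self):
        s = Sample("s", np.full((50, 2), 5.0), ["x", "y"], ["", ""])
        tpl = two_channel_template([
            GateDef("none", None, "rect", ("x", "y"), ((8.0, 9.0), (8.0, 9.0)))])
        h = apply_template(s, tpl)
        rec = [r for r in population_stats(h) if r["population"] == "/none"][0]
        assert rec["count"] == 0
        assert rec["proportion"] == 0.0
        assert rec["mfi"] == {"x": None, "y": None}

    def test_mean_vs_median_mfi(self):
        s = Sample("s", np.column_stack([[1.0, 1.0, 7.0], [0, 0, 0]]),
                   ["x", "y"], ["", ""])
        tpl = two_channel_template([
            GateDef("all", None, "rect", ("x", "y"),
                    ((-math.inf, math.inf), (-math.inf, math.inf)))])
        h = apply_template(s, tpl)
        med = population_stats(h, "median")[1]["mfi"]["x"]
        mean = population_stats(h, "mean")[1]["mfi"]["x"]
        assert med == 1.0 and mean == 3.0


class TestMatching:
    def test_substring_selects_all_mfi_nodes(self, small_gated):
        hits = match_populations(small_gated, "MFI", "substring")
        assert len(hits) == 5
        assert all(p.endswith("MFI") for p in hits)

    def test_exact_unique_terminal(self, small_gated):
        assert match_populations(small_gated, "WBC_perct", "exact") == ["/WBC_perct"]

    def test_regex_margin_nodes(self, small_gated):
        hits = match_populations(small_gated, "margin$", "regex")
        assert len(hits) == 5
        assert all(p.endswith("margin") for p in hits)

    def test_exact_ambiguity_is_error(self):
        paths = ["/", "/A", "/A/X", "/B", "/B/X"]
        with pytest.raises(GatingError, match="ambiguous"):
            match_populations(paths, "X", "exact")

    def test_path_mode(self, small_gated):
        assert match_populations(small_gated, "/WBC_perct/MNC", "path") == [
            "/WBC_perct/MNC"]
        with pytest.raises(GatingError):
            match_populations(small_gated, "/nope", "path")


class TestBoundaryEvents:
    def test_interior_events_zero(self):
        lin = LinearTransform(T=100.0)
        qt = QuantizedTransform(lin, 64)
        s = Sample("s", np.full((100, 1), 50.0), ["x"], [""])
        assert boundary_event_fraction(s, "x", qt) == 0.0

    def test_exact_five_percent_injection(self):
        lin = LinearTransform(T=100.0)
        qt = QuantizedTransform(lin, 64)
        vals = np.full(200, 50.0)
        vals[:10] = 100.0  # exactly top of scale
        s = Sample("s", vals[:, None], ["x"], [""])
        assert boundary_event_fraction(s, "x", qt) == 0.05

    def test_definition_equivalence(self, small_study):
        tpl = small_study.template
        qt = QuantizedTransform(tpl.transforms["FITC-A"], 4096)
        s = small_study.samples[0]
        x = s.events[:, s.channel_index("FITC-A")]
        expected = np.mean((x >= qt.raw_knots[-1]) | (x <= qt.raw_knots[0]))
        assert boundary_event_fraction(s, "FITC-A", qt) == expected
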