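"""Heat-tree layout, aesthetic mapping, size optimization and rendering."""
import json
import math
import re

import numpy as np
import pytest

from taxomap import (FixtureConfig, HeatTreeSpec, TaxmapError, layout_tree,
                     map_aesthetic, map_color, optimize_size_range, random_taxmap,
                     render)
from taxomap.heat_tree import _pairwise_overlap_fraction, compute_heat_tree

from conftest import make_taxmap


def circles_from_svg(path):
    text = open(path).read()
    out = {}
    for m in re.finditer(r'<circle cx="([\d.]+)" cy="([\d.]+)" r="([\d.]+)"[^/]*'
                         r'data-taxon="([^"]+)"', text):
        out[m.group(4)] = tuple(float(m.group(i)) for i in (1, 2, 3))
    return out


class TestLayout:
    def test_children_evenly_spaced_below_root(self):
        tm = make_taxmap([("R", None)] + [(f"C{i}", "R") for i in range(4)])
        lay = layout_tree(tm)
        ys = {t: lay.coords[t][1] for t in tm.taxon_ids}
        xs = sorted(lay.coords[f"C{i}"][0] for i in range(4))
        assert all(ys[f"C{i}"] == ys["C0"] for i in range(4))
        assert ys["R"] > ys["C0"]
        gaps = np.diff(xs)
        assert np.allclose(gaps, gaps[0])
        assert lay.coords["R"][0] == pytest.approx(np.mean(xs))

    def test_chain_is_collinear_distinct_layers(self):
        edges = [("n0", None)] + [(f"n{i}", f"n{i-1}") for i in range(1, 6)]
        lay = layout_tree(make_taxmap(edges))
        xs = {lay.coords[t][0] for t in lay.coords}
        ys = [lay.coords[f"n{i}"][1] for i in range(6)]
        assert len(xs) == 1
        assert len(set(ys)) == 6 and ys == sorted(ys, reverse=True)

    def test_no_subtree_extent_overlap_on_random_tree(self, forest_factory):
        tm = forest_factory(13, n_taxa=100, n_obs=10)
        lay = layout_tree(tm)
        sub = tm.subtaxa(recursive=True, include_input=True)

        def extent(t):
            xs = [lay.coords[c][0] for c in sub[t]]
            return min(xs), max(xs)

        for t in tm.taxon_ids:
            for c1 in tm.subtaxa([t], recursive=False)[t]:
                for c2 in tm.subtaxa([t], recursive=False)[t]:
                    if c1 >= c2:
                        continue
                    a, b = extent(c1), extent(c2)
                    assert a[1] < b[0] or b[1] < a[0]

    def test_force_directed_is_seed_deterministic(self, forest_factory):
        tm = forest_factory(14, n_taxa=30, n_obs=5)
        a = layout_tree(tm, "fruchterman-reingold", seed=3)
        b = layout_tree(tm, "fruchterman-reingold", seed=3)
        assert a.coords == b.coords

    def test_unknown_algorithm_rejected(self, chain_tm):
        with pytest.raises(TaxmapError, match="algorithm"):
            layout_tree(chain_tm, "circular")


class TestMapAesthetic:
    def test_affine_endpoints(self):
        assert map_aesthetic([0, 5, 10], (1, 3)).tolist() == [1.0, 2.0, 3.0]

    def test_constant_maps_to_midpoint(self):
        assert map_aesthetic([4, 4, 4], (1, 3)).tolist() == [2.0, 2.0, 2.0]

    def test_log10_of_nonpositive_errors(self):
        with pytest.raises(TaxmapError, match="log10"):
            map_aesthetic([0, 1], (0, 1), transform="log10")

    def test_monotone_and_attains_endpoints(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.random(15) * 100
            out = map_aesthetic(v, (2, 7), transform="sqrt")
            assert np.all(np.argsort(v, kind="stable") == np.argsort(out, kind="stable"))
            assert out.min() == pytest.approx(2) and out.max() == pytest.approx(7)

    def test_explicit_interval_clamps(self):
        out = map_aesthetic([-5, 0, 10, 20], (0, 1), interval=(0, 10))
        assert out.tolist() == [0.0, 0.0, 1.0, 1.0]


class TestMapColor:
    def test_two_anchor_endpoints_exact(self):
        assert map_color([0, 1], ("#0000ff", "#ff0000")) == ["#0000ff", "#ff0000"]

    def test_three_anchor_midpoint_exact(self):
        cols = map_color([0, 5, 10], ("#000000", "#00ff00", "#ffffff"))
        assert cols[1] == "#00ff00"

    def test_interpolation_equals_channelwise_oracle(self):
        rng = np.random.default_rng(2)
        palette = ("#102030", "#c0ffee", "#ff0080")
        anchors = np.array([(0x10, 0x20, 0x30), (0xC0, 0xFF, 0xEE), (0xFF, 0x00, 0x80)]) / 255
        v = rng.random(40)
        got = map_color(v, palette, interval=(0.0, 1.0))
        for val, hexcol in zip(v, got):
            x = val * 2
            i = min(int(x), 1)
            f = x - i
            rgb = anchors[i] * (1 - f) + anchors[i + 1] * f
            expect = "#%02x%02x%02x" % tuple(int(round(c * 255)) for c in rgb)
            assert hexcol == expect

    def test_values_clamp_to_explicit_interval(self):
        cols = map_color([-10, 110], ("#000000", "#ffffff"), interval=(0, 100))
        assert cols == ["#000000", "#ffffff"]

    def test_short_palette_rejected(self):
        with pytest.raises(TaxmapError, match="palette"):
            map_color([1, 2], ("#000000",))


class TestOptimizeSizeRange:
    def test_two_distant_nodes_take_the_maximum(self):
        pts = np.array([[0.1, 0.1], [0.9, 0.9]])
        lo, hi = optimize_size_range(pts, candidate_range=(0.01, 0.05))
        assert hi == 0.05 and lo == pytest.approx(0.25 * hi)

    def test_adjacent_nodes_bound_radius_by_distance(self):
        d = 0.08
        pts = np.array([[0.5, 0.5], [0.5 + d, 0.5]])
        lo, hi = optimize_size_range(pts, candidate_range=(0.005, 0.5))
        assert hi <= d
        assert _pairwise_overlap_fraction(pts, hi) <= 0.01 + 1e-9

    def test_fallback_to_minimum_candidate(self):
        pts = np.zeros((3, 2))  # coincident: any radius overlaps fully
        lo, hi = optimize_size_range(pts, candidate_range=(0.01, 0.1))
        assert hi == 0.01

    @pytest.mark.parametrize("seed", range(10))
    def test_overlap_bound_always_satisfied(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((30, 2))
        lo, hi = optimize_size_range(pts, candidate_range=(0.001, 0.2))
        if hi > 0.001:  # above the fallback, the bound must hold
            assert _pairwise_overlap_fraction(pts, hi) <= 0.01 + 1e-9
        assert 0 < lo < hi


class TestRender:
    def _tm(self, seed=21, n_roots=1, n_taxa=30):
        return random_taxmap(FixtureConfig(n_taxa=n_taxa, n_obs=60, n_roots=n_roots,
                                           seed=seed)).taxmap

    def test_single_taxon_renders_one_node_no_edges(self, tmp_path):
        tm = make_taxmap([("A", None)], [("o1", "A")])
        out = tmp_path / "one.svg"
        res = render(tm, HeatTreeSpec(), output=str(out))
        text = out.read_text()
        assert text.count("data-taxon") == 1
        assert "<polygon" not in text
        assert res.n_trees == 1

    def test_empty_taxmap_rejected(self):
        import pandas as pd
        from taxomap import Taxmap

        empty = Taxmap(pd.DataFrame({"taxon_id": [], "supertaxon_id": []}))
        with pytest.raises(TaxmapError, match="empty"):
            render(empty)

    def test_unknown_column_rejected(self, tmp_path):
        with pytest.raises(TaxmapError, match="nope"):
            render(self._tm(), HeatTreeSpec(node_color="nope"))

    @pytest.mark.parametrize("n_roots", [1, 3, 5])
    def test_one_subtree_per_root(self, tmp_path, n_roots):
        tm = self._tm(seed=30 + n_roots, n_roots=n_roots, n_taxa=40)
        out = tmp_path / "f.svg"
        res = render(tm, output=str(out))
        assert res.n_trees == len(tm.roots()) == n_roots
        groups = re.findall(r'<g id="(tree-\d+)">', out.read_text())
        assert len(groups) == n_roots

    def test_svg_byte_identical_for_same_inputs(self, tmp_path):
        tm = self._tm(seed=22)
        spec = HeatTreeSpec(node_color="n_obs", node_size_transform="sqrt")
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render(tm, spec, output=str(a), seed=5)
        render(tm, spec, output=str(b), seed=5)
        assert a.read_bytes() == b.read_bytes()

    def test_normalized_coordinates_invariant_to_output_size(self, tmp_path):
        tm = self._tm(seed=23)
        small, big = tmp_path / "s.svg", tmp_path / "b.svg"
        render(tm, output=str(small), width_px=400, height_px=400)
        render(tm, output=str(big), width_px=1000, height_px=1000)
        cs, cb = circles_from_svg(small), circles_from_svg(big)
        assert set(cs) == set(cb)
        for t in cs:
            for a, b in zip(np.array(cs[t]) / 400, np.array(cb[t]) / 1000):
                assert a == pytest.approx(b, abs=1e-4)

    def test_aesthetic_monotonicity(self, tmp_path):
        tm = self._tm(seed=24)
        spec = HeatTreeSpec(node_size="n_obs", node_color="n_obs")
        res = render(tm, spec)
        frame = tm.taxa_table()
        n = dict(zip(tm.taxon_ids, frame["n_obs"]))
        for a in tm.taxon_ids:
            for b in tm.taxon_ids:
                if n[a] < n[b]:
                    assert res.nodes[a]["r"] <= res.nodes[b]["r"] + 1e-12

    def test_legend_json_is_faithful(self, tmp_path):
        """Legend ticks re-mapped through map_aesthetic/map_color reproduce
        the recorded aesthetics exactly."""
        tm = self._tm(seed=25)
        spec = HeatTreeSpec(node_size="n_obs", node_color="n_obs",
                            node_color_transform="sqrt")
        out = tmp_path / "t.svg"
        render(tm, spec, output=str(out))
        meta = json.loads((tmp_path / "t.svg.legend.json").read_text())
        size = meta["legend"]["node_size"]
        redone = map_aesthetic(size["ticks"], size["out_interval"],
                               transform=size["transform"],
                               interval=size["value_interval"])
        assert redone.tolist() == pytest.approx(size["tick_sizes"])
        color = meta["legend"]["node_color"]
        redone_c = map_color(color["ticks"], color["palette"],
                             interval=color["value_interval"],
                             transform=color["transform"])
        assert redone_c == color["tick_colors"]
        # drawn node aesthetics at the tick values match too
        vmin_taxon = min(meta["nodes"], key=lambda t: tm.taxa_table()["n_obs"]
                         [tm.taxon_ids.index(t)])
        assert meta["nodes"][vmin_taxon]["r"] == pytest.approx(min(size["tick_sizes"]))

    def test_png_and_pdf_outputs_exist(self, tmp_path):
        tm = self._tm(seed=26, n_taxa=15)
        for ext in ("png", "pdf"):
            p = tmp_path / f"t.{ext}"
            render(tm, output=str(p))
            assert p.stat().st_size > 0

    def test_label_truncation_floor(self):
        tm = make_taxmap([("A", None), ("LongNameTaxonXYZ", "A")], [("o1", "A")])
        res = compute_heat_tree(tm)
        texts = [p for p in res.primitives if p["kind"] == "text" and p["group"] != "legend"]
        assert texts and all(p["size"] >= 0.007 for p in texts)
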