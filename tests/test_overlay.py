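"""Over-representation statistics and overlay geometry."""

from __future__ import annotations

import math

import numpy as np
import pytest

from _oracles import bh_stepup_enum, hypergeom_tail_exact
from pathviz.ehld import canonical_svg, export_svg, parse_ehld
from pathviz.fixtures import FixtureSpec, generate_ehld
from pathviz.highlight import HighlightBox
from pathviz.model import Rect
from pathviz.overlay import (
    AnalysisResult,
    OraError,
    OverlayStyle,
    PathwayEntitySets,
    PathwayStats,
    apply_overlay,
    bh_fdr,
    hit_bar_rect,
    ora,
    overlay_lld_labels,
    pvalue_to_color,
)
from pathviz.profiles import lerp_color


def _make_sets(rng: np.random.Generator, universe_size: int, n_sets: int):
    universe = [f"E{i:03d}" for i in range(universe_size)]
    sets = {}
    for s in range(n_sets):
        size = int(rng.integers(2, max(3, universe_size // 2)))
        members = rng.choice(universe_size, size=size, replace=False)
        sets[f"P{s:02d}"] = frozenset(universe[int(m)] for m in members)
    return PathwayEntitySets(frozenset(universe), sets), universe


class TestOra:
    def test_perfect_overlap_small_universe(self):
        universe = [f"E{i}" for i in range(20)]
        members = frozenset(universe[:5])
        sets = PathwayEntitySets(frozenset(universe), {"P": members})
        res = ora(universe[:5], sets)
        expected = 1 / math.comb(20, 5)
        assert res["P"].p_value == pytest.approx(expected, rel=1e-12)
        assert res["P"].found == 5 and res["P"].total == 5

    def test_zero_overlap_gives_p_one(self):
        universe = [f"E{i}" for i in range(20)]
        sets = PathwayEntitySets(frozenset(universe), {"P": frozenset(universe[:5])})
        res = ora(universe[5:10], sets)
        assert res["P"].p_value == pytest.approx(1.0)

    def test_matches_exact_rational_summation(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            universe_size = int(rng.integers(10, 61))
            sets, universe = _make_sets(rng, universe_size, int(rng.integers(1, 4)))
            q_size = int(rng.integers(1, universe_size))
            query = [universe[int(i)]
                     for i in rng.choice(universe_size, size=q_size, replace=False)]
            res = ora(query, sets)
            for pid, members in sets.sets.items():
                k = len(set(query) & members)
                exact = float(hypergeom_tail_exact(
                    k, universe_size, len(members), q_size))
                assert abs(res[pid].p_value - exact) < 1e-12

    def test_disjoint_query_rejected(self):
        universe = [f"E{i}" for i in range(20)]
        sets = PathwayEntitySets(frozenset(universe), {"P": frozenset(universe[:5])})
        with pytest.raises(OraError, match="disjoint"):
            ora(["X1", "X2"], sets)

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(5)
        sets, universe = _make_sets(rng, 50, 8)
        query = [universe[int(i)] for i in rng.choice(50, size=15, replace=False)]
        res = ora(query, sets)
        for stats in res.entries.values():
            assert stats.fdr >= stats.p_value - 1e-15


class TestBhFdr:
    @pytest.mark.parametrize(
        "p_in,expected",
        [
            ([0.2], [0.2]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
        ],
    )
    def test_examples(self, p_in, expected):
        assert bh_fdr(p_in) == pytest.approx(expected)

    def test_matches_stepup_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            m = int(rng.integers(1, 11))
            p = [float(x) for x in rng.uniform(0, 1, size=m)]
            assert bh_fdr(p) == pytest.approx(bh_stepup_enum(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = [float(x) for x in rng.uniform(0, 1, size=25)]
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert bh_fdr(p) == pytest.approx(list(sm_adj), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(OraError):
            bh_fdr([0.5, 1.5])


class TestPvalueToColor:
    def test_endpoints_and_grey_rule(self):
        style = OverlayStyle(gradient=("#FFFF33", "#FF6600"), grey="#C8C8C8")
        assert pvalue_to_color(0.0, style) == "#FFFF33"
        assert pvalue_to_color(0.2, style) == "#C8C8C8"
        assert pvalue_to_color(0.05, style) == "#C8C8C8"  # boundary is grey
        mid = pvalue_to_color(0.025, style)
        assert mid == lerp_color("#FFFF33", "#FF6600", 0.5)

    def test_continuous_below_threshold_constant_above(self):
        style = OverlayStyle()
        ps = np.linspace(0, 0.0499, 200)
        colors = [pvalue_to_color(float(p), style) for p in ps]
        # adjacent samples never jump more than a few units per channel
        for c1, c2 in zip(colors, colors[1:]):
            for i in (1, 3, 5):
                assert abs(int(c1[i:i + 2], 16) - int(c2[i:i + 2], 16)) <= 3
        for p in (0.05, 0.3, 0.99, 1.0):
            assert pvalue_to_color(p, style) == style.grey


class TestHitBar:
    @pytest.mark.parametrize(
        "found,total,width", [(0, 10, 0.0), (10, 10, 200.0), (6, 24, 50.0)]
    )
    def test_examples(self, found, total, width):
        bar = hit_bar_rect(found, total, Rect(5, 5, 200, 20))
        assert bar.w == pytest.approx(width)
        assert bar.x == 5 and bar.y == 25  # anchored bottom-left

    def test_width_exactly_proportional(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            total = int(rng.integers(1, 500))
            found = int(rng.integers(0, total + 1))
            w = float(rng.uniform(10, 400))
            bar = hit_bar_rect(found, total, Rect(0, 0, w, 20))
            assert math.isclose(bar.w * total, found * w, rel_tol=2 ** -50)

    def test_zero_total_rejected(self):
        with pytest.raises(OraError):
            hit_bar_rect(0, 0, Rect(0, 0, 10, 10))


def _result_for(pids: list[str], p_values: list[float]) -> AnalysisResult:
    fdrs = bh_fdr(p_values)
    return AnalysisResult({
        pid: PathwayStats(found=3, total=10, p_value=p, fdr=f)
        for pid, p, f in zip(pids, p_values, fdrs)
    })


class TestApplyOverlay:
    def test_counts_rects_bars_and_one_legend(self, ehld_svg):
        doc = parse_ehld(ehld_svg)
        pids = [r.pathway_id for r in doc.regions[:3]]
        apply_overlay(doc, _result_for(pids, [0.001, 0.02, 0.3]), OverlayStyle())
        out = export_svg(doc)
        assert out.count('class="overlay-rect"') == 3
        assert out.count('class="hit-bar"') == 3
        assert out.count('id="analysis-legend"') == 1

    def test_empty_result_leaves_document_unchanged(self, ehld_svg):
        doc = parse_ehld(ehld_svg)
        before = canonical_svg(export_svg(doc))
        apply_overlay(doc, AnalysisResult({}), OverlayStyle())
        assert canonical_svg(export_svg(doc)) == before
        assert "analysis-legend" not in export_svg(doc)

    def test_reapplication_is_idempotent(self, ehld_svg):
        doc = parse_ehld(ehld_svg)
        pids = [r.pathway_id for r in doc.regions]
        result = _result_for(pids, [0.01] * len(pids))
        apply_overlay(doc, result, OverlayStyle())
        once = canonical_svg(export_svg(doc))
        apply_overlay(doc, result, OverlayStyle())
        assert canonical_svg(export_svg(doc)) == once

    def test_strip_recovers_original(self, ehld_svg):
        doc = parse_ehld(ehld_svg)
        original = canonical_svg(export_svg(doc))
        pids = [r.pathway_id for r in doc.regions]
        apply_overlay(doc, _result_for(pids, [0.02] * len(pids)), OverlayStyle())
        assert canonical_svg(export_svg(doc, include_overlay=False)) == original

    def test_unknown_pathways_skipped_silently(self, ehld_svg):
        doc = parse_ehld(ehld_svg)
        apply_overlay(doc, _result_for(["R-GHOST"], [0.01]), OverlayStyle())
        assert "analysis-legend" not in export_svg(doc)


class TestOverlayLldLabels:
    def _boxes(self) -> list[HighlightBox]:
        return [
            HighlightBox(f"SP{i}", Rect(i * 120.0, 0, 100, 60), "#11223360",
                         f"Sub {i}", label_rect=Rect(i * 120.0 + 4, 4, 92, 20),
                         font_size=10.0)
            for i in range(3)
        ]

    def test_hit_box_gains_proportional_bar(self):
        boxes = self._boxes()
        result = AnalysisResult({
            "SP1": PathwayStats(found=6, total=24, p_value=0.01, fdr=0.02)
        })
        decorated = overlay_lld_labels(boxes, result, OverlayStyle())
        sp1 = next(b for b in decorated if b.subpathway_id == "SP1")
        assert sp1.bar is not None
        assert sp1.bar.w == pytest.approx(0.25 * sp1.label_rect.w)
        assert sp1.overlay_fill is not None
        untouched = [b for b in decorated if b.subpathway_id != "SP1"]
        assert all(b.bar is None and b.overlay_fill is None for b in untouched)

    def test_no_results_passes_through(self):
        boxes = self._boxes()
        assert overlay_lld_labels(boxes, AnalysisResult({}), OverlayStyle()) == boxes

    def test_bar_widths_proportional_across_random_results(self):
        rng = np.random.default_rng(17)
        boxes = self._boxes()
        for _ in range(10):
            total = int(rng.integers(1, 100))
            found = int(rng.integers(0, total + 1))
            result = AnalysisResult({
                "SP0": PathwayStats(found, total, 0.01, 0.01)
            })
            [sp0] = [b for b in overlay_lld_labels(boxes, result, OverlayStyle())
                     if b.subpathway_id == "SP0"]
            assert math.isclose(sp0.bar.w * total, found * sp0.label_rect.w,
                                rel_tol=2 ** -50)
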