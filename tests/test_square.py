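"""Square Method: boxes, overlap ratios, selection pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emophysio.square import (
    ClassBox,
    class_boxes,
    find_lowest_threshold,
    overlap_report,
    pair_score,
    select_features,
    threshold_grid,
)
from emophysio.synthetic import make_separable_table


def _box(cx, cy, hx, hy, label="c"):
    return ClassBox("x", "y", label, (cx, cy), (hx, hy))


def _mc_ratio(a, b, n=100_000, seed=0):
    """Monte-Carlo oracle: fraction of points of box a inside box b."""
    rng = np.random.default_rng(seed)
    ax0, ax1, ay0, ay1 = a.bounds
    xs = rng.uniform(ax0, ax1, n)
    ys = rng.uniform(ay0, ay1, n)
    bx0, bx1, by0, by1 = b.bounds
    return float(np.mean((xs >= bx0) & (xs <= bx1) & (ys >= by0) & (ys <= by1)))


class TestBoxes:
    def test_four_boxes_with_t_ci(self):
        rng = np.random.default_rng(0)
        tab = make_separable_table(n_subjects=10, n_features=2, seed=1)
        boxes = class_boxes(tab, ("f0", "f1"))
        assert len(boxes) == 4
        assert all(b.half_widths[0] >= 0 and b.half_widths[1] >= 0 for b in boxes)

    def test_zero_variance_gives_zero_width(self):
        tab = pd.DataFrame({
            "quadrant": ["a"] * 3 + ["b"] * 3,
            "f0": [1.0, 1.0, 1.0, 2.0, 2.1, 1.9],
            "f1": [0.0, 0.0, 0.0, 1.0, 1.2, 0.8],
        })
        boxes = class_boxes(tab, ("f0", "f1"))
        assert boxes[0].half_widths == (0.0, 0.0)
        assert boxes[0].center == (1.0, 0.0)

    def test_ci_shrinks_with_sqrt_n(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal(40)
        small = pd.DataFrame({"quadrant": "a", "f0": vals[:20], "f1": vals[:20]})
        big = pd.DataFrame({"quadrant": "a", "f0": np.tile(vals[:20], 2),
                            "f1": np.tile(vals[:20], 2)})
        hw_small = class_boxes(small, ("f0", "f1"))[0].half_widths[0]
        hw_big = class_boxes(big, ("f0", "f1"))[0].half_widths[0]
        # same sample moments, doubled n: width shrinks by ~1/sqrt(2)
        assert hw_big / hw_small == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_single_observation_rejected(self):
        tab = pd.DataFrame({"quadrant": ["a", "b", "b"],
                            "f0": [1.0, 2.0, 3.0], "f1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            class_boxes(tab, ("f0", "f1"))


class TestPairScore:
    def test_identical_boxes_full_overlap(self):
        boxes = [_box(0, 0, 1, 1, str(i)) for i in range(4)]
        ratios, A = pair_score(boxes)
        assert len(ratios) == 12
        assert all(r == 1.0 for r in ratios)
        assert A == 100.0

    def test_disjoint_boxes_zero(self):
        boxes = [_box(10 * i, 0, 1, 1, str(i)) for i in range(4)]
        assert pair_score(boxes)[1] == 0.0

    def test_smaller_box_gets_larger_ratio(self):
        """One intersection yields two ratios; the smaller box's is larger."""
        boxes = [_box(-10, 0, 1, 1, "1"), _box(0, 0, 2, 2, "2"),
                 _box(1.5, 0, 1, 1, "3"), _box(20, 0, 1, 1, "4")]
        ratios, _ = pair_score(boxes)
        order = list(itertools.permutations(range(4), 2))
        r_23 = ratios[order.index((1, 2))]  # overlap / area(class2)
        r_32 = ratios[order.index((2, 1))]  # overlap / area(class3)
        assert r_32 > r_23 > 0

    def test_matches_monte_carlo_oracle(self):
        """Intersection ratios agree with point counting within 1%."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            a = _box(rng.uniform(-1, 1), rng.uniform(-1, 1),
                     rng.uniform(0.1, 1.5), rng.uniform(0.1, 1.5), "a")
            b = _box(rng.uniform(-1, 1), rng.uniform(-1, 1),
                     rng.uniform(0.1, 1.5), rng.uniform(0.1, 1.5), "b")
            ratios, _ = pair_score([a, b, _box(99, 99, 1, 1, "c"),
                                    _box(-99, -99, 1, 1, "d")])
            assert ratios[0] == pytest.approx(_mc_ratio(a, b, seed=trial), abs=0.01)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(-5, 5), st.floats(-5, 5),
        st.floats(0, 2), st.floats(0, 2)), min_size=4, max_size=4))
    def test_score_bounds_hold_for_arbitrary_boxes(self, specs):
        """Ratios stay in [0, 1] and A in [0, 100] for any box geometry,
        including degenerate zero-width boxes."""
        boxes = [_box(cx, cy, hx, hy, str(i))
                 for i, (cx, cy, hx, hy) in enumerate(specs)]
        ratios, A = pair_score(boxes)
        assert len(ratios) == 12
        assert all(0.0 <= r <= 1.0 for r in ratios)
        assert 0.0 <= A <= 100.0

    def test_degenerate_box_containment_rule(self):
        point = _box(0.5, 0.5, 0.0, 0.0, "p")
        host = _box(0, 0, 1, 1, "h")
        far = _box(10, 10, 1, 1, "f")
        ratios, _ = pair_score([point, host, far, _box(-10, -10, 1, 1, "g")])
        assert ratios[0] == 1.0  # point inside host
        assert ratios[1] == 0.0  # point outside far


class TestSelection:
    def test_planted_feature_ranked_first(self):
        tab = make_separable_table(n_subjects=22, n_features=8,
                                   n_informative=1, separation=2.5, seed=2)
        res = select_features(tab, threshold=10.0, seed=0)
        assert res.selected and res.selected[0] == "f0"

    def test_separability_recovery_over_seeds(self):
        """The planted informative feature tops the ranking in >= 95% of
        50 seeded tables."""
        hits = 0
        for s in range(50):
            tab = make_separable_table(n_subjects=22, n_features=8,
                                       n_informative=1, separation=2.5, seed=s)
            res = select_features(tab, threshold=10.0, seed=s)
            if res.selected and res.selected[0] == "f0":
                hits += 1
        assert hits >= 48  # 95% of 50, rounded up

    def test_threshold_monotonicity(self):
        """Lowering the threshold never grows the retained-pair set."""
        tab = make_separable_table(n_subjects=22, n_features=6,
                                   n_informative=2, separation=1.5, seed=4)
        prev = None
        for thr in (100.0, 70.0, 50.0, 30.0, 10.0, 5.0):
            pairs = set(select_features(tab, thr, seed=0).retained_pairs)
            if prev is not None:
                assert pairs <= prev
            prev = pairs

    def test_vacuous_threshold_keeps_all_pairs(self):
        tab = make_separable_table(n_subjects=10, n_features=5, seed=5)
        res = select_features(tab, threshold=100.0, seed=0)
        assert len(res.retained_pairs) == 10  # C(5, 2)

    def test_duplicated_feature_pruned(self):
        tab = make_separable_table(n_subjects=22, n_features=4,
                                   n_informative=2, separation=2.0, seed=6)
        tab["f_dup"] = tab["f0"]  # |r| = 1 with f0
        res = select_features(tab, threshold=60.0, seed=0)
        survivors = {"f0", "f_dup"} - set(res.discarded_by_correlation)
        assert len(survivors) == 1

    def test_column_order_invariance(self):
        tab = make_separable_table(n_subjects=22, n_features=6,
                                   n_informative=2, separation=2.0, seed=8)
        shuffled = tab[list(tab.columns[:3]) + list(reversed(tab.columns[3:]))]
        a = select_features(tab, 30.0, seed=9)
        b = select_features(shuffled, 30.0, seed=9)
        assert a.selected == b.selected

    def test_empty_selection_is_valid(self):
        tab = make_separable_table(n_subjects=10, n_features=4,
                                   n_informative=0, seed=10)
        res = select_features(tab, threshold=0.0, seed=0)
        assert res.selected == [] and res.retained_pairs == []

    def test_lowest_threshold_retains_a_feature(self):
        tab = make_separable_table(n_subjects=22, n_features=5,
                                   n_informative=1, separation=2.0, seed=11)
        lo = find_lowest_threshold(tab)
        assert select_features(tab, lo, seed=0).selected
        grid = threshold_grid(tab)
        assert grid[0] == 100.0 and grid[-1] == lo

    def test_result_json_roundtrip(self, tmp_path):
        tab = make_separable_table(n_subjects=10, n_features=4, seed=12)
        res = select_features(tab, 50.0, seed=0)
        res.to_json(tmp_path / "sm.json")
        assert (tmp_path / "sm.json").read_text().startswith("{")


class TestOverlapReport:
    def test_identical_classes_full_overlap(self):
        rng = np.random.default_rng(0)
        n = 400
        tab = pd.DataFrame({
            "quadrant": np.repeat(list("abcd"), n // 4),
            "f0": rng.standard_normal(n), "f1": rng.standard_normal(n),
            "f2": rng.standard_normal(n),
        })
        rep = overlap_report(tab, ["f0", "f1", "f2"])
        assert list(rep["class"]) == ["a", "b", "c", "d", "Average"]
        assert rep["mean_overlap_pct"].iloc[-1] > 40.0

    def test_separated_classes_near_zero(self):
        rng = np.random.default_rng(1)
        rows = []
        for i, c in enumerate("abcd"):
            for _ in range(30):
                rows.append({"quadrant": c,
                             "f0": 10 * i + rng.normal(0, 0.1),
                             "f1": 10 * i + rng.normal(0, 0.1),
                             "f2": 10 * i + rng.normal(0, 0.1)})
        rep = overlap_report(pd.DataFrame(rows), ["f0", "f1", "f2"])
        assert rep["mean_overlap_pct"].iloc[-1] == pytest.approx(0.0, abs=1.0)

    def test_two_feature_fallback_notes_reduction(self):
        tab = make_separable_table(n_subjects=10, n_features=2, seed=2)
        rep = overlap_report(tab, ["f0", "f1"])
        assert "note" in rep.attrs
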