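"""The Square Method: box-overlap feature selection.

For every pair of features, each class is summarized by an axis-aligned
rectangle centered on the per-class feature means with half-widths equal to
the 95% confidence interval of the mean (Student-t). For 4 classes the 12
ordered overlap ratios (intersection area over each box's own area) are
averaged into the pair score A (percent). Pairs whose A exceeds a threshold
are discarded; each feature is weighted by the number of surviving pairs it
appears in; features correlated above 0.8 (|Pearson r|) lose the one with
lower weight (seeded random tie-break); the surviving features with weight
above the mean weight are selected, ranked by weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassBox",
    "SMResult",
    "class_boxes",
    "pair_score",
    "select_features",
    "overlap_report",
    "find_lowest_threshold",
    "threshold_grid",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (100.0, 90.0, 70.0, 50.0, 30.0, 20.0, 10.0)
CORR_CUT = 0.8


@dataclass(frozen=True)
class ClassBox:
    """Per-class 95%-CI rectangle over one feature pair."""

    feature_x: str
    feature_y: str
    class_label: str
    center: tuple[float, float]
    half_widths: tuple[float, float]

    @property
    def area(self) -> float:
        return 4.0 * self.half_widths[0] * self.half_widths[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, y_lo, y_hi)."""
        (cx, cy), (hx, hy) = self.center, self.half_widths
        return (cx - hx, cx + hx, cy - hy, cy + hy)


def _ci_half_width(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 observations per class")
    return float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))


def class_boxes(
    table: pd.DataFrame,
    pair: tuple[str, str],
    class_col: str = "quadrant",
) -> list[ClassBox]:
    """One CI box per class over the given feature pair (classes sorted)."""
    fx, fy = pair
    boxes = []
    for label, grp in sorted(table.groupby(class_col, observed=True), key=lambda kv: kv[0]):
        x = grp[fx].dropna().to_numpy()
        y = grp[fy].dropna().to_numpy()
        boxes.append(ClassBox(
            fx, fy, str(label),
            center=(float(np.mean(x)), float(np.mean(y))),
            half_widths=(_ci_half_width(x), _ci_half_width(y)),
        ))
    return boxes


def _intersection_area(a: ClassBox, b: ClassBox) -> float:
    ax0, ax1, ay0, ay1 = a.bounds
    bx0, bx1, by0, by1 = b.bounds
    dx = min(ax1, bx1) - max(ax0, bx0)
    dy = min(ay1, by1) - max(ay0, by0)
    return max(dx, 0.0) * max(dy, 0.0)


def _contained(a: ClassBox, b: ClassBox) -> bool:
    ax0, ax1, ay0, ay1 = a.bounds
    bx0, bx1, by0, by1 = b.bounds
    return ax0 >= bx0 and ax1 <= bx1 and ay0 >= by0 and ay1 <= by1


def pair_score(boxes: list[ClassBox]) -> tuple[list[float], float]:
    """Ordered overlap ratios and their mean A in percent.

    ratio(i, j) = area(i intersect j) / area(i): the same intersection counts
    twice, once against each box's own area, giving 12 ratios for 4 classes.
    A zero-area box has ratio 1 against boxes whose closure contains it,
    else 0.
    """
    ratios = []
    for a, b in permutations(boxes, 2):
        if a.area > 0:
            # clip: intersection cannot exceed own area, bar float roundoff
            ratios.append(min(_intersection_area(a, b) / a.area, 1.0))
        else:
            ratios.append(1.0 if _contained(a, b) else 0.0)
    return ratios, 100.0 * float(np.mean(ratios))


@dataclass
class SMResult:
    """Outcome of one Square Method run at a fixed threshold."""

    threshold: float
    retained_pairs: list[tuple[str, str]]
    weights: dict[str, int]
    selected: list[str]
    pair_scores: dict[tuple[str, str], float]
    discarded_by_correlation: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "retained_pairs": [list(p) for p in self.retained_pairs],
            "weights": self.weights,
            "selected": self.selected,
            "pair_scores": {f"{a}|{b}": v for (a, b), v in self.pair_scores.items()},
            "discarded_by_correlation": self.discarded_by_correlation,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _feature_columns(table: pd.DataFrame, feature_cols) -> list[str]:
    if feature_cols is not None:
        return list(feature_cols)
    return [c for c in table.columns
            if table[c].dtype.kind in "fc" and c not in ("flags",)]


def select_features(
    table: pd.DataFrame,
    threshold: float,
    corr_cut: float = CORR_CUT,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    class_col: str = "quadrant",
) -> SMResult:
    """Run the full Square Method pipeline at one overlap threshold.

    Column order does not affect the outcome (pairs are processed in sorted
    name order and ties broken by the seeded RNG).
    """
    features = sorted(_feature_columns(table, feature_cols))
    rng = np.random.default_rng(seed)

    pair_scores: dict[tuple[str, str], float] = {}
    retained: list[tuple[str, str]] = []
    weights: dict[str, int] = {f: 0 for f in features}
    for pair in combinations(features, 2):
        sub = table[[class_col, *pair]].dropna()
        boxes = class_boxes(sub, pair, class_col)
        _, A = pair_score(boxes)
        pair_scores[pair] = A
        if A <= threshold:
            retained.append(pair)
            weights[pair[0]] += 1
            weights[pair[1]] += 1

    # correlation pruning: the lower-weight feature of a correlated pair dies
    alive = [f for f in features if weights[f] > 0]
    corr = table[features].corr().abs() if len(features) > 1 else None
    discarded = []
    for fa, fb in combinations(sorted(alive), 2):
        if fa not in alive or fb not in alive:
            continue
        if corr is not None and corr.loc[fa, fb] > corr_cut:
            if weights[fa] == weights[fb]:
                loser = fa if rng.random() < 0.5 else fb
            else:
                loser = fa if weights[fa] < weights[fb] else fb
            alive.remove(loser)
            discarded.append(loser)

    if alive:
        w = np.array([weights[f] for f in alive], dtype=float)
        mean_w = w.mean()
        selected = [f for f in alive if weights[f] > mean_w]
        if not selected and np.all(w == w[0]):
            # degenerate tie: equal weights carry no ranking information, so
            # the mean rule keeps all surviving (uncorrelated) features
            selected = list(alive)
        selected.sort(key=lambda f: (-weights[f], f))
    else:
        selected = []
    return SMResult(threshold, retained, weights, selected, pair_scores, discarded)


def find_lowest_threshold(
    table: pd.DataFrame,
    corr_cut: float = CORR_CUT,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    class_col: str = "quadrant",
) -> float:
    """LO: the smallest integer percentage at which at least one feature
    survives selection."""
    for thr in range(1, 101):
        res = select_features(table, float(thr), corr_cut, seed, feature_cols, class_col)
        if res.selected:
            return float(thr)
    return 100.0


def threshold_grid(
    table: pd.DataFrame,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    class_col: str = "quadrant",
) -> list[float]:
    """Default sweep grid {100, 90, 70, 50, 30, 20, 10} plus LO."""
    lo = find_lowest_threshold(table, seed=seed, feature_cols=feature_cols,
                               class_col=class_col)
    grid = sorted(set(DEFAULT_THRESHOLDS) | {lo}, reverse=True)
    return [t for t in grid if t >= lo]


def overlap_report(
    table: pd.DataFrame,
    features: list[str],
    class_col: str = "quadrant",
) -> pd.DataFrame:
    """Per-class mean projection overlap for the top-3 features.

    For the three 2D projections of the top-3 feature box triplet, each
    class's ratios against the other classes are averaged; an ``Average`` row
    summarizes all classes. Percentages.
    """
    top = features[:3]
    if len(top) < 2:
        raise ValueError("need at least 2 features for an overlap report")
    projections = list(combinations(top, 2))
    per_class: dict[str, list[float]] = {}
    for pair in projections:
        boxes = class_boxes(table[[class_col, *pair]].dropna(), pair, class_col)
        for a in boxes:
            for b in boxes:
                if a is b:
                    continue
                r = (_intersection_area(a, b) / a.area if a.area > 0
                     else float(_contained(a, b)))
                per_class.setdefault(a.class_label, []).append(100.0 * r)
    rows = [{"class": c, "mean_overlap_pct": float(np.mean(v))}
            for c, v in sorted(per_class.items())]
    rows.append({"class": "Average",
                 "mean_overlap_pct": float(np.mean([r["mean_overlap_pct"] for r in rows]))})
    out = pd.DataFrame(rows)
    if len(projections) < 3:
        out.attrs["note"] = "fewer than 3 selected features: reduced projection set"
    return out
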