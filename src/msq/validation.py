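"""Validation statistics against manual annotations.

Segmented cells are compared with a reviewer's clicked points by a
point-in-polygon strategy with consumption (a matched cell leaves the
pool), yielding TP/FP/FN counts, the Dice score 2TP/(2TP+FP+FN) and
specificity. Small-sample correlations use an exact permutation Spearman
test: for n <= 9 without ties, the two-sided p-value is the tail
probability P(|rho_perm| >= |rho_observed|) over all n! rank permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon


@dataclass
class MatchCounts:
    """Confusion counts between predicted cells and manual points.

    tp: predicted cell containing a manual point (consumed pairings);
    fp: predicted cell never matched; fn: manual point inside no remaining
    cell; tn: only defined for cell-level label comparisons.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0 or (
                self.tn is not None and self.tn < 0):
            raise ValueError("counts must be non-negative")


def match_points_to_cells(points: list[tuple[float, float]],
                          polygons: list[np.ndarray],
                          ) -> tuple[MatchCounts, list[tuple[float, float]]]:
    """Greedy point-in-polygon matching with consumption.

    Points are processed in file order. A point inside an unconsumed
    polygon scores a TP and consumes that polygon (nearest-centroid
    tie-break when several contain it); a point inside none scores an FN
    and is returned as a residual marker (drawn as a 3-px circle in QC
    overlays); polygons never consumed score FPs.
    """
    polys = [Polygon(np.asarray(p, dtype=float)) for p in polygons]
    centroids = np.array([[g.centroid.x, g.centroid.y] for g in polys]) \
        if polys else np.empty((0, 2))
    consumed = np.zeros(len(polys), dtype=bool)
    counts = MatchCounts()
    residual: list[tuple[float, float]] = []
    for (px, py) in points:
        pt = shapely.points(px, py)
        hits = [i for i, g in enumerate(polys)
                if not consumed[i] and shapely.covers(g, pt)]
        if hits:
            if len(hits) > 1:
                d2 = ((centroids[hits] - (px, py)) ** 2).sum(axis=1)
                best = hits[int(np.argmin(d2))]
            else:
                best = hits[0]
            consumed[best] = True
            counts.tp += 1
        else:
            counts.fn += 1
            residual.append((px, py))
    counts.fp = int((~consumed).sum())
    return counts, residual


def dice_score(counts: MatchCounts) -> float:
    """Sørensen–Dice coefficient 2TP / (2TP + FP + FN); NaN if undefined."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return float("nan")
    return 2 * counts.tp / denom


def classification_metrics(predicted: np.ndarray, manual: np.ndarray) -> dict:
    """Cell-level confusion metrics for aligned boolean label vectors."""
    p = np.asarray(predicted, dtype=bool)
    m = np.asarray(manual, dtype=bool)
    if p.shape != m.shape:
        raise ValueError("label vectors must align per cell")
    tp = int((p & m).sum())
    fp = int((p & ~m).sum())
    fn = int((~p & m).sum())
    tn = int((~p & ~m).sum())
    out = {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    return out


def pr_curve(truth: np.ndarray, cluster_paths: np.ndarray,
             ranked_paths: list[str]) -> list[tuple[float, float]]:
    """Precision-recall points from sweeping cluster inclusion.

    Clusters are added in the given ranking (descending mean chromogen OD
    by convention); after each addition the covered cells are called
    positive and (recall, precision) recorded. The random baseline for
    such a sweep is the prevalence line precision = mean(truth).
    """
    truth = np.asarray(truth, dtype=bool)
    paths = np.asarray(cluster_paths, dtype=object)
    called = np.zeros(len(truth), dtype=bool)
    pts = []
    for path in ranked_paths:
        called |= (paths == path)
        tp = int((called & truth).sum())
        prec = tp / called.sum() if called.any() else float("nan")
        rec = tp / truth.sum() if truth.any() else 0.0
        pts.append((rec, prec))
    return pts


# ---------------------------------------------------------------------------
# exact Spearman
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    exact: bool
    has_ties: bool


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of ranks (average ranks under ties)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_exact(x: np.ndarray, y: np.ndarray,
                   exact_max_n: int = 9) -> SpearmanResult:
    """Spearman correlation with an exact small-sample permutation p-value.

    rho is computed from average ranks; without ties this equals
    ``1 - 6*sum(D^2) / (n*(n^2-1))``. For n <= ``exact_max_n`` and no
    ties, the two-sided p is the exact tail P(|rho_perm| >= |rho|) over
    all n! equally likely rank permutations; otherwise the usual
    t-distribution approximation is used and flagged as non-exact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, False, False)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    has_ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    rho = _spearman_rho(rx, ry)
    if n <= exact_max_n and not has_ties:
        p = _exact_tail_p(rx, ry, rho)
        return SpearmanResult(rho, p, n, True, False)
    t_rho, t_p = stats.spearmanr(x, y)
    return SpearmanResult(float(t_rho), float(t_p), n, False, has_ties)


def _exact_tail_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided tail over all n! permutations of one rank vector.

    Without ties rho is a deterministic function of sum(D^2), so the tail
    count reduces to counting permutations with sum(D^2) at or beyond
    either symmetric extreme.
    """
    n = len(rx)
    perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
    d2 = ((perms - rx[None, :]) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    hits = int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
    return hits / factorial(n)
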