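"""Compartment assignment, densities and nearest-neighbour proximity.

Cells are assigned to pathologist-annotated compartments by
point-in-polygon (boundary counts as inside; overlapping polygons resolve
by annotation file order). Proximity between two cell populations is
summarized as the mode of the Gaussian-KDE-smoothed distribution of
nearest-neighbour distances, one distance per population-A cell.
Distances are between centroids in µm, not boundary-to-boundary contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .core_io import AnnotationSet


@dataclass
class ProximitySummary:
    """Mode of minimal A->B distances within one compartment."""

    sample_id: str
    compartment: str
    population_a: str
    population_b: str
    n_a: int
    n_b: int
    mode_um: float
    bandwidth_um: float

    def __post_init__(self) -> None:
        if self.mode_um < 0:
            raise ValueError("mode must be non-negative")


def _prepared_polygons(annotations: AnnotationSet) -> list[tuple[str, Polygon]]:
    out = []
    for name, ring in annotations.polygons:
        poly = Polygon(np.asarray(ring, dtype=float))
        if not poly.is_valid:
            fixed = poly.buffer(0)
            if fixed.is_empty or not fixed.is_valid:
                warnings.warn(f"skipping unrepairable polygon {name!r}")
                continue
            warnings.warn(f"repaired invalid polygon {name!r}")
            if fixed.geom_type == "MultiPolygon":
                out.extend((name, g) for g in fixed.geoms)
                continue
            poly = fixed
        out.append((name, poly))
    return out


def assign_compartments(points: np.ndarray, annotations: AnnotationSet,
                        unassigned: str = "unassigned") -> np.ndarray:
    """Compartment label per (x, y) point; first matching polygon wins.

    Boundary points count as inside (``covers`` semantics).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.array([unassigned] * len(pts), dtype=object)
    remaining = np.ones(len(pts), dtype=bool)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    for name, poly in _prepared_polygons(annotations):
        if not remaining.any():
            break
        idx = np.nonzero(remaining)[0]
        inside = shapely.covers(poly, geoms[idx])
        hit = idx[inside]
        labels[hit] = name
        remaining[hit] = False
    return labels


def polygon_area_mm2(ring: np.ndarray, mpp: float) -> float:
    """Area of a level-0 pixel polygon in mm² (1 mm = 1000 µm)."""
    poly = Polygon(np.asarray(ring, dtype=float))
    return poly.area * (mpp ** 2) / 1e6


def compute_density(count: int, area_mm2: float) -> float:
    """Cells per mm² of analysed tissue."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return count / area_mm2


def nn_distances(a: np.ndarray, b: np.ndarray,
                 same_population: bool = False) -> np.ndarray:
    """Distance from each A cell to its nearest neighbour in B (µm).

    Inputs are (n, 2) centroid arrays already in µm. With
    ``same_population`` each point's zero self-distance is excluded.
    Distances are exact; the KD-tree is only a speed-up.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(b) == 0:
        raise ValueError("population B is empty")
    if same_population and len(a) < 2:
        raise ValueError("same-population distances need at least 2 cells in A")
    tree = cKDTree(b)
    if same_population:
        d, _ = tree.query(a, k=2)
        return d[:, 1]
    d, _ = tree.query(a, k=1)
    return d


def kde_mode(distances: np.ndarray, bandwidth: float | None = None,
             grid_size: int = 512) -> tuple[float, float]:
    """Mode of a Gaussian KDE over a distance sample, with the bandwidth.

    The KDE is evaluated on a ``grid_size``-point grid spanning
    [0, max + 3*bandwidth]; ties break toward the smaller distance. The
    default bandwidth is Scott's rule (n^(-1/5) * sigma-hat). A degenerate
    all-identical sample returns that value directly.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 2:
        raise ValueError("need at least 2 finite distances")
    if np.ptp(d) < 1e-12:
        return float(d[0]), 0.0
    if bandwidth is None:
        kde = stats.gaussian_kde(d, bw_method="scott")
    else:
        kde = stats.gaussian_kde(d, bw_method=bandwidth / d.std(ddof=1))
    bw = float(kde.factor * d.std(ddof=1))
    grid = np.linspace(0.0, d.max() + 3 * bw, grid_size)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))]), bw


def summarize_proximity(table: pd.DataFrame,
                        pairs: list[tuple[str, str]],
                        sample_id: str = "",
                        by_compartment: bool = True,
                        bandwidth: float | None = None
                        ) -> list[ProximitySummary]:
    """Build the proximity summary for marker-call populations.

    ``table`` must carry ``x_um``/``y_um``, boolean ``call_<marker>``
    columns, and (if stratifying) a ``compartment`` column. Pairs with too
    few cells (n_A < 2, or n_B < 1; n_B < 2 when A = B) are skipped.
    """
    comps = (sorted(table["compartment"].unique()) if by_compartment
             else ["all"])
    out: list[ProximitySummary] = []
    for comp in comps:
        sub = table if comp == "all" else table[table["compartment"] == comp]
        for pa, pb in pairs:
            a = sub.loc[sub[f"call_{pa}"].astype(bool),
                        ["x_um", "y_um"]].to_numpy()
            b = sub.loc[sub[f"call_{pb}"].astype(bool),
                        ["x_um", "y_um"]].to_numpy()
            same = pa == pb
            if len(a) < 2 or len(b) < (2 if same else 1):
                continue
            d = nn_distances(a, b, same_population=same)
            mode, bw = kde_mode(d, bandwidth=bandwidth)
            out.append(ProximitySummary(
                sample_id=sample_id, compartment=comp,
                population_a=pa, population_b=pb,
                n_a=len(a), n_b=len(b), mode_um=mode, bandwidth_um=bw))
    return out
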