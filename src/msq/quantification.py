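"""Per-cell feature extraction and cross-tile deduplication.

For every composite cell and every staining iteration, intensity
statistics of the chromogen channel (min, max, percentiles, mean, std) and
the median nuclear OD are computed over three compartments: nucleus,
3-px cytoplasm ring, and whole cell. Morphology (area, perimeter, ellipse
axes, eccentricity) comes from the shared composite nucleus once.

Features are computed on padded tiles, but a record survives only if its
centroid lies inside the tile's half-open core — since cores partition the
slide, every cell is counted exactly once regardless of tile overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .coords import Bounds
from .tiling import TileSpec

PERCENTILES = (10, 25, 50, 75, 90)
STAT_NAMES = ("min", "max", "p10", "p25", "p50", "p75", "p90", "mean", "std")
COMPARTMENTS = ("nucleus", "cytoplasm", "cell")


@dataclass
class FeatureRecord:
    """One features-table row: a cell with its per-stain statistics."""

    cell_id: str
    tile_row: int
    tile_col: int
    x_px: float
    y_px: float
    x_um: float
    y_um: float
    area_px: float
    perimeter_px: float
    major_px: float
    minor_px: float
    eccentricity: float
    support: int = 1
    rbc_flag: bool = False
    compartment: str = "unassigned"
    channel_stats: dict = field(default_factory=dict)
    cluster_paths: dict = field(default_factory=dict)
    marker_calls: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "cell_id": self.cell_id,
            "tile_row": self.tile_row, "tile_col": self.tile_col,
            "x_px": self.x_px, "y_px": self.y_px,
            "x_um": self.x_um, "y_um": self.y_um,
            "area_px": self.area_px, "perimeter_px": self.perimeter_px,
            "major_px": self.major_px, "minor_px": self.minor_px,
            "eccentricity": self.eccentricity,
            "support": self.support, "rbc_flag": self.rbc_flag,
            "compartment": self.compartment,
        }
        row.update(self.channel_stats)
        for marker, path in self.cluster_paths.items():
            row[f"cluster_{marker}"] = path
        for marker, call in self.marker_calls.items():
            row[f"call_{marker}"] = call
        return row


def compartment_stats(pixels: np.ndarray, prefix: str) -> dict:
    """Summary statistics of one compartment's chromogen pixel values.

    Percentiles use linear interpolation. An empty compartment yields
    NaN-marked statistics rather than zeros.
    """
    out: dict = {}
    if pixels.size == 0:
        for s in STAT_NAMES:
            out[f"{prefix}_{s}"] = np.nan
        return out
    pixels = np.asarray(pixels, dtype=float)
    qs = np.percentile(pixels, PERCENTILES, method="linear")
    out[f"{prefix}_min"] = float(pixels.min())
    out[f"{prefix}_max"] = float(pixels.max())
    for p, q in zip(PERCENTILES, qs):
        out[f"{prefix}_p{p}"] = float(q)
    out[f"{prefix}_mean"] = float(pixels.mean())
    out[f"{prefix}_std"] = float(pixels.std())
    return out


def quantify_cell(masks: dict,
                  channels: dict,
                  cell_id: str = "",
                  tile: TileSpec | None = None,
                  centroid_px: tuple[float, float] = (0.0, 0.0),
                  mpp: float = 0.5,
                  support: int = 1,
                  rbc_flag: bool = False) -> FeatureRecord:
    """Extract one cell's features.

    ``masks`` maps compartment name -> boolean mask; ``channels`` maps
    stain name -> (chromogen OD, nuclear OD) or (chromogen, nuclear,
    residual) rasters of the same shape; when a residual channel is given
    its nucleus median is recorded too (the RBC filter's input).
    Morphology (area, perimeter, ellipse axes from second moments,
    eccentricity) is measured once from the nucleus mask.
    """
    nucleus = np.asarray(masks["nucleus"], dtype=bool)
    for name, m in masks.items():
        for stain, chans in channels.items():
            for ch in chans:
                if m.shape != ch.shape:
                    raise ValueError(
                        f"mask {name!r} and channels of stain {stain!r} disagree")
    rp = measure.regionprops(nucleus.astype(np.uint8))[0]
    stats: dict = {}
    for stain, chans in channels.items():
        chrom, nuc = chans[0], chans[1]
        resid = chans[2] if len(chans) > 2 else None
        for comp in COMPARTMENTS:
            m = np.asarray(masks[comp], dtype=bool)
            stats.update(compartment_stats(chrom[m], f"{stain}_{comp}_chrom"))
            nuc_px = nuc[m]
            stats[f"{stain}_{comp}_nuclear_p50"] = (
                float(np.median(nuc_px)) if nuc_px.size else np.nan)
        if resid is not None:
            r_px = resid[nucleus]
            stats[f"{stain}_nucleus_residual_p50"] = (
                float(np.median(r_px)) if r_px.size else np.nan)
    cx, cy = centroid_px
    return FeatureRecord(
        cell_id=cell_id,
        tile_row=tile.row if tile else 0,
        tile_col=tile.col if tile else 0,
        x_px=float(cx), y_px=float(cy),
        x_um=float(cx) * mpp, y_um=float(cy) * mpp,
        area_px=float(rp.area),
        perimeter_px=float(rp.perimeter),
        major_px=float(rp.axis_major_length),
        minor_px=float(rp.axis_minor_length),
        eccentricity=float(rp.eccentricity),
        support=support, rbc_flag=rbc_flag,
        channel_stats=stats)


def collect_core_records(records: list[FeatureRecord],
                         spec: TileSpec) -> list[FeatureRecord]:
    """Keep only records whose centroid falls in the tile's half-open core.

    Left/top edges are inclusive, right/bottom exclusive, so each cell in
    an overlap strip belongs to exactly one tile.
    """
    core: Bounds = spec.core
    return [r for r in records if core.contains(r.x_px, r.y_px)]


def assemble_features_table(per_tile: list[list[FeatureRecord]]) -> pd.DataFrame:
    """Concatenate per-tile kept records into one table with unique ids.

    Ids are ``r{row}c{col}n{k}`` serialized from (tile row, tile col, local
    index); rows are sorted canonically by id so the output is independent
    of tile processing order. A collision means deduplication failed
    upstream and raises.
    """
    rows = []
    seen: set[str] = set()
    for records in per_tile:
        for k, rec in enumerate(records):
            if not rec.cell_id:
                rec.cell_id = f"r{rec.tile_row}c{rec.tile_col}n{k}"
            if rec.cell_id in seen:
                raise ValueError(f"cell id collision: {rec.cell_id}")
            seen.add(rec.cell_id)
            rows.append(rec.to_row())
    if not rows:
        return pd.DataFrame(columns=["cell_id"])
    df = pd.DataFrame(rows)
    return df.sort_values("cell_id", kind="stable").reset_index(drop=True)


def impute_for_clustering(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Replace NaN compartment statistics with 0 OD for clustering only.

    Returns the imputed copy and a per-row flag marking imputed cells; the
    stored features table keeps its NaN markers.
    """
    num = df.select_dtypes(include=[np.number])
    flagged = num.isna().any(axis=1)
    out = df.copy()
    out[num.columns] = num.fillna(0.0)
    return out, flagged
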