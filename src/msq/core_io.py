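"""Slide, annotation, configuration and table I/O plus tile stitching.

The on-disk formats are deliberately boring: pyramidal TIFF for images,
GeoJSON for pathologist annotations (QuPath-compatible), CSV for the
features table, and a plain-text ``key = value`` document for the run
configuration so a run can be replayed bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .coords import Bounds

BACKGROUND = 255  # white glass


# ---------------------------------------------------------------------------
# slides
# ---------------------------------------------------------------------------

@dataclass
class SlideImage:
    """An RGB brightfield slide held as an explicit resolution pyramid.

    ``levels[0]`` is full resolution; each further level is downscaled by an
    integer factor (sorted increasing). ``mpp`` is microns per pixel at
    level 0; the default 0.5 corresponds to a 1000-px tile spanning ~500 µm.
    """

    levels: list[np.ndarray]
    mpp: float = 0.5
    path: str | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("slide needs at least one level")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        h0, w0 = self.levels[0].shape[:2]
        if h0 < 1 or w0 < 1:
            raise ValueError("empty level-0 raster")
        prev = 0.0
        for lv in self.levels:
            ds = w0 / lv.shape[1]
            if ds < prev:
                raise ValueError("levels must be sorted by increasing downscale")
            prev = ds

    @property
    def width(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height(self) -> int:
        return self.levels[0].shape[0]

    @property
    def downsamples(self) -> list[float]:
        return [self.width / lv.shape[1] for lv in self.levels]

    @classmethod
    def from_array(cls, arr: np.ndarray, mpp: float = 0.5,
                   n_levels: int = 1) -> "SlideImage":
        """Build a pyramid from a level-0 raster by factor-2 box downscaling."""
        levels = [np.asarray(arr)]
        for _ in range(1, n_levels):
            prev = levels[-1]
            h, w = prev.shape[:2]
            if min(h, w) < 2:
                break
            he, we = h - h % 2, w - w % 2
            blk = prev[:he, :we].reshape(he // 2, 2, we // 2, 2, -1)
            levels.append(blk.mean(axis=(1, 3)).astype(prev.dtype).squeeze())
        return cls(levels=levels, mpp=mpp)

    @classmethod
    def from_tiff(cls, path: str | Path, mpp: float | None = None) -> "SlideImage":
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            if hasattr(series, "levels") and len(series.levels) > 1:
                levels = [lv.asarray() for lv in series.levels]
            else:
                levels = [p.asarray() for p in tf.pages]
            if mpp is None:
                mpp = _mpp_from_tags(tf) or 0.5
        levels.sort(key=lambda a: -a.shape[1])
        return cls(levels=levels, mpp=mpp, path=str(path))

    def write_tiff(self, path: str | Path) -> None:
        """Write all pyramid levels as TIFF pages (level 0 first)."""
        path = str(path)
        res = 1e4 / self.mpp  # px per cm
        with tifffile.TiffWriter(path) as tw:
            for lv in self.levels:
                tw.write(lv, resolution=(res, res), resolutionunit="CENTIMETER")

    def thumbnail(self, max_size: int = 1024) -> tuple[np.ndarray, float]:
        """Smallest stored level, further strided to fit ``max_size``.

        Returns the raster and its total downscale relative to level 0.
        """
        lv = self.levels[-1]
        ds = self.downsamples[-1]
        step = max(1, int(np.ceil(max(lv.shape[:2]) / max_size)))
        return lv[::step, ::step], ds * step


def _mpp_from_tags(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    px_per_unit = num / den
    if getattr(unit, "value", unit) == 3:  # centimeter
        return 1e4 / px_per_unit
    if getattr(unit, "value", unit) == 2:  # inch
        return 25.4e3 / px_per_unit
    return None


def read_region(slide: SlideImage, level: int, bounds: Bounds) -> np.ndarray:
    """Copy a half-open rectangle out of one pyramid level.

    Pixel (0, 0) of the output is the bounds origin.
    """
    if bounds.area == 0:
        raise ValueError(f"zero-area bounds {bounds}")
    lv = slide.levels[level]
    h, w = lv.shape[:2]
    extent = Bounds(0, 0, w, h)
    if not extent.covers(bounds):
        raise ValueError(f"bounds {bounds} outside level {level} extent {w}x{h}")
    return lv[bounds.y0:bounds.y1, bounds.x0:bounds.x1].copy()


# ---------------------------------------------------------------------------
# annotations (GeoJSON, QuPath-compatible)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Named region polygons plus optional labelled point annotations.

    Polygons are (name, exterior ring) pairs in level-0 pixel coordinates;
    file order is preserved because it is the priority signal when regions
    overlap. Points are (class label, x, y).
    """

    polygons: list[tuple[str, np.ndarray]] = field(default_factory=list)
    points: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.polygons]


def _feature_name(props: dict) -> str:
    cls = props.get("classification")
    if isinstance(cls, dict) and "name" in cls:
        return str(cls["name"])
    if isinstance(cls, str):
        return cls
    if "name" in props:
        return str(props["name"])
    return "unlabelled"


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of polygons and points.

    Unsupported geometry types are skipped with a warning; features without
    a classification are named "unlabelled". Coordinates are preserved
    exactly as stored (level-0 pixel units).
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    out = AnnotationSet()
    for feat in feats:
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        name = _feature_name(props)
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "Polygon":
            out.polygons.append((name, np.asarray(coords[0], dtype=float)))
        elif gtype == "MultiPolygon":
            for poly in coords:
                out.polygons.append((name, np.asarray(poly[0], dtype=float)))
        elif gtype == "Point":
            out.points.append((name, float(coords[0]), float(coords[1])))
        elif gtype == "MultiPoint":
            for pt in coords:
                out.points.append((name, float(pt[0]), float(pt[1])))
        else:
            warnings.warn(f"skipping unsupported geometry type {gtype!r}")
    return out


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    feats = []
    for name, ring in annotations.polygons:
        ring = np.asarray(ring, dtype=float)
        if len(ring) and not np.array_equal(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[:1]])
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
            "properties": {"classification": {"name": name}},
        })
    for name, x, y in annotations.points:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {"classification": {"name": name}},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def stitch_tiles(tiles: Sequence[tuple["TileSpec", np.ndarray]],
                 mode: str = "rgb",
                 extent: Bounds | None = None,
                 overlay_points: Sequence[tuple[str, float, float]] | None = None,
                 ) -> np.ndarray:
    """Mosaic padded tile rasters back into one whole-slide raster.

    Each output pixel is taken from the unique tile whose *core* contains
    it, so overlapping padded margins never appear twice. Core regions not
    covered by any provided tile are filled with background white (with a
    warning). ``overlay`` mode additionally paints 3-px dots at the given
    (class, x, y) points using a small colour cycle.
    """
    if mode not in ("rgb", "multichannel", "overlay"):
        raise ValueError(f"unknown stitch mode {mode!r}")
    if not tiles:
        raise ValueError("no tiles to stitch")
    if extent is None:
        extent = Bounds(min(t.core.x0 for t, _ in tiles),
                        min(t.core.y0 for t, _ in tiles),
                        max(t.core.x1 for t, _ in tiles),
                        max(t.core.y1 for t, _ in tiles))
    sample = tiles[0][1]
    nch = 1 if sample.ndim == 2 else sample.shape[2]
    if mode == "multichannel":
        out = np.zeros((extent.height, extent.width, nch), dtype=sample.dtype)
    else:
        out = np.full((extent.height, extent.width, 3), BACKGROUND,
                      dtype=np.uint8)
    covered = np.zeros((extent.height, extent.width), dtype=bool)
    for spec, raster in tiles:
        core, padded = spec.core, spec.padded
        oy, ox = core.y0 - extent.y0, core.x0 - extent.x0
        ry, rx = core.y0 - padded.y0, core.x0 - padded.x0
        patch = raster[ry:ry + core.height, rx:rx + core.width]
        if patch.ndim == 2:
            patch = patch[..., None]
        out[oy:oy + core.height, ox:ox + core.width] = patch
        covered[oy:oy + core.height, ox:ox + core.width] = True
    if not covered.all():
        warnings.warn("stitched extent not fully covered by tile cores; "
                      "missing regions filled with background")
    if mode == "overlay" and overlay_points:
        palette = [(220, 20, 60), (30, 144, 255), (34, 139, 34),
                   (255, 140, 0), (148, 0, 211)]
        classes = sorted({c for c, _, _ in overlay_points})
        for cls, x, y in overlay_points:
            colour = palette[classes.index(cls) % len(palette)]
            cy, cx = int(round(y)) - extent.y0, int(round(x)) - extent.x0
            yy, xx = np.mgrid[max(cy - 3, 0):min(cy + 4, out.shape[0]),
                              max(cx - 3, 0):min(cx + 4, out.shape[1])]
            keep = (yy - cy) ** 2 + (xx - cx) ** 2 <= 9
            out[yy[keep], xx[keep]] = colour
    return out


# ---------------------------------------------------------------------------
# features table
# ---------------------------------------------------------------------------

def write_features_table(records: "Iterable | pd.DataFrame",
                         path: str | Path) -> pd.DataFrame:
    """Write per-cell feature records to CSV, one row per cell.

    Accepts FeatureRecord objects (anything with ``to_row()``) or a
    DataFrame. Column order is stable; numeric fields round-trip at full
    precision (repr-based float formatting). Duplicate cell ids are an
    error because they indicate a deduplication failure upstream.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in records]
        cols: list[str] = []
        for r in rows:
            for k in r:
                if k not in cols:
                    cols.append(k)
        df = pd.DataFrame(rows, columns=cols)
    if "cell_id" in df.columns and df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids: {dupes[:5]}")
    df.to_csv(path, index=False, float_format=None)
    return df


def read_features_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of a run; stain 0 is the reference iteration.

    Defaults follow the protocol the pipeline was built around: 1000-px
    tiles (~500 µm at 0.5 µm/px) with 10% overlapping borders, a 60%
    cross-stain consensus within 3 µm, 3-px cytoplasm expansion, and PCA
    retaining 90% of the variance ahead of clustering.
    """

    stains: tuple[str, ...] = ("stain0",)
    tile_size: int = 1000
    overlap_frac: float = 0.10
    min_tissue_frac: float = 0.05
    consensus_frac: float = 0.60
    match_radius_um: float = 3.0
    cytoplasm_px: int = 3
    pca_var: float = 0.90
    k_clusters: int = 20
    seed: int = 0
    mpp: float = 0.5
    # tissue-mask thresholds (HSV) and cleanup
    s_min: float = 0.05
    v_max: float = 0.95
    min_object_px: int = 64
    # deconvolution
    od_floor: float = 0.15
    # per-stain 3x3 matrices, row-major, persisted for reproducibility
    stain_matrices: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 0.5):
            raise ValueError("overlap_frac must be in [0, 0.5)")
        if not (0 < self.consensus_frac <= 1):
            raise ValueError("consensus_frac must be in (0, 1]")
        if self.tile_size < 1 or self.mpp <= 0:
            raise ValueError("tile_size and mpp must be positive")
        self.stains = tuple(self.stains)

    @property
    def margin_px(self) -> int:
        """Padding per tile side; two neighbours share 2*margin px."""
        return int(round(self.overlap_frac / 2 * self.tile_size))

    @property
    def match_radius_px(self) -> float:
        return self.match_radius_um / self.mpp


def write_config(cfg: RunConfig, path: str | Path) -> None:
    lines = ["# msq run configuration"]
    for f in dc_fields(cfg):
        val = getattr(cfg, f.name)
        if f.name == "stains":
            val = ",".join(val)
        elif f.name == "stain_matrices":
            for stain, mat in val.items():
                flat = np.asarray(mat, dtype=float).ravel()
                lines.append(f"stain_matrix.{stain} = "
                             + ",".join(repr(float(v)) for v in flat))
            continue
        lines.append(f"{f.name} = {val!r}" if isinstance(val, float)
                     else f"{f.name} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    """Parse the plain-text config; unknown keys warn but never fail."""
    known = {f.name: f for f in dc_fields(RunConfig)}
    kwargs: dict = {}
    matrices: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key.startswith("stain_matrix."):
            stain = key.split(".", 1)[1]
            matrices[stain] = np.array(
                [float(v) for v in val.split(",")], dtype=float).reshape(3, 3)
        elif key == "stains":
            kwargs["stains"] = tuple(v for v in val.split(",") if v)
        elif key in known:
            typ = known[key].type
            if typ in ("int", int):
                kwargs[key] = int(val)
            elif typ in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        elif key != "stain_matrices":
            warnings.warn(f"unknown config key {key!r} ignored")
    cfg = RunConfig(**kwargs)
    cfg.stain_matrices = matrices
    return cfg
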