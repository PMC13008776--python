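"""End-to-end orchestration of the tile-based analysis.

``run_pipeline`` chains the modules exactly as the per-tile workflow
prescribes: tissue mask and tile plan on the reference stain, per-stain
stain-matrix estimation from thumbnails, coarse thumbnail translation,
per-tile affine+elastic registration of each later stain onto the first,
per-stain segmentation, cross-stain consensus reconciliation, cytoplasm
expansion and quantification — with metadata kept only for centroids
inside each tile's unextended core, so overlapping padding never double
counts a cell.

Tiles are independent: processing order cannot change the assembled table
because ids derive from tile grid coordinates and rows are canonically
sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import Bounds
from .core_io import RunConfig, SlideImage, read_region
from .deconvolution import StainMatrix, deconvolve_tile, estimate_stain_matrix
from .registration import (RegistrationParams, apply_deformation,
                           coarse_translate, register_tile_pair)
from .segmentation import (CompositeCell, expand_cytoplasm, filter_rbc,
                           reconcile_composite, segment_nuclei)
from .quantification import (FeatureRecord, assemble_features_table,
                             collect_core_records, quantify_cell)
from .tiling import TileSpec, compute_tissue_mask, plan_tiles


@dataclass
class PipelineResult:
    features: pd.DataFrame
    cells: list[CompositeCell]
    tiles: list[TileSpec]
    stain_matrices: dict
    registration_qc: pd.DataFrame
    coarse_offsets: list[tuple[int, int]]
    qc: dict = field(default_factory=dict)


def run_pipeline(slides: list[SlideImage], cfg: RunConfig,
                 register: bool = True,
                 registration_params: RegistrationParams | None = None,
                 backend: str = "builtin",
                 segmentation_kwargs: dict | None = None,
                 rbc_filtering: bool = True) -> PipelineResult:
    """Run the full brightfield pipeline on one slide panel.

    ``slides[0]`` is the reference iteration. Set ``register=False`` for
    panels known to be pre-aligned (skips the affine/elastic stage but
    keeps everything else identical).
    """
    if not slides:
        raise ValueError("no slides")
    if len(slides) != len(cfg.stains):
        raise ValueError("one slide per configured stain required")
    seg_kw = segmentation_kwargs or {}
    ref = slides[0]

    thumb0, ds0 = ref.thumbnail()
    mask = compute_tissue_mask(thumb0, s_min=cfg.s_min, v_max=cfg.v_max,
                               min_object_px=cfg.min_object_px)
    tiles = plan_tiles(mask, cfg, downscale=ds0,
                       slide_extent=(ref.width, ref.height))

    matrices: dict[str, StainMatrix] = {}
    offsets: list[tuple[int, int]] = [(0, 0)]
    for s, slide in enumerate(slides):
        thumb, ds = slide.thumbnail()
        matrices[cfg.stains[s]] = estimate_stain_matrix(
            thumb, od_floor=cfg.od_floor)
        if s > 0:
            ft = thumb0
            if ft.shape != thumb.shape:
                hh = min(ft.shape[0], thumb.shape[0])
                ww = min(ft.shape[1], thumb.shape[1])
                ft, thumb = ft[:hh, :ww], thumb[:hh, :ww]
            dx, dy, _, low = coarse_translate(ft, thumb, downscale=ds)
            offsets.append((0, 0) if low else (-dx, -dy))

    per_tile_records: list[list[FeatureRecord]] = []
    all_cells: list[CompositeCell] = []
    qc_rows = []
    for spec in tiles:
        records, cells, qc = _process_tile(
            spec, slides, cfg, matrices, offsets, register,
            registration_params, backend, seg_kw)
        per_tile_records.append(records)
        all_cells.extend(cells)
        qc_rows.extend(qc)

    if rbc_filtering:
        _apply_rbc_filter(per_tile_records, cfg)

    table = assemble_features_table(per_tile_records)
    qc_df = pd.DataFrame(
        qc_rows, columns=["tile_row", "tile_col", "stain",
                          "metric_before", "metric_after", "kind"])
    return PipelineResult(features=table, cells=all_cells, tiles=tiles,
                          stain_matrices=matrices, registration_qc=qc_df,
                          coarse_offsets=offsets,
                          qc={"n_tiles": len(tiles),
                              "analysed_area_mm2": sum(
                                  t.core.area for t in tiles) * cfg.mpp ** 2 / 1e6})


def _process_tile(spec: TileSpec, slides: list[SlideImage], cfg: RunConfig,
                  matrices: dict, offsets: list[tuple[int, int]],
                  register: bool, reg_params: RegistrationParams | None,
                  backend: str, seg_kw: dict):
    ref = slides[0]
    padded = spec.padded
    fixed_rgb = read_region(ref, 0, padded)
    m0 = matrices[cfg.stains[0]]
    fixed_chrom, fixed_nuc, fixed_res = deconvolve_tile(fixed_rgb, m0)

    channels = {cfg.stains[0]: (fixed_chrom, fixed_nuc, fixed_res)}
    per_stain_objs = [segment_nuclei(fixed_nuc, backend=backend,
                                     seed=cfg.seed, stain=0, **seg_kw)]
    qc_rows = []
    for s in range(1, len(slides)):
        mslide = slides[s]
        dx, dy = offsets[s]
        mb = padded.shift(dx, dy).clip(mslide.width, mslide.height)
        moving_rgb = np.full((padded.height, padded.width, 3), 255,
                             dtype=np.uint8)
        sub = read_region(mslide, 0, mb) if mb.area else None
        if sub is not None:
            oy, ox = mb.y0 - (padded.y0 + dy), mb.x0 - (padded.x0 + dx)
            moving_rgb[oy:oy + mb.height, ox:ox + mb.width] = sub
        ms = matrices[cfg.stains[s]]
        _, moving_nuc, _ = deconvolve_tile(moving_rgb, ms)
        if register:
            fld = register_tile_pair(fixed_nuc, moving_nuc, reg_params)
            moving_rgb = apply_deformation(moving_rgb, fld, fill=255.0)
            qc_rows.append((spec.row, spec.col, cfg.stains[s],
                            fld.metric_before, fld.metric_after,
                            fld.provenance.get("kind", "?")))
        chrom, nuc, res = deconvolve_tile(moving_rgb, ms)
        channels[cfg.stains[s]] = (chrom, nuc, res)
        per_stain_objs.append(segment_nuclei(nuc, backend=backend,
                                             seed=cfg.seed, stain=s, **seg_kw))

    cells = reconcile_composite(per_stain_objs, cfg,
                                offset=(padded.x0, padded.y0))
    records = []
    shape = (padded.height, padded.width)
    for k, cell in enumerate(cells):
        if cell.coords is None:
            continue
        nuc_mask = np.zeros(shape, dtype=bool)
        nuc_mask[cell.coords[:, 0], cell.coords[:, 1]] = True
        nucleus, cyto, whole = expand_cytoplasm(nuc_mask, cfg.cytoplasm_px)
        rec = quantify_cell(
            {"nucleus": nucleus, "cytoplasm": cyto, "cell": whole},
            channels,
            cell_id=f"r{spec.row}c{spec.col}n{k}",
            tile=spec,
            centroid_px=cell.centroid,
            mpp=cfg.mpp,
            support=cell.support)
        records.append(rec)
    kept = collect_core_records(records, spec)
    # overlap padding means border cells recur in neighbouring tiles;
    # a cell belongs to the unique tile whose core holds its centroid
    kept_cells = [c for c in cells if spec.core.contains(*c.centroid)]
    return kept, kept_cells, qc_rows


def _apply_rbc_filter(per_tile_records: list[list[FeatureRecord]],
                      cfg: RunConfig) -> None:
    """Flag hypothesized RBCs on the kept records, cohort-wide."""
    flat = [r for recs in per_tile_records for r in recs]
    if not flat:
        return
    stains = cfg.stains
    nuc = np.array([np.nanmedian([r.channel_stats.get(
        f"{s}_nucleus_nuclear_p50", np.nan) for s in stains]) for r in flat])
    res = np.array([np.nanmedian([r.channel_stats.get(
        f"{s}_nucleus_residual_p50", np.nan) for s in stains]) for r in flat])
    if np.isnan(nuc).all() or np.isnan(res).all():
        return
    proxies = [CompositeCell(cell_id=i, centroid=(0, 0), centroid_um=(0, 0),
                             polygon=np.empty((0, 2)), support=1, members=[])
               for i in range(len(flat))]
    filter_rbc(proxies, np.nan_to_num(nuc), np.nan_to_num(res))
    for rec, proxy in zip(flat, proxies):
        rec.rbc_flag = proxy.rbc_flag
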