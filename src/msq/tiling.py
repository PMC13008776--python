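"""Tissue masking and overlap-padded tile planning.

The slide is split into non-overlapping 1000-px *cores* (so cores partition
the tissue bounding box exactly — the deduplication guarantee) and each
core is padded by ``overlap_frac/2 * tile_size`` per side, giving
neighbouring padded tiles a shared strip of 10% of the tile size at
defaults. Registration and segmentation run on padded tiles so cells near
edges keep their context; metadata is later collected from cores only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color, draw, morphology
from scipy import ndimage

from .coords import Bounds
from .core_io import RunConfig


@dataclass(frozen=True)
class TileSpec:
    """One grid element: half-open core and padded bounds in level-0 px."""

    row: int
    col: int
    core: Bounds
    padded: Bounds
    tissue_frac: float = 1.0
    offset: tuple[int, int] = (0, 0)  # stain-specific coarse translation

    def __post_init__(self) -> None:
        if not self.padded.covers(self.core):
            raise ValueError("padded bounds must contain the core")
        if not (0.0 <= self.tissue_frac <= 1.0):
            raise ValueError("tissue_frac outside [0, 1]")


def compute_tissue_mask(thumbnail: np.ndarray,
                        manual_regions: list[np.ndarray] | None = None,
                        s_min: float = 0.05,
                        v_max: float = 0.95,
                        close_radius: int = 2,
                        min_object_px: int = 64) -> np.ndarray:
    """Binary tissue mask of a thumbnail (True = tissue).

    Automatic rule: a pixel is tissue when its HSV saturation exceeds
    ``s_min`` and its value falls below ``v_max`` — background glass is
    bright and unsaturated. The raw mask is then morphologically closed,
    hole-filled, and stripped of objects below ``min_object_px``.

    ``manual_regions`` (polygon rings in thumbnail coordinates), when
    given, REPLACE the automatic mask entirely.
    """
    h, w = np.asarray(thumbnail).shape[:2]
    if manual_regions is not None:
        mask = np.zeros((h, w), dtype=bool)
        for ring in manual_regions:
            ring = np.asarray(ring, dtype=float)
            rr, cc = draw.polygon(ring[:, 1], ring[:, 0], shape=(h, w))
            mask[rr, cc] = True
        return mask
    hsv = color.rgb2hsv(np.asarray(thumbnail, dtype=np.uint8))
    mask = (hsv[..., 1] > s_min) & (hsv[..., 2] < v_max)
    if close_radius > 0:
        mask = morphology.closing(mask, morphology.disk(close_radius))
    mask = ndimage.binary_fill_holes(mask)
    lab, _ = ndimage.label(mask)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = np.isin(lab, np.nonzero(counts >= min_object_px)[0])
    if not mask.any():
        warnings.warn("no tissue found: mask is empty")
    return mask


def tissue_fraction(spec: TileSpec, mask: np.ndarray,
                    downscale: float = 1.0) -> float:
    """Fraction of the tile core covered by tissue, in [0, 1]."""
    c = spec.core
    x0 = int(np.floor(c.x0 / downscale))
    y0 = int(np.floor(c.y0 / downscale))
    x1 = max(int(np.ceil(c.x1 / downscale)), x0 + 1)
    y1 = max(int(np.ceil(c.y1 / downscale)), y0 + 1)
    sub = mask[y0:min(y1, mask.shape[0]), x0:min(x1, mask.shape[1])]
    if sub.size == 0:
        return 0.0
    return float(sub.mean())


def plan_tiles(mask: np.ndarray, cfg: RunConfig,
               downscale: float = 1.0,
               slide_extent: tuple[int, int] | None = None) -> list[TileSpec]:
    """Plan the tile grid over the tissue bounding box.

    Cores are ``tile_size`` squares anchored at the bounding-box origin
    (the trailing row/column clipped at the slide edge), pairwise disjoint
    and jointly covering the box. Tiles whose core holds less than
    ``min_tissue_frac`` tissue are dropped. Padded bounds add
    ``cfg.margin_px`` per side, clipped at the slide extent.

    ``downscale`` maps mask pixels to level-0 px; ``slide_extent`` is
    (width, height) at level 0 and defaults to the mask extent scaled up.
    """
    if not mask.any():
        return []
    if slide_extent is None:
        slide_extent = (int(round(mask.shape[1] * downscale)),
                        int(round(mask.shape[0] * downscale)))
    sw, sh = slide_extent
    ys, xs = np.nonzero(mask)
    bx0 = int(np.floor(xs.min() * downscale))
    by0 = int(np.floor(ys.min() * downscale))
    bx1 = min(int(np.ceil((xs.max() + 1) * downscale)), sw)
    by1 = min(int(np.ceil((ys.max() + 1) * downscale)), sh)
    ts, margin = cfg.tile_size, cfg.margin_px
    n_rows = int(np.ceil((by1 - by0) / ts))
    n_cols = int(np.ceil((bx1 - bx0) / ts))
    specs: list[TileSpec] = []
    for r in range(n_rows):
        for c in range(n_cols):
            core = Bounds(bx0 + c * ts, by0 + r * ts,
                          min(bx0 + (c + 1) * ts, bx1),
                          min(by0 + (r + 1) * ts, by1))
            padded = core.expand(margin).clip(sw, sh)
            spec = TileSpec(row=r, col=c, core=core, padded=padded)
            frac = tissue_fraction(spec, mask, downscale)
            if frac >= cfg.min_tissue_frac:
                specs.append(TileSpec(row=r, col=c, core=core, padded=padded,
                                      tissue_frac=frac))
    return specs
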