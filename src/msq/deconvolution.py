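"""Colour deconvolution of chromogenic brightfield stains.

Transmitted light mixes stain absorbances linearly in optical-density (OD)
space (Beer-Lambert), so an RGB pixel unmixes into per-stain concentrations
through a 3x3 stain matrix. The matrix is estimated per staining iteration
from the slide thumbnail with a Macenko-style procedure: project tissue OD
pixels onto their principal plane and take the extreme percentile angles as
the two stain vectors. The third (residual) channel is the normalized cross
product and absorbs whatever the two stains do not explain.

OD uses base 10 with white level ``i0 = 255`` throughout, so tests can pin
exact values (pixel 25.5 -> OD 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Standard published OD vectors (unit norm below) used as reference hues to
# label the recovered columns: haematoxylin is blue-purple, AEC red.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
AEC_OD = np.array([0.2743, 0.6796, 0.6803])
DAB_OD = np.array([0.268, 0.570, 0.776])
EOSIN_OD = np.array([0.070, 0.990, 0.110])  # the classic RBC confounder hue


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class StainMatrix:
    """Columns are unit-norm OD vectors: chromogen, nuclear, residual."""

    matrix: np.ndarray  # 3x3, columns [chromogen, nuclear, residual]
    labels: tuple[str, str, str] = ("chromogen", "nuclear", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"columns must be unit norm, got {norms}")
        if np.linalg.cond(m) > 1e8:
            raise ValueError("stain vectors are linearly dependent")
        self.matrix = m

    @property
    def chromogen(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def nuclear(self) -> np.ndarray:
        return self.matrix[:, 1]

    @property
    def residual(self) -> np.ndarray:
        return self.matrix[:, 2]

    @classmethod
    def from_stain_vectors(cls, chromogen: np.ndarray,
                           nuclear: np.ndarray) -> "StainMatrix":
        """Build from two stain hues; residual = normalized cross product."""
        c, n = _unit(np.asarray(chromogen, float)), _unit(np.asarray(nuclear, float))
        r = _unit(np.cross(c, n))
        return cls(np.column_stack([c, n, r]))


def default_stain_matrix() -> StainMatrix:
    """AEC chromogen over haematoxylin counterstain."""
    return StainMatrix.from_stain_vectors(AEC_OD, HEMATOXYLIN_OD)


def rgb_to_od(rgb: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Beer-Lambert: od = -log10(max(rgb, 1) / i0), elementwise.

    Clamping at 1 bounds the OD of a fully absorbing pixel and avoids
    log(0); white (i0) maps to exactly 0.
    """
    arr = np.asarray(rgb, dtype=float)
    return -np.log10(np.maximum(arr, 1.0) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped and quantized to uint8."""
    rgb = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def estimate_stain_matrix(thumbnail: np.ndarray,
                          od_floor: float = 0.15,
                          angle_percentile: float = 1.0,
                          reference_chromogen: np.ndarray = AEC_OD,
                          reference_nuclear: np.ndarray = HEMATOXYLIN_OD,
                          ) -> StainMatrix:
    """Estimate chromogen/nuclear/residual vectors from a slide thumbnail.

    Macenko-style: tissue pixels (OD norm above ``od_floor``) are projected
    onto the plane of the two leading principal OD directions; the stain
    vectors are the directions at the extreme (1%/99% by default)
    percentiles of the in-plane angle. Columns are ordered by matching
    against the reference hues.

    Raises ValueError when fewer than 100 tissue pixels are available.
    """
    od = rgb_to_od(thumbnail).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > od_floor]
    if len(tissue) < 100:
        raise ValueError(
            f"insufficient tissue: {len(tissue)} pixels above OD {od_floor}")
    # principal plane of the OD cloud
    _, _, vt = np.linalg.svd(tissue - 0, full_matrices=False)
    plane = vt[:2]  # 2x3
    if plane[0] @ tissue.mean(axis=0) < 0:
        plane[0] *= -1
    proj = tissue @ plane.T  # n x 2
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100 - angle_percentile)
    v1 = np.array([np.cos(lo), np.sin(lo)]) @ plane
    v2 = np.array([np.cos(hi), np.sin(hi)]) @ plane
    v1, v2 = _unit(v1), _unit(v2)
    for v in (v1, v2):  # absorbances are non-negative
        if v.sum() < 0:
            v *= -1
    ref_c, ref_n = _unit(reference_chromogen), _unit(reference_nuclear)
    # assign the recovered pair to chromogen/nuclear by total cosine match
    if abs(v1 @ ref_c) + abs(v2 @ ref_n) >= abs(v2 @ ref_c) + abs(v1 @ ref_n):
        chrom, nuc = v1, v2
    else:
        chrom, nuc = v2, v1
    return StainMatrix.from_stain_vectors(chrom, nuc)


def deconvolve_tile(tile: np.ndarray, m: StainMatrix, i0: float = 255.0
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an RGB tile into (chromogen, nuclear, residual) OD rasters.

    Per-pixel least-squares solve of ``od = M @ c``; negative concentrations
    are clipped to zero (no renormalization).
    """
    if np.linalg.cond(m.matrix) > 1e8:
        raise ValueError("singular stain matrix")
    od = rgb_to_od(tile, i0=i0).reshape(-1, 3)
    conc = np.linalg.solve(m.matrix, od.T).T  # exact LSQ for square full-rank M
    conc = np.clip(conc, 0.0, None)
    h, w = np.asarray(tile).shape[:2]
    conc = conc.reshape(h, w, 3)
    return conc[..., 0], conc[..., 1], conc[..., 2]
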