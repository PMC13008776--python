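"""Ground-truthed synthetic slides, fluorescence stacks and point patterns.

The renderer emulates the data model of iterative chromogenic staining:
white glass background, elliptical nuclei absorbing haematoxylin-like OD,
AEC-like chromogen in the cytoplasm ring of marker-positive cells,
anucleate RBC-like discs carrying residual colour, per-iteration random
affine + smooth elastic warps, per-iteration cell dropout, and Gaussian
pixel noise. Everything rendered is traceable: the ground truth stores
per-cell positions before and after each stain's warp (solved exactly from
the warp's backward map), per-stain survival, marker positivity and the
stain matrix used, so registration and segmentation error are measurable
in pixels against analytic truth rather than by image similarity alone.

It does not attempt photorealistic histology texture or scanner artefacts
beyond noise and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .deconvolution import EOSIN_OD, StainMatrix, default_stain_matrix, od_to_rgb


@dataclass
class WarpParams:
    """Backward map of one stain's image onto the reference frame.

    ``input = R(theta) @ (output - centre) + centre + shift + elastic(output)``
    where elastic is a separable sinusoid of the stated amplitude.
    """

    rot_deg: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)  # (dx, dy)
    elastic_amplitude: float = 0.0
    elastic_wavelength: float = 512.0
    elastic_phase: tuple[float, float] = (0.0, 0.0)
    centre: tuple[float, float] = (0.0, 0.0)

    def backward(self, x: np.ndarray, y: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Map output (warped-image) coords to input (reference) coords."""
        th = np.deg2rad(self.rot_deg)
        cx, cy = self.centre
        dx, dy = self.shift
        xr = np.cos(th) * (x - cx) - np.sin(th) * (y - cy) + cx + dx
        yr = np.sin(th) * (x - cx) + np.cos(th) * (y - cy) + cy + dy
        a, lam = self.elastic_amplitude, self.elastic_wavelength
        px, py = self.elastic_phase
        xr = xr + a * np.sin(2 * np.pi * y / lam + px)
        yr = yr + a * np.sin(2 * np.pi * x / lam + py)
        return xr, yr

    def forward_point(self, xin: float, yin: float,
                      tol: float = 1e-9, max_iter: int = 100
                      ) -> tuple[float, float]:
        """Where a reference point lands in the warped image.

        Solves backward(p) = (xin, yin) by damped fixed-point iteration;
        exact to ``tol`` because the warp is smooth and near-identity.
        """
        x, y = float(xin), float(yin)
        for _ in range(max_iter):
            bx, by = self.backward(np.array(x), np.array(y))
            ex, ey = float(bx) - xin, float(by) - yin
            if abs(ex) < tol and abs(ey) < tol:
                break
            x -= ex
            y -= ey
        return x, y


@dataclass
class GroundTruth:
    """Complete provenance for one rendered panel."""

    cells: pd.DataFrame
    warps: list[WarpParams]
    stain_matrix: StainMatrix
    mpp: float = 0.5
    params: dict = field(default_factory=dict)


def _place_cells(rng: np.random.Generator, n: int, shape: tuple[int, int],
                 min_sep: float, pad: float, max_tries_factor: int = 200
                 ) -> np.ndarray:
    """Random positions with pairwise separation >= min_sep (grid hashing)."""
    h, w = shape
    if w - 2 * pad <= 0 or h - 2 * pad <= 0:
        raise ValueError("image too small for requested padding")
    cell = min_sep / np.sqrt(2)
    gw, gh = int(w / cell) + 1, int(h / cell) + 1
    grid: dict[tuple[int, int], int] = {}
    pts: list[tuple[float, float]] = []
    tries = 0
    limit = max_tries_factor * n
    while len(pts) < n:
        tries += 1
        if tries > limit:
            raise ValueError(
                f"cannot place {n} cells with separation {min_sep:.1f} in "
                f"{w}x{h}; lower the density")
        x = rng.uniform(pad, w - pad)
        y = rng.uniform(pad, h - pad)
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for ix in range(gx - 2, gx + 3):
            for iy in range(gy - 2, gy + 3):
                j = grid.get((ix, iy))
                if j is not None and np.hypot(pts[j][0] - x,
                                              pts[j][1] - y) < min_sep:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            grid[(gx, gy)] = len(pts)
            pts.append((x, y))
    return np.asarray(pts)


def _paint_ellipse(canvas: np.ndarray, x: float, y: float, a: float, b: float,
                   angle: float, amplitude: float, ring: float = 0.0,
                   edge: float = 1.0) -> None:
    """Add a soft-edged filled ellipse (or annulus of width ``ring``)."""
    h, w = canvas.shape
    r_out = max(a, b) + ring + edge + 1
    x0, x1 = max(int(x - r_out), 0), min(int(x + r_out) + 2, w)
    y0, y1 = max(int(y - r_out), 0), min(int(y + r_out) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    if ring > 0:
        rho_in = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        rho_out = np.sqrt((u / (a + ring)) ** 2 + (v / (b + ring)) ** 2)
        profile = np.clip((1 - rho_out) / (edge / (a + ring)), 0, 1) \
            * np.clip((rho_in - 1) / (edge / a), 0, 1)
    else:
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        profile = np.clip((1 - rho) / (edge / a), 0, 1)
    canvas[y0:y1, x0:x1] += amplitude * profile


def render_micsss_panel(n_stains: int = 5,
                        n_cells: int = 500,
                        shape: tuple[int, int] = (2000, 2000),
                        positive_frac: float | list[float] = 0.2,
                        artifact_count: int = 20,
                        rbc_count: int = 0,
                        dropout_rate: float = 0.1,
                        warp_magnitude: float = 5.0,
                        affine_rot_deg: float = 1.0,
                        affine_shift_px: float = 6.0,
                        elastic_wavelength: float = 512.0,
                        noise_sd: float = 1.5,
                        mpp: float = 0.5,
                        radius_range: tuple[float, float] = (4.0, 6.5),
                        cytoplasm_px: float = 3.0,
                        tissue_od: float = 0.13,
                        stain_matrix: StainMatrix | None = None,
                        apply_warps: bool = True,
                        seed: int = 0,
                        ) -> tuple[list[np.ndarray], GroundTruth]:
    """Render one iteratively stained panel with complete ground truth.

    Returns one RGB uint8 raster per staining iteration (stain 0 is the
    unwarped reference) and the GroundTruth. ``positive_frac`` may be a
    scalar (shared by all markers) or one value per stain. ``rbc_count``
    anucleate discs and ``artifact_count`` single-stain blobs are added on
    top of ``n_cells`` true cells; dropout removes each true cell from
    each stain independently with the given rate, except that geometry is
    guaranteed in no particular stain.
    """
    if min(n_cells, artifact_count, rbc_count, n_stains) < 0 or n_stains == 0:
        raise ValueError("counts must be non-negative and n_stains >= 1")
    rng = np.random.default_rng(seed)
    m = stain_matrix or default_stain_matrix()
    h, w = shape
    pos_frac = (list(positive_frac) if np.ndim(positive_frac)
                else [float(positive_frac)] * n_stains)

    n_total = n_cells + rbc_count + artifact_count
    r_lo, r_hi = radius_range
    min_sep = 2 * (r_hi + cytoplasm_px) + 4
    pad = 2 * (affine_shift_px + warp_magnitude) + r_hi + 10
    pts = (_place_cells(rng, n_total, shape, min_sep, pad)
           if n_total else np.empty((0, 2)))

    rows = []
    for i in range(n_total):
        is_rbc = n_cells <= i < n_cells + rbc_count
        artifact_stain = -1
        if i >= n_cells + rbc_count:
            artifact_stain = int(rng.integers(0, n_stains))
        radius = float(rng.uniform(r_lo, r_hi))
        row = {
            "cell_id": i,
            "x": float(pts[i, 0]), "y": float(pts[i, 1]),
            "radius": radius,
            "ellipticity": float(rng.uniform(0.75, 1.0)),
            "angle": float(rng.uniform(0, np.pi)),
            # anucleate RBCs still pick up weak counterstain at their rim
            # plus a strong eosin-like hue (the classic false-nucleus trap)
            "nuclear_od": (float(rng.uniform(0.35, 0.45)) if is_rbc
                           else float(rng.uniform(0.55, 1.0))),
            "chromogen_od": float(rng.uniform(0.4, 0.8)),
            "residual_od": float(rng.uniform(0.8, 1.1)) if is_rbc else 0.0,
            "is_rbc": is_rbc,
            "artifact_stain": artifact_stain,
        }
        for s in range(n_stains):
            if artifact_stain >= 0:
                row[f"survives_{s}"] = (s == artifact_stain)
                row[f"positive_{s}"] = False
            else:
                row[f"survives_{s}"] = bool(rng.random() >= dropout_rate)
                row[f"positive_{s}"] = (not is_rbc
                                        and bool(rng.random() < pos_frac[s]))
        rows.append(row)
    cells = pd.DataFrame(rows) if rows else _empty_truth_frame(n_stains)

    warps = [WarpParams(centre=(w / 2, h / 2))]  # stain 0: identity
    for s in range(1, n_stains):
        if apply_warps:
            warps.append(WarpParams(
                rot_deg=float(rng.uniform(-affine_rot_deg, affine_rot_deg)),
                shift=(float(rng.uniform(-affine_shift_px, affine_shift_px)),
                       float(rng.uniform(-affine_shift_px, affine_shift_px))),
                elastic_amplitude=float(rng.uniform(0.5, 1.0)) * warp_magnitude,
                elastic_wavelength=elastic_wavelength,
                elastic_phase=(float(rng.uniform(0, 2 * np.pi)),
                               float(rng.uniform(0, 2 * np.pi))),
                centre=(w / 2, h / 2)))
        else:
            warps.append(WarpParams(centre=(w / 2, h / 2)))

    # faint stain wash over the tissue footprint: distinguishes tissue from
    # bare glass (the masking signal) without obscuring nuclei
    tissue = _tissue_wash(shape, margin=pad * 0.4, edge=8.0)

    rasters = []
    for s in range(n_stains):
        chrom = np.zeros(shape, dtype=float)
        nuc = tissue * tissue_od
        eos = np.zeros(shape, dtype=float)
        for row in rows:
            if not row[f"survives_{s}"]:
                continue
            a = row["radius"]
            b = a * row["ellipticity"]
            if row["is_rbc"]:
                _paint_ellipse(eos, row["x"], row["y"], a, b, row["angle"],
                               row["residual_od"])
                _paint_ellipse(nuc, row["x"], row["y"], a, b, row["angle"],
                               row["nuclear_od"])
            else:
                _paint_ellipse(nuc, row["x"], row["y"], a, b, row["angle"],
                               row["nuclear_od"])
                if row[f"positive_{s}"]:
                    _paint_ellipse(chrom, row["x"], row["y"], a, b,
                                   row["angle"], row["chromogen_od"],
                                   ring=cytoplasm_px)
        eosin = EOSIN_OD / np.linalg.norm(EOSIN_OD)
        od = (chrom[..., None] * m.chromogen
              + nuc[..., None] * m.nuclear
              + eos[..., None] * eosin)
        rgb = od_to_rgb(od).astype(float)
        if s > 0 and apply_warps:
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            bx, by = warps[s].backward(xx, yy)
            warped = np.empty_like(rgb)
            for ch in range(3):
                warped[..., ch] = ndimage.map_coordinates(
                    rgb[..., ch], [by, bx], order=1, mode="constant",
                    cval=255.0)
            rgb = warped
        if noise_sd > 0:
            rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
        rasters.append(np.clip(np.round(rgb), 0, 255).astype(np.uint8))

    # post-warp positions, solved from each stain's backward map
    for s in range(n_stains):
        if len(cells) == 0:
            cells[f"x_warp_{s}"] = []
            cells[f"y_warp_{s}"] = []
            continue
        if warps[s].rot_deg == 0 and warps[s].shift == (0.0, 0.0) \
                and warps[s].elastic_amplitude == 0:
            cells[f"x_warp_{s}"] = cells["x"]
            cells[f"y_warp_{s}"] = cells["y"]
        else:
            fw = [warps[s].forward_point(x, y)
                  for x, y in zip(cells["x"], cells["y"])]
            cells[f"x_warp_{s}"] = [p[0] for p in fw]
            cells[f"y_warp_{s}"] = [p[1] for p in fw]

    truth = GroundTruth(cells=cells, warps=warps, stain_matrix=m, mpp=mpp,
                        params={"n_stains": n_stains, "n_cells": n_cells,
                                "dropout_rate": dropout_rate,
                                "warp_magnitude": warp_magnitude,
                                "seed": seed})
    return rasters, truth


def warp_raster(raster: np.ndarray, warp: WarpParams,
                fill: float = 255.0) -> np.ndarray:
    """Apply a warp's backward map to an image (linear interpolation)."""
    h, w = raster.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    bx, by = warp.backward(xx, yy)
    if raster.ndim == 2:
        return ndimage.map_coordinates(raster.astype(float), [by, bx],
                                       order=1, mode="constant", cval=fill
                                       ).astype(raster.dtype)
    out = np.empty_like(raster)
    for ch in range(raster.shape[2]):
        out[..., ch] = ndimage.map_coordinates(
            raster[..., ch].astype(float), [by, bx], order=1,
            mode="constant", cval=fill).astype(raster.dtype)
    return out


def _tissue_wash(shape: tuple[int, int], margin: float,
                 edge: float = 8.0) -> np.ndarray:
    """Soft-edged rectangular tissue footprint in [0, 1]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.minimum.reduce([xx - margin, w - margin - xx,
                           yy - margin, h - margin - yy])
    return np.clip(d / edge, 0.0, 1.0)


def _empty_truth_frame(n_stains: int) -> pd.DataFrame:
    cols = ["cell_id", "x", "y", "radius", "ellipticity", "angle",
            "nuclear_od", "chromogen_od", "residual_od", "is_rbc",
            "artifact_stain"]
    for s in range(n_stains):
        cols += [f"survives_{s}", f"positive_{s}"]
    return pd.DataFrame(columns=cols)


def render_if_stack(n_channels: int = 4,
                    n_cells: int = 200,
                    shape: tuple[int, int] = (1000, 1000),
                    positive_frac: float | list[float] = 0.2,
                    noise_sd: float = 0.01,
                    radius_range: tuple[float, float] = (4.0, 6.5),
                    seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Render a pre-aligned fluorescence stack (channel 0 = nuclear).

    Fluorescence is additive (dark background, bright signal) and needs no
    deconvolution or registration; each marker channel m >= 1 lights the
    cytoplasm ring of its positive cells.
    """
    if n_channels < 1:
        raise ValueError("need at least the nuclear channel")
    rng = np.random.default_rng(seed)
    h, w = shape
    r_lo, r_hi = radius_range
    pts = (_place_cells(rng, n_cells, shape, 2 * (r_hi + 3) + 4, r_hi + 8)
           if n_cells else np.empty((0, 2)))
    pos_frac = (list(positive_frac) if np.ndim(positive_frac)
                else [float(positive_frac)] * max(n_channels - 1, 1))
    rows = []
    stack = np.zeros((h, w, n_channels), dtype=np.float32)
    for i in range(n_cells):
        a = float(rng.uniform(r_lo, r_hi))
        row = {"cell_id": i, "x": float(pts[i, 0]), "y": float(pts[i, 1]),
               "radius": a, "ellipticity": float(rng.uniform(0.75, 1.0)),
               "angle": float(rng.uniform(0, np.pi)),
               "nuclear_od": float(rng.uniform(0.5, 1.0)),
               "is_rbc": False, "artifact_stain": -1}
        for ch in range(1, n_channels):
            row[f"positive_{ch}"] = bool(rng.random() < pos_frac[ch - 1])
        rows.append(row)
        b = a * row["ellipticity"]
        _paint_ellipse(stack[..., 0], row["x"], row["y"], a, b, row["angle"],
                       row["nuclear_od"])
        for ch in range(1, n_channels):
            if row[f"positive_{ch}"]:
                _paint_ellipse(stack[..., ch], row["x"], row["y"], a, b,
                               row["angle"], float(rng.uniform(0.4, 0.8)),
                               ring=3.0)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape).astype(np.float32)
        stack = np.clip(stack, 0.0, None)
    cells = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["cell_id", "x", "y"])
    truth = GroundTruth(cells=cells, warps=[WarpParams()] * 1,
                        stain_matrix=default_stain_matrix(),
                        params={"kind": "if", "n_channels": n_channels,
                                "seed": seed})
    return stack, truth


def sample_point_pattern(kind: str, n: int, seed: int = 0,
                         d: float = 20.0, spacing: float = 25.0,
                         extent: float = 1000.0,
                         n_clusters: int = 5,
                         cluster_sd: float = 15.0) -> dict[str, np.ndarray]:
    """Labelled point sets with analytically known NN structure.

    kinds: ``paired`` — A points far apart, each with one B partner at
    exact distance ``d`` (so every A->B nearest-neighbour distance is d);
    ``regular`` — a square grid with spacing ``spacing`` (all same-set NN
    distances equal spacing); ``clustered`` — Gaussian clumps.
    """
    if n < 2:
        raise ValueError("need n >= 2 points")
    rng = np.random.default_rng(seed)
    if kind == "paired":
        n_a = n // 2
        a = _place_cells(rng, n_a, (int(extent), int(extent)),
                         min_sep=3.0 * d, pad=d + 2)
        angles = rng.uniform(0, 2 * np.pi, n_a)
        b = a + d * np.column_stack([np.cos(angles), np.sin(angles)])
        return {"A": a, "B": b}
    if kind == "regular":
        side = int(np.ceil(np.sqrt(n)))
        xs, ys = np.meshgrid(np.arange(side) * spacing,
                             np.arange(side) * spacing)
        pts = np.column_stack([xs.ravel(), ys.ravel()])[:n]
        return {"A": pts.astype(float)}
    if kind == "clustered":
        centres = rng.uniform(5 * cluster_sd, extent - 5 * cluster_sd,
                              (n_clusters, 2))
        which = rng.integers(0, n_clusters, n)
        pts = centres[which] + rng.normal(0, cluster_sd, (n, 2))
        return {"A": pts}
    raise ValueError(f"unknown pattern kind {kind!r}")
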