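"""Placido ring extraction: LAB color mask, cleanup, center, labels, sector radii.

The reflected rings are segmented by thresholding the enhanced image in CIELAB
around the reference ring color, binarized, labeled from the innermost ring
outward, and measured as mean radial distance from the corneal center in 24
half-open sectors of 15 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .geometry import polar_grid, sector_centers, sector_index


@dataclass(frozen=True)
class ColorMaskSpec:
    """Reference CIELAB ring color and band widths for the mask.

    L and a use a +/- k_sd * SD band around the reference mean; the b channel
    has no measured SD and uses a fixed tolerance instead.
    """

    mean_L: float = 50.449
    sd_L: float = 3.8
    mean_a: float = 73.090
    sd_a: float = 4.6
    mean_b: float = 51.361
    tol_b: float = 10.0
    k_sd: float = 2.0

    def __post_init__(self):
        if min(self.sd_L, self.sd_a, self.tol_b, self.k_sd) <= 0:
            raise ValueError("band widths must be positive")


@dataclass
class RingLabels:
    """Labeled ring raster: index 1..K by increasing mean radial distance."""

    labels: np.ndarray  # int raster, 0 = background
    center: tuple[float, float]  # (x, y) px
    mean_radii: np.ndarray  # (K,) mean radial distance per ring, increasing

    @property
    def n_rings(self) -> int:
        return len(self.mean_radii)


def lab_color_mask(lab: np.ndarray, spec: ColorMaskSpec | None = None) -> np.ndarray:
    """Binary mask of pixels within the LAB color band of the rings."""
    spec = spec or ColorMaskSpec()
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    return (
        (np.abs(L - spec.mean_L) <= spec.k_sd * spec.sd_L)
        & (np.abs(a - spec.mean_a) <= spec.k_sd * spec.sd_a)
        & (np.abs(b - spec.mean_b) <= spec.tol_b)
    )


def clean_mask(mask: np.ndarray, min_component_px: int = 25) -> np.ndarray:
    """Morphological closing (3x3) then removal of components below size."""
    closed = morphology.closing(mask.astype(bool), footprint=np.ones((3, 3), dtype=bool))
    lbl, n = ndimage.label(closed, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return closed
    sizes = np.bincount(lbl.ravel())
    keep = sizes >= min_component_px
    keep[0] = False
    return keep[lbl]


def find_center(mask: np.ndarray) -> tuple[float, float]:
    """Corneal center: centroid of the innermost connected component.

    "Innermost" is judged by mean radial distance about the global mask
    centroid; with a single component its own centroid is returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no rings found: empty mask")
    lbl, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    ys, xs = np.nonzero(mask)
    gx, gy = xs.mean(), ys.mean()
    if n == 1:
        return (gx, gy)
    best = None
    for comp in range(1, n + 1):
        cy, cx = np.nonzero(lbl == comp)
        mean_r = np.hypot(cx - gx, cy - gy).mean()
        if best is None or mean_r < best[0]:
            best = (mean_r, cx.mean(), cy.mean())
    return (best[1], best[2])


def refine_center(
    mask: np.ndarray,
    center0: tuple[float, float],
    n_iter: int = 4,
    n_sectors: int = 24,
) -> tuple[float, float]:
    """Sharpen a center estimate by joint decentering/cone regression.

    A decentering offset shifts the measured radius of *every* ring by the
    same first-harmonic cosine pattern, whereas a keratoconic cone scales
    the rings it crosses down by a smooth Gaussian factor of position on the
    corneal plane.  Both patterns are fit jointly to the sector radii,

        rho_k(theta) = R_k * (1 - A exp(-|x_k(theta) - c|^2 / 2 sigma^2))
                       + a cos(theta) + b sin(theta),

    with per-ring baselines R_k, cone amplitude A >= 0, cone position c and
    width sigma, and the residual center offset (a, b).  Residuals are
    weighted by 1/R_k since radius jitter grows with ring size; modelling
    the cone explicitly keeps it from masquerading as decentering.
    """
    from scipy.optimize import least_squares

    theta = np.radians(sector_centers(n_sectors))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # the data are sector means, so the cone term is averaged over sub-angles
    n_sub = 5
    width = 2.0 * np.pi / n_sectors
    sub = theta[:, None] + (np.arange(n_sub) + 0.5) / n_sub * width - width / 2.0
    cos_sub, sin_sub = np.cos(sub), np.sin(sub)
    center = center0
    for _ in range(n_iter):
        labels = label_rings(mask, center)
        rho_map = measure_radii(labels, n_sectors)
        ok = np.isfinite(rho_map)
        rows = np.flatnonzero(ok.sum(axis=1) >= 12)
        if rows.size == 0:
            break
        R0 = np.nanmedian(rho_map[rows], axis=1)
        k_idx, s_idx = np.nonzero(ok[rows])
        rho = rho_map[rows][k_idx, s_idx]
        base = R0[k_idx]
        w = 1.0 / base
        r_max = float(R0.max())

        i_min = int(np.argmin(rho / base))
        p0 = np.concatenate([
            R0,
            [max(1.0 - (rho / base).min(), 1e-3),
             base[i_min] * cos_t[s_idx[i_min]], base[i_min] * sin_t[s_idx[i_min]],
             0.4 * r_max, 0.0, 0.0],
        ])
        n_r = rows.size

        def resid(p):
            R_k = p[:n_r]
            amp, cx, cy, sigma, a, b = p[n_r:]
            # cone footprint on the corneal plane, at the undistorted radii
            Rb = R_k[k_idx][:, None]
            pxs = Rb * cos_sub[s_idx]
            pys = Rb * sin_sub[s_idx]
            cone = amp * np.exp(
                -((pxs - cx) ** 2 + (pys - cy) ** 2) / (2.0 * sigma**2)
            ).mean(axis=1)
            model = R_k[k_idx] * (1.0 - cone) + a * cos_t[s_idx] + b * sin_t[s_idx]
            return w * (model - rho)

        lo = np.concatenate([np.full(n_r, 1.0),
                             [0.0, -r_max, -r_max, 0.05 * r_max, -r_max, -r_max]])
        hi = np.concatenate([np.full(n_r, 10.0 * r_max),
                             [0.6, r_max, r_max, 2.0 * r_max, r_max, r_max]])
        sol = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi), max_nfev=200)
        a, b = sol.x[-2:]
        # direction theta corresponds to pixel displacement (cos, -sin)
        center = (center[0] + a, center[1] - b)
        if np.hypot(a, b) < 0.01:
            break
    return center


def label_rings(mask: np.ndarray, center: tuple[float, float]) -> RingLabels:
    """Order connected components by mean radial distance from ``center``."""
    mask = np.asarray(mask, dtype=bool)
    lbl, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no rings found: empty mask")
    dist, _ = polar_grid(mask.shape, center)
    mean_r = ndimage.mean(dist, labels=lbl, index=np.arange(1, n + 1))
    order = np.argsort(mean_r)
    sorted_r = mean_r[order]
    if n > 1 and np.min(np.diff(sorted_r)) < 2.0:
        raise ValueError("rings merged: two components with mean radii differing < 2 px")
    remap = np.zeros(n + 1, dtype=int)
    remap[1 + order] = np.arange(1, n + 1)
    return RingLabels(labels=remap[lbl], center=center, mean_radii=sorted_r)


def measure_radii(ring_labels: RingLabels, n_sectors: int = 24) -> np.ndarray:
    """(K, n_sectors) matrix of mean radial pixel distance per ring and sector.

    Sector s covers angles [360/n * s, 360/n * (s+1)); entries with no pixels
    are NaN.

    Entries estimate the stroke mid-line radius: the raw pixel mean m of an
    annulus sector overshoots the mid-line by (t²/12 + Var_θ(ρ))/ρ — pixel
    density grows with radius — which equals the per-sector pixel-radius
    variance s² divided by m, so m − s²/m removes the bias to second order.
    """
    if 360 % n_sectors != 0:
        raise ValueError("n_sectors must divide 360")
    lbl = ring_labels.labels
    K = ring_labels.n_rings
    dist, theta = polar_grid(lbl.shape, ring_labels.center)
    on = lbl > 0
    sec = sector_index(theta[on], n_sectors)
    ring = lbl[on] - 1
    flat = ring * n_sectors + sec
    sums = np.bincount(flat, weights=dist[on], minlength=K * n_sectors)
    sq_sums = np.bincount(flat, weights=dist[on] ** 2, minlength=K * n_sectors)
    counts = np.bincount(flat, minlength=K * n_sectors)
    with np.errstate(invalid="ignore"):
        m = sums / counts
        var = sq_sums / counts - m**2
        out = m - np.maximum(var, 0.0) / m
    return out.reshape(K, n_sectors)


def radius_map_frame(radius_map: np.ndarray) -> pd.DataFrame:
    """RadiusMap as a DataFrame: rows = rings, columns = sector center angles."""
    k, s = radius_map.shape
    cols = [f"{c:.1f}" for c in sector_centers(s)]
    return pd.DataFrame(radius_map, index=np.arange(1, k + 1), columns=cols)


def extract_radius_map(
    lab: np.ndarray,
    mask_spec: ColorMaskSpec | None = None,
    min_component_px: int = 25,
    n_sectors: int = 24,
) -> tuple[np.ndarray, RingLabels]:
    """Mask → clean → center (+ harmonic refinement) → label → measure."""
    mask = clean_mask(lab_color_mask(lab, mask_spec), min_component_px)
    center = refine_center(mask, find_center(mask), n_sectors=n_sectors)
    labels = label_rings(mask, center)
    return measure_radii(labels, n_sectors), labels
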