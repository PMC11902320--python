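"""Corneal topography: curvature calibration, keratometric diopters, elevation.

The keratometric equation converts a local radius of curvature r (in meters)
into corneal power D = (n − 1)/r with the standardized keratometric index
n = 1.3375; with r in millimeters this is the familiar Φ = 337.5 / r.
Measured ring radii are mapped to local curvature by the proportional convex-
mirror model shared with the phantom generator: a ring reflected at the radius
it would have on the reference cornea (r_ref = 7.85 mm) implies r_c = r_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import sector_centers

KERATOMETRIC_INDEX = 1.3375
KERATOMETRIC_CONSTANT = 337.5  # (n - 1) * 1000, for r in mm
R_REF_MM = 7.85


@dataclass(frozen=True)
class CalibrationSpec:
    """Pixel scale and reference geometry linking ring radii to curvature."""

    mm_per_pixel: float | None = None
    r_ref: float = R_REF_MM
    ring_radii_ref: tuple[float, ...] = tuple(np.linspace(1.0, 5.0, 9))
    n: float = KERATOMETRIC_INDEX

    def __post_init__(self):
        if self.mm_per_pixel is not None and self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.r_ref <= 0:
            raise ValueError("r_ref must be positive")
        r = np.asarray(self.ring_radii_ref)
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("ring_radii_ref must be positive and strictly increasing")
        if self.n <= 1:
            raise ValueError("refractive index must exceed 1")


def calibrate_radii(radius_map_px: np.ndarray, calib: CalibrationSpec) -> np.ndarray:
    """Local radius of curvature r_c (mm) from measured ring radii (px).

    r_c(k, s) = r_ref * (radius_px * mm_per_pixel) / ring_radii_ref[k].
    NaN (absent) entries propagate.
    """
    if calib.mm_per_pixel is None:
        raise ValueError("calibration required: mm_per_pixel is unset")
    radius_map_px = np.asarray(radius_map_px, dtype=float)
    k = radius_map_px.shape[0]
    if k > len(calib.ring_radii_ref):
        raise ValueError("more rings measured than reference radii provided")
    refs = np.asarray(calib.ring_radii_ref[:k])[:, None]
    return calib.r_ref * (radius_map_px * calib.mm_per_pixel) / refs


def keratometric_power(r_mm):
    """Corneal power Φ = 337.5 / r (r in mm), i.e. (n − 1)/r with r in meters."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r[np.isfinite(r)] <= 0):
        raise ValueError("radius of curvature must be positive")
    out = KERATOMETRIC_CONSTANT / r
    return float(out) if np.isscalar(r_mm) else out


def diopter_map(r_mm_map: np.ndarray) -> np.ndarray:
    """Elementwise keratometric power; Φ · r = 337.5 on every present entry."""
    return keratometric_power(r_mm_map)


def elevation_map(r_mm_map: np.ndarray, rho_mm_map: np.ndarray) -> np.ndarray:
    """Spherical sag above the apex plane: z = r − sqrt(r² − ρ²).

    ``rho_mm_map`` holds the corneal-plane distances (calibrated ring
    distances) at which the local radius applies.
    """
    r = np.asarray(r_mm_map, dtype=float)
    rho = np.asarray(rho_mm_map, dtype=float)
    present = np.isfinite(r) & np.isfinite(rho)
    if np.any(rho[present] >= r[present]):
        raise ValueError("radius smaller than chord: rho must be < r")
    with np.errstate(invalid="ignore"):
        return r - np.sqrt(r**2 - rho**2)


@dataclass
class ConeFit:
    """Least-squares Gaussian-cone decomposition of a curvature map."""

    base_radius_mm: float
    amplitude_mm: float
    center: tuple[float, float]  # (eccentricity mm, angle deg)
    sigma_mm: float
    residual_rms: float


def fit_cone(r_mm_map: np.ndarray, calib: CalibrationSpec) -> ConeFit:
    """Fit r_c(x) = base − amp·exp(−|x − c|²/2σ²) over the ring/sector grid.

    Pooling all grid entries makes the amplitude estimate robust to per-entry
    measurement noise, unlike the raw map minimum.
    """
    r = np.asarray(r_mm_map, dtype=float)
    k, s = r.shape
    rho = np.asarray(calib.ring_radii_ref[:k])[:, None]
    theta = np.radians(sector_centers(s))[None, :]
    x = (rho * np.cos(theta)).ravel()
    y = (rho * np.sin(theta)).ravel()
    z = r.ravel()
    ok = np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]

    base0 = float(np.median(z))
    i0 = int(np.argmin(z))
    p0 = [base0, max(base0 - z.min(), 1e-3), x[i0], y[i0], 1.5]

    def resid(p):
        base, amp, cx, cy, sigma = p
        return base - amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2)) - z

    sol = least_squares(
        resid,
        p0,
        bounds=([1.0, 0.0, -6.0, -6.0, 0.3], [20.0, 15.0, 6.0, 6.0, 5.0]),
    )
    base, amp, cx, cy, sigma = sol.x
    ecc = float(np.hypot(cx, cy))
    ang = float(np.degrees(np.arctan2(cy, cx)) % 360.0)
    return ConeFit(
        base_radius_mm=float(base),
        amplitude_mm=float(amp),
        center=(ecc, ang),
        sigma_mm=float(sigma),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def render_heatmap(diopter_map_: np.ndarray, path) -> None:
    """Diopter heat map PNG; warm colors mark steeper (higher-power) regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k, s = diopter_map_.shape
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(diopter_map_, aspect="auto", cmap="jet", origin="lower")
    ax.set_xlabel("sector center angle (deg)")
    ax.set_ylabel("ring index")
    ax.set_xticks(np.arange(s)[::4])
    ax.set_xticklabels([f"{c:.0f}" for c in sector_centers(s)[::4]])
    ax.set_yticks(np.arange(k))
    ax.set_yticklabels(np.arange(1, k + 1))
    fig.colorbar(im, ax=ax, label="corneal power (D)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
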