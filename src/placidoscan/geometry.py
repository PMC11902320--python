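"""Shared pixel/polar geometry conventions.

Coordinates are 0-based pixel indices with the origin at the top-left corner.
Angles are measured counterclockwise from the image +x axis as the image is
*displayed* (i.e. with the y axis pointing down in memory, a positive angle
sweeps from "east" through "north").  Sectors are half-open intervals
[w*s, w*(s+1)) of width w = 360/n_sectors degrees.
"""

from __future__ import annotations

import numpy as np


def polar_grid(shape: tuple[int, int], center: tuple[float, float]):
    """Per-pixel radius (px) and angle (deg in [0, 360)) about ``center``.

    Parameters
    ----------
    shape : (height, width) of the raster.
    center : (x, y) pixel coordinates of the pole.
    """
    h, w = shape
    yy, xx = np.indices((h, w), dtype=float)
    dx = xx - center[0]
    dy = yy - center[1]
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(-dy, dx)) % 360.0
    return radius, angle


def sector_centers(n_sectors: int = 24) -> np.ndarray:
    """Center angle (deg) of each half-open sector."""
    width = 360.0 / n_sectors
    return (np.arange(n_sectors) + 0.5) * width


def sector_index(angle_deg: np.ndarray, n_sectors: int = 24) -> np.ndarray:
    """Sector each angle falls in; every angle belongs to exactly one sector."""
    width = 360.0 / n_sectors
    idx = np.floor((np.asarray(angle_deg) % 360.0) / width).astype(int)
    # guard against angle == 360.0 - eps rounding up
    return np.clip(idx, 0, n_sectors - 1)


def periodic_interp(angle_deg: np.ndarray, node_values: np.ndarray) -> np.ndarray:
    """Linear interpolation of values given at sector centers, periodic in angle."""
    n = len(node_values)
    centers = sector_centers(n)
    xp = np.concatenate([centers, centers[:1] + 360.0])
    fp = np.concatenate([node_values, node_values[:1]])
    t = (np.asarray(angle_deg) - centers[0]) % 360.0 + centers[0]
    return np.interp(t, xp, fp)
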