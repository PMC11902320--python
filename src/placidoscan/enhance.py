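"""Low-light image enhancement: median denoising and invert–dehaze–invert in CIELAB.

The haze image-formation model is I(x) = J(x)·r(x) + A·(1 − r(x)), where A is
the ambient (air) light and r(x) the per-pixel transmission.  Dehazing inverts
it as J(x) = (I(x) − A) / max(r(x), r0) + A.  For dim photographs the model is
applied to the *inverted* image (a dark scene inverts to a hazy-looking bright
one), which is the purpose of the L-channel inversion bracketing the dehaze
step.  A and r(x) are estimated with the dark-channel prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import lab2rgb, rgb2lab


@dataclass(frozen=True)
class HazeParams:
    """Parameters of the enhancement chain (all intensities on a [0, 1] scale)."""

    r0: float = 0.1  # transmission floor
    dark_channel_window: int = 15
    airlight_percentile: float = 0.001  # fraction of brightest dark-channel pixels
    omega: float = 0.95  # haze retention factor
    saturation_factor: float = 1.2
    median_kernel: int = 3

    def __post_init__(self):
        if not (0 < self.r0 < 1):
            raise ValueError("r0 must lie in (0, 1)")
        if self.dark_channel_window < 3 or self.dark_channel_window % 2 == 0:
            raise ValueError("dark_channel_window must be odd and >= 3")
        if not (0 < self.airlight_percentile <= 1):
            raise ValueError("airlight_percentile must lie in (0, 1]")
        if not (0 <= self.omega <= 1):
            raise ValueError("omega must lie in [0, 1]")
        if self.saturation_factor < 1:
            raise ValueError("saturation_factor must be >= 1")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")


def _as_float(image: np.ndarray) -> tuple[np.ndarray, bool]:
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0, True
    return np.asarray(image, dtype=float), False


def median_denoise(image: np.ndarray, median_kernel: int = 3) -> np.ndarray:
    """Per-channel median filter; a kernel of 1 is the identity."""
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median_kernel must be odd and >= 1")
    if median_kernel == 1:
        return image.copy()
    if image.ndim == 2:
        return ndimage.median_filter(image, size=median_kernel)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.median_filter(image[..., c], size=median_kernel)
    return out


def color_convert(image: np.ndarray, direction: str) -> np.ndarray:
    """Standard sRGB (D65) <-> CIELAB conversion.

    RGB input may be uint8 or float in [0, 1]; LAB is always float with
    L in [0, 100] and a, b roughly in [-128, 127].
    """
    if direction == "rgb2lab":
        rgb, _ = _as_float(image)
        return rgb2lab(np.clip(rgb, 0.0, 1.0))
    if direction == "lab2rgb":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # out-of-gamut values are clipped
            return np.clip(lab2rgb(image), 0.0, 1.0)
    raise ValueError(f"unknown direction {direction!r}; expected 'rgb2lab' or 'lab2rgb'")


def invert_lab(lab: np.ndarray) -> np.ndarray:
    """L <- 100 - L; chroma untouched so hue is preserved.  An involution."""
    out = lab.copy()
    out[..., 0] = 100.0 - out[..., 0]
    return out


def _dark_channel(rgb: np.ndarray, window: int) -> np.ndarray:
    return ndimage.minimum_filter(rgb.min(axis=2), size=window)


def estimate_haze(image: np.ndarray, params: HazeParams) -> tuple[np.ndarray, np.ndarray]:
    """Dark-channel-prior estimates of the airlight A and transmission map r(x).

    A is the mean color of the brightest ``airlight_percentile`` fraction of
    pixels ranked by dark channel; r(x) = 1 − ω · darkchannel(I/A)(x).
    """
    rgb, _ = _as_float(image)
    if rgb.max() <= 0:
        raise ValueError("cannot estimate airlight from an all-black image")
    dark = _dark_channel(rgb, params.dark_channel_window)
    n = max(1, int(round(params.airlight_percentile * dark.size)))
    idx = np.argpartition(dark.ravel(), -n)[-n:]
    A = rgb.reshape(-1, 3)[idx].mean(axis=0)
    A = np.maximum(A, 1e-6)
    norm_dark = _dark_channel(rgb / A, params.dark_channel_window)
    r_map = 1.0 - params.omega * norm_dark
    return A, np.clip(r_map, 1e-6, 1.0)


def dehaze_apply(image: np.ndarray, A: np.ndarray, r_map: np.ndarray, r0: float = 0.1) -> np.ndarray:
    """Recover the scene: J(x) = (I(x) − A) / max(r(x), r0) + A, clipped to [0, 1]."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    rgb, was_uint8 = _as_float(image)
    denom = np.maximum(np.asarray(r_map, dtype=float), r0)
    J = (rgb - A) / denom[..., None] + A
    J = np.clip(J, 0.0, 1.0)
    return (J * 255).round().astype(np.uint8) if was_uint8 else J


def boost_saturation(lab: np.ndarray, saturation_factor: float) -> np.ndarray:
    """Scale the a/b chroma channels; L is untouched."""
    if saturation_factor < 1:
        raise ValueError("saturation_factor must be >= 1")
    out = lab.copy()
    out[..., 1:] = np.clip(out[..., 1:] * saturation_factor, -128.0, 127.0)
    return out


def enhance(image: np.ndarray, params: HazeParams | None = None) -> np.ndarray:
    """Full chain: median → LAB → invert → dehaze (in RGB of the inverted
    image) → saturation boost → invert back → RGB.

    Returns the same dtype as the input (uint8 in, uint8 out).
    """
    params = params or HazeParams()
    rgb, was_uint8 = _as_float(image)
    rgb = median_denoise(rgb, params.median_kernel)
    lab = color_convert(rgb, "rgb2lab")
    lab_inv = invert_lab(lab)
    rgb_inv = color_convert(lab_inv, "lab2rgb")
    A, r_map = estimate_haze(rgb_inv, params)
    rgb_dehazed = dehaze_apply(rgb_inv, A, r_map, params.r0)
    lab_out = color_convert(rgb_dehazed, "rgb2lab")
    lab_out = boost_saturation(lab_out, params.saturation_factor)
    lab_out = invert_lab(lab_out)
    out = color_convert(lab_out, "lab2rgb")
    return (out * 255).round().astype(np.uint8) if was_uint8 else out


def rms_contrast(image: np.ndarray) -> float:
    """RMS contrast of the luminance (L channel) — used as the enhancement metric."""
    lab = color_convert(image, "rgb2lab") if image.ndim == 3 else image
    L = lab[..., 0] if image.ndim == 3 else image
    return float(np.std(L))
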