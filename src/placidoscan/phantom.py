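"""Synthetic corneal phantoms with reflected Placido-ring patterns.

The generator plays the role of the physical eye-model photographs used to
develop smartphone videokeratoscopy: a pattern of concentric bright rings is
"reflected" off a parametric cornea and rasterized together with a plain
iris/sclera background, illumination scaling and measurement noise.

The cornea is modelled as a convex mirror whose local radius of curvature
r_c(ρ, θ) is uniform for a healthy eye and locally reduced by a Gaussian cone
for keratoconus.  The reflected radius of ring k at azimuth θ follows the
proportional mirror model

    ρ_k(θ) = ring_radii_ref[k] · r_c(θ) / r_ref,        r_ref = 7.85 mm,

so a steeper cornea (smaller r_c) pulls the reflected rings inward.  The
reference radius is chosen so the keratometric power of a healthy cornea is
337.5 / 7.85 ≈ 43 D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import periodic_interp, polar_grid, sector_centers

#: Reference (healthy) corneal radius of curvature in mm.
R_REF_MM = 7.85

#: Cone amplitude (mm of local radius reduction) for each disease stage.
STAGE_AMPLITUDES_MM = {0: 0.0, 1: 0.5, 2: 1.0, 3: 1.8, 4: 2.8}

HEALTHY, DISEASED = "healthy", "diseased"


def _lab_to_rgb_triple(lab: tuple[float, float, float]) -> tuple[float, float, float]:
    from skimage.color import lab2rgb

    arr = lab2rgb(np.asarray(lab, dtype=float).reshape(1, 1, 3))[0, 0]
    return tuple(float(v) for v in np.clip(arr, 0.0, 1.0))


# Source color of the rendered ring stroke.  The extraction mask references
# the ring color as it appears *after* the enhancement chain (whose dehaze and
# saturation stages deepen red hues), so the source color is calibrated such
# that a well-lit phantom's rings land on the reference CIELAB ring color of
# the mask once enhanced.
DEFAULT_RING_LAB = (38.5, 42.8, 18.7)
DEFAULT_RING_RGB = _lab_to_rgb_triple(DEFAULT_RING_LAB)


@dataclass(frozen=True)
class PlacidoSpec:
    """Geometry and colors of the projected ring pattern."""

    n_rings: int = 9
    #: mid-radius of each ring as reflected by the *reference* cornea, in mm
    ring_radii_ref: tuple[float, ...] = None  # type: ignore[assignment]
    thickness_mm: float = 0.2
    ring_color: tuple[float, float, float] = DEFAULT_RING_RGB
    background_color: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.ring_radii_ref is None:
            radii = tuple(np.linspace(1.0, 5.0, self.n_rings))
            object.__setattr__(self, "ring_radii_ref", radii)
        else:
            object.__setattr__(self, "ring_radii_ref", tuple(float(r) for r in self.ring_radii_ref))
        self.validate()

    def validate(self) -> None:
        r = np.asarray(self.ring_radii_ref, dtype=float)
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if len(r) != self.n_rings:
            raise ValueError("ring_radii_ref length must equal n_rings")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("ring_radii_ref must be strictly increasing and positive")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if self.n_rings > 1 and np.min(np.diff(r)) <= self.thickness_mm:
            raise ValueError("adjacent rings overlap: gap must exceed thickness")


@dataclass(frozen=True)
class CorneaProfile:
    """Parametric anterior corneal surface: uniform dome plus optional cone.

    ``cone_center`` is the polar position (eccentricity mm, angle deg) of the
    cone apex on the corneal plane; ``cone_amplitude_mm`` is the reduction of
    the local radius of curvature at the apex.
    """

    base_radius_mm: float = R_REF_MM
    cone_amplitude_mm: float = 0.0
    cone_center: tuple[float, float] = (1.0, 270.0)
    cone_sigma_mm: float = 1.5
    stage: int = 0

    def __post_init__(self):
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be positive")
        if not (0 <= self.cone_amplitude_mm < self.base_radius_mm):
            raise ValueError("cone_amplitude_mm must satisfy 0 <= amplitude < base radius")
        if self.cone_sigma_mm <= 0:
            raise ValueError("cone_sigma_mm must be positive")
        if (self.stage == 0) != (self.cone_amplitude_mm == 0.0):
            raise ValueError("stage 0 iff cone_amplitude_mm == 0")

    @classmethod
    def from_stage(
        cls,
        stage: int,
        cone_center: tuple[float, float] = (1.0, 270.0),
        cone_sigma_mm: float = 1.5,
        base_radius_mm: float = R_REF_MM,
    ) -> "CorneaProfile":
        if stage not in STAGE_AMPLITUDES_MM:
            raise ValueError(f"unknown stage {stage}; expected 0-4")
        return cls(
            base_radius_mm=base_radius_mm,
            cone_amplitude_mm=STAGE_AMPLITUDES_MM[stage],
            cone_center=cone_center,
            cone_sigma_mm=cone_sigma_mm,
            stage=stage,
        )

    @property
    def label(self) -> str:
        return DISEASED if self.stage >= 1 else HEALTHY

    def local_radius(self, rho_mm, theta_deg):
        """Local radius of curvature r_c at polar corneal position (ρ, θ)."""
        rho = np.asarray(rho_mm, dtype=float)
        theta = np.radians(np.asarray(theta_deg, dtype=float))
        x = rho * np.cos(theta)
        y = rho * np.sin(theta)
        ecc, ang = self.cone_center
        cx = ecc * np.cos(np.radians(ang))
        cy = ecc * np.sin(np.radians(ang))
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        r_c = self.base_radius_mm - self.cone_amplitude_mm * np.exp(
            -d2 / (2.0 * self.cone_sigma_mm**2)
        )
        if np.any(r_c <= 0):
            raise ValueError("cone parameters yield non-positive radius of curvature")
        return r_c


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging geometry, scale and noise of the simulated capture."""

    working_distance_mm: float = 200.0
    mm_per_pixel: float = 0.03
    image_size_px: tuple[int, int] = (384, 384)  # (width, height)
    radius_noise_frac: float = 0.02
    pixel_noise_sd: float = 0.01
    illumination: float = 1.0
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    iris_radius_mm: float = 5.8
    iris_color: tuple[float, float, float] = (0.30, 0.20, 0.12)
    sclera_color: tuple[float, float, float] = (0.78, 0.76, 0.72)
    background_texture_sd: float = 0.0

    def __post_init__(self):
        if self.working_distance_mm <= 0 or self.mm_per_pixel <= 0:
            raise ValueError("working distance and mm_per_pixel must be positive")
        if min(self.image_size_px) <= 0:
            raise ValueError("image_size_px must be positive")
        if self.radius_noise_frac < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if not (0 < self.illumination <= 1):
            raise ValueError("illumination must lie in (0, 1]")

    @property
    def center_px(self) -> tuple[float, float]:
        w, h = self.image_size_px
        return ((w - 1) / 2.0 + self.center_offset_px[0], (h - 1) / 2.0 + self.center_offset_px[1])


@dataclass
class PhantomImage:
    """Rendered 8-bit RGB phantom plus the scale it was drawn at."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mm_per_pixel: float
    center_px: tuple[float, float]
    eye_id: str = ""

    def save(self, path) -> None:
        Image.fromarray(self.pixels).save(path)


@dataclass
class GroundTruth:
    """Noise-free per-ring/per-sector truth emitted alongside each phantom."""

    radii_px: np.ndarray  # (K, S)
    radii_mm: np.ndarray  # (K, S)
    curvature_mm: np.ndarray  # (K, S) local radius of curvature
    label: str
    stage: int
    eye_id: str = ""

    def __post_init__(self):
        if (self.label == DISEASED) != (self.stage >= 1):
            raise ValueError("label diseased iff stage >= 1")

    def to_frame(self) -> pd.DataFrame:
        k, s = self.radii_px.shape
        centers = sector_centers(s)
        rings, sectors = np.meshgrid(np.arange(1, k + 1), centers, indexing="ij")
        return pd.DataFrame(
            {
                "eye_id": self.eye_id,
                "ring": rings.ravel(),
                "sector_deg": sectors.ravel(),
                "radius_px": self.radii_px.ravel(),
                "radius_mm": self.radii_mm.ravel(),
                "r_c_mm": self.curvature_mm.ravel(),
                "label": self.label,
                "stage": self.stage,
            }
        )


def _check_ring_bounds(radii_px, thickness_px, acq: AcquisitionSpec) -> None:
    w, h = acq.image_size_px
    cx, cy = acq.center_px
    margin = min(cx, cy, w - 1 - cx, h - 1 - cy)
    outer = np.max(np.asarray(radii_px), axis=tuple(range(1, np.ndim(radii_px)))) + thickness_px / 2
    for k, r in enumerate(np.atleast_1d(outer)):
        if r > margin:
            raise ValueError(f"ring {k + 1} exceeds image bounds ({r:.1f} px > {margin:.1f} px)")


def render_placido_pattern(spec: PlacidoSpec, acq: AcquisitionSpec) -> np.ndarray:
    """Rasterize the flat ring pattern as shown on the phone screen."""
    spec.validate()
    w, h = acq.image_size_px
    radii_px = np.asarray(spec.ring_radii_ref) / acq.mm_per_pixel
    thickness_px = spec.thickness_mm / acq.mm_per_pixel
    _check_ring_bounds(radii_px[:, None], thickness_px, acq)

    dist, _ = polar_grid((h, w), acq.center_px)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_color
    for r in radii_px:
        band = np.abs(dist - r) <= thickness_px / 2
        img[band] = spec.ring_color
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def reflect_pattern(
    spec: PlacidoSpec,
    profile: CorneaProfile,
    acq: AcquisitionSpec,
    rng: np.random.Generator | None = None,
    eye_id: str = "",
    n_sectors: int = 24,
) -> tuple[PhantomImage, GroundTruth]:
    """Render the ring pattern as reflected by ``profile``.

    Radius jitter is drawn at the ``n_sectors`` sector nodes per ring and
    interpolated periodically in angle, so noisy rings stay closed curves.
    Because the reflection of nested rings off a smooth convex surface is
    order-preserving, jitter is truncated so that adjacent noisy rings keep a
    separation of at least the stroke thickness and never merge or cross.
    The returned :class:`GroundTruth` stores the noise-free radii, averaged
    over each sector (matching the sector-mean measurement downstream).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(0)
    w, h = acq.image_size_px
    cx, cy = acq.center_px
    dist, theta = polar_grid((h, w), (cx, cy))
    thickness_px = spec.thickness_mm / acq.mm_per_pixel

    refs = np.asarray(spec.ring_radii_ref)
    centers = sector_centers(n_sectors)

    # noise-free ground truth, averaged over each sector on a 1-degree comb
    sub = (np.arange(360) + 0.5)[None, :]  # (1, 360)
    r_c_fine = profile.local_radius(refs[:, None], sub)
    rho_fine = refs[:, None] * r_c_fine / R_REF_MM
    r_c_true = r_c_fine.reshape(spec.n_rings, n_sectors, -1).mean(axis=2)
    radii_mm_true = rho_fine.reshape(spec.n_rings, n_sectors, -1).mean(axis=2)
    radii_px_true = radii_mm_true / acq.mm_per_pixel

    # scene background
    img = np.empty((h, w, 3), dtype=float)
    img[:] = acq.sclera_color
    img[dist * acq.mm_per_pixel <= acq.iris_radius_mm] = acq.iris_color
    if acq.background_texture_sd > 0:
        img += rng.normal(0.0, acq.background_texture_sd, img.shape)

    # multiplicative jitter at sector nodes, truncated to preserve nesting
    if acq.radius_noise_frac > 0:
        base_nodes = refs[:, None] * profile.local_radius(refs[:, None], centers[None, :]) / R_REF_MM
        eps = rng.normal(0.0, acq.radius_noise_frac, (spec.n_rings, n_sectors))
        noisy_nodes = base_nodes * (1.0 + eps)
        # keep noisy neighbors separable: stroke width plus a 5 px guard band
        # (a 3x3 closing downstream can bridge gaps of up to ~3 px)
        min_sep_mm = spec.thickness_mm + 5.0 * acq.mm_per_pixel
        noisy_nodes[0] = np.maximum(noisy_nodes[0], min_sep_mm)
        for k in range(1, spec.n_rings):
            noisy_nodes[k] = np.maximum(noisy_nodes[k], noisy_nodes[k - 1] + min_sep_mm)
        eps = noisy_nodes / base_nodes - 1.0
    else:
        eps = None

    # reflected rings, evaluated continuously in angle
    max_radii = np.empty(spec.n_rings)
    for k, ref in enumerate(refs):
        scale = profile.local_radius(ref, theta) / R_REF_MM
        rho_px = ref * scale / acq.mm_per_pixel
        if eps is not None:
            rho_px = rho_px * (1.0 + periodic_interp(theta, eps[k]))
        max_radii[k] = rho_px.max()
        img[np.abs(dist - rho_px) <= thickness_px / 2] = spec.ring_color
    _check_ring_bounds(max_radii[:, None], thickness_px, acq)

    img *= acq.illumination
    if acq.pixel_noise_sd > 0:
        img += rng.normal(0.0, acq.pixel_noise_sd, img.shape)
    pixels = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)

    phantom = PhantomImage(pixels=pixels, mm_per_pixel=acq.mm_per_pixel, center_px=(cx, cy), eye_id=eye_id)
    truth = GroundTruth(
        radii_px=radii_px_true,
        radii_mm=radii_mm_true,
        curvature_mm=r_c_true,
        label=profile.label,
        stage=profile.stage,
        eye_id=eye_id,
    )
    return phantom, truth


def generate_dataset(
    n_healthy: int = 50,
    n_diseased: int = 50,
    stage_mix: dict[int, float] | None = None,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
    spec: PlacidoSpec | None = None,
    cone_sigma_mm: float = 1.5,
) -> list[tuple[PhantomImage, GroundTruth]]:
    """Deterministically generate a labeled phantom cohort.

    Defaults emulate the study design: 100 eyes, 50 healthy and 50 diseased
    with stages 1-4 equally mixed, 2% radius jitter.  Cone position is drawn
    per diseased eye (eccentricity U(0.5, 1.0) mm, angle U(0, 360)).
    """
    if n_healthy < 0 or n_diseased < 0:
        raise ValueError("counts must be non-negative")
    if stage_mix is None:
        stage_mix = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}
    if any(s not in (1, 2, 3, 4) for s in stage_mix):
        raise ValueError("stage_mix keys must be stages 1-4")
    acq = acq or AcquisitionSpec()
    spec = spec or PlacidoSpec()
    rng = np.random.default_rng(seed)

    # largest-remainder apportionment of diseased eyes over stages
    stages = sorted(stage_mix)
    weights = np.asarray([stage_mix[s] for s in stages], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("stage_mix must have positive total weight")
    weights = weights / weights.sum()
    quota = weights * n_diseased
    counts = np.floor(quota).astype(int)
    rem = n_diseased - counts.sum()
    counts[np.argsort(quota - counts)[::-1][:rem]] += 1

    stage_list = [0] * n_healthy + [s for s, c in zip(stages, counts) for _ in range(c)]
    items = []
    for i, stage in enumerate(stage_list):
        eye_id = f"eye{i:03d}"
        if stage == 0:
            profile = CorneaProfile()
        else:
            ecc = rng.uniform(0.5, 1.0)
            ang = rng.uniform(0.0, 360.0)
            profile = CorneaProfile.from_stage(stage, cone_center=(ecc, ang), cone_sigma_mm=cone_sigma_mm)
        items.append(reflect_pattern(spec, profile, acq, rng=rng, eye_id=eye_id))
    return items


def write_dataset(items, out_dir) -> Path:
    """Write PNGs, a ground-truth CSV and a JSON manifest; return the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, entries = [], []
    for phantom, truth in items:
        png = out / f"{phantom.eye_id}.png"
        phantom.save(png)
        frames.append(truth.to_frame())
        entries.append(
            {
                "eye_id": phantom.eye_id,
                "image": png.name,
                "label": truth.label,
                "stage": truth.stage,
                "mm_per_pixel": phantom.mm_per_pixel,
                "center_px": list(phantom.center_px),
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"n_items": len(entries), "items": entries}, indent=2))
    return manifest


def generate_feature_table(
    n_eyes: int,
    class_params: dict[str, dict],
    seed: int = 0,
    spec: PlacidoSpec | None = None,
    n_sectors: int = 24,
) -> pd.DataFrame:
    """Feature-level fixture: per-ring diopter draws without any rendering.

    ``class_params`` maps a label to ``{"mean_d": m, "sd_d": s, "frac": f}``
    where mean/sd may be scalars or per-ring sequences and the fractions sum
    to one.
    """
    spec = spec or PlacidoSpec()
    rng = np.random.default_rng(seed)
    labels = sorted(class_params)
    fracs = np.asarray([class_params[c].get("frac", 1.0 / len(labels)) for c in labels], float)
    quota = fracs / fracs.sum() * n_eyes
    counts = np.floor(quota).astype(int)
    counts[np.argsort(quota - counts)[::-1][: n_eyes - counts.sum()]] += 1

    centers = sector_centers(n_sectors)
    refs = np.asarray(spec.ring_radii_ref)
    records = []
    eye = 0
    for label, count in zip(labels, counts):
        mean = np.broadcast_to(np.asarray(class_params[label]["mean_d"], float), (spec.n_rings,))
        sd = np.broadcast_to(np.asarray(class_params[label]["sd_d"], float), (spec.n_rings,))
        if np.any(sd <= 0):
            raise ValueError("diopter SD must be positive")
        for _ in range(count):
            eye_id = f"eye{eye:03d}"
            diopters = rng.normal(mean[:, None], sd[:, None], (spec.n_rings, n_sectors))
            for k in range(spec.n_rings):
                for s in range(n_sectors):
                    records.append(
                        {
                            "eye_id": eye_id,
                            "ring": k + 1,
                            "sector_deg": centers[s],
                            "distance_mm": refs[k],
                            "radius_mm": 337.5 / diopters[k, s],
                            "diopter": diopters[k, s],
                            "label": label,
                        }
                    )
            eye += 1
    return pd.DataFrame.from_records(records)


def curvature_map(profile: CorneaProfile, spec: PlacidoSpec, n_sectors: int = 24) -> np.ndarray:
    """True local radius of curvature sampled on the ring x sector grid."""
    refs = np.asarray(spec.ring_radii_ref)
    return profile.local_radius(refs[:, None], sector_centers(n_sectors)[None, :])
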