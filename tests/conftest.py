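"""Shared fixtures: small phantoms and their extracted maps, computed once."""

from __future__ import annotations

import numpy as np
import pytest

import placidoscan as ps
from placidoscan import enhance as enh
from placidoscan import rings as rg
from placidoscan import topo as tp


@pytest.fixture(scope="session")
def placido_spec():
    return ps.PlacidoSpec()


@pytest.fixture(scope="session")
def quiet_acq():
    """Noise-free acquisition at the default scale."""
    return ps.AcquisitionSpec(radius_noise_frac=0.0, pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def healthy_phantom(placido_spec, quiet_acq):
    """Noise-free healthy phantom (uniform 7.85 mm dome)."""
    return ps.reflect_pattern(placido_spec, ps.CorneaProfile(), quiet_acq)


@pytest.fixture(scope="session")
def cone_phantom(placido_spec, quiet_acq):
    """Noise-free stage-3 keratoconic phantom, cone in the inferior cornea."""
    profile = ps.CorneaProfile.from_stage(3, cone_center=(1.0, 262.5))
    return ps.reflect_pattern(placido_spec, profile, quiet_acq)


def _run_imaging(pixels, acq, spec):
    lab = enh.color_convert(enh.enhance(pixels), "rgb2lab")
    radius_map, labels = rg.extract_radius_map(lab)
    calib = tp.CalibrationSpec(mm_per_pixel=acq.mm_per_pixel, ring_radii_ref=spec.ring_radii_ref)
    r_mm = tp.calibrate_radii(radius_map, calib)
    return radius_map, labels, r_mm, tp.diopter_map(r_mm)


@pytest.fixture(scope="session")
def healthy_maps(healthy_phantom, quiet_acq, placido_spec):
    """(radius_map_px, RingLabels, r_mm, diopter) for the healthy phantom."""
    phantom_img, _ = healthy_phantom
    return _run_imaging(phantom_img.pixels, quiet_acq, placido_spec)


@pytest.fixture(scope="session")
def cone_maps(cone_phantom, quiet_acq, placido_spec):
    """Same maps for the stage-3 cone phantom."""
    phantom_img, _ = cone_phantom
    return _run_imaging(phantom_img.pixels, quiet_acq, placido_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
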