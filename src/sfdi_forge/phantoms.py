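"""Synthetic tissue phantoms for every supported experiment.

All scenes are constructible with one call and zero external inputs.
The optical properties are literature values for oesophageal tissue at
635 nm: healthy tissue, squamous cell carcinoma (SCC) and Barrett's
oesophagus (BO) with mild chronic inflammation, plus the reference
material used for system calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import OpticalProperties
from .render import Camera, Projector, Scene

__all__ = [
    "TISSUES",
    "PhantomSpec",
    "make_flat_scene",
    "make_scc_scene",
    "make_bo_scene",
    "make_reference_scene",
    "make_calibration_set",
    "CALIBRATION_RANGES",
]

#: Tissue optical properties (mu_a, mu_s' in mm^-1 at 635 nm; g=0.8, n=1.4).
TISSUES = {
    "healthy": OpticalProperties.from_reduced(0.058, 0.75),
    "scc": OpticalProperties.from_reduced(0.12, 0.64),
    "bo": OpticalProperties.from_reduced(0.057, 0.51),
    "reference": OpticalProperties.from_reduced(0.217, 5.94),
    "tube_wall": OpticalProperties.from_reduced(0.076, 2.99),
}

#: Characterised property span of the nine calibration materials.
CALIBRATION_RANGES = {"mu_a": (0.08, 0.22), "mu_s_prime": (1.4, 6.5)}


@dataclass(frozen=True)
class PhantomSpec:
    """Name, geometry and per-region properties of a phantom."""

    name: str
    geometry: dict
    regions: dict  # region name -> OpticalProperties
    source: str = "oesophageal tissue at 635 nm"


def _default_camera(resolution=(256, 256), extent=(200.0, 200.0)) -> Camera:
    return Camera(position=(0.0, 0.0, 500.0), extent=extent, resolution=resolution)


def make_flat_scene(
    props: OpticalProperties,
    resolution=(256, 256),
    extent=(200.0, 200.0),
    name: str = "flat",
) -> Scene:
    """Homogeneous flat semi-infinite sample filling the field of view."""
    shape = tuple(resolution)
    return Scene(
        height=np.zeros(shape),
        mu_a=np.full(shape, props.mu_a),
        mu_s_prime=np.full(shape, props.mu_s_prime),
        g=props.g,
        n=props.n,
        camera=_default_camera(resolution, extent),
        projector=Projector(),
        name=name,
    )


def make_reference_scene(resolution=(256, 256), extent=(200.0, 200.0)) -> Scene:
    """The calibration reference material (mu_a=0.217, mu_s'=5.94 mm^-1)."""
    return make_flat_scene(TISSUES["reference"], resolution, extent, name="reference")


def make_scc_scene(resolution=(256, 256), extent=(200.0, 200.0)) -> Scene:
    """Squamous-cell-carcinoma spheroid on healthy oesophageal tissue.

    An 80 mm diameter tumour spheroid (40 mm apex height, modelled as a
    hemispherical bump) with mu_a=0.12 / mu_s'=0.64 sits on a flat
    healthy background with mu_a=0.058 / mu_s'=0.75 mm^-1.
    """
    scene = make_flat_scene(TISSUES["healthy"], resolution, extent, name="scc")
    xc, yc = scene.camera.reference_grid()
    r = np.sqrt(xc**2 + yc**2)
    radius = 40.0
    inside = r < radius
    scene.height[inside] = np.sqrt(np.clip(radius**2 - r[inside] ** 2, 0.0, None))
    scc = TISSUES["scc"]
    scene.mu_a[inside] = scc.mu_a
    scene.mu_s_prime[inside] = scc.mu_s_prime
    return scene


def scc_region_masks(scene: Scene):
    """(tumour, healthy-background) pixel masks of the SCC scene."""
    xc, yc = scene.camera.reference_grid()
    r = np.sqrt(xc**2 + yc**2)
    return r < 40.0, r >= 45.0


def make_bo_scene(resolution=(256, 256), extent=(200.0, 200.0)) -> Scene:
    """Barrett's oesophagus (left half) adjacent to healthy tissue (right half).

    Both halves are flat; the single straight interface runs down the
    image centre.  BO: mu_a=0.057, mu_s'=0.51; healthy: 0.058, 0.75.
    """
    scene = make_flat_scene(TISSUES["healthy"], resolution, extent, name="bo")
    xc, _ = scene.camera.reference_grid()
    left = xc < 0.0
    bo = TISSUES["bo"]
    scene.mu_a[left] = bo.mu_a
    scene.mu_s_prime[left] = bo.mu_s_prime
    return scene


def bo_region_masks(scene: Scene, interface_band_px: int = 5):
    """(BO, healthy) masks excluding a band around the interface."""
    h, w = scene.camera.resolution
    cols = np.arange(w)[None, :].repeat(h, axis=0)
    mid = w // 2
    bo = cols < mid - interface_band_px
    healthy = cols >= mid + interface_band_px
    return bo, healthy


def make_calibration_set(n: int = 9, ranges: dict | None = None):
    """Homogeneous calibration materials on a property lattice.

    Returns a list of ``(scene_factory_props, OpticalProperties)`` —
    i.e. the known property values laid out as the Cartesian product of
    endpoints and midpoints over the characterised span
    (mu_a 0.08-0.22, mu_s' 1.4-6.5 mm^-1 for the default 3x3 = 9).
    """
    ranges = ranges or CALIBRATION_RANGES
    if n == 1:
        return [TISSUES["reference"]]
    k = int(round(np.sqrt(n)))
    if k * k != n:
        raise ValueError("n must be a perfect square for a grid layout")
    mu_a = np.linspace(*ranges["mu_a"], k)
    mu_sp = np.linspace(*ranges["mu_s_prime"], k)
    return [
        OpticalProperties.from_reduced(ma, ms)
        for ma in mu_a
        for ms in mu_sp
    ]
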