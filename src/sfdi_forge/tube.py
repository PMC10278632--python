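"""Structured illumination inside a tubular lumen.

A forward-viewing camera and projector sit above the proximal opening
of a tube whose inner wall is the tissue of interest.  A planar
sinusoid projected down the tube produces a wildly varying spatial
frequency along the wall; the pre-distortion computed here instead
assigns each projector direction the pattern value of the wall point it
hits, so the wall sees a constant longitudinal frequency.

Because the illumination still falls off steeply along the tube, raw
modulation cannot be calibrated by a single reference: the wall is
divided into longitudinal sections (a greedy mean-intensity rule with
the >10-count criterion on the 8-bit normalised DC image) and one
empirically derived look-up table is built per section.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .optics import OpticalProperties, diffuse_reflectance_fx
from .phantoms import TISSUES
from .render import ExposedImage, auto_exposure
from .sfdi import ImageStack, LookupTable, PropertyMaps, build_empirical_lut, demodulate

__all__ = [
    "TubeGeometry",
    "TubeScene",
    "SectionedLUT",
    "predistort",
    "normalize_0_255",
    "make_tube_scene",
    "render_tube",
    "render_tube_wall_stack",
    "unroll_tube_image",
    "section_by_intensity",
    "build_sectioned_luts",
    "recover_tube_maps",
]

EQUISPACED_PHASES = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)


@dataclass(frozen=True)
class TubeGeometry:
    """Tube and instrument geometry (mm).

    Defaults: 250 mm tube, 20 mm bore, 80 mm outer diameter, camera
    110 mm and projector 100 mm above the proximal opening, both on the
    tube axis.  z runs from 0 at the opening to ``length`` at the
    distal end, which is capped with the wall material.
    """

    length: float = 250.0
    inner_diameter: float = 20.0
    outer_diameter: float = 80.0
    camera_standoff: float = 110.0
    projector_standoff: float = 100.0

    def __post_init__(self) -> None:
        if min(self.length, self.inner_diameter, self.outer_diameter,
               self.camera_standoff, self.projector_standoff) <= 0:
            raise ValueError("all tube dimensions must be positive")
        if self.inner_diameter >= self.outer_diameter:
            raise ValueError("inner diameter must be smaller than outer diameter")

    @property
    def a(self) -> float:
        """Inner (bore) radius, mm."""
        return self.inner_diameter / 2.0


@dataclass
class TubeScene:
    """Tube geometry plus wall material (optionally azimuth-dependent).

    ``quadrant_props`` overrides the wall material over one 90-degree
    sector (azimuth start in radians).
    """

    tube: TubeGeometry = field(default_factory=TubeGeometry)
    wall: OpticalProperties = field(default_factory=lambda: TISSUES["tube_wall"])
    quadrant_props: Optional[OpticalProperties] = None
    quadrant_start: float = 0.0
    projector_power: float = 5.0

    def props_at(self, azimuth: np.ndarray):
        """(mu_a, mu_s') arrays for wall points at the given azimuths."""
        mu_a = np.full_like(azimuth, self.wall.mu_a, dtype=float)
        mu_sp = np.full_like(azimuth, self.wall.mu_s_prime, dtype=float)
        if self.quadrant_props is not None:
            rel = (azimuth - self.quadrant_start) % (2.0 * math.pi)
            sel = rel < math.pi / 2.0
            mu_a[sel] = self.quadrant_props.mu_a
            mu_sp[sel] = self.quadrant_props.mu_s_prime
        return mu_a, mu_sp


def make_tube_scene(
    deviating_quadrant: Optional[OpticalProperties] = None,
    wall: Optional[OpticalProperties] = None,
    tube: Optional[TubeGeometry] = None,
) -> TubeScene:
    """Default 250/80/20 mm tube, homogeneous or with one deviating quadrant."""
    return TubeScene(
        tube=tube or TubeGeometry(),
        wall=wall or TISSUES["tube_wall"],
        quadrant_props=deviating_quadrant,
    )


def predistort(
    tube: TubeGeometry,
    fx_wall: float,
    phase: float = 0.0,
    n_px: int = 1024,
) -> np.ndarray:
    """Pre-distorted projector pattern: concentric rings in [0, 1].

    The projector direction with polar tangent rho hits the wall at
    depth z = a / rho - s_p (s_p the projector standoff), so assigning
    that direction the value 0.5 + 0.5 sin(2 pi fx_wall z + phase)
    makes the realised longitudinal frequency on the wall uniform.
    Directions inside the distal cone carry the end-cap (z = L) value;
    directions outside the bore carry the DC level.

    Raises if the ring frequency at the distal end exceeds the Nyquist
    limit of the projector pixel grid, reporting the maximum admissible
    frequency.
    """
    if fx_wall < 0:
        raise ValueError("fx_wall must be >= 0")
    a, sp, L = tube.a, tube.projector_standoff, tube.length
    rho_min = a / (sp + L)
    rho_max = a / sp
    half = 1.1 * rho_max
    pitch = 2.0 * half / n_px
    if fx_wall > 0:
        # local ring frequency in projector-tangent units: f * |dz/drho|
        f_px_max = fx_wall * a / rho_min**2 * pitch
        if f_px_max > 0.5:
            admissible = 0.5 * rho_min**2 / (a * pitch)
            raise ValueError(
                f"Nyquist violation at the distal end: fx_wall={fx_wall} "
                f"needs {f_px_max:.2f} cycles/pixel; maximum admissible "
                f"fx_wall at n_px={n_px} is {admissible:.4f} mm^-1"
            )
    u = (np.arange(n_px) + 0.5) * pitch - half
    U, V = np.meshgrid(u, u)
    rho = np.sqrt(U**2 + V**2)
    with np.errstate(divide="ignore"):
        z = a / np.maximum(rho, 1e-12) - sp
    z = np.clip(z, 0.0, L)
    pattern = 0.5 + 0.5 * np.sin(2.0 * math.pi * fx_wall * z + phase)
    pattern[rho > rho_max] = 0.5
    return pattern


def normalize_0_255(pattern: np.ndarray):
    """Linearly rescale a float pattern to the full 8-bit range.

    Returns ``(uint8 image, (lo, hi))`` where lo -> 0 and hi -> 255;
    the scale is kept so the float original can be reconstructed to
    within quantisation.  A constant pattern cannot be normalised.
    """
    pattern = np.asarray(pattern, dtype=float)
    lo, hi = float(pattern.min()), float(pattern.max())
    if hi <= lo:
        raise ValueError("constant pattern cannot be normalised to 0-255")
    u8 = np.round((pattern - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return u8, (lo, hi)


def _camera_grid(tube: TubeGeometry, resolution: int):
    """Camera-pixel polar-tangent coordinates (rho, azimuth)."""
    cs = tube.camera_standoff
    half = 1.1 * tube.a / cs
    t = (np.arange(resolution) + 0.5) / resolution * 2 * half - half
    TX, TY = np.meshgrid(t, t)
    rho = np.sqrt(TX**2 + TY**2)
    az = np.arctan2(TY, TX) % (2.0 * math.pi)
    return rho, az


def _wall_intensity(
    scene: TubeScene,
    z: np.ndarray,
    azimuth: np.ndarray,
    fx_wall: float,
    phase: float,
    pattern_mode: str,
) -> np.ndarray:
    """Physical wall radiance under the projected pattern (fast model)."""
    tube = scene.tube
    a, sp = tube.a, tube.projector_standoff
    r2 = (sp + z) ** 2 + a**2
    r = np.sqrt(r2)
    cos_i = a / r
    irr = scene.projector_power / (4.0 * math.pi * r2) * cos_i
    mu_a, mu_sp = scene.props_at(azimuth)
    rd_dc = diffuse_reflectance_fx(None, 0.0, mu_a=mu_a, mu_s_prime=mu_sp)
    if pattern_mode == "predistorted":
        ac = 0.5 * np.sin(2.0 * math.pi * fx_wall * z + phase)
        f_loc = np.full_like(z, fx_wall)
    elif pattern_mode == "naive":
        # planar sinusoid: its value at the wall follows the projector
        # ray's lateral position at the tube-top plane
        x_top = a * sp / (sp + z) * np.cos(azimuth)
        ac = 0.5 * np.sin(2.0 * math.pi * fx_wall * x_top + phase)
        # realised longitudinal frequency: f |d x_top / dz|
        f_loc = fx_wall * a * sp / (sp + z) ** 2 * np.abs(np.cos(azimuth))
    else:
        raise ValueError(f"unknown pattern mode {pattern_mode!r}")
    rd_ac = diffuse_reflectance_fx(None, np.clip(f_loc, 0.0, None), mu_a=mu_a, mu_s_prime=mu_sp)
    return irr * (0.5 * rd_dc + ac * rd_ac)


def render_tube(
    scene: TubeScene,
    fx_wall: float,
    phase: float = 0.0,
    pattern_mode: str = "predistorted",
    resolution: int = 256,
    exposure: float | str = "auto",
) -> ExposedImage:
    """Camera image of the illuminated tube (fast analytic model).

    The annular wall region dominates the frame; the distal end cap
    (same material) fills the centre and the bright proximal top face
    the corners.
    """
    tube = scene.tube
    a, cs, sp, L = tube.a, tube.camera_standoff, tube.projector_standoff, tube.length
    rho, az = _camera_grid(tube, resolution)
    img = np.zeros_like(rho)

    wall = (rho >= a / (cs + L)) & (rho < a / cs)
    z = a / np.maximum(rho[wall], 1e-12) - cs
    img[wall] = _wall_intensity(scene, z, az[wall], fx_wall, phase, pattern_mode)

    # distal end cap: flat disc of wall material at z = L
    cap = rho < a / (cs + L)
    r_cap = rho[cap] * (cs + L)
    r2 = (sp + L) ** 2 + r_cap**2
    cos_i = (sp + L) / np.sqrt(r2)
    irr = scene.projector_power / (4.0 * math.pi * r2) * cos_i
    mu_a, mu_sp = scene.props_at(az[cap])
    rd = diffuse_reflectance_fx(None, 0.0, mu_a=mu_a, mu_s_prime=mu_sp)
    if pattern_mode == "predistorted":
        cap_val = 0.5 + 0.5 * math.sin(2.0 * math.pi * fx_wall * L + phase)
    else:
        x_top = r_cap * sp / (sp + L) * np.cos(az[cap])
        cap_val = 0.5 + 0.5 * np.sin(2.0 * math.pi * fx_wall * x_top + phase)
    img[cap] = irr * rd * cap_val

    # proximal top face: bright annulus of wall material at z = 0
    top = rho >= a / cs
    r_top = np.clip(rho[top] * cs, None, tube.outer_diameter / 2.0)
    r2 = sp**2 + r_top**2
    cos_i = sp / np.sqrt(r2)
    irr = scene.projector_power / (4.0 * math.pi * r2) * cos_i
    mu_a, mu_sp = scene.props_at(az[top])
    rd = diffuse_reflectance_fx(None, 0.0, mu_a=mu_a, mu_s_prime=mu_sp)
    img[top] = irr * rd * 0.5

    t = auto_exposure(img) if exposure == "auto" else float(exposure)
    return ExposedImage(pixels=img * 2.0 ** (-t), t_exposure=t)


def unroll_tube_image(
    image: np.ndarray,
    tube: TubeGeometry,
    n_z: int = 120,
    n_az: int = 90,
):
    """Polar-map a camera image of the tube into wall coordinates.

    Returns ``(wall_map, z_centers, az_centers)`` with ``wall_map``
    shaped (n_z, n_az): rows are longitudinal position z (mm from the
    proximal opening), columns circumferential angle.  The mapping is
    the analytic inverse of the camera projection (z <-> image radius)
    and is exactly invertible up to pixel sampling.
    """
    image = np.asarray(image, dtype=float)
    res = image.shape[0]
    a, cs = tube.a, tube.camera_standoff
    half = 1.1 * a / cs
    z = (np.arange(n_z) + 0.5) * tube.length / n_z
    az = (np.arange(n_az) + 0.5) * 2.0 * math.pi / n_az
    Z, AZ = np.meshgrid(z, az, indexing="ij")
    rho = a / (cs + Z)
    tx = rho * np.cos(AZ)
    ty = rho * np.sin(AZ)
    cols = (tx + half) / (2 * half) * res - 0.5
    rows = (ty + half) / (2 * half) * res - 0.5
    wall = map_coordinates(image, [rows, cols], order=1, mode="nearest")
    return wall, z, az


def render_tube_wall_stack(
    scene: TubeScene,
    fx_wall: float,
    pattern_mode: str = "predistorted",
    resolution: int = 256,
    n_z: int = 120,
    n_az: int = 90,
    phases=EQUISPACED_PHASES,
) -> ImageStack:
    """Three-phase stack rendered, exposure-corrected and unrolled to wall coordinates."""
    from .render import exposure_correct

    imgs = []
    t_shared = None
    for ph in phases:
        img = render_tube(
            scene, fx_wall, ph, pattern_mode, resolution,
            exposure=("auto" if t_shared is None else t_shared),
        )
        if t_shared is None:
            t_shared = img.t_exposure
        wall, _, _ = unroll_tube_image(exposure_correct(img), scene.tube, n_z, n_az)
        imgs.append(wall)
    return ImageStack(images=np.stack(imgs), fx=fx_wall, phases=tuple(phases))


def section_by_intensity(
    dc_image: np.ndarray,
    tube: TubeGeometry,
    n_rings: int = 10,
    threshold: float = 10.0,
):
    """Longitudinal sectioning by the >10-count mean-intensity rule.

    The DC wall image (or an already-unrolled wall map) is reduced to
    ``n_rings`` candidate rings of equal length along z, normalised to
    the full 8-bit range, and the rings are grown greedily into
    sections: a ring opens a new section when its mean differs from the
    running section mean by more than ``threshold`` counts.

    Returns the section edges as z positions (mm), e.g. 6 edges for 5
    sections.  A uniform image yields a single section (with a
    warning that a global LUT will be used).
    """
    dc_image = np.asarray(dc_image, dtype=float)
    if dc_image.ndim == 2 and dc_image.shape[0] != n_rings:
        wall = dc_image
        if dc_image.shape[0] * dc_image.shape[1] > 4 * n_rings:
            profile = wall.mean(axis=1) if wall.shape[0] >= wall.shape[1] else wall.mean(axis=0)
        else:
            profile = wall.ravel()
    elif dc_image.ndim == 2:
        profile = dc_image.mean(axis=1)
    else:
        profile = dc_image
    lo, hi = float(profile.min()), float(profile.max())
    if hi <= lo:
        warnings.warn("uniform intensity: single section (global LUT)", stacklevel=2)
        return np.array([0.0, tube.length])
    counts = (profile - lo) / (hi - lo) * 255.0
    edges_idx = np.linspace(0, len(counts), n_rings + 1).astype(int)
    ring_means = np.array(
        [counts[edges_idx[k]: edges_idx[k + 1]].mean() for k in range(n_rings)]
    )
    boundaries = [0]
    section = [ring_means[0]]
    for k in range(1, n_rings):
        if abs(ring_means[k] - np.mean(section)) > threshold:
            boundaries.append(k)
            section = [ring_means[k]]
        else:
            section.append(ring_means[k])
    boundaries.append(n_rings)
    z_edges = np.asarray(boundaries, dtype=float) * tube.length / n_rings
    if len(z_edges) < 3:
        warnings.warn("fewer than 2 sections resolvable: using a single global LUT",
                      stacklevel=2)
    return z_edges


@dataclass
class SectionedLUT:
    """One empirical look-up table per longitudinal tube section."""

    boundaries: np.ndarray  # z edges, mm; len = n_sections + 1
    luts: list

    def __post_init__(self) -> None:
        if len(self.luts) != len(self.boundaries) - 1:
            raise ValueError("need exactly one LUT per section")

    @property
    def n_sections(self) -> int:
        return len(self.luts)

    def section_of(self, z: np.ndarray) -> np.ndarray:
        """Section index of each z (clipped into the covered range)."""
        idx = np.searchsorted(self.boundaries, z, side="right") - 1
        return np.clip(idx, 0, self.n_sections - 1)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("boundaries", data=self.boundaries)
            for k, lut in enumerate(self.luts):
                grp = f.create_group(f"section_{k}")
                for name in ("dc", "ac", "mu_a", "mu_s_prime"):
                    grp.create_dataset(name, data=getattr(lut, name))
                grp.attrs["interpolation"] = lut.interpolation
                grp.attrs["fx"] = lut.fx

    @classmethod
    def load(cls, path) -> "SectionedLUT":
        import h5py

        with h5py.File(path, "r") as f:
            boundaries = f["boundaries"][:]
            luts = []
            for k in range(len(boundaries) - 1):
                grp = f[f"section_{k}"]
                luts.append(
                    LookupTable(
                        dc=grp["dc"][:],
                        ac=grp["ac"][:],
                        mu_a=grp["mu_a"][:],
                        mu_s_prime=grp["mu_s_prime"][:],
                        kind="empirical",
                        interpolation=str(grp.attrs["interpolation"]),
                        fx=float(grp.attrs["fx"]),
                    )
                )
        return cls(boundaries=boundaries, luts=luts)


def _section_nodes(stack: ImageStack, z: np.ndarray, edges: np.ndarray):
    """Per-section median (DC, AC) of an unrolled wall stack."""
    m_ac, m_dc = demodulate(stack)
    nodes = []
    for k in range(len(edges) - 1):
        sel = (z >= edges[k]) & (z < edges[k + 1])
        nodes.append((float(np.median(m_dc[sel])), float(np.median(m_ac[sel]))))
    return nodes


def build_sectioned_luts(
    calibration_props: Sequence[OpticalProperties],
    fx_wall: float,
    tube: Optional[TubeGeometry] = None,
    boundaries: Optional[np.ndarray] = None,
    resolution: int = 256,
    n_z: int = 120,
    n_az: int = 90,
    interpolation: str = "bicubic",
):
    """Per-section empirical LUTs from renders of known wall materials.

    Each calibration material is rendered as a homogeneous tube under
    the pre-distorted three-phase patterns; section boundaries default
    to the >10-count rule applied to the first material's DC image.
    Returns ``(SectionedLUT, global_lut)`` where the global LUT is the
    un-sectioned equivalent built from whole-wall statistics.
    """
    tube = tube or TubeGeometry()
    per_material = []
    z_ref = None
    for props in calibration_props:
        scene = TubeScene(tube=tube, wall=props)
        stack = render_tube_wall_stack(scene, fx_wall, "predistorted", resolution, n_z, n_az)
        wall_dc = demodulate(stack)[1]
        per_material.append((props, stack, wall_dc))
        if z_ref is None:
            z_ref = np.linspace(0, tube.length, n_z, endpoint=False) + tube.length / (2 * n_z)
    if boundaries is None:
        boundaries = section_by_intensity(per_material[0][2], tube)
    n_sections = len(boundaries) - 1

    section_cal = [[] for _ in range(n_sections)]
    global_cal = []
    for props, stack, _ in per_material:
        nodes = _section_nodes(stack, z_ref, boundaries)
        for k, node in enumerate(nodes):
            section_cal[k].append((node, props))
        whole = _section_nodes(stack, z_ref, np.array([0.0, tube.length]))[0]
        global_cal.append((whole, props))

    luts = [
        build_empirical_lut(cal, fx=fx_wall, interpolation=interpolation)
        for cal in section_cal
    ]
    global_lut = build_empirical_lut(global_cal, fx=fx_wall, interpolation=interpolation)
    return SectionedLUT(boundaries=np.asarray(boundaries, float), luts=luts), global_lut


def recover_tube_maps(
    stack: ImageStack,
    slut: SectionedLUT,
    tube: Optional[TubeGeometry] = None,
) -> PropertyMaps:
    """Per-pixel property recovery in wall coordinates with sectioned LUTs.

    Each unrolled wall pixel is demodulated and inverted with the
    empirical LUT of its own longitudinal section.  Passing a
    single-section :class:`SectionedLUT` recovers with a global
    (un-sectioned) LUT for comparison.
    """
    tube = tube or TubeGeometry()
    m_ac, m_dc = demodulate(stack)
    n_z = m_dc.shape[0]
    z = np.linspace(0, tube.length, n_z, endpoint=False) + tube.length / (2 * n_z)
    sec = slut.section_of(z)
    mu_a = np.full_like(m_dc, np.nan)
    mu_sp = np.full_like(m_dc, np.nan)
    oob = np.zeros_like(m_dc, dtype=bool)
    for k in range(slut.n_sections):
        rows = sec == k
        if not rows.any():
            continue
        a, s, o = slut.luts[k].query(m_dc[rows], m_ac[rows])
        mu_a[rows] = a
        mu_sp[rows] = s
        oob[rows] = o
    return PropertyMaps(mu_a=mu_a, mu_s_prime=mu_sp, oob_mask=oob)
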