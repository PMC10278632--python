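"""Synthesises camera images of scenes under projected fringe patterns.

The fast mode treats every pixel's neighbourhood as a locally planar
semi-infinite medium: the incident irradiance (inverse-square, cosine
obliquity, optional shadowing) is split into its DC and AC components,
which reflect with the diffusion-model diffuse reflectance at zero
frequency and at the locally realised projected frequency respectively.
This is exactly the physics the SFDI inversion assumes, which makes the
whole forward-inverse loop self-consistent and testable.

A Monte-Carlo mode traces photons through the volume for homogeneous
planar scenes and serves as the statistical oracle for the fast mode.

Geometry: the camera is a pinhole above the reference plane z = 0
(heights positive toward the camera); pixel (0, 0) is the top-left
corner, x to the right and y down; all lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit
from scipy.ndimage import map_coordinates

from .optics import OpticalProperties, SpatialFrequency, diffuse_reflectance_fx
from .transport import TransportConfig

__all__ = [
    "FringePattern",
    "Projector",
    "Camera",
    "Scene",
    "ExposedImage",
    "render",
    "render_phase_stack",
    "exposure_correct",
    "auto_exposure",
]

EQUISPACED_PHASES = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)


@dataclass(frozen=True)
class FringePattern:
    """Sinusoidal projection pattern 0.5 + 0.5 sin(omega c + phase).

    ``orientation`` names the reference-plane axis along which the
    sinusoid varies: ``"y"`` (the SFDI default, insensitive to height
    because the projector offset is along x) or ``"x"`` (profilometry:
    height displaces the pattern).
    """

    fx: float
    phase: float = 0.0
    orientation: str = "y"
    amplitude: float = 0.5
    offset: float = 0.5

    def __post_init__(self) -> None:
        if self.fx < 0:
            raise ValueError("fx must be >= 0")
        if self.orientation not in ("x", "y"):
            raise ValueError("orientation must be 'x' or 'y'")
        if not (0.0 <= self.offset - self.amplitude and self.offset + self.amplitude <= 1.0 + 1e-12):
            raise ValueError("pattern must stay within [0, 1]")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.fx

    def value(self, coord):
        return self.offset + self.amplitude * np.sin(self.omega * np.asarray(coord) + self.phase)


@dataclass(frozen=True)
class Projector:
    """Point projector: position (mm) and radiant power (W).

    The default pose (35 mm lateral offset at 500 mm height) is the
    4-degree camera-projector offset of a conventional planar SFDI
    bench.
    """

    position: tuple = (35.0, 0.0, 500.0)
    power: float = 5.0


@dataclass(frozen=True)
class Camera:
    """Pinhole camera looking straight down at the reference plane."""

    position: tuple = (0.0, 0.0, 500.0)
    extent: tuple = (200.0, 200.0)  # (width, height) of the imaged field, mm
    resolution: tuple = (256, 256)  # (rows, cols)

    @property
    def pixel_pitch(self) -> tuple:
        return (self.extent[1] / self.resolution[0], self.extent[0] / self.resolution[1])

    def reference_grid(self):
        """Reference-plane (x, y) coordinates of each pixel centre."""
        h, w = self.resolution
        ex, ey = self.extent
        x = (np.arange(w) + 0.5) / w * ex - ex / 2.0 + self.position[0]
        y = (np.arange(h) + 0.5) / h * ey - ey / 2.0 + self.position[1]
        return np.meshgrid(x, y)


@dataclass
class Scene:
    """Heightfield scene with per-pixel material maps.

    ``height``, ``mu_a`` and ``mu_s_prime`` are arrays on the camera's
    reference-plane pixel grid; ``g`` and ``n`` are shared scalars.
    """

    height: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    g: float = 0.8
    n: float = 1.4
    projector: Projector = field(default_factory=Projector)
    camera: Camera = field(default_factory=Camera)
    ambient: float = 0.0
    specular: Optional[dict] = None  # e.g. {"ks": 0.05, "shininess": 40}
    name: str = "scene"

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_s_prime = np.asarray(self.mu_s_prime, dtype=float)
        if not (self.height.shape == self.mu_a.shape == self.mu_s_prime.shape):
            raise ValueError("height and material maps must share one shape")
        if self.height.shape != tuple(self.camera.resolution):
            raise ValueError("scene arrays must match the camera resolution")
        for pos in (self.projector.position, self.camera.position):
            if not np.all(np.isfinite(pos)):
                raise ValueError("projector and camera poses must be finite")
        if np.any(self.mu_s_prime <= 0):
            raise ValueError("fast rendering requires mu_s_prime > 0 everywhere")

    @property
    def is_planar(self) -> bool:
        return bool(np.all(self.height == 0.0))

    @property
    def is_homogeneous(self) -> bool:
        return np.ptp(self.mu_a) == 0.0 and np.ptp(self.mu_s_prime) == 0.0


@dataclass
class ExposedImage:
    """Intensity map with its exposure setting (stops).

    Physical linear intensity is recovered as pixels * 2**t_exposure
    (:func:`exposure_correct`).
    """

    pixels: np.ndarray
    t_exposure: Optional[float]
    bit_depth: Optional[int] = None
    pixel_pitch: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be >= 0")


def auto_exposure(physical: np.ndarray, target: float = 0.5) -> float:
    """Exposure (stops) putting the mean rendered intensity mid-range.

    Mirrors the practice of adjusting camera exposure until the average
    8-bit intensity is near the middle of 0-255, then correcting by
    2**t afterwards.
    """
    mean = float(np.mean(physical))
    if mean <= 0:
        return 0.0
    return math.log2(mean / target)


def exposure_correct(img: ExposedImage) -> np.ndarray:
    """Undo the exposure setting: output = pixels * 2**t_exposure."""
    if img.t_exposure is None:
        raise ValueError("exposure metadata missing (already corrected?)")
    return img.pixels * 2.0**img.t_exposure


def _bilinear(arr: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return map_coordinates(arr, [rows, cols], order=1, mode="nearest")


def _surface_lookup(scene: Scene, xs, ys):
    """Map physical (x, y) to fractional array indices and sample maps."""
    cam = scene.camera
    h, w = cam.resolution
    ex, ey = cam.extent
    cols = (xs - cam.position[0] + ex / 2.0) / ex * w - 0.5
    rows = (ys - cam.position[1] + ey / 2.0) / ey * h - 0.5
    return rows, cols


def _find_surface(scene: Scene, n_iter: int = 6):
    """Intersect every camera ray with the heightfield.

    Fixed-point iteration on z: a surface point of height z seen by the
    pixel whose reference-plane coordinate is (x_c, y_c) sits at
    (x_c, y_c) scaled toward the camera axis by (1 - z / z_cam).
    Converges quickly for the smooth phantoms considered here.
    """
    cam = scene.camera
    xc, yc = cam.reference_grid()
    cx, cy, cz = cam.position
    z = np.zeros_like(xc)
    for _ in range(n_iter):
        shrink = 1.0 - z / cz
        xs = cx + (xc - cx) * shrink
        ys = cy + (yc - cy) * shrink
        rows, cols = _surface_lookup(scene, xs, ys)
        z = _bilinear(scene.height, rows, cols)
    return xs, ys, z, rows, cols


def _shadow_mask(scene: Scene, xs, ys, zs, n_steps: int = 24) -> np.ndarray:
    """True where the line of sight to the projector is blocked."""
    px, py, pz = scene.projector.position
    blocked = np.zeros(xs.shape, dtype=bool)
    for k in range(1, n_steps):
        t = k / n_steps
        x = xs + (px - xs) * t
        y = ys + (py - ys) * t
        z = zs + (pz - zs) * t
        rows, cols = _surface_lookup(scene, x, y)
        hsurf = _bilinear(scene.height, rows, cols)
        blocked |= hsurf > z + 1e-6
    return blocked


def render(
    scene: Scene,
    pattern: FringePattern,
    mode: str = "fast",
    cfg: Optional[TransportConfig] = None,
    exposure: float | str = "auto",
    shadows: bool = True,
) -> ExposedImage:
    """Render one exposure-tagged image of the scene under the pattern."""
    if mode == "fast":
        physical = _render_fast(scene, pattern, shadows=shadows)
    elif mode == "mc":
        physical = _render_mc(scene, pattern, cfg or TransportConfig())
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    physical = physical + scene.ambient
    t = auto_exposure(physical) if exposure == "auto" else float(exposure)
    return ExposedImage(
        pixels=physical * 2.0 ** (-t),
        t_exposure=t,
        pixel_pitch=scene.camera.pixel_pitch,
    )


def _render_fast(scene: Scene, pattern: FringePattern, shadows: bool = True) -> np.ndarray:
    xs, ys, zs, rows, cols = _find_surface(scene)
    mu_a = _bilinear(scene.mu_a, rows, cols)
    mu_sp = _bilinear(scene.mu_s_prime, rows, cols)

    # surface normal from the height gradient (y is the row axis)
    dy, dx = np.gradient(scene.height, *scene.camera.pixel_pitch)
    gx = _bilinear(dx, rows, cols)
    gy = _bilinear(dy, rows, cols)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)

    px, py, pz = scene.projector.position
    vx, vy, vz = px - xs, py - ys, pz - zs
    r = np.sqrt(vx**2 + vy**2 + vz**2)
    cos_i = (-gx * vx - gy * vy + vz) / (norm * r)
    cos_i = np.clip(cos_i, 0.0, None)
    irradiance = scene.projector.power / (4.0 * math.pi * r**2) * cos_i
    if shadows and not scene.is_planar:
        irradiance[_shadow_mask(scene, xs, ys, zs)] = 0.0

    # projector ray continued to the reference plane defines the pattern phase
    u = pz / np.maximum(pz - zs, 1e-9)
    qx = px + (xs - px) * u
    qy = py + (ys - py) * u
    coord = qx if pattern.orientation == "x" else qy

    if pattern.fx > 0 and pattern.amplitude > 0:
        # realised local frequency on the surface (cycles per mm of arc)
        axis = 1 if pattern.orientation == "x" else 0
        pitch = scene.camera.pixel_pitch[axis]
        dcoord = np.gradient(coord, axis=axis) / pitch
        lateral = np.gradient(xs if axis == 1 else ys, axis=axis) / pitch
        dzs = np.gradient(zs, axis=axis) / pitch
        arc = np.sqrt(lateral**2 + dzs**2)
        fx_local = pattern.fx * np.abs(dcoord) / np.maximum(arc, 1e-9)
        fx_local = np.clip(fx_local, 0.0, None)
    else:
        fx_local = 0.0

    rd_dc = diffuse_reflectance_fx(None, 0.0, mu_a=mu_a, mu_s_prime=mu_sp, n=scene.n)
    rd_ac = diffuse_reflectance_fx(None, fx_local, mu_a=mu_a, mu_s_prime=mu_sp, n=scene.n)
    ac = pattern.amplitude * np.sin(pattern.omega * coord + pattern.phase)
    img = irradiance * (pattern.offset * rd_dc + ac * rd_ac)

    if scene.specular:
        ks = float(scene.specular.get("ks", 0.05))
        m = float(scene.specular.get("shininess", 40.0))
        cx, cy, cz = scene.camera.position
        wx, wy, wz = cx - xs, cy - ys, cz - zs
        wn = np.sqrt(wx**2 + wy**2 + wz**2)
        hx, hy, hz = vx / r + wx / wn, vy / r + wy / wn, vz / r + wz / wn
        hn = np.sqrt(hx**2 + hy**2 + hz**2)
        ndoth = np.clip((-gx * hx - gy * hy + hz) / (norm * hn), 0.0, 1.0)
        img = img + ks * irradiance * pattern.value(coord) * ndoth**m
    return np.clip(img, 0.0, None)


def illumination_gain(height: np.ndarray, camera: Camera, projector: Projector) -> np.ndarray:
    """Per-pixel illumination gain of a surface relative to the flat plane.

    Surface elevation moves each point closer to the projector
    (inverse-square gain) and tilts it away from the incident direction
    (cosine loss); the returned factor is the ratio of the two incident
    irradiances,

        G = [cos(theta_i) / r^2]_surface / [cos(theta_i) / r^2]_plane.

    Dividing measured modulation maps by G is the standard profile-based
    intensity correction of SFDI: the ``height`` argument is the
    *per-pixel* height of the surface point each camera pixel sees —
    exactly what the fringe-profilometry pipeline returns — closing the
    shape-then-optical-properties loop.  Pixels facing away from the
    projector come out as 0 and should be masked downstream.
    """
    xs, ys, zs, gx, gy = _per_pixel_surface(height, camera)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    px, py, pz = projector.position
    vx, vy, vz = px - xs, py - ys, pz - zs
    r2 = vx**2 + vy**2 + vz**2
    cos_i = np.clip((-gx * vx - gy * vy + vz) / (norm * np.sqrt(r2)), 0.0, None)
    xc, yc = camera.reference_grid()
    r2_ref = (px - xc) ** 2 + (py - yc) ** 2 + pz**2
    cos_ref = pz / np.sqrt(r2_ref)
    return (cos_i / r2) / (cos_ref / r2_ref)


def _per_pixel_surface(height: np.ndarray, camera: Camera):
    """Surface positions and slopes from a per-pixel height map.

    A pixel whose reference-plane coordinate is (x_c, y_c) and whose
    viewed point has height z sees the surface at (x_c, y_c) scaled
    toward the camera axis by (1 - z / z_cam); slopes are taken with
    respect to the true lateral surface coordinates.
    """
    zs = np.nan_to_num(np.asarray(height, dtype=float), nan=0.0)
    xc, yc = camera.reference_grid()
    cx, cy, cz = camera.position
    shrink = 1.0 - zs / cz
    xs = cx + (xc - cx) * shrink
    ys = cy + (yc - cy) * shrink
    dz_r, dz_c = np.gradient(zs)
    dx_c = np.gradient(xs, axis=1)
    dy_r = np.gradient(ys, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gx = np.where(np.abs(dx_c) > 1e-12, dz_c / dx_c, 0.0)
        gy = np.where(np.abs(dy_r) > 1e-12, dz_r / dy_r, 0.0)
    return xs, ys, zs, gx, gy


def local_frequency(
    height: np.ndarray,
    camera: Camera,
    projector: Projector,
    fx: float,
    orientation: str = "y",
) -> np.ndarray:
    """Locally realised projected frequency on an elevated surface.

    On a tilted surface the fringe pattern is stretched along the
    surface arc, so the medium experiences a lower spatial frequency
    than the nominal ``fx`` projected onto the reference plane.  The
    estimate mirrors the forward renderer: the projector-ray pattern
    coordinate and the surface arc length are both differentiated along
    the fringe axis.  ``height`` is the per-pixel height map recovered
    by profilometry.  Used by the optional per-pixel frequency
    correction of the inverse pipeline.
    """
    xs, ys, zs, _, _ = _per_pixel_surface(height, camera)
    px, py, pz = projector.position
    u = pz / np.maximum(pz - zs, 1e-9)
    qx = px + (xs - px) * u
    qy = py + (ys - py) * u
    coord = qx if orientation == "x" else qy
    axis = 1 if orientation == "x" else 0
    dcoord = np.gradient(coord, axis=axis)
    lateral = np.gradient(xs if axis == 1 else ys, axis=axis)
    dz = np.gradient(zs, axis=axis)
    arc = np.sqrt(lateral**2 + dz**2)
    return fx * np.abs(dcoord) / np.maximum(arc, 1e-9)


@njit(cache=True)
def _mc_image_kernel(
    mu_a, mu_s, g, n, entry_x, entry_y, weight, seed,
    x0, y0, pitch_x, pitch_y, nrow, ncol, max_events, roulette_w,
):
    np.random.seed(seed)
    img = np.zeros((nrow, ncol))
    mu_t = mu_a + mu_s
    rsp = ((n - 1.0) / (n + 1.0)) ** 2
    for ip in range(entry_x.shape[0]):
        w = weight[ip] * (1.0 - rsp)
        # roulette plays relative to the launch weight of this photon
        w_floor = roulette_w * w
        x = entry_x[ip]
        y = entry_y[ip]
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        events = 0
        alive = True
        while alive:
            s = -math.log(np.random.random()) / mu_t
            zn = z + uz * s
            if uz < 0.0 and zn < 0.0:
                t = -z / uz
                x += ux * t
                y += uy * t
                z = 0.0
                ci = -uz
                si2 = 1.0 - ci * ci
                st2 = n * n * si2
                if st2 >= 1.0:
                    refl = 1.0
                else:
                    ct = math.sqrt(1.0 - st2)
                    rs_ = (n * ci - ct) / (n * ci + ct)
                    rp_ = (n * ct - ci) / (n * ct + ci)
                    refl = 0.5 * (rs_ * rs_ + rp_ * rp_)
                esc = w * (1.0 - refl)
                col = int((x - x0) / pitch_x)
                row = int((y - y0) / pitch_y)
                if 0 <= row < nrow and 0 <= col < ncol:
                    img[row, col] += esc
                w *= refl
                uz = -uz
                if w <= 0.0:
                    alive = False
                continue
            x += ux * s
            y += uy * s
            z = zn
            events += 1
            w *= mu_s / mu_t
            if w <= 0.0:
                alive = False
                continue
            if g == 0.0:
                cost = 2.0 * np.random.random() - 1.0
            else:
                frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cost = (1.0 + g * g - frac * frac) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
            sint = math.sqrt(1.0 - cost * cost)
            phi = 2.0 * math.pi * np.random.random()
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                den = math.sqrt(1.0 - uz * uz)
                uxn = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                uyn = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                uzn = -sint * cosp * den + uz * cost
                nrm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / nrm
                uy = uyn / nrm
                uz = uzn / nrm
            if w < w_floor:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    alive = False
            if alive and events >= max_events:
                alive = False
    return img


def _render_mc(scene: Scene, pattern: FringePattern, cfg: TransportConfig) -> np.ndarray:
    """Photon-traced image of a homogeneous planar scene."""
    if not scene.is_planar or not scene.is_homogeneous:
        raise ValueError("mc render mode supports homogeneous planar scenes only")
    props = OpticalProperties.from_reduced(
        float(scene.mu_a.flat[0]), float(scene.mu_s_prime.flat[0]), g=scene.g, n=scene.n
    )
    cam = scene.camera
    xc, yc = cam.reference_grid()
    px, py, pz = scene.projector.position
    r = np.sqrt((px - xc) ** 2 + (py - yc) ** 2 + pz**2)
    cos_i = pz / r
    irr = scene.projector.power / (4.0 * math.pi * r**2) * cos_i
    coord = xc if pattern.orientation == "x" else yc
    incident = irr * pattern.value(coord)

    pitch_y, pitch_x = cam.pixel_pitch
    area = pitch_x * pitch_y
    p_tot = float(np.sum(incident)) * area
    prob = (incident / incident.sum()).ravel()
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(prob.size, size=cfg.n_photons, p=prob)
    rows, cols = np.unravel_index(idx, incident.shape)
    # jitter within the pixel
    ex, ey = cam.extent
    x0 = cam.position[0] - ex / 2.0
    y0 = cam.position[1] - ey / 2.0
    entry_x = x0 + (cols + rng.random(cfg.n_photons)) * pitch_x
    entry_y = y0 + (rows + rng.random(cfg.n_photons)) * pitch_y
    weight = np.full(cfg.n_photons, p_tot / cfg.n_photons)
    img = _mc_image_kernel(
        props.mu_a,
        props.mu_s,
        props.g,
        props.n,
        entry_x,
        entry_y,
        weight,
        cfg.seed,
        x0,
        y0,
        pitch_x,
        pitch_y,
        cam.resolution[0],
        cam.resolution[1],
        cfg.max_events,
        cfg.roulette_threshold,
    )
    return img / area  # exitance per unit area, same units as fast mode


def render_phase_stack(
    scene: Scene,
    fx,
    phases=EQUISPACED_PHASES,
    mode: str = "fast",
    cfg: Optional[TransportConfig] = None,
    orientation: str = "y",
    exposure: float | str = "auto",
    shadows: bool = True,
):
    """Render the three-phase stack at one spatial frequency.

    The three phases must be equispaced (the demodulator depends on it);
    all three share the exposure chosen for the first phase so the stack
    stays co-registered in intensity as well as in geometry.
    Returns an :class:`sfdi_forge.sfdi.ImageStack` of exposure-corrected
    images.
    """
    from .sfdi import ImageStack  # local import to avoid a cycle

    phases = tuple(float(p) for p in phases)
    if len(phases) != 3:
        raise ValueError("exactly 3 phases are required")
    d1 = (phases[1] - phases[0]) % (2 * math.pi)
    d2 = (phases[2] - phases[1]) % (2 * math.pi)
    if not (math.isclose(d1, d2, abs_tol=1e-9) and math.isclose(d1, 2 * math.pi / 3, abs_tol=1e-9)):
        raise ValueError("phases must be equispaced by 2*pi/3")

    f = fx.fx if isinstance(fx, SpatialFrequency) else float(fx)
    images = []
    t_shared = None
    for k, ph in enumerate(phases):
        pat = FringePattern(fx=f, phase=ph, orientation=orientation)
        sub_cfg = None
        if cfg is not None:
            sub_cfg = replace(cfg, seed=(cfg.seed + 7919 * k) % 2**31)
        img = render(
            scene,
            pat,
            mode=mode,
            cfg=sub_cfg,
            exposure=(exposure if t_shared is None else t_shared),
            shadows=shadows,
        )
        if t_shared is None:
            t_shared = img.t_exposure
        images.append(exposure_correct(img))
    return ImageStack(images=np.stack(images), fx=f, phases=phases)
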