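"""Virtual double-integrating-sphere (DIS) experiment and slab inversion.

A thin slab of the material under test sits between a reflectance sphere
and a transmission sphere.  Detector powers are reduced to the
normalised reflectance MR and transmittance MT,

    MR = r_std (R2_sample - R2_empty) / (R2_std - R2_empty)
    MT = (T2_sample - T2_blocked) / (T2_open - T2_blocked)

which are then inverted to (mu_a, mu_s') by matching a seeded
Monte-Carlo slab forward model.  Sphere throughput is modelled by the
standard integrating-sphere gain factor by default (the measurands MR
and MT normalise it out to first order); an explicit stochastic
cavity-bounce mode exists for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import least_squares

from .optics import OpticalProperties
from .transport import TransportConfig, run_slab

__all__ = [
    "SphereConfig",
    "DISMeasurementSet",
    "simulate_dis",
    "normalized_reflectance",
    "normalized_transmittance",
    "SlabForwardModel",
    "invert_slab",
]


@dataclass(frozen=True)
class SphereConfig:
    """Integrating-sphere geometry and reference standard.

    Defaults: 100 mm diameter spheres with wall reflectance 0.99,
    10 mm square ports, a 1 mm sample and a 0.7 reflectance standard.
    """

    sphere_diameter: float = 100.0
    wall_reflectance: float = 0.99
    port_side: float = 10.0
    sample_thickness: float = 1.0
    baffled: bool = True
    r_std: float = 0.7
    stray_fraction: float = 0.002  # stray-light power fraction on each detector

    def __post_init__(self) -> None:
        if not 0.0 < self.wall_reflectance < 1.0:
            raise ValueError(
                f"nonphysical sphere: wall reflectance must be in (0, 1), "
                f"got {self.wall_reflectance}"
            )
        if self.port_side >= self.sphere_diameter:
            raise ValueError("port side must be smaller than the sphere diameter")
        if self.sample_thickness <= 0:
            raise ValueError("sample thickness must be > 0")

    @property
    def port_fraction(self) -> float:
        """Open-port area fraction of one square port."""
        return self.port_side**2 / (math.pi * self.sphere_diameter**2)


@dataclass(frozen=True)
class DISMeasurementSet:
    """Raw detected powers (W) of the two spheres plus the standard value.

    ``R2_*`` are reflectance-sphere powers with the sample, the
    reflectance standard, and the empty port in place; ``T2_*`` are
    transmission-sphere powers with the sample, the open beam, and the
    blocked beam.
    """

    R2_sample: float
    R2_std: float
    R2_empty: float
    T2_sample: float
    T2_open: float
    T2_blocked: float
    r_std: float = 0.7

    def __post_init__(self) -> None:
        for name in ("R2_sample", "R2_std", "R2_empty", "T2_sample", "T2_open", "T2_blocked"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.T2_open <= self.T2_blocked:
            raise ValueError("T2_open must exceed T2_blocked")
        if self.R2_std <= self.R2_empty:
            raise ValueError("R2_std must exceed R2_empty")

    def to_csv(self, path) -> None:
        names = ["R2_sample", "R2_std", "R2_empty", "T2_sample", "T2_open", "T2_blocked", "r_std"]
        with open(path, "w") as fh:
            fh.write("quantity,power_W\n")
            for nm in names:
                fh.write(f"{nm},{getattr(self, nm)!r}\n")


def _sphere_gain_throughput(wall_reflectance: float, n_ports: int, port_fraction: float) -> float:
    """Analytic multiple-reflection gain of an integrating sphere."""
    loss = 1.0 - n_ports * port_fraction
    return wall_reflectance / (1.0 - wall_reflectance * loss)


def _sphere_gain_mc(
    wall_reflectance: float,
    n_ports: int,
    port_fraction: float,
    rng: np.random.Generator,
    n_rays: int = 50_000,
) -> float:
    """Stochastic cavity-bounce estimate of the sphere gain (validation mode).

    Each ray bounces on the wall (absorbed with probability
    1 - wall_reflectance) and escapes through a port with the open-port
    probability after each bounce; the expected number of surviving wall
    re-emissions equals the analytic throughput gain.
    """
    escape = n_ports * port_fraction
    gains = np.zeros(n_rays)
    alive = np.ones(n_rays, dtype=bool)
    while alive.any():
        survive = rng.random(n_rays) < wall_reflectance
        alive &= survive
        gains[alive] += 1.0
        stay = rng.random(n_rays) >= escape
        alive &= stay
    return float(np.mean(gains))


def simulate_dis(
    props: OpticalProperties,
    sphere: SphereConfig | None = None,
    cfg: TransportConfig | None = None,
    source_power: float = 5.0,
    mode: str = "throughput",
) -> DISMeasurementSet:
    """Simulate the six DIS detector powers for a thin slab sample.

    The slab response comes from the seeded Monte-Carlo transport model;
    sphere multiple reflections are applied as the analytic throughput
    gain (default) or via a stochastic cavity-bounce estimate
    (``mode="mc"``).  The baffle excludes specular sample returns, so the
    reflectance channel sees the diffuse reflectance only.
    """
    sphere = sphere or SphereConfig()
    cfg = cfg or TransportConfig()
    slab = run_slab(props, sphere.sample_thickness, cfg)
    rd = slab.reflectance
    tt = slab.transmittance

    f = sphere.port_fraction
    if mode == "throughput":
        g_r = _sphere_gain_throughput(sphere.wall_reflectance, 2, f)
        g_t = _sphere_gain_throughput(sphere.wall_reflectance, 1, f)
    elif mode == "mc":
        rng = np.random.default_rng(cfg.seed + 101)
        g_r = _sphere_gain_mc(sphere.wall_reflectance, 2, f, rng)
        g_t = _sphere_gain_mc(sphere.wall_reflectance, 1, f, rng)
    else:
        raise ValueError(f"unknown sphere mode {mode!r}")

    stray = sphere.stray_fraction * source_power
    p = source_power
    return DISMeasurementSet(
        R2_sample=p * g_r * rd + stray,
        R2_std=p * g_r * sphere.r_std + stray,
        R2_empty=stray,
        T2_sample=p * g_t * tt + stray,
        T2_open=p * g_t + stray,
        T2_blocked=stray,
        r_std=sphere.r_std,
    )


def normalized_reflectance(m: DISMeasurementSet) -> float:
    """MR = r_std (R2_sample - R2_empty) / (R2_std - R2_empty)."""
    den = m.R2_std - m.R2_empty
    if den <= 0:
        raise ValueError("calibration failure: R2_std - R2_empty must be > 0")
    return m.r_std * (m.R2_sample - m.R2_empty) / den


def normalized_transmittance(m: DISMeasurementSet) -> float:
    """MT = (T2_sample - T2_blocked) / (T2_open - T2_blocked)."""
    den = m.T2_open - m.T2_blocked
    if den <= 0:
        raise ValueError("calibration failure: T2_open - T2_blocked must be > 0")
    return (m.T2_sample - m.T2_blocked) / den


class SlabForwardModel:
    """Smooth (MR, MT) forward surfaces over a log-spaced property grid.

    Each grid node is a seeded Monte-Carlo slab run; smoothing bivariate
    splines in (log mu_a, log mu_s') tame the residual counting noise.
    Built once per (g, n, thickness) and cached.
    """

    def __init__(
        self,
        g: float = 0.8,
        n: float = 1.4,
        thickness: float = 1.0,
        mu_a_range: tuple = (0.01, 0.45),
        mu_sp_range: tuple = (0.3, 8.5),
        shape: tuple = (14, 14),
        n_photons: int = 8000,
        seed: int = 1234,
    ) -> None:
        self.g = g
        self.n = n
        self.thickness = thickness
        self.log_mu_a = np.linspace(*np.log(mu_a_range), shape[0])
        self.log_mu_sp = np.linspace(*np.log(mu_sp_range), shape[1])
        mr = np.empty(shape)
        mt = np.empty(shape)
        cfg = TransportConfig(
            n_photons=n_photons, seed=seed, roulette_threshold=1e-3
        )
        for i, la in enumerate(self.log_mu_a):
            for j, ls in enumerate(self.log_mu_sp):
                props = OpticalProperties.from_reduced(
                    math.exp(la), math.exp(ls), g=g, n=n
                )
                node_cfg = replace(cfg, seed=(seed + 977 * i + 13 * j) % 2**31)
                res = run_slab(props, thickness, node_cfg)
                mr[i, j] = res.reflectance
                mt[i, j] = res.transmittance
        sigma2 = 0.25 / n_photons
        s = mr.size * sigma2
        self._mr = RectBivariateSpline(self.log_mu_a, self.log_mu_sp, mr, s=s)
        self._mt = RectBivariateSpline(self.log_mu_a, self.log_mu_sp, mt, s=s)
        self._nodes_mr = mr
        self._nodes_mt = mt

    def mr(self, mu_a, mu_sp):
        return self._mr(np.log(mu_a), np.log(mu_sp), grid=False)

    def mt(self, mu_a, mu_sp):
        return self._mt(np.log(mu_a), np.log(mu_sp), grid=False)

    @property
    def bounds_log(self):
        return (
            (self.log_mu_a[0], self.log_mu_a[-1]),
            (self.log_mu_sp[0], self.log_mu_sp[-1]),
        )


_MODEL_CACHE: dict = {}


def get_slab_forward_model(g: float = 0.8, n: float = 1.4, thickness: float = 1.0, **kw) -> SlabForwardModel:
    key = (g, n, thickness, tuple(sorted(kw.items())))
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = SlabForwardModel(g=g, n=n, thickness=thickness, **kw)
    return _MODEL_CACHE[key]


def invert_slab(
    MR: float,
    MT: float,
    g: float = 0.8,
    n: float = 1.4,
    thickness: float = 1.0,
    forward: SlabForwardModel | None = None,
) -> OpticalProperties:
    """Invert (MR, MT) to optical properties via the slab forward model.

    A coarse grid search over the forward surfaces seeds a bounded
    least-squares refinement in (log mu_a, log mu_s').  A non-interacting
    sample (MR ~ 0, MT ~ clear-slab transmittance) short-circuits to
    zero coefficients.
    """
    if MR < 0 or not 0 <= MT <= 1:
        raise ValueError("require MR >= 0 and 0 <= MT <= 1")
    # clear-medium short circuit
    r_normal = ((n - 1.0) / (n + 1.0)) ** 2
    t_clear = (1.0 - r_normal) / (1.0 + r_normal)
    if MR <= 1e-4 and MT >= t_clear - 1e-3:
        return OpticalProperties(mu_a=0.0, mu_s=0.0, g=g, n=n)

    fwd = forward or get_slab_forward_model(g=g, n=n, thickness=thickness)
    la_grid = np.linspace(fwd.log_mu_a[0], fwd.log_mu_a[-1], 40)
    ls_grid = np.linspace(fwd.log_mu_sp[0], fwd.log_mu_sp[-1], 40)
    LA, LS = np.meshgrid(la_grid, ls_grid, indexing="ij")
    res2 = (fwd._mr(la_grid, ls_grid) - MR) ** 2 + (fwd._mt(la_grid, ls_grid) - MT) ** 2
    i0, j0 = np.unravel_index(np.argmin(res2), res2.shape)
    x0 = np.array([LA[i0, j0], LS[i0, j0]])

    (la_lo, la_hi), (ls_lo, ls_hi) = fwd.bounds_log

    def resid(x):
        return np.array(
            [
                float(fwd._mr(x[0], x[1], grid=False)) - MR,
                float(fwd._mt(x[0], x[1], grid=False)) - MT,
            ]
        )

    sol = least_squares(
        resid, x0, bounds=([la_lo, ls_lo], [la_hi, ls_hi]), xtol=1e-12, ftol=1e-12
    )
    r = resid(sol.x)
    scale = max(MR, MT, 1e-3)
    if np.linalg.norm(r) / scale > 0.1:
        corners = {
            (a, sgrid): (float(fwd._mr(a, sgrid, grid=False)), float(fwd._mt(a, sgrid, grid=False)))
            for a in (la_lo, la_hi)
            for sgrid in (ls_lo, ls_hi)
        }
        raise ValueError(
            f"no consistent (mu_a, mu_s') in the search box for MR={MR:.4f}, "
            f"MT={MT:.4f}; residual {np.linalg.norm(r):.4f}. "
            f"Forward-surface corners (log-space -> (MR, MT)): {corners}"
        )
    return OpticalProperties.from_reduced(
        math.exp(sol.x[0]), math.exp(sol.x[1]), g=g, n=n
    )
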