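"""The SFDI inverse pipeline.

Three-phase demodulation separates each pixel's response into a DC and
an AC modulation amplitude; calibration against a reference material of
known properties converts modulation to diffuse reflectance; and a
look-up table (model-based on diffuse-reflectance axes, or empirically
derived on raw modulation axes) inverts the (DC, AC) pair to absorption
and reduced scattering coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    LinearNDInterpolator,
    NearestNDInterpolator,
    RegularGridInterpolator,
)

from .optics import DEFAULT_FX, OpticalProperties, SpatialFrequency, diffuse_reflectance_fx
from .transport import TransportConfig, hankel_rd, run_halfspace

__all__ = [
    "ImageStack",
    "LookupTable",
    "PropertyMaps",
    "demodulate",
    "calibrate",
    "build_model_lut",
    "build_empirical_lut",
    "invert_lut",
    "recover_maps",
    "region_median",
]


@dataclass
class ImageStack:
    """Three exposure-corrected, co-registered intensity maps.

    ``images`` has shape (3, H, W); ``phases`` are the three equispaced
    phase offsets of the projected sinusoid at spatial frequency ``fx``.
    """

    images: np.ndarray
    fx: float
    phases: tuple = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != 3:
            raise ValueError("ImageStack requires 3 images of equal shape")
        ph = np.asarray(self.phases, dtype=float)
        d = np.diff(ph) % (2 * math.pi)
        if not np.allclose(d, 2 * math.pi / 3, atol=1e-9):
            raise ValueError("phases must be equispaced by 2*pi/3")


def demodulate(stack: ImageStack):
    """Per-pixel AC and DC modulation amplitudes of a three-phase stack.

    Uses the standard three-phase identities

        M_DC = (I1 + I2 + I3) / 3
        M_AC = (sqrt(2)/3) sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)

    which are exact for I_k = DC + AC sin(theta + phi_k) with equispaced
    phi_k.  Returns ``(M_AC, M_DC)``.
    """
    i1, i2, i3 = stack.images
    m_dc = (i1 + i2 + i3) / 3.0
    m_ac = (math.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    return m_ac, m_dc


def calibrate(
    sample: tuple,
    reference: tuple,
    ref_props: OpticalProperties,
    fx,
):
    """Convert modulation maps to diffuse-reflectance maps.

    ``sample`` and ``reference`` are ``(M_AC, M_DC)`` pairs imaged under
    identical geometry and exposure handling.  The reference of known
    properties carries the system's modulation transfer function, so

        Rd_sample = (M_sample / M_reference) * Rd_model(ref_props)

    per pixel and per frequency component.  Pixels with zero reference
    modulation are masked (NaN) and reported via the returned mask.
    """
    f = fx.fx if isinstance(fx, SpatialFrequency) else float(fx)
    s_ac, s_dc = np.asarray(sample[0], float), np.asarray(sample[1], float)
    r_ac, r_dc = np.asarray(reference[0], float), np.asarray(reference[1], float)
    rd_model_dc = diffuse_reflectance_fx(ref_props, 0.0)
    rd_model_ac = diffuse_reflectance_fx(ref_props, f)
    bad = (r_dc <= 0) | (r_ac <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rd_dc = np.where(bad, np.nan, s_dc / np.where(bad, 1.0, r_dc) * rd_model_dc)
        rd_ac = np.where(bad, np.nan, s_ac / np.where(bad, 1.0, r_ac) * rd_model_ac)
    return rd_dc, rd_ac, bad


@dataclass
class LookupTable:
    """Grid mapping (DC, AC) values to (mu_a, mu_s').

    ``kind`` is ``"model"`` (axes are diffuse reflectance, from a light
    propagation model) or ``"empirical"`` (axes are raw modulation,
    derived from calibration measurements).  Queries inside the convex
    hull of the nodes use the recorded interpolation policy; queries
    outside fall back to the nearest node and are flagged.
    """

    dc: np.ndarray
    ac: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    kind: str = "model"
    interpolation: str = "bicubic"  # or "nearest"
    fx: float = DEFAULT_FX
    meta: dict = field(default_factory=dict)
    _interp: object = field(default=None, repr=False)
    _nearest: object = field(default=None, repr=False)
    _hull: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("dc", "ac", "mu_a", "mu_s_prime"):
            setattr(self, name, np.asarray(getattr(self, name), float).ravel())
        if not (len(self.dc) == len(self.ac) == len(self.mu_a) == len(self.mu_s_prime)):
            raise ValueError("node arrays must have equal length")
        if len(self.dc) == 0:
            raise ValueError("empty look-up table")
        if self.interpolation not in ("bicubic", "linear", "nearest"):
            raise ValueError(f"unknown interpolation policy {self.interpolation!r}")
        self._build()

    def _build(self) -> None:
        pts = np.column_stack([self.dc, self.ac])
        vals = np.column_stack([self.mu_a, self.mu_s_prime])
        self._nearest = NearestNDInterpolator(pts, vals)
        if self.interpolation == "nearest" or len(self.dc) < 4:
            self._interp = None
        elif self.interpolation == "bicubic":
            self._interp = CloughTocher2DInterpolator(pts, vals, rescale=True)
        else:
            self._interp = LinearNDInterpolator(pts, vals, rescale=True)

    def query(self, dc, ac):
        """Look up (mu_a, mu_s') for (DC, AC) values.

        Returns ``(mu_a, mu_s_prime, oob_mask)`` where the mask marks
        queries resolved by the nearest-node fallback (outside the node
        hull or non-finite inputs).
        """
        dc = np.asarray(dc, float)
        ac = np.asarray(ac, float)
        scalar = dc.ndim == 0 and ac.ndim == 0
        dc, ac = np.atleast_1d(dc), np.atleast_1d(ac)
        finite = np.isfinite(dc) & np.isfinite(ac)
        out = np.full(dc.shape + (2,), np.nan)
        if self._interp is not None:
            out[finite] = self._interp(dc[finite], ac[finite])
        oob = ~np.isfinite(out[..., 0])
        need = oob & finite
        if np.any(need):
            out[need] = self._nearest(dc[need], ac[need])
        mu_a = np.clip(out[..., 0], 0.0, None)
        mu_sp = np.clip(out[..., 1], 0.0, None)
        if scalar:
            return float(mu_a[0]), float(mu_sp[0]), bool(oob[0])
        return mu_a, mu_sp, oob

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("dc", "ac", "mu_a", "mu_s_prime"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["kind"] = self.kind
            f.attrs["interpolation"] = self.interpolation
            f.attrs["fx"] = self.fx

    @classmethod
    def load(cls, path) -> "LookupTable":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                dc=f["dc"][:],
                ac=f["ac"][:],
                mu_a=f["mu_a"][:],
                mu_s_prime=f["mu_s_prime"][:],
                kind=str(f.attrs["kind"]),
                interpolation=str(f.attrs["interpolation"]),
                fx=float(f.attrs["fx"]),
            )

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.dc, self.ac, self.mu_a, self.mu_s_prime]),
            delimiter=",",
            header="dc,ac,mu_a_per_mm,mu_s_prime_per_mm",
            comments="",
        )


@dataclass
class PropertyMaps:
    """Recovered per-pixel optical-property maps (mm^-1).

    ``oob_mask`` flags pixels resolved by the out-of-hull nearest-node
    fallback; they are reported, never silently interpolated.
    """

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    oob_mask: np.ndarray

    def __post_init__(self) -> None:
        ok = np.isfinite(self.mu_a)
        if np.any(self.mu_a[ok] < 0) or np.any(self.mu_s_prime[np.isfinite(self.mu_s_prime)] < 0):
            raise ValueError("property maps must be non-negative where defined")


# paper-era ranges for the model LUT: mu_a 0.001-0.3, mu_s' 0.1-8.5 mm^-1
MODEL_LUT_MU_A = (0.001, 0.3)
MODEL_LUT_MU_SP = (0.1, 8.5)


def build_model_lut(
    fx=DEFAULT_FX,
    mu_a_range: tuple = MODEL_LUT_MU_A,
    mu_sp_range: tuple = MODEL_LUT_MU_SP,
    shape: tuple = (30, 30),
    forward: str = "diffusion",
    n: float = 1.4,
    g: float = 0.8,
    cfg: Optional[TransportConfig] = None,
    interpolation: str = "bicubic",
) -> LookupTable:
    """Model-based LUT: (Rd_DC, Rd_AC) nodes over a log-spaced property grid.

    ``forward`` selects the diffusion closed form (fast, default) or the
    Monte-Carlo transport model (``"mc"``; radial response Hankel-
    transformed to fx — use small grids, each node is a full MC run).
    """
    f = fx.fx if isinstance(fx, SpatialFrequency) else float(fx)
    mu_a = np.geomspace(*mu_a_range, shape[0])
    mu_sp = np.geomspace(*mu_sp_range, shape[1])
    ga, gs = np.meshgrid(mu_a, mu_sp, indexing="ij")
    if forward == "diffusion":
        dc = diffuse_reflectance_fx(None, 0.0, mu_a=ga, mu_s_prime=gs, n=n)
        ac = diffuse_reflectance_fx(None, f, mu_a=ga, mu_s_prime=gs, n=n)
    elif forward == "mc":
        cfg = cfg or TransportConfig(n_photons=20_000)
        dc = np.empty(shape)
        ac = np.empty(shape)
        for i in range(shape[0]):
            for j in range(shape[1]):
                props = OpticalProperties.from_reduced(ga[i, j], gs[i, j], g=g, n=n)
                seed = (cfg.seed + 7919 * i + 103 * j) % 2**31
                rr = run_halfspace(props, TransportConfig(
                    n_photons=cfg.n_photons, seed=seed,
                    roulette_threshold=cfg.roulette_threshold,
                    max_events=cfg.max_events))
                dc[i, j] = hankel_rd(rr, 0.0)
                ac[i, j] = hankel_rd(rr, f)
    else:
        raise ValueError(f"unknown forward model {forward!r}")

    # inversion is ambiguous if the node surface folds over
    if np.any(np.diff(dc, axis=0) >= 0):
        warnings.warn("model LUT DC surface is not strictly decreasing in mu_a", stacklevel=2)
    return LookupTable(
        dc=dc, ac=ac, mu_a=ga, mu_s_prime=gs,
        kind="model", interpolation=interpolation, fx=f,
        meta={"forward": forward, "shape": shape},
    )


def build_empirical_lut(
    calibration: Sequence[tuple],
    fx=DEFAULT_FX,
    grid_shape: tuple = (100, 100),
    extend: float = 0.5,
    interpolation: str = "bicubic",
) -> LookupTable:
    """Empirically derived LUT from a small set of calibration measurements.

    ``calibration`` holds ``((dc, ac), props)`` pairs — typically the
    nine materials of a 3x3 property lattice.  The measured DC and AC
    surfaces are first linearly interpolated over the property lattice
    and linearly extrapolated ``extend`` cells beyond each edge, lifting
    the 9 nodes to a dense ``grid_shape`` table (default 100 x 100).
    Queries then use bicubic-style interpolation in (DC, AC) space.
    """
    f = fx.fx if isinstance(fx, SpatialFrequency) else float(fx)
    mu_a_vals = np.array(sorted({round(p.mu_a, 12) for _, p in calibration}))
    mu_sp_vals = np.array(sorted({round(p.mu_s_prime, 12) for _, p in calibration}))
    na, ns = len(mu_a_vals), len(mu_sp_vals)
    if na < 2 or ns < 2 or na * ns != len(calibration):
        raise ValueError(
            "calibration points must form a non-degenerate property lattice"
        )
    dc_nodes = np.full((na, ns), np.nan)
    ac_nodes = np.full((na, ns), np.nan)
    for (dc, ac), p in calibration:
        i = int(np.argmin(np.abs(mu_a_vals - p.mu_a)))
        j = int(np.argmin(np.abs(mu_sp_vals - p.mu_s_prime)))
        dc_nodes[i, j] = dc
        ac_nodes[i, j] = ac
    if np.any(~np.isfinite(dc_nodes)):
        raise ValueError("calibration lattice has missing nodes")
    # degenerate surface: all points collinear in (DC, AC)
    pts = np.column_stack([dc_nodes.ravel(), ac_nodes.ravel()])
    spread = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-12 + 1e-9 * np.abs(pts).max()) < 2:
        raise ValueError("degenerate calibration surface: points are collinear in (DC, AC)")

    itp_dc = RegularGridInterpolator(
        (mu_a_vals, mu_sp_vals), dc_nodes, bounds_error=False, fill_value=None
    )
    itp_ac = RegularGridInterpolator(
        (mu_a_vals, mu_sp_vals), ac_nodes, bounds_error=False, fill_value=None
    )
    da = np.diff(mu_a_vals).mean() * extend
    ds = np.diff(mu_sp_vals).mean() * extend
    ga = np.linspace(mu_a_vals[0] - da, mu_a_vals[-1] + da, grid_shape[0])
    gs = np.linspace(max(mu_sp_vals[0] - ds, 0.05), mu_sp_vals[-1] + ds, grid_shape[1])
    ga = np.clip(ga, 1e-4, None)
    # snap the nearest grid lines onto the calibration lattice so the
    # dense table reproduces the measured points exactly
    for v in mu_a_vals:
        ga[int(np.argmin(np.abs(ga - v)))] = v
    for v in mu_sp_vals:
        gs[int(np.argmin(np.abs(gs - v)))] = v
    GA, GS = np.meshgrid(ga, gs, indexing="ij")
    q = np.column_stack([GA.ravel(), GS.ravel()])
    return LookupTable(
        dc=itp_dc(q),
        ac=itp_ac(q),
        mu_a=GA,
        mu_s_prime=GS,
        kind="empirical",
        interpolation=interpolation,
        fx=f,
        meta={"n_calibration": len(calibration), "grid_shape": grid_shape},
    )


def invert_lut(dc_map, ac_map, lut: LookupTable) -> PropertyMaps:
    """Per-pixel LUT inversion of (DC, AC) maps to property maps."""
    mu_a, mu_sp, oob = lut.query(np.asarray(dc_map), np.asarray(ac_map))
    return PropertyMaps(mu_a=mu_a, mu_s_prime=mu_sp, oob_mask=oob)


def recover_maps(
    sample_stack: ImageStack,
    reference_stack: Optional[ImageStack],
    ref_props: Optional[OpticalProperties],
    lut: LookupTable,
) -> PropertyMaps:
    """Full inverse pipeline: demodulate -> calibrate -> invert.

    With a model LUT the modulation is first calibrated to diffuse
    reflectance against the reference stack.  With an empirical LUT the
    raw modulation is inverted directly (the LUT itself absorbs the
    system response); the reference arguments are then unused.
    """
    if reference_stack is not None and sample_stack.fx != reference_stack.fx:
        raise ValueError("sample and reference stacks must share fx")
    s_ac, s_dc = demodulate(sample_stack)
    if lut.kind == "model":
        if reference_stack is None or ref_props is None:
            raise ValueError("model-LUT recovery requires a reference stack and properties")
        r_ac, r_dc = demodulate(reference_stack)
        rd_dc, rd_ac, _ = calibrate((s_ac, s_dc), (r_ac, r_dc), ref_props, sample_stack.fx)
        return invert_lut(rd_dc, rd_ac, lut)
    return invert_lut(s_dc, s_ac, lut)


def region_median(maps: PropertyMaps, mask) -> tuple:
    """Median (mu_a, mu_s') over a boolean pixel region."""
    mask = np.asarray(mask, bool)
    return (
        float(np.nanmedian(maps.mu_a[mask])),
        float(np.nanmedian(maps.mu_s_prime[mask])),
    )
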