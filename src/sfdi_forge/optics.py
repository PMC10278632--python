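"""Physical types and closed-form optics used throughout the toolkit.

The central object is :class:`OpticalProperties`, describing a turbid
medium by its absorption coefficient ``mu_a`` (mm^-1), scattering
coefficient ``mu_s`` (mm^-1), scattering anisotropy ``g`` (the mean cosine
of the single-scattering deflection angle) and refractive index ``n``.
The reduced scattering coefficient ``mu_s_prime = mu_s * (1 - g)`` is the
quantity SFDI actually maps.

The module also provides the semi-infinite spatial-frequency-domain
diffusion solution :func:`diffuse_reflectance_fx`, which serves as the
fast forward model for rendering and look-up-table generation, with the
Monte-Carlo transport module acting as its independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "SpatialFrequency",
    "hg_sample",
    "hg_pdf",
    "fresnel_unpolarized",
    "effective_boundary_reflectance",
    "diffuse_reflectance_fx",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical description of a homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm^-1), >= 0.
    mu_s : float
        Scattering coefficient (mm^-1), >= 0.
    g : float, optional
        Scattering anisotropy, -1 < g < 1.  Default 0.8, typical of
        tissue at the gastro-oesophageal junction.
    n : float, optional
        Refractive index, >= 1.  Default 1.4.
    """

    mu_a: float
    mu_s: float
    g: float = 0.8
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must satisfy |g| < 1, got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g) (mm^-1)."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def mu_tr(self) -> float:
        """Transport attenuation coefficient mu_a + mu_s' (mm^-1)."""
        return self.mu_a + self.mu_s_prime

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / (mu_a + mu_s)."""
        return self.mu_s / self.mu_t

    @classmethod
    def from_reduced(
        cls, mu_a: float, mu_s_prime: float, g: float = 0.8, n: float = 1.4
    ) -> "OpticalProperties":
        """Construct from the reduced scattering coefficient.

        Round-trips with :attr:`mu_s_prime`: the stored ``mu_s`` is
        ``mu_s_prime / (1 - g)``.
        """
        return cls(mu_a=mu_a, mu_s=mu_s_prime / (1.0 - g), g=g, n=n)

    def to_dict(self) -> dict:
        """Plain-text serialisable form {mu_a, mu_s_prime, g, n}."""
        return {
            "mu_a": float(self.mu_a),
            "mu_s_prime": float(self.mu_s_prime),
            "g": float(self.g),
            "n": float(self.n),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalProperties":
        if "mu_s_prime" in d:
            return cls.from_reduced(
                mu_a=float(d["mu_a"]),
                mu_s_prime=float(d["mu_s_prime"]),
                g=float(d.get("g", 0.8)),
                n=float(d.get("n", 1.4)),
            )
        return cls(
            mu_a=float(d["mu_a"]),
            mu_s=float(d["mu_s"]),
            g=float(d.get("g", 0.8)),
            n=float(d.get("n", 1.4)),
        )


#: Default projected spatial frequency (mm^-1).  The choice is typical
#: SFDI practice for tissue; every pipeline entry point takes it as a
#: parameter.
DEFAULT_FX = 0.2


@dataclass(frozen=True)
class SpatialFrequency:
    """Spatial frequency of a projected sinusoid.

    ``fx`` is in cycles per mm; ``omega = 2 pi fx`` is the angular
    frequency in rad/mm.
    """

    fx: float

    def __post_init__(self) -> None:
        if self.fx < 0:
            raise ValueError(f"spatial frequency must be >= 0, got {self.fx}")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.fx


def _as_fx(fx) -> float:
    return fx.fx if isinstance(fx, SpatialFrequency) else float(fx)


def hg_pdf(cos_theta, g: float):
    """Henyey-Greenstein density p(cos theta)."""
    if not abs(g) < 1.0:
        raise ValueError(f"anisotropy g must satisfy |g| < 1, got {g}")
    c = np.asarray(cos_theta, dtype=float)
    return (1.0 - g * g) / (2.0 * (1.0 + g * g - 2.0 * g * c) ** 1.5)


def hg_sample(g: float, u1, u2):
    """Sample a Henyey-Greenstein deflection from two uniform variates.

    Uses the closed-form inverse CDF; at g = 0 it reduces to an isotropic
    ``cos theta = 2 u1 - 1``.  Returns ``(cos_theta, phi)`` with the
    azimuth ``phi`` uniform on [0, 2 pi).
    """
    if not abs(g) < 1.0:
        raise ValueError(f"anisotropy g must satisfy |g| < 1, got {g}")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any((u1 < 0) | (u1 >= 1)) or np.any((u2 < 0) | (u2 >= 1)):
        raise ValueError("uniform variates must lie in [0, 1)")
    if g == 0.0:
        cos_theta = 2.0 * u1 - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        cos_theta = (1.0 + g * g - frac * frac) / (2.0 * g)
        cos_theta = np.clip(cos_theta, -1.0, 1.0)
    phi = 2.0 * math.pi * u2
    if cos_theta.ndim == 0:
        return float(cos_theta), float(phi)
    return cos_theta, phi


def fresnel_unpolarized(n1: float, n2: float, cos_incident):
    """Unpolarised Fresnel reflection probability at a smooth boundary.

    ``cos_incident`` is the direction cosine against the surface normal,
    in [0, 1].  Total internal reflection returns 1.
    """
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    ci = np.asarray(cos_incident, dtype=float)
    if np.any((ci < 0.0) | (ci > 1.0)):
        raise ValueError("cos_incident must lie in [0, 1]")
    scalar = ci.ndim == 0
    ci = np.atleast_1d(ci)

    si2 = 1.0 - ci * ci
    # Snell: n1 sin(i) = n2 sin(t)
    st2 = (n1 / n2) ** 2 * si2
    out = np.ones_like(ci)
    prop = st2 < 1.0  # transmitted wave propagates
    ct = np.sqrt(np.clip(1.0 - st2[prop], 0.0, 1.0))
    cip = ci[prop]
    rs = (n1 * cip - n2 * ct) / (n1 * cip + n2 * ct)
    rp = (n1 * ct - n2 * cip) / (n1 * ct + n2 * cip)
    out[prop] = 0.5 * (rs * rs + rp * rp)
    # Grazing incidence with a propagating branch still reflects fully.
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def effective_boundary_reflectance(n: float) -> float:
    """Effective internal reflection coefficient R_eff of a tissue-air boundary.

    Groenhuis polynomial parameterisation in the relative index
    n_rel = n_tissue / n_outside:

        R_eff = 0.0636 n + 0.668 + 0.710 / n - 1.440 / n^2

    This is the standard choice for the partial-current boundary
    condition of the diffusion approximation and is the one used to
    derive the boundary constant ``A`` in :func:`diffuse_reflectance_fx`.
    """
    if n < 1.0:
        raise ValueError("refractive index must be >= 1")
    if n == 1.0:
        return 0.0
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffuse_reflectance_fx(props, fx=0.0, *, mu_a=None, mu_s_prime=None, n=None):
    """Spatial-frequency-domain diffuse reflectance of a semi-infinite medium.

    Standard diffusion-approximation solution for a homogeneous
    semi-infinite medium with an index-mismatched boundary under
    spatially modulated illumination:

        mu_tr   = mu_a + mu_s'
        a'      = mu_s' / mu_tr                      (reduced albedo)
        mu_eff' = sqrt(3 mu_a mu_tr + (2 pi fx)^2)   (scalar photon density
                                                      attenuation at fx)
        Rd(fx)  = 3 A a' / ((mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A))

    where ``A = (1 - R_eff) / (2 (1 + R_eff))`` with R_eff from
    :func:`effective_boundary_reflectance`.

    Parameters may be given either as a single :class:`OpticalProperties`
    (``props``) or as arrays via the ``mu_a`` / ``mu_s_prime`` / ``n``
    keywords (``props=None``), which broadcasts over property grids.
    """
    if props is not None:
        mu_a = props.mu_a
        mu_s_prime = props.mu_s_prime
        n = props.n
    if n is None:
        n = 1.4
    mu_a = np.asarray(mu_a, dtype=float)
    mu_sp = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_sp <= 0):
        raise ValueError(
            "diffusion approximation requires mu_s_prime > 0; "
            "use the transport module for non-scattering media"
        )
    if isinstance(fx, SpatialFrequency):
        fx = fx.fx
    f = np.asarray(fx, dtype=float)
    scalar = mu_a.ndim == 0 and mu_sp.ndim == 0 and f.ndim == 0
    if np.any(f < 0):
        raise ValueError("spatial frequency must be >= 0")

    reff = effective_boundary_reflectance(float(n))
    A = (1.0 - reff) / (2.0 * (1.0 + reff))
    mu_tr = mu_a + mu_sp
    a_prime = mu_sp / mu_tr
    mu_eff_p = np.sqrt(3.0 * mu_a * mu_tr + (2.0 * np.pi * f) ** 2)
    x = mu_eff_p / mu_tr
    rd = 3.0 * A * a_prime / ((x + 1.0) * (x + 3.0 * A))
    rd = np.clip(rd, 0.0, 1.0)
    return float(rd) if scalar else rd
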