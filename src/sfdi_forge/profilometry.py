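"""Height-map reconstruction by phase-shifted fringe projection.

Fringes are projected along the camera-projector offset axis (rotated
90 degrees from the SFDI orientation) so that surface height displaces
the observed pattern.  The three-step phase estimator retrieves the
wrapped phase, a quality-guided unwrapper restores continuity, and the
crossed-optical-axes relation

    h(x, y) = l0 dphi / (dphi - 2 pi f0 d)

maps the phase difference against a flat reference plane to height,
with l0 the projector-to-reference distance, d the camera-projector
separation and f0 the projected frequency at the reference plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.restoration import unwrap_phase as _sk_unwrap

from .sfdi import ImageStack

__all__ = [
    "ProfilometryGeometry",
    "PhaseMap",
    "phase_from_three",
    "unwrap",
    "phase_difference",
    "height_map",
    "recover_height",
]


@dataclass(frozen=True)
class ProfilometryGeometry:
    """Fringe-projection geometry (mm and mm^-1)."""

    l0: float = 500.0
    d: float = 35.0
    f0: float = 0.1

    def __post_init__(self) -> None:
        if self.l0 <= 0 or self.d <= 0 or self.f0 <= 0:
            raise ValueError("l0, d and f0 must all be > 0")


@dataclass
class PhaseMap:
    """Per-pixel phase (rad) with a validity mask.

    Wrapped maps hold values in (-pi, pi]; ``unwrapped`` records whether
    2-pi continuity has been restored.
    """

    phase: np.ndarray
    mask: np.ndarray
    unwrapped: bool = False

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


def phase_from_three(stack: ImageStack, rel_amp_tol: float = 1e-6) -> PhaseMap:
    """Wrapped phase from three equispaced phase-shifted images.

    For I_k = DC + AC sin(theta + phi_k) the complex sum
    S = sum_k I_k exp(-i phi_k) equals (3 AC / 2) exp(i(theta - pi/2)),
    so theta = arg(S) + pi/2 exactly.  Pixels whose modulation amplitude
    2|S|/3 is negligible relative to the stack mean carry no fringe
    information and are masked.
    """
    phases = np.asarray(stack.phases)
    s = np.tensordot(np.exp(-1j * phases), stack.images, axes=(0, 0))
    theta = np.angle(s) + math.pi / 2.0
    theta = np.angle(np.exp(1j * theta))  # rewrap to (-pi, pi]
    amp = 2.0 * np.abs(s) / 3.0
    scale = float(np.mean(np.abs(stack.images)))
    mask = amp <= rel_amp_tol * max(scale, 1e-300)
    return PhaseMap(phase=theta, mask=mask, unwrapped=False)


def unwrap(p: PhaseMap, reference_pixel: tuple = (0, 0)) -> PhaseMap:
    """Two-dimensional phase unwrapping.

    Continuity is restored with a quality-guided algorithm (masked
    pixels are excluded); the global 2-pi branch is fixed so the
    reference pixel keeps its wrapped value.
    """
    if p.unwrapped:
        return p
    marr = np.ma.array(p.phase, mask=p.mask)
    out = np.asarray(_sk_unwrap(marr))
    r, c = reference_pixel
    shift = 2.0 * math.pi * round((out[r, c] - p.phase[r, c]) / (2.0 * math.pi))
    return PhaseMap(phase=out - shift, mask=p.mask.copy(), unwrapped=True)


def phase_difference(sample: PhaseMap, reference: PhaseMap) -> PhaseMap:
    """Unwrapped phase difference sample - reference.

    The difference is formed on the wrapped principal branch first (so
    common large phase ramps cancel before unwrapping) and then
    unwrapped.
    """
    d = np.angle(np.exp(1j * (sample.phase - reference.phase)))
    mask = sample.mask | reference.mask
    return unwrap(PhaseMap(phase=d, mask=mask, unwrapped=False))


def height_map(dphi: PhaseMap, geom: ProfilometryGeometry) -> np.ndarray:
    """Phase difference to height: h = l0 dphi / (dphi - 2 pi f0 d).

    Near-zero denominators are masked (NaN) rather than divided through.
    The phase difference must be measured against the flat reference
    plane (dphi = 0 maps to h = 0).
    """
    scale = 2.0 * math.pi * geom.f0 * geom.d
    den = dphi.phase - scale
    bad = dphi.mask | (np.abs(den) < 1e-9 * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = geom.l0 * dphi.phase / den
    h = np.where(bad, np.nan, h)
    return h


def recover_height(
    sample_stack: ImageStack,
    reference_stack: ImageStack,
    geom: Optional[ProfilometryGeometry] = None,
) -> np.ndarray:
    """Full shape pipeline: phase retrieval, unwrapping, phase-to-height.

    ``reference_stack`` images the flat reference plane under the same
    fringes; ``geom.f0`` must match the projected frequency.
    """
    geom = geom or ProfilometryGeometry()
    ps = phase_from_three(sample_stack)
    pr = phase_from_three(reference_stack)
    dphi = phase_difference(ps, pr)
    return height_map(dphi, geom)
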