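"""File I/O: scene/property configs, images and look-up tables.

Images are written either as 8/16-bit PNG (with a saturation check that
mirrors mid-range exposure practice) or as lossless floating-point
TIFF; configs are YAML or JSON; look-up tables go through HDF5 (see
:class:`sfdi_forge.sfdi.LookupTable`).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .optics import OpticalProperties
from .render import ExposedImage

__all__ = [
    "save_properties",
    "load_properties",
    "save_scene_spec",
    "load_scene_spec",
    "scene_from_spec",
    "write_image",
    "read_image",
]


def save_properties(props: OpticalProperties, path) -> None:
    """Write optical properties as {mu_a, mu_s_prime, g, n} YAML/JSON."""
    path = Path(path)
    data = props.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def load_properties(path) -> OpticalProperties:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return OpticalProperties.from_dict(data)


def save_scene_spec(spec: dict, path) -> None:
    """Write a phantom scene description (name + parameters)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec, indent=2))
    else:
        path.write_text(yaml.safe_dump(spec))


def load_scene_spec(path) -> dict:
    path = Path(path)
    text = path.read_text()
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)


def scene_from_spec(spec: dict):
    """Build a scene from a spec dict: {"phantom": name, **kwargs}.

    Supported phantom names: flat (requires ``properties``), reference,
    scc, bo, tube (returns a :class:`sfdi_forge.tube.TubeScene`).
    """
    from . import phantoms
    from .tube import make_tube_scene

    spec = dict(spec)
    name = spec.pop("phantom")
    resolution = tuple(spec.pop("resolution", (256, 256)))
    extent = tuple(spec.pop("extent", (200.0, 200.0)))
    if name == "flat":
        props = OpticalProperties.from_dict(spec.pop("properties"))
        return phantoms.make_flat_scene(props, resolution, extent)
    if name == "reference":
        return phantoms.make_reference_scene(resolution, extent)
    if name == "scc":
        return phantoms.make_scc_scene(resolution, extent)
    if name == "bo":
        return phantoms.make_bo_scene(resolution, extent)
    if name == "tube":
        quadrant = spec.pop("deviating_quadrant", None)
        if quadrant is not None:
            quadrant = OpticalProperties.from_dict(quadrant)
        wall = spec.pop("wall", None)
        if wall is not None:
            wall = OpticalProperties.from_dict(wall)
        return make_tube_scene(deviating_quadrant=quadrant, wall=wall)
    raise ValueError(f"unknown phantom {name!r}")


def write_image(img, path, bit_depth: int | None = None) -> None:
    """Write an image: float TIFF (lossless) or quantised PNG.

    PNG output rescales to the full range after checking saturation:
    a warning is raised when more than 1% of pixels sit at the top
    code value, mirroring the practice of exposing to keep the average
    mid-range.  :class:`ExposedImage` inputs are written as rendered
    (exposure metadata is the caller's to track).
    """
    pixels = img.pixels if isinstance(img, ExposedImage) else np.asarray(img)
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels.astype(np.float32))
        return
    if path.suffix != ".png":
        raise ValueError("images are written as .png or .tif/.tiff")
    depth = bit_depth or 8
    if depth not in (8, 16):
        raise ValueError("PNG bit depth must be 8 or 16")
    top = 2**depth - 1
    peak = float(pixels.max())
    scale = top / peak if peak > 0 else 1.0
    quant = np.round(pixels * scale)
    if np.mean(quant >= top) > 0.01:
        warnings.warn("more than 1% of pixels saturate the code range", stacklevel=2)
    iio.imwrite(path, quant.astype(np.uint8 if depth == 8 else np.uint16))


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF back as a float array (no rescaling)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    return np.asarray(iio.imread(path), dtype=float)
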