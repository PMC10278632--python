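"""Height mapping by three-step fringe-projection profilometry.

Fringes are projected at 0.1 mm^-1 (rotated 90 degrees from the SFDI
orientation so height displaces the pattern); the phase shift against a
flat reference plane maps to height through the crossed-optical-axes
relation h = l0*dphi / (dphi - 2*pi*f0*d).
"""

import numpy as np

from sfdi_forge.phantoms import TISSUES, make_flat_scene, make_scc_scene
from sfdi_forge.profilometry import ProfilometryGeometry, recover_height
from sfdi_forge.render import render_phase_stack

geom = ProfilometryGeometry(l0=500.0, d=35.0, f0=0.1)
reference = render_phase_stack(
    make_flat_scene(TISSUES["healthy"]), geom.f0, orientation="x"
)

plate = make_flat_scene(TISSUES["healthy"])
plate.height[:] = 10.0
h_plate = recover_height(
    render_phase_stack(plate, geom.f0, orientation="x"), reference, geom
)
print(f"flat plate raised 10 mm -> recovered {np.nanmean(h_plate[32:-32, 32:-32]):.3f} mm")

spheroid = render_phase_stack(make_scc_scene(), geom.f0, orientation="x")
h = recover_height(spheroid, reference, geom)
print(f"80 mm tumour spheroid   -> recovered apex {np.nanmax(h[96:160, 96:160]):.2f} mm "
      "(true 40 mm)")
print()
print("The same stacks that map optical properties therefore also quantify")
print("polyp morphology, at no extra acquisition cost.")
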