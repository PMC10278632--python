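"""Virtual double-integrating-sphere characterisation of a slab sample.

A 1 mm slab sits between a reflectance and a transmission sphere; the
detected powers reduce to the normalised reflectance MR and
transmittance MT, which a Monte-Carlo slab forward model inverts back
to the absorption and reduced scattering coefficients.
"""

from sfdi_forge.dis import (
    invert_slab,
    normalized_reflectance,
    normalized_transmittance,
    simulate_dis,
)
from sfdi_forge.optics import OpticalProperties
from sfdi_forge.transport import TransportConfig

truth = OpticalProperties.from_reduced(mu_a=0.1, mu_s_prime=1.0)
measurement = simulate_dis(truth, cfg=TransportConfig(n_photons=200_000, seed=5))
mr = normalized_reflectance(measurement)
mt = normalized_transmittance(measurement)
print(f"normalised reflectance  MR = {mr:.4f}")
print(f"normalised transmittance MT = {mt:.4f}")

recovered = invert_slab(mr, mt)
print(f"true      mu_a = {truth.mu_a:.4f}, mu_s' = {truth.mu_s_prime:.4f} (1/mm)")
print(f"recovered mu_a = {recovered.mu_a:.4f}, mu_s' = {recovered.mu_s_prime:.4f} (1/mm)")
print()
print("This virtual bench is how reference materials get their certified")
print("optical properties before they calibrate the imaging pipeline.")
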