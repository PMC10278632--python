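"""Barrett's oesophagus beside healthy tissue: scattering-only contrast.

The two flat half-samples have nearly identical absorption but the
inflamed segment scatters much less; the recovered maps should separate
the tissues in mu_s' while staying flat in mu_a.
"""

from sfdi_forge.experiments import bo_contrast

result = bo_contrast()

print("Barrett's oesophagus (left half) vs healthy tissue (right half):")
print(f"  BO:       mu_a = {result['bo']['mu_a']:.4f}  "
      f"mu_s' = {result['bo']['mu_s_prime']:.4f}  (1/mm)")
print(f"  healthy:  mu_a = {result['healthy']['mu_a']:.4f}  "
      f"mu_s' = {result['healthy']['mu_s_prime']:.4f}  (1/mm)")
print(f"  mu_a ratio  = {result['mu_a_ratio']:.3f}  (expected ~0.98)")
print(f"  mu_s' ratio = {result['mu_s_prime_ratio']:.3f}  (expected 0.68)")
print()
print("Absorption is indistinguishable between the halves; the 32% drop in")
print("reduced scattering is what flags the pre-cancerous segment.")
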