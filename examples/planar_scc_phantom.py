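"""Squamous-cell-carcinoma spheroid on healthy tissue: optical-property contrast.

Builds the 80 mm tumour-spheroid phantom, images it with three-phase
sinusoidal illumination at 0.2 mm^-1, and recovers absorption and
reduced-scattering maps with a model look-up table (profile-corrected
using the height map the toolkit itself reconstructs).
"""

from sfdi_forge.experiments import scc_contrast

result = scc_contrast()

print("SCC spheroid vs healthy background (median over regions):")
print(f"  tumour:      mu_a = {result['tumour']['mu_a']:.4f}  "
      f"mu_s' = {result['tumour']['mu_s_prime']:.4f}  (1/mm)")
print(f"  background:  mu_a = {result['background']['mu_a']:.4f}  "
      f"mu_s' = {result['background']['mu_s_prime']:.4f}  (1/mm)")
print(f"  mu_a ratio  = {result['mu_a_ratio']:.3f}  "
      f"(true contrast {result['expected']['mu_a_ratio']:.3f})")
print(f"  mu_s' ratio = {result['mu_s_prime_ratio']:.3f}  "
      f"(true contrast {result['expected']['mu_s_prime_ratio']:.3f})")
print()
print("A ratio near 2 in absorption with mildly reduced scattering is the")
print("optical signature that separates the carcinoma from healthy mucosa.")
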