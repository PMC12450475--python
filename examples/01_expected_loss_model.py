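"""Closed-form expected transcription loss on a synthetic gene catalog.

Builds a mouse-liver-like catalog (9,000 genes), converts a UV dose ladder
to whole-genome lesion counts, and evaluates E[w_M] = sum_j alpha_j
(1-(1-q_j)^M) along it.
"""

import txstress as tx
from txstress.synth import CatalogConfig, make_catalog

catalog = make_catalog(CatalogConfig(), seed=0)
print(f"catalog: {len(catalog)} genes, L = {catalog.genome_length_L:.2e} bp")
print(f"expression-weighted mean gene length: "
      f"{(catalog.alpha * catalog.lengths).sum() / 1e3:.0f} kb\n")

print("dose (J/m2)  density(/100kb)  total TBLs   E[loss] %")
for dose in (0.0, 1.0, 2.0, 4.0, 6.0):
    density = tx.uv_dose_to_density(dose)
    M = tx.density_to_count(density, catalog.genome_length_L)
    loss = 100.0 * tx.expected_loss(catalog, M)
    print(f"{dose:11.1f}  {density:15.2f}  {M:10,d}  {loss:9.1f}")

print("\nEach J/m2 deposits ~0.55 lesions per 100 kb; long, highly")
print("expressed genes are hit first, so loss rises sublinearly with dose.")
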