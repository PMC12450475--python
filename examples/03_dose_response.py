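"""UV dose-response: intensity -> loss, polynomial fits, error table.

Generates replicate EU-intensity observations from the model on a
human-fibroblast-like catalog, converts them to transcription loss, fits
linear and cubic dose-response curves, and tabulates model-vs-data errors.
"""

import numpy as np

import txstress as tx
from txstress.synth import HUMAN_CATALOG_CONFIG, CatalogConfig, make_catalog, make_dose_response

cfg = CatalogConfig(**{**HUMAN_CATALOG_CONFIG.__dict__, "n_genes": 4_000})
catalog = make_catalog(cfg, seed=1)
doses = [0, 1, 2, 3, 4, 5, 6]
obs = make_dose_response(catalog, doses, noise_sd_pct=2.0, seed=2)
losses = tx.intensity_to_loss(obs)
print(losses.round(2).to_string(index=False))

x = losses["dose"].to_numpy()
y = losses["loss_pct"].to_numpy()
linear = tx.fit_polynomial(x, y, 1)
cubic = tx.fit_polynomial(x, y, 3)
print(f"\nlinear RSS {linear.rss:.2f}  >=  cubic RSS {cubic.rss:.2f}")
print(f"low-dose slope: {tx.per_tbl_slope(linear) / 0.55:.1f} "
      "% loss per (TBL per 100 kb)")

model_losses = np.array([
    100.0 * tx.expected_loss(
        catalog,
        tx.density_to_count(tx.uv_dose_to_density(d), catalog.genome_length_L),
    )
    for d in x[1:]
])
table = tx.error_table(model_losses, y[1:], losses["sem_pct"].to_numpy()[1:],
                       doses=x[1:])
print("\nmodel-vs-data error table (non-reference doses):")
print(table.table.round(2).to_string(index=False))
print(f"\nmean absolute error: {table.means['abs_error_pct']:.2f} %-points, "
      f"{table.means['abs_error_sems']:.2f} SEM multiples")
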