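"""Generate a synthetic 25-site study and assemble its site table.

The generator draws landscapes, latent structural variables, per-mummy
detections and plot surveys from a known ground-truth path model; the
site table joins parasitism/hyperparasitism rates, community summaries,
web metrics and landscape covers per site-year.
"""

import pandas as pd

from aphidweb import build_site_table
from aphidweb.simulate import SimulationConfig, generate_study

pd.set_option("display.width", 120)

bundle = generate_study(SimulationConfig(seed=42, n_sites=25))
print(
    f"{len(bundle.detections)} mummies, {len(bundle.surveys)} survey rows, "
    f"{len(bundle.landscapes)} landscape sectors"
)

table = build_site_table(bundle.detections, bundle.surveys, bundle.landscapes)
cols = [
    "site_id", "year", "parasitism", "hyperparasitism",
    "parasitoid_richness", "hyperparasitoid_diversity",
    "generality", "vulnerability", "secondary_crops", "sidi",
]
print(table[cols].head(8).round(3).to_string(index=False))
# parasitism is the pooled mummy share of all aphids (the ecosystem
# service); hyperparasitism the share of mummies carrying a
# hyperparasitoid (the disservice). Both vary between sites because the
# ground-truth path model links them to diversity, web structure and
# landscape composition.
print("mean ES =", round(table["parasitism"].mean(), 3),
      " mean EDS =", round(table["hyperparasitism"].mean(), 3))
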