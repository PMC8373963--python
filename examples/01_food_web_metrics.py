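"""Weighted metrics of a small primary-hyperparasitoid food web.

Builds a quantitative web from a handful of mummy detection records and
prints the weighted generality (Gq), vulnerability (Vq) and connectance
(Cq) together with the per-taxon effective partner numbers.
"""

from aphidweb import DetectionRecord, build_web, taxon_entropies, web_metrics


def mummy(sid, primary, hyper=None):
    return DetectionRecord(
        site_id="demo",
        year=2015,
        sample_id=sid,
        primary_species=primary,
        hyper_species=(hyper,) if hyper else (),
    )


records = [
    mummy("m1", "Binodoxys communis", "Syrphophagus spp."),
    mummy("m2", "Binodoxys communis", "Syrphophagus spp."),
    mummy("m3", "Binodoxys communis", "Pachyneuron aphidis"),
    mummy("m4", "Aphelinus albipodus", "Pachyneuron aphidis"),
    mummy("m5", "Binodoxys communis"),  # parasitized but not hyperparasitized
]

web = build_web(records)
print("interaction matrix (rows = primary parasitoids, cols = hyperparasitoids):")
print("  lower:", web.lower_species)
print("  upper:", web.upper_species)
print(web.b)

eff = taxon_entropies(web)
print("effective host species per hyperparasitoid (n_N):", eff["n_N"].round(4))
print("effective consumer species per parasitoid (n_P):", eff["n_P"].round(4))

m = web_metrics(web)
print(f"Gq = {m.generality:.4f}  (mean effective hosts per consumer)")
print(f"Vq = {m.vulnerability:.4f}  (mean effective consumers per host)")
print(f"Cq = {m.connectance:.4f}  over s = {m.n_acting_species} acting species")
# Gq near 1 means specialist hyperparasitoids; Vq above 1 means primary
# parasitoids shared by several hyperparasitoid species.
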