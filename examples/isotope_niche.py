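"""Stable-isotope niches: lipid correction, within-site tests, ellipse areas.

Simulates per-individual delta13C / delta15N values for three sympatric
species (one shifted in carbon only), applies the C:N-based lipid
normalization, and summarizes niche separation and overlap.
"""

import ecomorph as em

cfg = em.default_config(seed=1)
table = em.lipid_correct(em.simulate_isotopes(cfg))
shift = (table["d13C_corrected"] - table["d13C"]).mean()
print(f"lipid correction shifted delta13C by {shift:+.2f} permil on average")

tests = em.within_site_tests(table)
print(tests[["site", "element", "F", "p"]])
print("pattern: species differ in carbon source (d13C) but feed at the")
print("same trophic level (no d15N difference)")

per_group, overlap = em.niche_ellipses(table, by="species")
print(per_group[["group", "n", "sea", "seac"]])
print("SEAc: standard ellipse area (permil^2), small-sample corrected")
print(overlap)
print("the two algae-feeders overlap; the carbon-shifted species stands apart")
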