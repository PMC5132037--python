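"""Diet composition, Schoener overlap, and relative gut length.

Simulates six-category stomach compositions for three species, summarizes
mean diets, flags substantial pairwise overlap (Schoener's D > 0.6), and
tests group differences in relative gut length on a synthetic gut table.
"""

import numpy as np
import pandas as pd

import ecomorph as em

cfg = em.default_config(seed=1)
diet = em.simulate_diet(cfg)

summary = em.composition_summary(diet, by="species")
print(summary.round(1))
print("mean % by volume per category; each row sums to 100")

mat = em.schoener_matrix(diet, by="species")
print(mat.round(3))
print("D > 0.6 marks substantial dietary overlap")

# synthetic gut-length table: the cellulose-feeder gets a relatively longer gut
rng = np.random.default_rng(1)
rows = []
for species, rgl_mean in [("alcalica", 1.14), ("latilabris", 1.08), ("ndalalani", 1.08)]:
    sl = rng.uniform(45, 95, 20)
    rgl = rng.normal(rgl_mean, 0.02, 20)
    rows.append(
        pd.DataFrame(
            {
                "specimen_id": [f"{species}_{i}" for i in range(20)],
                "species": species,
                "site": "site05",
                "gut_length": 10 ** (rgl * np.log10(sl)),
                "standard_length": sl,
            }
        )
    )
gut = pd.concat(rows, ignore_index=True)
res = em.relative_gut_length_tests(gut)
print(f"relative gut length ANOVA: F={res.statistic:.1f}, p={res.p_value:.2e}")
print(res.pairwise.round(4))
print("a longer relative gut is consistent with a higher-fibre (plant) diet")
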