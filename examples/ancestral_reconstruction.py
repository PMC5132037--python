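"""Ancestral states, 95% phenogram intervals, and phylomorphospace.

Simulates Brownian-motion trait evolution on the default five-taxon tree,
reconstructs internal-node states by branch-length-weighted squared-change
parsimony, and reports REML-based uncertainty at the root.
"""

import ecomorph as em
from ecomorph.simulate import default_tree

tree = default_tree()
print(f"tree: {tree.n_tips} tips, height {tree.height():.2f} substitutions/site")

trait = em.simulate_bm(tree, sigma2=1.0, root=0.0, seed=3)
print("simulated tip values:", {k: round(v, 3) for k, v in trait.items()})

rec = em.phenogram95(tree, trait)
lo, hi = rec.ci95[0, 0]
print(f"REML Brownian rate sigma^2 = {rec.sigma2[0]:.3f}")
print(f"root state {rec.node_states[0, 0]:+.3f}, 95% interval [{lo:+.3f}, {hi:+.3f}]")
print("(narrow intervals near the tips, widest at the root)")

scores = {t: [em.simulate_bm(tree, 1.0, seed=s)[t] for s in (3, 4)] for t in tree.tip_labels}
coords, edges = em.phylomorphospace(tree, scores)
print(f"phylomorphospace: {coords.shape[0]} node positions, {len(edges)} edges")
print("root projects to", coords[0].round(3), "- inside the hull of the tips")
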