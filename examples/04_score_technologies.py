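"""Value and rank candidate technologies with the additive value function.

Each technology gets one score per leaf on a declared scale (here [0, 1]).
Its composite value is V = Σ_i ŵ_i Σ_j ŵ_ij Σ_k ŵ_ijk s_ijk — the weighted
sum over leaves with the product of normalized weights along each path — so
V lives on the score scale and decomposes exactly into per-domain
contributions.
"""

import numpy as np

from mcda_hta import (
    ScoreSheet,
    aggregate_value,
    build_weight_table,
    default_survey_profiles,
    load_default_tree,
    rank_technologies,
    results_frame,
    simulate_allocations,
)

tree = load_default_tree()
allocs = simulate_allocations(tree, default_survey_profiles(tree), seed=42)
wt = build_weight_table(allocs)

rng = np.random.default_rng(7)
sheets = [
    # a broadly strong technology, one strong only on "Need for intervention",
    # and a weak comparator
    ScoreSheet("gene_panel", {l: float(rng.uniform(0.65, 0.9)) for l in tree.leaves()}),
    ScoreSheet("proton_unit", {l: (0.9 if l.startswith("d1") else 0.35)
                               for l in tree.leaves()}),
    ScoreSheet("legacy_device", {l: float(rng.uniform(0.1, 0.4)) for l in tree.leaves()}),
]

ranked = rank_technologies([aggregate_value(wt, s) for s in sheets])
print(results_frame(ranked).round(4).to_string())
print()
for res in ranked:
    top_domain = max(res.domain_contributions, key=res.domain_contributions.get)
    print(f"rank {res.rank}: {res.technology_id:13s} V = {res.value:.4f} "
          f"(largest contribution: {tree.index[top_domain].label!r} "
          f"= {res.domain_contributions[top_domain]:.4f})")
# V is on the score scale: 1.0 would mean a perfect score on every leaf.
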