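"""Tajima relative-rate test and the lineage gene-loss screen.

The relative-rate test asks whether two lineages accumulated substitutions
at equal rates relative to an outgroup; the loss screen reports anchor genes
supported in at least one comparison-clade species but in none of the
ingroup species.
"""

import numpy as np
import pandas as pd

from phylostage import PresenceMatrix, lineage_loss_screen, tajima_rrt

# --- relative rates on a synthetic aligned triplet ----------------------
rng = np.random.default_rng(0)
aa = list("ACDEFGHIKLMNPQRSTVWY")
outgroup = "".join(rng.choice(aa, 400))


def evolve(seq, rate):
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    arr[mask] = rng.choice(aa, int(mask.sum()))
    return "".join(arr)


fast = evolve(outgroup, 0.20)   # fast-evolving lineage A
slow = evolve(outgroup, 0.05)   # slow-evolving lineage B
res = tajima_rrt(fast, slow, outgroup)
print(f"lineage-unique sites: A={res.m_a}, B={res.m_b} over {res.n_sites_used} sites")
print(f"Tajima RRT chi2={res.chi2:.2f} (df={res.df}), p={res.pvalue:.3g}")
# A significant chi2 with m_A >> m_B means lineage A evolved faster.

# --- gene-loss screen ---------------------------------------------------
presence = pd.DataFrame(
    {
        "ingroup_sp1": [True, False, False, True],
        "ingroup_sp2": [True, False, False, False],
        "comparison_sp1": [True, True, False, True],
        "comparison_sp2": [True, True, False, True],
    },
    index=["anchor_g1", "anchor_g2", "anchor_g3", "anchor_g4"],
)
matrix = PresenceMatrix(
    presence,
    ingroup=["ingroup_sp1", "ingroup_sp2"],
    comparison=["comparison_sp1", "comparison_sp2"],
)
lost = lineage_loss_screen(matrix)
print(f"genes lost in the ingroup lineage: {lost}")
# anchor_g2 is present in the comparison clade but in no ingroup species ->
# lost; anchor_g3 is absent everywhere, so there is no evidence it ever
# existed outside the outgroup and it is not called lost.
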