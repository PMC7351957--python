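"""Identify evolutionarily conserved developmental stages across four species.

Simulates an hourglass-shaped dataset (divergence lowest at mid-development)
on the tree (Anj,(Apj,(Sp,Lv))), scores every cross-species stage
combination by summed 1 - Spearman expression distances, and reports Ptop:
the percentage of the top-1% most conserved combinations containing each
stage, with mean +- SD over 30 replicate-resampled (BRI) tables and a
Friedman test of stage effects.
"""

from phylostage import SimulationConfig, SpeciesTree, ptop_with_bri, simulate_expression_dataset

stages = {sp: [f"st{i + 1:02d}" for i in range(10)] for sp in ["Anj", "Apj", "Sp", "Lv"]}
config = SimulationConfig(
    seed=1, n_groups=500, n_replicates=2, dropout_rate=0.0, stages_per_species=stages
)
tables, truth = simulate_expression_dataset(config)
tree = SpeciesTree.from_newick(config.tree_newick)

result = ptop_with_bri(list(tables.values()), tree, B=30, q=0.01, seed=2)

print("species  stage   mean_ptop  sd_ptop")
for sp in result.level:
    for stage in result.mean[sp].index:
        print(f"{sp:<8} {stage:<7} {result.mean[sp][stage]:8.1f}  {result.sd[sp][stage]:6.1f}")
    fr = result.friedman(sp)
    print(
        f"{sp}: Ptop peaks at {result.mean[sp].idxmax()} "
        f"(true conserved window {truth.true_conserved_stages[sp]}); "
        f"Friedman chi2={fr.statistic:.1f}, df={fr.df}, p={fr.pvalue:.2e}"
    )

# High Ptop marks stages over-represented among the most conserved
# cross-species combinations: with an hourglass profile the peak sits in
# mid-development, and the Friedman p-value says the stage differences are
# robust to which biological replicate was sampled.
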