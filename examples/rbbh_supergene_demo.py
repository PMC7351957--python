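"""Reciprocal-best-hit 1:1 orthology and supergene concatenation.

Simulates proteomes evolved along the species tree (with decoy paralogs),
derives per-species reciprocal best hits from the synthetic 12-column hit
tables, anchors 1:1 ortholog sets on a reference species, and concatenates
per-set sequences into a per-species supermatrix with a partition table.
"""

from phylostage import (
    ProteomeParams,
    SimulationConfig,
    anchored_one_to_one,
    best_hits,
    concatenate_supergene,
    reciprocal_best_pairs,
    simulate_proteome_set,
)

config = SimulationConfig(
    seed=5, n_groups=40, proteome=ProteomeParams(mutation_rate=0.03, decoy_fraction=0.2)
)
proteomes = simulate_proteome_set(config)

reference = "Anj"
pair_maps = {}
for sp in proteomes.sequences:
    if sp == reference:
        continue
    ab = best_hits(proteomes.hit_tables[(reference, sp)])   # e-value <= 1e-5, best bitscore
    ba = best_hits(proteomes.hit_tables[(sp, reference)])
    pair_maps[sp] = reciprocal_best_pairs(ab, ba)
    print(f"{reference}<->{sp}: {len(pair_maps[sp])} reciprocal best pairs")

sets = anchored_one_to_one(reference, pair_maps)
correct = sum(
    s.genes == proteomes.true_ortholog_map[s.reference_gene.split("_", 1)[1]] for s in sets
)
print(f"1:1 ortholog sets across all species: {len(sets)} ({correct} match the truth)")

# Concatenate the (already equal-length, per-group) sequences of the first
# five sets into a supergene, in set order
aligned = {
    s.reference_gene: {sp: proteomes.sequences[sp][g] for sp, g in s.genes.items()}
    for s in sets[:5]
}
order = [s.reference_gene for s in sets[:5]]
matrix, partitions = concatenate_supergene(aligned, order)
total = sum(end - start for _, start, end in partitions)
print(f"supermatrix: {len(matrix)} species x {total} columns; partitions:")
for name, start, end in partitions:
    print(f"  {name} = {start + 1}-{end}")

# Each ortholog set contributes one contiguous column block per species;
# the partition lines are what a phylogenetics run would consume.
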