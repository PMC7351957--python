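"""K-mer-histogram genome-size estimation from simulated reads.

Simulates 40x, 100 bp reads with 0.5% substitution errors from a 100 kb
genome, counts canonical 17-mers, finds the error valley and coverage peak
of the depth histogram, and applies size = k-mer number / peak depth.
"""

from phylostage import (
    ReadParams,
    SimulationConfig,
    count_kmers,
    estimate_genome_size,
    simulate_reads,
)

config = SimulationConfig(
    seed=7,
    read_params=ReadParams(genome_length=100_000, coverage=40.0,
                           read_length=100, error_rate=0.005),
)
readset = simulate_reads(config)
print(f"simulated {len(readset.reads)} reads from a {readset.true_genome_size:,} bp genome")

hist = count_kmers(readset.reads, k=17)
print(f"{hist.total_kmers:,} 17-mer tokens, {len(hist.as_dict())} distinct depths")

est = estimate_genome_size(hist)
err = 100.0 * abs(est.genome_size_bp - readset.true_genome_size) / readset.true_genome_size
print(f"error valley at depth {est.valley_depth}, coverage peak at depth {est.peak_depth}")
print(f"k-mer number above the valley: {est.kmer_number:,}")
print(f"estimated genome size: {est.genome_size_bp:,.0f} bp ({err:.1f}% from truth)")

# Depths at or below the valley are sequencing-error k-mers and are excluded
# from the k-mer number; dividing the remaining token count by the peak
# depth recovers the genome length.
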