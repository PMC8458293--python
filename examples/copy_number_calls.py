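"""Call chromosome losses from binned read-depth coverage.

Simulates low-pass sequencing of a cell line that lost one copy of chr3,
maps bins onto genes, centers the per-gene log2 coverage and calls somy
per chromosome.
"""

from monosomics import (SimGenome, assign_bins_to_genes, call_somy_per_chromosome,
                        center_coverage, per_gene_log2_median, simulate_annotation,
                        simulate_read_depth)

genome = SimGenome(chromosomes=tuple((f"chr{i}", 1_000_000) for i in range(1, 9)),
                   genes_per_chromosome=100, seed=1)
annotation = simulate_annotation(genome)
karyotype = {f"chr{i}": 2 for i in range(1, 9)}
karyotype["chr3"] = 1  # monosomy 3

bins = simulate_read_depth(annotation, karyotype, bin_size=10_000,
                           mean_depth=100.0, dispersion=0.05, seed=2)
gene_bins = assign_bins_to_genes(bins, annotation)
centered = center_coverage(per_gene_log2_median(gene_bins))
calls = call_somy_per_chromosome(centered)

print(f"{'chromosome':<12}{'median log2':>12}  call")
for call in calls:
    print(f"{call.chromosome:<12}{call.median_log2:>12.3f}  {call.call}")
print()
print("A disomic chromosome centers near 0; the lost chromosome sits near")
print("log2(1/2) = -1 and is called 'loss' (cutoff -0.5).")
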