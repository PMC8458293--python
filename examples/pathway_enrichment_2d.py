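"""Two-dimensional annotation enrichment on paired fold changes.

Scores every annotation term (here: chromosome-location terms plus a
complex-membership term) in the mRNA dimension and the protein dimension
simultaneously; a term whose members cluster at the bottom of both
rankings gets two negative scores, like the monosomic chromosome itself.
"""

from monosomics import AnnotationSet, enrichment_2d
from monosomics.dosage import build_fold_change_table, log2_fold_change, \
    median_shift_normalize_pair
from monosomics.simulate import SimGenome, simulate_annotation, simulate_expression

genome = SimGenome(chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000),
                                ("chr13", 2_000_000)),
                   genes_per_chromosome=300, seed=3)
annotation = simulate_annotation(genome)
sim = simulate_expression(annotation, {"chr13"}, seed=4)
monosomic = set(annotation.loc[annotation["chromosome"] == "chr13", "gene"])
fcs = {}
for name, sample, parental in (("mrna", sim.mrna, sim.mrna_parental),
                               ("protein", sim.protein, sim.protein_parental)):
    s, p = median_shift_normalize_pair(sample, parental, monosomic)
    fcs[name] = log2_fold_change(s, p)
fc = build_fold_change_table(fcs["mrna"], fcs["protein"], annotation, {"chr13"})

terms = [AnnotationSet(f"chrom:{chrom}", chrom, frozenset(sub["gene"]), "chromosome")
         for chrom, sub in annotation.groupby("chromosome")]
terms.append(AnnotationSet("CORUM", "complex subunits",
                           frozenset(annotation.loc[annotation["is_corum"], "gene"]),
                           "complex"))

matched = fc.dropna(subset=["mrna_log2fc", "protein_log2fc"]).set_index("gene")
result = enrichment_2d(matched["mrna_log2fc"], matched["protein_log2fc"], terms,
                       min_size=10, fdr_threshold=0.02, filter_results=False)

print(result[["term_id", "n_members", "score_x", "score_y", "p_value", "fdr"]]
      .round(4).to_string(index=False))
print()
print("score_x / score_y are mRNA / protein rank scores in [-1, 1];")
print("the monosomic chromosome term scores strongly negative in both")
print("dimensions and passes the 0.02 FDR threshold.")
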