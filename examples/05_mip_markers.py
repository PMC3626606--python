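"""MITE insertion polymorphism (MIP) marker analysis.

Simulates a 50-locus band-score panel over two diploids, their
allotetraploid and an outgroup; dates each insertion by its timing group;
clusters accessions by Jaccard/UPGMA; and tests F2 segregation.
"""

from mitescope.mip_analysis import (F2Counts, classify_matrix,
                                    jaccard_similarity, polymorphism_report,
                                    segregation_chi_square, summarize_groups,
                                    upgma_tree)
from mitescope.synthetic_data import simulate_f2, simulate_mip_panel

matrix, truth = simulate_mip_panel(50, within_species_poly_rate=0.0, seed=40)
labels = classify_matrix(matrix)
summary = summarize_groups(labels)
print("timing groups:", {g: summary["counts"][g]
                         for g in ("Bs", "Br-I", "Br-II", "Bo-I", "Bo-II")})
print(f"shared in the genus: {summary['shared_pct']}%  "
      f"species-unique: {summary['unique_pct']}%")
# Bs insertions predate the diploid split; -II groups postdate
# allopolyploidization, so they are the youngest

poly = polymorphism_report(matrix)
print(f"polymorphic loci across the panel: {poly['n_polymorphic']}"
      f"/{len(matrix.loci)} ({poly['polymorphic_pct']}%)")

tree = upgma_tree(jaccard_similarity(matrix))
print("UPGMA dendrogram:", tree.newick())
# merge heights are distance/2, so similarity level s cuts at (1-s)/2
print("clusters at similarity 0.30:",
      [sorted(c) for c in tree.cut((1 - 0.30) / 2)])

counts = simulate_f2(94, seed=41)
res = segregation_chi_square(counts)
print(f"simulated F2 {counts.n_p1hom}:{counts.n_het}:{counts.n_p2hom} -> "
      f"chi2={res['chi2']:.3f}, p={res['p']:.3f}")
obs = segregation_chi_square(F2Counts(22, 50, 21))
print(f"observed F2 22:50:21 -> chi2={obs['chi2']:.3f}, p={obs['p']:.3f} "
      f"(consistent with 1:2:1 codominant inheritance)")
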