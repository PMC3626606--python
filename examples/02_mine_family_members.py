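"""Mine family members of a consensus across a synthetic genome.

Plants 40 diverged copies (2% substitutions) into a 400 kb genome, mines
them back by seeded local alignment, filters to relatively intact members
and reconstructs one pre-insertion empty site.
"""

from mitescope.member_mining import (filter_intact, reconstruct_empty_site,
                                     search_members)
from mitescope.synthetic_data import (generate_gene_models, generate_genome,
                                      make_consensus_fixture, plant_elements)

model = make_consensus_fixture(seed=42)
genome = generate_genome(400_000, 0.6, seed=10)
genome, genes = generate_gene_models(genome, 20, seed=11)
res = plant_elements(genome, genes, model, 40, mutation_rate=0.02, seed=12)

hits = search_members(model.consensus, res.genome)
print(f"planted {len(res.truth)} copies, recovered {len(hits)} hits")
mean_id = sum(h.identity for h in hits) / len(hits)
print(f"mean identity {mean_id:.3f} "
      f"(copies diverged by 2% substitutions from the consensus)")

intact = filter_intact(hits, coverage_min=0.8, identity_min=0.8)
print(f"{len(intact)} hits cover >=80% of the element at >=80% identity")

site = reconstruct_empty_site(res.genome, hits[0], flank_len=30)
print(f"empty site around first hit: ...{site[20:45]}... "
      f"(one TA left where the element sat)")
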