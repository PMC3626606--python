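"""Structural validation of a Stowaway-like element.

Builds the 260 bp consensus fixture (33 bp TIRs, TA target-site
duplication), plants one copy in a small genome, and runs each structural
check plus the composite verdict.
"""

from mitescope.element_structure import (detect_tsd, find_tir, hairpin_score,
                                         validate_mite)
from mitescope.synthetic_data import generate_genome, make_consensus_fixture, plant_elements

model = make_consensus_fixture(length=260, tir_len=33, seed=42)
print(f"consensus: {len(model.consensus)} bp, "
      f"TIR {model.tir_len} bp, internal {model.internal_len} bp")

tir = find_tir(model.consensus)
print(f"TIR arms: {tir.arm_len} bp, {tir.mismatches} mismatches, "
      f"A+T {tir.at_fraction_arms:.2f}")
# the arms are the element's termini; >=0.69 A+T is the family's signature

genome = generate_genome(20_000, 0.6, seed=1)
res = plant_elements(genome, [], model, 1, mutation_rate=0.0, seed=2,
                     region_bias={"genic": 0, "near1k": 0, "near2k": 0,
                                  "near3k": 0, "intergenic": 1.0})
span = (res.truth[0].start, res.truth[0].end)

tsd = detect_tsd(res.genome, span)
print(f"TSD at insertion site: {tsd.motif!r} on both flanks")
# insertion duplicated the TA dinucleotide of the target site

print(f"hairpin propensity (paired fraction): "
      f"{hairpin_score(model.consensus):.2f}")

verdict = validate_mite(res.genome, span, model=model)
print(f"composite verdict: passes={verdict.passes}, checks={verdict.checks}")
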