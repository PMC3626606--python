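# Methods

## Element model and structural checks

An element is modelled as `TIR + internal + revcomp(TIR)` with a
dinucleotide `TA` target-site duplication (TSD) on both flanks. The
defaults describe the motivating family: 260 bp total, 33 bp TIR arms with
≥ 0.69 A+T, 194 bp internal region, whole element ≥ 0.55 A+T (the 0.55
whole-element bound is this package's choice; only the TIR composition is
a family signature).

**TIR detection** (`find_tir`) is ungapped: every arm length `L` in
[min_len, max_len] (defaults 10–60) pairs the 5' prefix against the
reverse complement of the 3' suffix; lengths with identity < 0.8 are
disqualified, and among qualifying lengths the arm maximizing
`matches − mismatches` is reported (ties toward fewer mismatches). A
"longest qualifying arm" rule is deliberately not used: for an exact
33 bp arm, any 34–41 bp extension trivially keeps identity ≥ 0.8, so the
longest qualifying arm would never equal the biological arm length. The
score rule stops the arm where ragged extension into the internal region
costs more than it gains. `N` never matches anything, including `N`.

**TSD detection** (`detect_tsd`) has two modes: Stowaway mode requires the
given motif (`TA`) on both immediate flanks; generic mode scans k = 11…2
and reports the longest identical flanking k-mer. Spans at a contig edge
return no call (conservative: unverifiable ≠ verified).

**Hairpin propensity** (`hairpin_pairs`) is the maximum number of
non-crossing Watson–Crick pairs with a minimum loop of 3 nt — a
base-pair-maximization proxy for fold-back structure, not a thermodynamic
model (no stacking, no ΔG). It is reported but disabled in the default
composite verdict, because fold-back structure is descriptive rather than
diagnostic for family membership.

**Composite validation** (`validate_mite`) checks, in order: length
< 600 bp, TIR present, TSD present, whole-element A+T ≥ 0.55, and
(optionally) normalized hairpin score ≥ 0.5.

**De novo scanning** (`scan_candidates`) enumerates TA…TA-bracketed
windows of 80–600 bp whose outermost 8 bp form an exact inverted repeat,
then fully validates each survivor. Because chance 10 bp/80% arms occur in
every A/T-rich megabase, the scanner's curation default demands a 16 bp
arm at 90% identity; this was calibrated on element-free simulated genomes
(0 false candidates over 6 × 0.5 Mb plus 3 × 1 Mb at 60% A+T; 15 bp gave
≈ 0.2/Mb) and leaves recovery of planted intact copies unchanged. The
exact-8 bp prefilter means copies whose outermost TIR bases are mutated
are invisible to the scanner — mining diverged members is
`search_members`' job. When a TA–TA flank context makes `span ± TSD` a
second valid candidate, the inner span is kept (the TSD is host sequence);
remaining overlaps resolve to the longest TIR arm.

## Member mining

`search_members` is a self-contained seed-and-extend nucleotide search:
exact 11-mer seeding of the query and its reverse complement, seed
clusters (diagonal starts within 120 bp) expanded to padded windows, and
local alignment of the query in each window with +1/−2 match/mismatch and
−5/−2 affine gaps. The optimal local alignment is computed by Biopython's
`PairwiseAligner` (C implementation) with an explicit ACGTN matrix so `N`
matches nothing; tests verify its scores against an independent
pure-Python Smith–Waterman on short pairs. E-values use the
Karlin–Altschul form `E = K·m·n·e^(−λS)` with (λ, K) = (1.28, 0.46), the
ungapped approximation for the +1/−2 scheme; the default cutoff is 1e−10.
`identity` is the matching fraction of aligned columns; `coverage` is the
aligned fraction of the *consensus* (the element structure), so truncated
copies score low coverage regardless of their local identity.

Overlapping hits are merged to the best-scoring one **regardless of
strand**: a TIR-bearing query always produces a weaker mirror-orientation
arm match over the same locus, which is the same element, not a second
copy (keeping it would double every copy count). Abutting hits stay
separate, so fragmented adjacent elements are preserved. `filter_intact`
keeps hits with coverage ≥ 0.8 **and** identity ≥ 0.8 (both phrasings of
"relatively intact" appear in the field; both thresholds are exposed).

An engine limitation: this is desk-scale (a few Mb per call). For real
genomes, external BLASTn hits can be loaded into the same `ElementHit`
type via `io_formats.read_hits`.

## Insertion annotation

Distance is the gap between the hit span and the nearest gene span
(transcription unit, not CDS); overlap ⇒ genic, with the exon/intron
sub-call made at the hit midpoint (robust to boundary-straddling hits).
Bins: 0 < d < 1 kb, 1–2 kb, 2–3 kb, and intergenic. The sources describe
the outer boundary as both "less than 3 kb" and "> 3 kb", leaving
d = 3000 unassigned; this package assigns d ≥ 3000 to intergenic.
Percentages are rounded half-up to one decimal, which reproduces the
printed 697-element table exactly (10.2/40.3/19.2/8.9/21.4; 548 = 78.6%
within 3 kb). Chromosome density is Mb per element to two decimals;
chromosomes with zero elements are flagged rather than given an infinite
density.

## Copy number

`proportional_estimate`: `N = round(H·G/D)`, half-up (printed estimates
are integers). `gss_formula_estimate` evaluates the published
survey-sequence formula **verbatim**:
`N = ((1/c)/2)·H·(1 + (L−2T)/(L+2T))`, c = D/G. The printed formula's
brackets are unbalanced; this reading is the literal one, every term is
reported, and each estimate carries a provenance note. On the printed
survey inputs it yields 540 (*B. oleracea*: H=399, D=470 Mb, G=696 Mb,
L=700, T=33) and 759 (*B. napus*: H=11, D=15 Mb, G=1132 Mb), whereas the
source table prints 1464 and 2490 — the formula as printed does not
reproduce its own table (the source is also internally inconsistent about
H and D for these rows), so the discrepancy is documented rather than
patched, and only the proportional estimate (1440) is treated as
reproducible. The correction factor `1 + (L−2T)/(L+2T)` lies in (1, 2) for
0 < 2T < L and decreases in T.

`estimate_ci` quantifies both estimators by simulation (fresh survey reads
→ search → estimate, per replicate; a read contributes at most one hit);
`assembly_subset_estimates` checks the proportional estimator on random
tile subsets of an assembly (100 kb tiles; hits wholly inside retained
tiles are counted, so ~0.1% of boundary-straddling hits are lost — far
inside the 5% recovery tolerance used).

## MIP analysis

Species-level presence uses the **any-accession** rule by default (a
species is "present" if any of its accessions shows the band); `all` and
`majority` are available because the sources never state how accession
disagreement rolls up. Timing groups: rapa ∧ oleracea → Bs; one diploid
only → -I if the allotetraploid carries the band, else -II;
allotetraploid-only or empty → unclassified (the five-group scheme has no
bin for these). Shared/unique percentages are reported to the nearest
integer, raw fractions alongside.

Jaccard similarity ignores shared absences; an all-zero off-diagonal pair
is defined as J = 1 with a warning (no evidence of difference, but no
evidence at all). UPGMA uses arithmetic-mean cluster distances on
d = 1 − J, merge heights d/2 (so the tree is ultrametric), and breaks ties
by the lexicographically smallest pair of cluster names — fully
deterministic. The implementation is this package's own and is verified
against `scipy.cluster.hierarchy` average-linkage cophenetic distances; a
`cut(height)` operation yields clusters at a similarity level s via
height (1−s)/2. The F2 test is Pearson's χ² (scipy) against 1:2:1 with
df = 2; the observed 22:50:21 counts give χ² ≈ 0.548, p ≈ 0.76.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) using numpy's PCG64.

- **Genomes** are i.i.d. base draws at a target A+T (default 0.60 — a
  typical euchromatic plant composition). No repeats, no isochores, no
  pre-existing transposons.
- **Gene models** are non-overlapping, with 2–8 exons of 100–400 bp and
  introns of 80–400 bp by default; exon bodies are rewritten at 0.54 A+T
  and introns at 0.65 A+T, reproducing the coding/non-coding composition
  contrast the annotation analysis measures. No UTRs, no alternative
  splicing (multi-transcript GFF3 input uses the first transcript, with a
  warning), no nested genes.
- **Planting** replaces a genomic `TA` with `TA + copy + TA`, so empty-site
  reconstruction is exactly invertible at mutation rate 0. Copies receive
  i.i.d. substitutions (no indels — a deliberate simplification that keeps
  identity/coverage semantics crisp); the default rate 0.02 is a free
  choice standing in for an unpublished divergence distribution. The
  region bias defaults to the genome-wide observed proportions
  (71/281/134/62/149 of 697 for genic/<1 kb/1–2 kb/2–3 kb/intergenic);
  genic plantings are restricted to introns (an exonic override exists for
  negative tests). Chosen sites are kept ≥ 3.3 kb apart so no insertion
  can move another site across a distance-bin boundary, and gene models
  are returned coordinate-shifted into the post-insertion system — which
  is what makes "the classifier recovers every truth label" a meaningful
  invariant. Site selection is greedy with internal retries; simulated
  genomes should provide roughly one near-gene site per gene flank at
  this separation (100 genes per 2 Mb supports 200 planted copies
  comfortably).
- **Survey reads** are uniform fixed-length fragments (default 700 bp,
  both strands); `n = round(coverage·G/L)` exactly. No length jitter, no
  sequencing error, no paired ends.
- **MIP panels** draw each locus's timing group (default probabilities are
  the observed 50-locus tallies: 9/17/5/18/1 over Bs/Br-I/Br-II/Bo-I/
  Bo-II), set species states from the group definition (the allotetraploid
  carries the union of the diploid states for Bs), and flip accession
  calls independently at the within-species polymorphism rate. The
  outgroup is always absent. Two rapa, three oleracea, two napus and one
  outgroup accession by default, mirroring a typical genotyping panel.
- **F2 counts** are multinomial (¼, ½, ¼).

Passing tests on these inputs demonstrate the pipeline's internal
consistency — recall on planted copies, exact empty-site inversion,
estimator bias, label recovery — not performance on real genomes, which
contain nested/truncated elements, indel divergence and repeat families
this generator deliberately omits.

## Problem sizes and tolerances

The test suite and acceptance script use: 2 Mb genomes with 100 genes and
200 planted copies (recall, validation, empty sites, subset estimates at
50% retention × 100 replicates), 1 Mb element-free genomes for scanner
specificity, 60-locus MIP panels, and 10–100 replicate Monte-Carlo checks
with fixed seeds. Composition targets are asserted to ±0.01 (pooled over
≳10⁵ bases), mutation-rate identity to ±0.02–0.03, estimator recovery to
5%, and oracle equivalences exactly (hairpin, UPGMA) or to floating-point
tolerance (alignment scores). Everything runs in well under a minute on
one CPU.

## Known limitations

Gapped TIRs, autonomous-element (Mariner-like transposase) detection,
thermodynamic folding, translated search, repeat masking, promoter/UTR
annotation and linkage mapping beyond the single-locus χ² are out of
scope. The mining engine is not a replacement for BLAST+ at genome scale.
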