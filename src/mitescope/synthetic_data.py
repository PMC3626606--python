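"""Synthetic inputs with known ground truth.

Every generator here is a pure function of its parameters and a seed, and
emulates the statistical structure the analysis modules assume:

- a Stowaway-like consensus element: 260 bp, 33 bp A/T-rich terminal
  inverted repeats (TIRs), 194 bp internal region, TA target site
  duplication (TSD);
- genomes with gene models whose exons run ~54% A+T and introns ~65% A+T;
- element copies planted at existing TA dinucleotides (which become the
  duplicated TSD), biased toward gene-rich regions;
- low-coverage genome survey reads (700 bp);
- MITE insertion polymorphism (MIP) panels over two diploid species and
  their allotetraploid, plus an outgroup;
- F2 genotype counts segregating 1:2:1.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from ._seq import at_fraction, hamming, revcomp
from .io_formats import GeneModel, SequenceRecord

__all__ = [
    "ElementModel", "TruthRecord", "GssSurvey", "PlantResult",
    "ParameterError", "PlacementError",
    "make_consensus_fixture", "generate_genome", "generate_gene_models",
    "plant_elements", "simulate_gss", "simulate_mip_panel", "simulate_f2",
    "REGION_CLASSES", "DEFAULT_REGION_BIAS",
]


class ParameterError(ValueError):
    """A generator was called with infeasible or out-of-range parameters."""


class PlacementError(ValueError):
    """The genome cannot accommodate the requested placements."""


#: Region classes for insertion sites, in fixed reporting order.
REGION_CLASSES = ("genic", "near1k", "near2k", "near3k", "intergenic")

#: Default insertion bias: the observed genome-wide class proportions of a
#: high-copy Stowaway family in B. rapa (71/281/134/62/149 out of 697).
DEFAULT_REGION_BIAS = {
    "genic": 71 / 697,
    "near1k": 281 / 697,
    "near2k": 134 / 697,
    "near3k": 62 / 697,
    "intergenic": 149 / 697,
}

# Chosen sites are kept at least this far apart so that one insertion can
# never move another planted site across a distance-bin boundary.
_MIN_SITE_SEPARATION = 3300


@dataclass
class ElementModel:
    """Consensus sequence plus the structural parameters of the family."""

    consensus: str
    tir_len: int
    internal_len: int
    tsd_motif: str = "TA"
    at_min_tir: float = 0.69

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if self.tir_len < 1:
            raise ParameterError("tir_len must be >= 1 (TIRs are mandatory)")
        if len(self.consensus) != 2 * self.tir_len + self.internal_len:
            raise ParameterError(
                "consensus length must equal 2*tir_len + internal_len"
            )
        arm5 = self.consensus[: self.tir_len]
        arm3 = self.consensus[-self.tir_len:]
        mism = hamming(arm5, revcomp(arm3))
        if mism > int(0.2 * self.tir_len):
            raise ParameterError(
                f"TIR arms disagree at {mism} positions; not inverted repeats"
            )
        for arm in (arm5, arm3):
            if at_fraction(arm) < self.at_min_tir:
                raise ParameterError(
                    f"TIR arm A+T below required {self.at_min_tir}"
                )

    def __len__(self) -> int:
        return len(self.consensus)

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "tir_len": self.tir_len,
            "internal_len": self.internal_len,
            "tsd_motif": self.tsd_motif,
            "at_min_tir": self.at_min_tir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElementModel":
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for one planted copy (post-insertion coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    mutations_applied: int
    tsd: str
    region_class: str


@dataclass
class PlantResult:
    """Planted genome plus truth table and coordinate-shifted gene models."""

    genome: SequenceRecord
    truth: list[TruthRecord]
    genes: list[GeneModel]


@dataclass
class GssSurvey:
    """A genome-survey-sequence read set and its summary statistics."""

    reads: list[SequenceRecord]
    db_size: int
    mean_read_len: float
    genome_size: int

    def __post_init__(self) -> None:
        assert self.db_size == sum(len(r) for r in self.reads)

    @property
    def coverage(self) -> float:
        return self.db_size / self.genome_size


def _draw_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), size=n, p=p)).decode()


def make_consensus_fixture(length: int = 260, tir_len: int = 33,
                           at_min_tir: float = 0.69,
                           seed: int | None = None) -> ElementModel:
    """Generate a structurally valid Stowaway-like consensus.

    The element is ``tir_len`` A/T-rich TIR + internal region + exact
    reverse complement of the TIR, with TA as the TSD motif. Deterministic
    for a fixed seed.
    """
    if tir_len < 1:
        raise ParameterError("tir_len must be >= 1 (TIRs are mandatory)")
    internal = length - 2 * tir_len
    if internal < 1:
        raise ParameterError(
            f"length {length} leaves no internal region for tir_len {tir_len}"
        )
    from .element_structure import find_tir

    rng = np.random.default_rng(seed)
    for _ in range(1000):
        arm = _draw_seq(rng, tir_len, max(at_min_tir + 0.06, 0.72))
        if at_fraction(arm) < at_min_tir:
            continue
        inner = _draw_seq(rng, internal, 0.62)
        consensus = arm + inner + revcomp(arm)
        if at_fraction(consensus) < 0.6:
            continue
        # the detected TIR must be the nominal one: the internal region
        # must not extend the arm pairing
        tir = find_tir(consensus, min_len=min(10, tir_len),
                       max_len=max(60, tir_len))
        if tir is None or tir.arm_len != tir_len or tir.mismatches != 0:
            continue
        return ElementModel(
            consensus=consensus, tir_len=tir_len, internal_len=internal,
            tsd_motif="TA", at_min_tir=at_min_tir,
        )
    raise ParameterError("could not satisfy composition constraints")


def generate_genome(size: int, at_fraction_target: float = 0.6,
                    seed: int | None = None, name: str = "chr1") -> SequenceRecord:
    """I.i.d. random genome with P(A)=P(T)=at/2 and P(C)=P(G)=(1-at)/2."""
    if size < 1:
        raise ParameterError("genome size must be >= 1")
    if not 0 < at_fraction_target < 1:
        raise ParameterError("at_fraction must lie in the open interval (0,1)")
    rng = np.random.default_rng(seed)
    return SequenceRecord(id=name, seq=_draw_seq(rng, size, at_fraction_target))


DEFAULT_EXON_PROFILE = {
    "n_exons": (2, 8),
    "exon_len": (100, 400),
    "intron_len": (80, 400),
}


def generate_gene_models(genome: SequenceRecord, n_genes: int,
                         exon_profile: dict | None = None,
                         seed: int | None = None,
                         exon_at: float = 0.54, intron_at: float = 0.65,
                         min_gap: int = 400,
                         ) -> tuple[SequenceRecord, list[GeneModel]]:
    """Place non-overlapping gene models and rewrite their composition.

    Exon bases are regenerated at ``exon_at`` A+T and intron bases at
    ``intron_at`` A+T, mimicking the compositional contrast between coding
    and non-coding genic sequence in a euchromatic plant genome. Returns the
    rewritten genome and the gene models.
    """
    profile = dict(DEFAULT_EXON_PROFILE, **(exon_profile or {}))
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return genome, []
    structures = []
    for _ in range(n_genes):
        ne = int(rng.integers(profile["n_exons"][0], profile["n_exons"][1] + 1))
        exon_lens = rng.integers(profile["exon_len"][0],
                                 profile["exon_len"][1] + 1, size=ne)
        intron_lens = rng.integers(profile["intron_len"][0],
                                   profile["intron_len"][1] + 1, size=max(ne - 1, 0))
        structures.append((exon_lens, intron_lens))
    gene_lens = [int(e.sum() + i.sum()) for e, i in structures]
    total = sum(gene_lens) + min_gap * (n_genes + 1)
    free = len(genome.seq) - total
    if free < 0:
        raise PlacementError(
            f"genome of {len(genome.seq)} bp too small for {n_genes} genes"
        )
    # distribute the leftover space randomly among the n_genes+1 gaps
    extra = rng.multinomial(free, np.full(n_genes + 1, 1 / (n_genes + 1)))
    seq = list(genome.seq)
    genes = []
    pos = 0
    for i, ((exon_lens, intron_lens), glen) in enumerate(zip(structures, gene_lens)):
        pos += min_gap + int(extra[i])
        start = pos
        exons = []
        cur = start
        for j, el in enumerate(exon_lens):
            exons.append((cur, cur + int(el)))
            seq[cur : cur + int(el)] = _draw_seq(rng, int(el), exon_at)
            cur += int(el)
            if j < len(intron_lens):
                il = int(intron_lens[j])
                seq[cur : cur + il] = _draw_seq(rng, il, intron_at)
                cur += il
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(
            gene_id=f"gene_{i + 1:04d}", chrom=genome.id,
            start=start, end=start + glen, strand=strand, exons=exons,
        ))
        pos = start + glen
    return SequenceRecord(id=genome.id, seq="".join(seq)), genes


def _classify_ta_sites(ta: np.ndarray, genes: list[GeneModel]) -> np.ndarray:
    """Region class index per TA site; -1 for unusable (boundary-straddling
    or exon-overlapping) sites. Distances anticipate the post-insertion
    element span so planting and downstream classification agree."""
    classes = np.full(ta.size, -1, dtype=np.int64)
    if not genes:
        classes[:] = REGION_CLASSES.index("intergenic")
        return classes
    gs = np.array([g.start for g in genes])
    ge = np.array([g.end for g in genes])
    idx = np.searchsorted(gs, ta, side="right") - 1
    for i, p in enumerate(ta):
        j = int(idx[i])
        if j >= 0 and gs[j] <= p and p + 2 <= ge[j]:
            # inside a gene: usable only if the TA lies wholly in an intron
            for s, e in genes[j].introns:
                if s <= p and p + 2 <= e:
                    classes[i] = REGION_CLASSES.index("genic")
                    break
            continue
        if j >= 0 and p < ge[j]:
            continue  # straddles a gene boundary
        d_left = (p + 2) - ge[j] if j >= 0 else np.inf
        d_right = gs[j + 1] - p if j + 1 < len(gs) else np.inf
        d = min(d_left, d_right)
        if d <= 0:
            continue
        if d < 1000:
            classes[i] = REGION_CLASSES.index("near1k")
        elif d < 2000:
            classes[i] = REGION_CLASSES.index("near2k")
        elif d < 3000:
            classes[i] = REGION_CLASSES.index("near3k")
        else:
            classes[i] = REGION_CLASSES.index("intergenic")
    return classes


def _select_sites(ta: np.ndarray, classes: np.ndarray, want: np.ndarray,
                  rng: np.random.Generator) -> tuple[list[int], dict[int, str]]:
    """Greedy per-class selection of TA sites respecting the separation."""
    chosen: list[int] = []  # kept sorted
    chosen_class: dict[int, str] = {}
    for ci, cname in enumerate(REGION_CLASSES):
        pool = ta[classes == ci]
        if want[ci] > len(pool):
            raise PlacementError(
                f"not enough TA sites in region class {cname!r}: "
                f"need {want[ci]}, have {len(pool)}"
            )
        order = rng.permutation(len(pool))
        taken = 0
        for k in order:
            if taken == want[ci]:
                break
            p = int(pool[k])
            j = bisect.bisect_left(chosen, p)
            if j > 0 and p - chosen[j - 1] < _MIN_SITE_SEPARATION:
                continue
            if j < len(chosen) and chosen[j] - p < _MIN_SITE_SEPARATION:
                continue
            chosen.insert(j, p)
            chosen_class[p] = cname
            taken += 1
        if taken < want[ci]:
            raise PlacementError(
                f"could not place {want[ci]} elements in region class "
                f"{cname!r} with {_MIN_SITE_SEPARATION} bp separation"
            )
    return chosen, chosen_class


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0:
        return seq, 0
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[int(rng.integers(3))]
    return "".join(arr), int(hits.size)


def plant_elements(genome: SequenceRecord, genes: list[GeneModel],
                   model: ElementModel, n: int, mutation_rate: float = 0.02,
                   region_bias: dict | None = None, seed: int | None = None,
                   allow_exonic: bool = False) -> PlantResult:
    """Plant ``n`` mutated element copies at existing TA dinucleotides.

    Each insertion replaces one genomic ``TA`` with ``TA + copy + TA``, so
    the target dinucleotide becomes the duplicated TSD and excising the
    element plus one TA restores the pre-insertion sequence exactly. Genic
    insertions are restricted to introns. Copies receive i.i.d. base
    substitutions at ``mutation_rate``. Returns the new genome, a truth
    table in post-insertion coordinates, and gene models shifted to match.
    """
    if not 0 <= mutation_rate <= 0.3:
        raise ParameterError("mutation_rate must lie in [0, 0.3]")
    if model.tsd_motif != "TA":
        raise ParameterError("planting currently supports the TA TSD motif only")
    bias = dict(DEFAULT_REGION_BIAS if region_bias is None else region_bias)
    if set(bias) != set(REGION_CLASSES):
        raise ParameterError(f"region_bias must have keys {REGION_CLASSES}")
    probs = np.array([bias[c] for c in REGION_CLASSES], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ParameterError("region_bias must sum to 1")
    rng = np.random.default_rng(seed)
    seq = genome.seq
    enc = np.frombuffer(seq.encode(), np.uint8)
    ta = np.flatnonzero((enc[:-1] == ord("T")) & (enc[1:] == ord("A")))
    classes = _classify_ta_sites(ta, genes)
    if allow_exonic:
        # negative-testing override: treat exon-internal TA sites as genic
        gs = np.array([g.start for g in genes]) if genes else np.empty(0)
        ge = np.array([g.end for g in genes]) if genes else np.empty(0)
        for i, p in enumerate(ta):
            j = int(np.searchsorted(gs, p, side="right") - 1) if genes else -1
            if j >= 0 and gs[j] <= p and p + 2 <= ge[j]:
                classes[i] = REGION_CLASSES.index("genic")
    want = rng.multinomial(n, probs)
    chosen, chosen_class = None, None
    failure: PlacementError | None = None
    for _attempt in range(5):  # greedy selection may dead-end; retry fresh
        try:
            chosen, chosen_class = _select_sites(ta, classes, want, rng)
            break
        except PlacementError as exc:
            failure = exc
    if chosen is None:
        raise failure
    L = len(model)
    parts = []
    truth = []
    prev = 0
    offset = 0
    for p in chosen:
        copy, n_mut = _mutate(model.consensus, mutation_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = copy if strand == "+" else revcomp(copy)
        parts.append(seq[prev:p])
        parts.append("TA" + planted + "TA")
        truth.append(TruthRecord(
            chrom=genome.id, start=p + 2 + offset, end=p + 2 + L + offset,
            strand=strand, mutations_applied=n_mut, tsd="TA",
            region_class=chosen_class[p],
        ))
        prev = p + 2
        offset += L + 2
    parts.append(seq[prev:])
    new_seq = "".join(parts)
    ips = np.array(chosen) + 2  # insertion points in old coordinates
    def shift(x: int) -> int:
        return int(x + (L + 2) * np.searchsorted(ips, x, side="right"))
    new_genes = [
        GeneModel(
            gene_id=g.gene_id, chrom=g.chrom, start=shift(g.start),
            end=shift(g.end), strand=g.strand,
            exons=[(shift(s), shift(e)) for s, e in g.exons],
        )
        for g in genes
    ]
    return PlantResult(
        genome=SequenceRecord(id=genome.id, seq=new_seq),
        truth=truth, genes=new_genes,
    )


def simulate_gss(genome: SequenceRecord, coverage: float, read_len: int = 700,
                 seed: int | None = None) -> GssSurvey:
    """Uniform fixed-length shotgun reads at the requested coverage.

    Emits round(coverage * G / L) reads; both strands sampled equally.
    """
    G = len(genome.seq)
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    if read_len > G:
        raise ParameterError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    n = round(coverage * G / read_len)
    starts = rng.integers(0, G - read_len + 1, size=n)
    reads = []
    for i, s in enumerate(sorted(int(x) for x in starts)):
        frag = genome.seq[s : s + read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(SequenceRecord(id=f"gss_{i + 1:06d}", seq=frag))
    return GssSurvey(
        reads=reads, db_size=sum(len(r) for r in reads),
        mean_read_len=read_len if n else 0.0, genome_size=G,
    )


#: Default accessions per species, mirroring a typical MIP genotyping panel
#: over two Brassica diploids, their allotetraploid, and A. thaliana.
DEFAULT_ACCESSIONS = {
    "B.rapa": 2,
    "B.oleracea": 3,
    "B.napus": 2,
    "outgroup": 1,
}

#: Default timing-group probabilities: the tallies observed for a 50-locus
#: panel (9 Bs, 17 Br-I, 5 Br-II, 18 Bo-I, 1 Bo-II).
DEFAULT_GROUP_PROBS = {
    "Bs": 9 / 50, "Br-I": 17 / 50, "Br-II": 5 / 50,
    "Bo-I": 18 / 50, "Bo-II": 1 / 50,
}

# species-level presence (rapa, oleracea, napus) implied by each group
_GROUP_STATE = {
    "Bs": (1, 1, 1),
    "Br-I": (1, 0, 1),
    "Br-II": (1, 0, 0),
    "Bo-I": (0, 1, 1),
    "Bo-II": (0, 1, 0),
}


def simulate_mip_panel(n_loci: int, group_probs: dict | None = None,
                       accessions_per_species: dict | None = None,
                       within_species_poly_rate: float = 0.0,
                       seed: int | None = None):
    """Simulate a MIP band-score matrix with known timing-group truth.

    Each locus draws a timing group; species-level presence follows the
    group definition (the allotetraploid carries the union of the diploid
    states). Accession calls equal the species state, flipped independently
    at ``within_species_poly_rate``. The outgroup is always absent. Returns
    (MipMatrix, truth group labels).
    """
    from .mip_analysis import MipMatrix, TIMING_GROUPS

    probs = dict(DEFAULT_GROUP_PROBS if group_probs is None else group_probs)
    if set(probs) != set(TIMING_GROUPS):
        raise ParameterError(f"group_probs must have keys {TIMING_GROUPS}")
    pvec = np.array([probs[g] for g in TIMING_GROUPS], dtype=float)
    if (pvec < 0).any() or not np.isclose(pvec.sum(), 1.0):
        raise ParameterError("group_probs must be nonnegative and sum to 1")
    if not 0 <= within_species_poly_rate <= 1:
        raise ParameterError("within_species_poly_rate must lie in [0,1]")
    acc = dict(DEFAULT_ACCESSIONS if accessions_per_species is None
               else accessions_per_species)
    for sp in ("B.rapa", "B.oleracea", "B.napus"):
        if acc.get(sp, 0) < 1:
            raise ParameterError(f"need at least one accession of {sp}")
    rng = np.random.default_rng(seed)
    accessions, species = [], []
    for sp, k in acc.items():
        for i in range(k):
            accessions.append(f"{sp}_{i + 1}")
            species.append(sp)
    loci = [f"locus_{i + 1:03d}" for i in range(n_loci)]
    truth = [TIMING_GROUPS[int(i)]
             for i in rng.choice(len(TIMING_GROUPS), size=n_loci, p=pvec)]
    cells = np.zeros((len(accessions), n_loci), dtype=np.int64)
    sp_index = {"B.rapa": 0, "B.oleracea": 1, "B.napus": 2}
    for j, grp in enumerate(truth):
        state = _GROUP_STATE[grp]
        for i, sp in enumerate(species):
            if sp == "outgroup":
                continue
            v = state[sp_index[sp]]
            if within_species_poly_rate and rng.random() < within_species_poly_rate:
                v = 1 - v
            cells[i, j] = v
    return MipMatrix(accessions=accessions, species=species, loci=loci,
                     cells=cells), truth


def simulate_f2(n: int, seed: int | None = None):
    """Multinomial F2 genotype counts under codominant 1:2:1 segregation."""
    from .mip_analysis import F2Counts

    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a, h, b = rng.multinomial(n, [0.25, 0.5, 0.25])
    return F2Counts(n_p1hom=int(a), n_het=int(h), n_p2hom=int(b))
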