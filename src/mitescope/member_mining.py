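"""Genome-wide mining of family members of a consensus element.

A self-contained seed-and-extend nucleotide search: exact word seeding on
both strands, local alignment around each seed cluster (affine gaps), and
Karlin-Altschul E-values. Desk-scale by design — a few megabases per call —
with hit semantics matching a conventional BLASTn workflow so that results
from an external aligner can be dropped into the same downstream analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import kmer_codes, revcomp
from .io_formats import SequenceRecord

__all__ = [
    "ElementHit", "SearchParams", "search_members", "filter_intact",
    "extract_flanks", "reconstruct_empty_site", "ReconstructionError",
]


class ReconstructionError(ValueError):
    """Empty-site reconstruction failed (no TSD on a flank)."""


@dataclass
class ElementHit:
    """A located family member on a genome.

    ``identity`` is the fraction of aligned columns that match; ``coverage``
    is the fraction of the consensus covered by the alignment (measured
    over the query, i.e. the element structure, not over the hit).
    """

    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    score: float
    evalue: float
    tsd: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SearchParams:
    """Nucleotide-search parameters (conventional BLASTn-style defaults)."""

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    evalue_max: float = 1e-10
    identity_min: float = 0.0
    coverage_min: float = 0.0
    # Karlin-Altschul parameters for the +1/-2 scheme (ungapped approximation)
    lambda_: float = 1.28
    k: float = 0.46
    # seeds whose implied element starts are within this distance are one window
    cluster_gap: int = 120
    window_pad: int = 40

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        open_gap_score=params.gap_open,
        extend_gap_score=params.gap_extend,
    )
    # explicit matrix over ACGTN so that N matches nothing, itself included
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = params.match if (a == b and a != "N") else params.mismatch
    aligner.substitution_matrix = mat
    return aligner


def evalue(score: float, m: int, n: int, params: SearchParams) -> float:
    """Karlin-Altschul expectation value E = K * m * n * exp(-lambda * S)."""
    return params.k * m * n * math.exp(-params.lambda_ * score)


def _alignment_stats(aln) -> tuple[int, int, int, int, int]:
    """(matches, aligned_columns, query_cols, target_start, target_end)."""
    tblocks, qblocks = aln.aligned
    matches = 0
    cols = 0
    qcols = 0
    target, query = aln.target, aln.query
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b and a != "N":
                matches += 1
        cols += te - ts
        qcols += qe - qs
    # gap columns between consecutive aligned blocks
    for i in range(len(tblocks) - 1):
        cols += (tblocks[i + 1][0] - tblocks[i][1]) + (qblocks[i + 1][0] - qblocks[i][1])
    return matches, cols, qcols, int(tblocks[0][0]), int(tblocks[-1][1])


def _seed_windows(qcodes_map: dict[int, list[int]], genome_codes: np.ndarray,
                  qlen: int, params: SearchParams) -> list[tuple[int, int]]:
    """Cluster seed diagonals into candidate genomic windows."""
    starts = []
    hits = np.flatnonzero(np.isin(genome_codes, list(qcodes_map.keys())))
    for g in hits:
        for qoff in qcodes_map[int(genome_codes[g])]:
            starts.append(int(g) - qoff)
    if not starts:
        return []
    starts.sort()
    windows = []
    ws = starts[0]
    prev = starts[0]
    for s in starts[1:]:
        if s - prev > params.cluster_gap:
            windows.append((ws, prev))
            ws = s
        prev = s
    windows.append((ws, prev))
    pad = params.window_pad
    return [(max(0, a - pad), b + qlen + pad) for a, b in windows]


def search_members(consensus: str | SequenceRecord,
                   genome: SequenceRecord | list[SequenceRecord] | str,
                   params: SearchParams | None = None) -> list[ElementHit]:
    """Find family members of ``consensus`` on both strands of ``genome``.

    Seeds exact ``word_size``-mers of the query (and its reverse
    complement), clusters seeds into candidate windows, locally aligns the
    query within each window, and retains hits with E-value at most
    ``evalue_max``. Overlapping same-strand hits are merged to the best
    scoring one. Hit spans are always reported on the forward strand of the
    genome, with ``strand`` recording the query orientation.
    """
    params = params or SearchParams()
    query = (consensus.seq if isinstance(consensus, SequenceRecord)
             else str(consensus)).upper()
    if len(query) < params.word_size:
        raise ValueError("consensus shorter than word_size")
    if isinstance(genome, str):
        genome = [SequenceRecord(id="seq", seq=genome)]
    elif isinstance(genome, SequenceRecord):
        genome = [genome]
    total_n = sum(len(g.seq) for g in genome)
    aligner = _aligner(params)
    queries = {"+": query, "-": revcomp(query)}
    qcodes: dict[str, dict[int, list[int]]] = {}
    for strand, q in queries.items():
        codes = kmer_codes(q, params.word_size)
        d: dict[int, list[int]] = {}
        for off, c in enumerate(codes):
            if c >= 0:
                d.setdefault(int(c), []).append(off)
        qcodes[strand] = d
    hits: list[ElementHit] = []
    for rec in genome:
        gcodes = kmer_codes(rec.seq, params.word_size)
        for strand, q in queries.items():
            for ws, we in _seed_windows(qcodes[strand], gcodes, len(q), params):
                window = rec.seq[ws : min(we, len(rec.seq))]
                alns = aligner.align(window, q)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                score = aln.score
                ev = evalue(score, len(query), total_n, params)
                if ev > params.evalue_max:
                    continue
                matches, cols, qcols, t0, t1 = _alignment_stats(aln)
                if cols == 0:
                    continue
                hits.append(ElementHit(
                    chrom=rec.id, start=ws + t0, end=ws + t1, strand=strand,
                    identity=matches / cols, coverage=qcols / len(query),
                    score=float(score), evalue=ev,
                ))
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[ElementHit]) -> list[ElementHit]:
    """Resolve >=1 bp overlaps to the best-scoring hit.

    Overlaps are merged regardless of strand: a query with terminal
    inverted repeats always yields a weaker mirror-orientation arm match
    over the same locus, which is the same element, not a second copy.
    Abutting (non-overlapping) hits stay separate.
    """
    kept: list[ElementHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.chrom, h.start)):
        clash = any(
            k.chrom == h.chrom and h.start < k.end and k.start < h.end
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start))
    return kept


def filter_intact(hits: list[ElementHit], coverage_min: float = 0.8,
                  identity_min: float = 0.8) -> list[ElementHit]:
    """Keep relatively intact members: coverage AND identity at thresholds.

    Both cutoffs are inclusive; the defaults retain members covering at
    least 80% of the element structure at 80% identity.
    """
    return [h for h in hits
            if h.coverage >= coverage_min and h.identity >= identity_min]


def extract_flanks(genome: str | SequenceRecord, hit: ElementHit,
                   flank_len: int) -> tuple[str, str]:
    """Sequences immediately flanking a hit, truncated at contig ends."""
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    seq = genome.seq if isinstance(genome, SequenceRecord) else genome
    left = seq[max(0, hit.start - flank_len) : hit.start]
    right = seq[hit.end : hit.end + flank_len]
    return left, right


def reconstruct_empty_site(genome: str | SequenceRecord, hit: ElementHit,
                           tsd: str = "TA", flank_len: int = 50) -> str:
    """Reconstruct the pre-insertion allele around a hit.

    The empty site carries exactly one copy of the TSD where the element
    (plus its duplicated TSD) sits: left flank + tsd + right flank. Raises
    ReconstructionError when either immediate flank is not the TSD.
    """
    seq = genome.seq if isinstance(genome, SequenceRecord) else genome
    k = len(tsd)
    left_tsd = seq[hit.start - k : hit.start]
    right_tsd = seq[hit.end : hit.end + k]
    if left_tsd != tsd or right_tsd != tsd:
        raise ReconstructionError(
            f"hit {hit.chrom}:{hit.start}-{hit.end} not flanked by "
            f"{tsd!r} (saw {left_tsd!r}/{right_tsd!r})"
        )
    left = seq[max(0, hit.start - k - flank_len) : hit.start - k]
    right = seq[hit.end + k : hit.end + k + flank_len]
    return left + tsd + right
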