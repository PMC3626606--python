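"""Structural characterization of MITE candidates.

A Stowaway-like MITE is short (<600 bp), A/T rich, bounded by terminal
inverted repeats (TIRs: the 5' prefix is the reverse complement of the 3'
suffix) and flanked by a duplicated TA target site. This module detects
those features on candidate spans and provides a desk-scale candidate
scanner over whole (small) genomes.

The hairpin score is a base-pair-maximization proxy (non-crossing
Watson-Crick pairing with a minimum loop), not a thermodynamic folding
model; it is reported but disabled in the default composite verdict.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import at_fraction, hamming, kmer_codes, revcomp
from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TirReport", "TsdReport", "StructuralVerdict", "ScanParams",
    "find_tir", "detect_tsd", "at_content", "hairpin_pairs", "hairpin_score",
    "validate_mite", "scan_candidates",
]


@dataclass
class TirReport:
    """Longest qualifying terminal inverted-repeat pairing of an element."""

    arm_len: int
    mismatches: int
    arm5_span: tuple[int, int]
    arm3_span: tuple[int, int]
    at_fraction_arms: float


@dataclass
class TsdReport:
    """Target site duplication found on the immediate flanks of a span."""

    motif: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]


@dataclass
class StructuralVerdict:
    """Composite structural validation result; always returned."""

    passes: bool
    checks: dict[str, bool]
    tir: TirReport | None = None
    tsd: TsdReport | None = None
    at: float | None = None
    hairpin_norm: float | None = None


def at_content(seq: str) -> float:
    """A+T fraction over called bases; N excluded from both numerator and
    denominator. Undefined (ValueError) for empty or all-N input."""
    return at_fraction(seq)


def find_tir(seq: str, min_len: int = 10, max_len: int = 60,
             identity_min: float = 0.8) -> TirReport | None:
    """Best terminal inverted-repeat arm pairing, ungapped.

    Every arm length L in [min_len, max_len] pairs the 5' prefix against
    the reverse complement of the 3' suffix; lengths whose identity falls
    below ``identity_min`` are disqualified. Among qualifying lengths the
    arm maximizing matches - mismatches is reported, so a clean arm is not
    inflated by a ragged extension into the internal region; equal scores
    resolve toward fewer mismatches. Returns None when no length
    qualifies. N never matches.
    """
    n = len(seq)
    if n < 2 * min_len:
        return None
    seq = seq.upper()
    best = None
    for L in range(min_len, min(max_len, n // 2) + 1):
        mism = hamming(seq[:L], revcomp(seq[-L:]))
        if 1 - mism / L < identity_min:
            continue
        score = L - 2 * mism
        if best is None or score > best[2] or (score == best[2] and mism < best[1]):
            best = (L, mism, score)
    if best is None:
        return None
    L, mism, _ = best
    arms = seq[:L] + seq[-L:]
    return TirReport(
        arm_len=L, mismatches=mism, arm5_span=(0, L), arm3_span=(n - L, n),
        at_fraction_arms=at_fraction(arms),
    )


def detect_tsd(genome: str | SequenceRecord, span: tuple[int, int],
               motif: str | None = "TA", max_len: int = 11) -> TsdReport | None:
    """Target-site duplication on the immediate flanks of ``span``.

    With ``motif`` given (Stowaway mode) both flanks must equal the motif
    exactly. With ``motif=None`` (generic mode) the longest k in [2, max_len]
    with identical immediate flanking k-mers is reported, preferring larger
    k. Spans at a contig edge with no verifiable flank return None.
    """
    seq = genome.seq if isinstance(genome, SequenceRecord) else genome
    s, e = span
    if motif is not None:
        k = len(motif)
        if s - k < 0 or e + k > len(seq):
            logger.info("span %s at contig edge: flank truncated, no TSD call", span)
            return None
        if seq[s - k : s] == motif and seq[e : e + k] == motif and "N" not in motif:
            return TsdReport(motif=motif, left_span=(s - k, s), right_span=(e, e + k))
        return None
    for k in range(min(max_len, 11), 1, -1):
        if s - k < 0 or e + k > len(seq):
            continue
        left = seq[s - k : s]
        if left == seq[e : e + k] and "N" not in left:
            return TsdReport(motif=left, left_span=(s - k, s), right_span=(e, e + k))
    if s - 2 < 0 or e + 2 > len(seq):
        logger.info("span %s at contig edge: flank truncated, no TSD call", span)
    return None


def hairpin_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of non-crossing Watson-Crick pairs (A-T, G-C).

    Dynamic program over subsequences: a base j either stays unpaired or
    pairs with some earlier base k at distance > min_loop, splitting the
    problem in two. This measures fold-back (hairpin) propensity only; no
    stacking or free-energy terms.
    """
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 = {min_loop + 2}")
    s = seq.upper()
    pairable = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]
            for k in range(i, j - min_loop):
                if (s[k], s[j]) in pairable:
                    left = N[i][k - 1] if k > i else 0
                    cand = left + N[k + 1][j - 1] + 1
                    if cand > best:
                        best = cand
            N[i][j] = best
    return N[0][n - 1]


def hairpin_score(seq: str, min_loop: int = 3) -> float:
    """Hairpin pairs normalized by the maximum possible, len(seq)/2."""
    return hairpin_pairs(seq, min_loop) / (len(seq) / 2)


DEFAULT_VALIDATE_THRESHOLDS = {
    "max_element_len": 600,
    "tir_min_len": 10,
    "tir_max_len": 60,
    "tir_identity_min": 0.8,
    "at_min": 0.55,
    "hairpin_min": 0.5,
    "check_hairpin": False,
}


def validate_mite(genome: str | SequenceRecord, span: tuple[int, int],
                  model=None, thresholds: dict | None = None) -> StructuralVerdict:
    """Composite structural verdict for a candidate span.

    Checks, in order: element length below the MITE bound (600 bp); a
    qualifying TIR; a TSD on both flanks (the model's motif for Stowaway,
    generic 2-11 bp otherwise); overall A+T at least ``at_min``; and,
    when enabled, normalized hairpin score at least ``hairpin_min`` (off by
    default: fold-back structure is descriptive, not diagnostic).
    """
    th = dict(DEFAULT_VALIDATE_THRESHOLDS, **(thresholds or {}))
    seq = genome.seq if isinstance(genome, SequenceRecord) else genome
    s, e = span
    if not (0 <= s < e <= len(seq)):
        raise ValueError(f"span {span} outside genome of length {len(seq)}")
    elem = seq[s:e]
    checks: dict[str, bool] = {}
    checks["length_ok"] = len(elem) < th["max_element_len"]
    tir = find_tir(elem, min_len=th["tir_min_len"], max_len=th["tir_max_len"],
                   identity_min=th["tir_identity_min"])
    checks["tir_ok"] = tir is not None
    motif = model.tsd_motif if model is not None else th.get("tsd_motif", "TA")
    tsd = detect_tsd(seq, span, motif=motif)
    checks["tsd_ok"] = tsd is not None
    try:
        at = at_fraction(elem)
    except ValueError:
        at = None
    checks["at_ok"] = at is not None and at >= th["at_min"]
    hp = None
    if th["check_hairpin"]:
        hp = hairpin_score(elem)
        checks["hairpin_ok"] = hp >= th["hairpin_min"]
    return StructuralVerdict(
        passes=all(checks.values()), checks=checks, tir=tir, tsd=tsd,
        at=at, hairpin_norm=hp,
    )


@dataclass
class ScanParams:
    """Parameters for the TA...TA-bracketed candidate scanner.

    The de novo scanner needs a stricter TIR requirement than per-span
    validation: a 10 bp arm at 80% identity is reached by chance in any
    megabase of A/T-rich sequence, so the scanner's curation default
    demands a 16 bp arm at 90% identity (zero chance candidates per
    megabase of element-free 60% A+T sequence in calibration). Both are
    configuration, not biology; loosen them to trade specificity for
    sensitivity.
    """

    min_len: int = 80
    max_len: int = 600
    min_tir: int = 16
    tir_identity_min: float = 0.9
    tsd_motif: str = "TA"
    # exact terminal seed used to prefilter TA pairs before full validation;
    # copies whose outermost prefilter_len TIR bases are mutated are missed
    prefilter_len: int = 8
    thresholds: dict = field(default_factory=dict)


def scan_candidates(genome: str | SequenceRecord,
                    params: ScanParams | None = None
                    ) -> list[tuple[tuple[int, int], StructuralVerdict]]:
    """De novo candidate scan: TA...TA windows with qualifying termini.

    Enumerates pairs of TA dinucleotides bracketing a window of allowed
    length whose outermost ``prefilter_len`` bases form an exact inverted
    repeat, then runs the full structural validation on each survivor.
    Overlapping passing candidates are resolved to the longest TIR arm.
    """
    params = params or ScanParams()
    seq = (genome.seq if isinstance(genome, SequenceRecord) else genome).upper()
    n = len(seq)
    k = params.prefilter_len
    enc = np.frombuffer(seq.encode(), np.uint8)
    ta = np.flatnonzero((enc[:-1] == ord("T")) & (enc[1:] == ord("A")))
    if ta.size == 0 or n < params.min_len + 4:
        return []
    fwd = kmer_codes(seq, k)                     # code of seq[p:p+k]
    rc_codes = kmer_codes(revcomp(seq), k)       # code of revcomp(seq)[q:q+k]
    # element candidate: starts at s = ta_i + 2, ends at e = ta_j;
    # termini qualify when seq[s:s+k] == revcomp(seq[e-k:e]), i.e.
    # fwd[s] == rc_codes[n - e]
    end_by_code: dict[int, list[int]] = defaultdict(list)
    for p in ta:
        e = int(p)                                # element end candidate
        if e - k >= 0 and n - e < rc_codes.size and rc_codes[n - e] >= 0:
            end_by_code[int(rc_codes[n - e])].append(e)
    for ends in end_by_code.values():
        ends.sort()
    candidates = []
    for p in ta:
        s = int(p) + 2
        if s + k > n or fwd[s] < 0:
            continue
        ends = end_by_code.get(int(fwd[s]))
        if not ends:
            continue
        lo = np.searchsorted(ends, s + params.min_len)
        hi = np.searchsorted(ends, s + params.max_len, side="right")
        for e in ends[lo:hi]:
            th = dict(params.thresholds)
            th.setdefault("tir_min_len", params.min_tir)
            th.setdefault("tir_identity_min", params.tir_identity_min)
            th.setdefault("max_element_len", params.max_len + 1)
            th.setdefault("tsd_motif", params.tsd_motif)
            verdict = validate_mite(seq, (s, e), thresholds=th)
            if verdict.passes:
                candidates.append(((s, e), verdict))
    # A TA-TA context around a true element also brackets span +/- the TSD:
    # the outer candidate's arms have merely absorbed the duplicated target
    # site, which is host sequence. Collapse such pairs to the inner span.
    spans = {c[0] for c in candidates}
    kmot = len(params.tsd_motif)
    candidates = [
        ((s, e), v) for (s, e), v in candidates
        if not ((s + kmot, e - kmot) in spans
                and seq[s : s + kmot] == params.tsd_motif
                and seq[e - kmot : e] == params.tsd_motif)
    ]
    # resolve remaining overlaps to the highest TIR arm length
    candidates.sort(key=lambda c: (-(c[1].tir.arm_len if c[1].tir else 0),
                                   c[0][0]))
    kept: list[tuple[tuple[int, int], StructuralVerdict]] = []
    for (s, e), v in candidates:
        if any(s < ke and ks < e for (ks, ke), _ in kept):
            continue
        kept.append(((s, e), v))
    kept.sort(key=lambda c: c[0])
    return kept
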