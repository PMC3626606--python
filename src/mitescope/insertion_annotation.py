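"""Classification of element insertions relative to gene models.

Insertions are binned by their distance to the nearest gene span: genic
(overlapping, sub-classified exon/intron by the hit midpoint), near-genic
at <1 kb, 1-2 kb and 2-3 kb, and intergenic at >=3 kb. The 3 kb boundary
itself is assigned to the intergenic bin. Percentages are rounded half-up
to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .io_formats import GeneModel, SequenceRecord

__all__ = [
    "InsertionClass", "DensityRecord", "PositionSummary",
    "classify_insertion", "summarize_positions", "chromosome_density",
    "regional_at_composition", "CATEGORIES",
]

#: Fixed reporting order of insertion categories.
CATEGORIES = ("GENIC", "NEAR_1KB", "NEAR_2KB", "NEAR_3KB", "INTERGENIC")

#: Maps the synthetic planter's region-class labels onto these categories.
REGION_CLASS_TO_CATEGORY = {
    "genic": "GENIC", "near1k": "NEAR_1KB", "near2k": "NEAR_2KB",
    "near3k": "NEAR_3KB", "intergenic": "INTERGENIC",
}


@dataclass
class InsertionClass:
    category: str
    sub: str  # exon | intron | none
    nearest_gene: str | None
    distance: int


@dataclass
class DensityRecord:
    """Per-chromosome element density: Mb of chromosome per element."""

    chrom: str
    length: int
    n_elements: int
    mb_per_element: float | None  # None when the chromosome has no elements


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open spans; 0 when they overlap."""
    if b[0] >= a[1]:
        return b[0] - a[1]
    if a[0] >= b[1]:
        return a[0] - b[1]
    return 0


def classify_insertion(hit, genes: list[GeneModel]) -> InsertionClass:
    """Classify one hit against the gene models of its chromosome.

    Distance is the minimum gap between the hit span and any gene span on
    the same chromosome (0 on overlap). Overlapping hits are GENIC, with
    the exon/intron sub-call made at the hit midpoint. Distance ties
    resolve to the leftmost gene.
    """
    span = (hit.start, hit.end)
    same = [g for g in genes if g.chrom == hit.chrom]
    if not same:
        return InsertionClass(category="INTERGENIC", sub="none",
                              nearest_gene=None, distance=-1)
    best_gene = None
    best_d = None
    for g in sorted(same, key=lambda g: g.start):
        d = _gap(span, g.span)
        if best_d is None or d < best_d:
            best_d, best_gene = d, g
    if best_d == 0:
        mid = (hit.start + hit.end) // 2
        sub = "intron"
        for s, e in best_gene.exons:
            if s <= mid < e:
                sub = "exon"
                break
        return InsertionClass(category="GENIC", sub=sub,
                              nearest_gene=best_gene.gene_id, distance=0)
    if best_d < 1000:
        cat = "NEAR_1KB"
    elif best_d < 2000:
        cat = "NEAR_2KB"
    elif best_d < 3000:
        cat = "NEAR_3KB"
    else:
        cat = "INTERGENIC"
    return InsertionClass(category=cat, sub="none",
                          nearest_gene=best_gene.gene_id, distance=best_d)


@dataclass
class PositionSummary:
    """Category counts and percentages plus the within-3-kb aggregate."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    within_3kb_count: int
    within_3kb_pct: float

    def as_rows(self) -> list[tuple[str, int, float]]:
        rows = [(c, self.counts[c], self.percentages[c]) for c in CATEGORIES]
        rows.append(("Total", self.total, 100.0))
        return rows


def summarize_positions(classes) -> PositionSummary:
    """Tally insertion categories and report percentages (half-up, 1 dp).

    Accepts InsertionClass objects, category names, or a mapping of
    category name to count. Also aggregates everything within 3 kb of a
    gene (genic plus all near-genic bins).
    """
    counts = dict.fromkeys(CATEGORIES, 0)
    if isinstance(classes, dict):
        for c, k in classes.items():
            counts[c] += int(k)
    else:
        items = list(classes)
        if not items:
            raise ValueError("no insertion classes to summarize")
        for item in items:
            cat = item.category if isinstance(item, InsertionClass) else str(item)
            counts[cat] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no insertion classes to summarize")
    pct = {c: _round_half_up(100 * counts[c] / total, 1) for c in CATEGORIES}
    within = sum(counts[c] for c in CATEGORIES[:-1])
    return PositionSummary(
        counts=counts, percentages=pct, total=total,
        within_3kb_count=within,
        within_3kb_pct=_round_half_up(100 * within / total, 1),
    )


def chromosome_density(hits, chrom_lengths: dict[str, int]
                       ) -> tuple[list[DensityRecord], float]:
    """Per-chromosome Mb-per-element density and mean elements/chromosome.

    Density is chromosome length in Mb divided by element count, rounded to
    2 decimals; chromosomes without elements get a None density (flagged
    degenerate rather than infinite).
    """
    per = dict.fromkeys(chrom_lengths, 0)
    for h in hits:
        if h.chrom not in chrom_lengths:
            raise ValueError(f"no length known for chromosome {h.chrom!r}")
        per[h.chrom] += 1
    records = []
    for chrom, length in chrom_lengths.items():
        n = per[chrom]
        mb = _round_half_up(length / 1e6 / n, 2) if n else None
        records.append(DensityRecord(chrom=chrom, length=length,
                                     n_elements=n, mb_per_element=mb))
    mean = sum(per.values()) / len(chrom_lengths)
    return records, mean


def regional_at_composition(genome: SequenceRecord | list[SequenceRecord],
                            genes: list[GeneModel]) -> dict:
    """Pooled A+T composition of exonic, intronic and intergenic space.

    Returns fractions and total bp per class; a class with no bases gets a
    None fraction.
    """
    genomes = genome if isinstance(genome, list) else [genome]
    # per-chromosome class mask: 0 intergenic, 1 intron, 2 exon
    encs = {g.id: np.frombuffer(g.seq.encode(), np.uint8) for g in genomes}
    masks = {cid: np.zeros(e.size, dtype=np.uint8) for cid, e in encs.items()}
    for g in genes:
        if g.chrom not in encs:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        masks[g.chrom][g.start : g.end] = 1
        for s, e in g.exons:
            masks[g.chrom][s:e] = 2
    out = {}
    for label, code in (("exonic", 2), ("intronic", 1), ("intergenic", 0)):
        at = acgt = 0
        for cid, enc in encs.items():
            sel = enc[masks[cid] == code]
            a = int(np.count_nonzero(sel == ord("A")) + np.count_nonzero(sel == ord("T")))
            c = int(np.count_nonzero(sel == ord("C")) + np.count_nonzero(sel == ord("G")))
            at += a
            acgt += a + c
        out[f"{label}_at"] = at / acgt if acgt else None
        out[f"{label}_bp"] = acgt
    return out
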