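"""Readers and writers for the formats the pipeline touches.

Internally every interval in this package is a 0-based half-open span.
GFF3 (1-based inclusive) and BED (0-based half-open) are converted at the
boundary, in this module only.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

from . import __version__
from ._seq import VALID_BASES

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the expected syntax."""


class GffValidationError(ValueError):
    """Raised when a GFF3 feature hierarchy is internally inconsistent."""


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}, uppercased on ingest."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence record {self.id!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene with its exon chain; introns are the within-span complement.

    ``span`` and ``exons`` use 0-based half-open coordinates. Exons must be
    sorted, non-overlapping and contained in the gene span.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise GffValidationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene span "
                    f"[{self.start},{self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise GffValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


# Documented ranges for the named thresholds a run may carry.
THRESHOLD_RANGES: dict[str, tuple[float, float]] = {
    "identity_min": (0.0, 1.0),
    "coverage_min": (0.0, 1.0),
    "evalue_max": (0.0, float("inf")),
    "tir_min_len": (1.0, 1000.0),
    "at_min": (0.0, 1.0),
    "near_bin_kb": (0.0, float("inf")),
}


@dataclass
class RunConfig:
    """Seed, thresholds and file paths for one pipeline run."""

    seed: int
    thresholds: dict[str, float] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.thresholds.items():
            lo, hi = THRESHOLD_RANGES.get(name, (-float("inf"), float("inf")))
            if not (lo <= value <= hi):
                raise ValueError(
                    f"threshold {name}={value} outside documented range "
                    f"[{lo},{hi}]"
                )

    def config_hash(self) -> str:
        canon = repr((self.seed, sorted(self.thresholds.items()), sorted(self.paths.items())))
        return hashlib.md5(canon.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed={self.seed}\n")
            for k, v in sorted(self.thresholds.items()):
                fh.write(f"threshold.{k}={v}\n")
            for k, v in sorted(self.paths.items()):
                fh.write(f"path.{k}={v}\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        seed = 0
        thresholds: dict[str, float] = {}
        paths: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                if key == "seed":
                    seed = int(value)
                elif key.startswith("threshold."):
                    thresholds[key[len("threshold."):]] = float(value)
                elif key.startswith("path."):
                    paths[key[len("path."):]] = value
                else:
                    raise ValueError(f"unknown config key {key!r}")
        return cls(seed=seed, thresholds=thresholds, paths=paths)


def header_lines(config: RunConfig | None = None) -> list[str]:
    """Comment header recording provenance, prepended to every output file."""
    lines = [f"# mitescope {__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config.config_hash()} seed={config.seed}")
    return lines


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, uppercasing sequences.

    Raises FastaParseError naming the offending line on malformed headers,
    illegal characters or empty sequences.
    """
    path = Path(path)
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - SeqIO internal errors
        raise FastaParseError(f"{path}: {exc}") from exc
    # Biopython silently skips leading junk before the first '>'.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected FASTA header line"
                    )
                break
    records = []
    for rec in raw:
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"{path}:{_find_bad_line(path, bad)}: illegal character(s) "
                f"{sorted(bad)} in record {rec.id!r}"
            )
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def _find_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records wrapped at ``width`` columns (read/write round-trips)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon features into GeneModels (0-based half-open).

    When a gene carries several mRNAs the exon chain of the first transcript
    (by coordinate) is used and a warning is logged; the alternative chains
    are ignored.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if len(mrnas) > 1:
            logger.warning(
                "gene %s has %d mRNAs; using the first transcript's exons",
                gene.id, len(mrnas),
            )
        if mrnas:
            exon_parent = mrnas[0]
        else:
            exon_parent = gene
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(exon_parent, featuretype="exon")
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path, config: RunConfig | None = None) -> None:
    """Write GeneModels as gene/mRNA/exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines(config):
            fh.write(line + "\n")
        for g in genes:
            base = f"{g.chrom}\tmitescope\t"
            fh.write(
                base + f"gene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                base + f"mRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    base + f"exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


def write_hits(hits, bed_path: str | Path, tsv_path: str | Path | None = None,
               config: RunConfig | None = None) -> None:
    """Write element hits as BED6 plus a TSV sidecar with alignment metrics.

    Output is sorted by (chrom, start). BED spans are 0-based half-open; the
    BED score column carries the alignment score clipped to [0, 1000].
    """
    bed_path = Path(bed_path)
    if tsv_path is None:
        tsv_path = bed_path.with_suffix(".tsv")
    hits = sorted(hits, key=lambda h: (h.chrom, h.start, h.end))
    for h in hits:
        if h.start < 0 or h.end < 0:
            raise ValueError(f"negative coordinate in hit {h.chrom}:{h.start}-{h.end}")
    head = header_lines(config)
    with open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        for line in head:
            bed.write(line + "\n")
            tsv.write(line + "\n")
        tsv.write(
            "chrom\tstart\tend\tname\tstrand\tidentity\tcoverage\tscore\tevalue\ttsd\n"
        )
        for i, h in enumerate(hits, 1):
            name = f"mite_{i}"
            bed_score = int(min(1000, max(0, round(h.score))))
            bed.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{name}\t{bed_score}\t{h.strand}\n"
            )
            tsd = getattr(h, "tsd", None) or "."
            tsv.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{name}\t{h.strand}\t"
                f"{h.identity:.4f}\t{h.coverage:.4f}\t{h.score:.1f}\t"
                f"{h.evalue:.3g}\t{tsd}\n"
            )


def read_hits(tsv_path: str | Path):
    """Read the TSV sidecar written by :func:`write_hits` back into hits."""
    from .member_mining import ElementHit

    hits = []
    with open(tsv_path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                ElementHit(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), strand=f[4],
                    identity=float(f[5]), coverage=float(f[6]),
                    score=float(f[7]), evalue=float(f[8]),
                    tsd=None if f[9] == "." else f[9],
                )
            )
    return hits
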