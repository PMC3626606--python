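"""MITE insertion polymorphism (MIP) marker analysis.

A MIP panel scores the presence (1) or absence (0) of an element insertion
at each locus across accessions of several species. For two diploids and
their allotetraploid, species-level presence patterns date each insertion
relative to speciation and allopolyploidization:

- Bs: present in both diploids (inserted before they diverged);
- Br-I / Bo-I: unique to one diploid and present in the allotetraploid
  (inserted after divergence, before hybridization);
- Br-II / Bo-II: unique to one diploid and absent from the allotetraploid
  (inserted after hybridization);
- loci fitting none of these (e.g. allotetraploid-only) are unclassified.

The module also provides Jaccard similarity over binary profiles (shared
absences ignored), UPGMA clustering with an ultrametric Newick dendrogram,
and a chi-square test of codominant 1:2:1 F2 segregation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MipMatrix", "F2Counts", "TIMING_GROUPS", "UNCLASSIFIED",
    "call_species_presence", "classify_timing_group", "classify_matrix",
    "summarize_groups", "polymorphism_report", "jaccard_similarity",
    "upgma_tree", "UpgmaNode", "segregation_chi_square",
]

#: The five timing groups in fixed reporting order.
TIMING_GROUPS = ("Bs", "Br-I", "Br-II", "Bo-I", "Bo-II")
UNCLASSIFIED = "unclassified"

SPECIES = ("B.rapa", "B.oleracea", "B.napus", "outgroup")


@dataclass
class MipMatrix:
    """Binary band scores: accessions (with species labels) x loci."""

    accessions: list[str]
    species: list[str]
    loci: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (len(self.accessions), len(self.loci)):
            raise ValueError("cells shape must be (accessions, loci)")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be 0/1")
        if len(self.species) != len(self.accessions):
            raise ValueError("one species label per accession required")
        unknown = set(self.species) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species labels: {sorted(unknown)}")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.accessions, columns=self.loci)

    def to_tsv(self, path: str | Path) -> None:
        df = self.frame.copy()
        df.insert(0, "species", self.species)
        df.to_csv(path, sep="\t", index_label="accession")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        species = df.pop("species").tolist()
        return cls(accessions=df.index.tolist(), species=species,
                   loci=df.columns.tolist(), cells=df.to_numpy())


@dataclass
class F2Counts:
    """Codominant F2 genotype counts (P1 homozygote, het, P2 homozygote)."""

    n_p1hom: int
    n_het: int
    n_p2hom: int

    def __post_init__(self) -> None:
        if min(self.n_p1hom, self.n_het, self.n_p2hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("total count must be >= 1")

    @property
    def total(self) -> int:
        return self.n_p1hom + self.n_het + self.n_p2hom


def call_species_presence(matrix: MipMatrix, locus: str,
                          rule: str = "any") -> dict:
    """Reduce accession band scores at one locus to species-level calls.

    ``rule`` is one of {any, all, majority}: a species is called present
    when any / all / more than half of its accessions score 1. Species
    whose accessions disagree are flagged polymorphic-within-species.
    """
    if rule not in {"any", "all", "majority"}:
        raise ValueError("rule must be one of {any, all, majority}")
    j = matrix.loci.index(locus)
    col = matrix.cells[:, j]
    presence: dict[str, bool] = {}
    polymorphic: dict[str, bool] = {}
    for sp in dict.fromkeys(matrix.species):
        vals = col[[i for i, s in enumerate(matrix.species) if s == sp]]
        if rule == "any":
            presence[sp] = bool(vals.any())
        elif rule == "all":
            presence[sp] = bool(vals.all())
        else:
            presence[sp] = bool(vals.sum() * 2 > vals.size)
        polymorphic[sp] = bool(vals.min() != vals.max())
    return {"presence": presence, "polymorphic": polymorphic}


def classify_timing_group(presence: dict) -> str:
    """Timing group from species-level presence of rapa/oleracea/napus."""
    rapa = bool(presence.get("B.rapa"))
    oler = bool(presence.get("B.oleracea"))
    napus = bool(presence.get("B.napus"))
    if rapa and oler:
        return "Bs"
    if rapa:
        return "Br-I" if napus else "Br-II"
    if oler:
        return "Bo-I" if napus else "Bo-II"
    return UNCLASSIFIED


def classify_matrix(matrix: MipMatrix, rule: str = "any") -> dict[str, str]:
    """Timing group per locus for a whole panel."""
    return {
        locus: classify_timing_group(
            call_species_presence(matrix, locus, rule=rule)["presence"])
        for locus in matrix.loci
    }


def _pct_int(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def summarize_groups(labels) -> dict:
    """Group counts plus shared / species-unique insertion fractions.

    ``shared`` is the Bs fraction of classified loci; ``unique`` aggregates
    the four species-specific groups. Percentages are reported to the
    nearest integer, raw fractions alongside.
    """
    labels = list(labels.values()) if isinstance(labels, dict) else list(labels)
    counts = {g: 0 for g in TIMING_GROUPS + (UNCLASSIFIED,)}
    for lab in labels:
        counts[lab] += 1
    classified = sum(counts[g] for g in TIMING_GROUPS)
    if classified == 0:
        raise ValueError("no classified loci")
    shared = counts["Bs"] / classified
    unique = sum(counts[g] for g in TIMING_GROUPS[1:]) / classified
    return {
        "counts": counts, "n_classified": classified,
        "shared_fraction": shared, "unique_fraction": unique,
        "shared_pct": _pct_int(100 * shared),
        "unique_pct": _pct_int(100 * unique),
    }


def polymorphism_report(matrix: MipMatrix) -> dict:
    """Panel-wide and within-species polymorphism of each locus.

    A locus is polymorphic across the panel when the non-outgroup
    accessions do not all share one state; within-species rates count loci
    where accessions of that species disagree.
    """
    if len(matrix.accessions) < 2:
        raise ValueError("need at least two accessions")
    non_out = [i for i, s in enumerate(matrix.species) if s != "outgroup"]
    flags = {}
    for j, locus in enumerate(matrix.loci):
        col = matrix.cells[non_out, j]
        flags[locus] = bool(col.min() != col.max())
    n = len(matrix.loci)
    within = {}
    for sp in dict.fromkeys(matrix.species):
        if sp == "outgroup":
            continue
        rows = [i for i, s in enumerate(matrix.species) if s == sp]
        if len(rows) < 2:
            within[sp] = None
            continue
        k = sum(
            1 for j in range(n)
            if matrix.cells[rows, j].min() != matrix.cells[rows, j].max()
        )
        within[sp] = k / n if n else None
    poly = sum(flags.values())
    return {
        "per_locus": flags,
        "n_polymorphic": poly,
        "polymorphic_fraction": poly / n if n else None,
        "polymorphic_pct": _pct_int(100 * poly / n) if n else None,
        "within_species_rates": within,
    }


def jaccard_similarity(matrix: MipMatrix) -> pd.DataFrame:
    """Accession-by-accession Jaccard similarity over the binary profiles.

    J(x, y) = |x AND y| / |x OR y|; shared absences carry no signal. A pair
    of all-zero profiles is defined as J = 1 with a warning.
    """
    if len(matrix.accessions) < 2:
        raise ValueError("need at least two accessions")
    X = matrix.cells.astype(np.int64)
    inter = X @ X.T
    totals = X.sum(axis=1)
    union = totals[:, None] + totals[None, :] - inter
    J = np.ones_like(inter, dtype=float)
    off_diag = ~np.eye(union.shape[0], dtype=bool)
    if (union[off_diag] == 0).any():
        warnings.warn("all-zero profile pair: Jaccard defined as 1",
                      stacklevel=2)
    nz = union > 0
    J[nz] = inter[nz] / union[nz]
    np.fill_diagonal(J, 1.0)
    return pd.DataFrame(J, index=matrix.accessions, columns=matrix.accessions)


@dataclass
class UpgmaNode:
    """A node of an ultrametric UPGMA dendrogram."""

    name: str | None = None
    height: float = 0.0
    children: list["UpgmaNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(
                c._newick(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:g}"

    def cut(self, height: float) -> list[list[str]]:
        """Clusters obtained by cutting every branch crossing ``height``."""
        if self.height <= height:
            return [self.leaves()]
        out = []
        for c in self.children:
            out.extend(c.cut(height))
        return out


def upgma_tree(similarity: pd.DataFrame) -> UpgmaNode:
    """UPGMA dendrogram from a similarity matrix (distance d = 1 - J).

    Cluster-to-cluster distance is the arithmetic mean of member pairwise
    distances; merge heights are d/2 so root-to-leaf path lengths are
    equal. Ties are broken by the lexicographically smallest pair of
    cluster names, making the tree deterministic.
    """
    names = list(similarity.index)
    if list(similarity.columns) != names:
        raise ValueError("similarity matrix must be square with matching labels")
    S = similarity.to_numpy(dtype=float)
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    D = 1.0 - S
    # cluster state: representative name = lexicographically smallest leaf
    clusters: dict[str, UpgmaNode] = {
        n: UpgmaNode(name=n, height=0.0) for n in names
    }
    sizes = {n: 1 for n in names}
    dist = {
        frozenset((a, b)): D[i, j]
        for i, a in enumerate(names) for j, b in enumerate(names) if i < j
    }
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        (pair, d) = best
        a, b = sorted(pair)
        node = UpgmaNode(
            name=None, height=d / 2,
            children=sorted(
                [clusters[a], clusters[b]],
                key=lambda c: sorted(c.leaves())[0],
            ),
        )
        na, nb = sizes[a], sizes[b]
        merged = a  # keep the lexicographically smaller label
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        del clusters[b]
        clusters[merged] = node
        sizes[merged] = na + nb
    return next(iter(clusters.values()))


def segregation_chi_square(counts: F2Counts,
                           ratio: tuple = (1, 2, 1)) -> dict:
    """Pearson chi-square of F2 genotype counts against an expected ratio.

    The default 1:2:1 is the codominant single-locus Mendelian expectation.
    Scaling the ratio (e.g. 2:4:2) leaves the test unchanged.
    """
    if len(ratio) != 3 or min(ratio) <= 0:
        raise ValueError("ratio must be three positive numbers")
    obs = np.array([counts.n_p1hom, counts.n_het, counts.n_p2hom], dtype=float)
    total = obs.sum()
    if total < 1:
        raise ValueError("zero total count")
    exp = total * np.asarray(ratio, dtype=float) / sum(ratio)
    chi2, p = stats.chisquare(obs, exp)
    return {"chi2": float(chi2), "df": 2, "p": float(p)}
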