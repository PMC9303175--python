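"""Uncorrected pairwise distances and the barcode-gap diagnostic.

Distances are plain p-distances (substitution counts over compared sites,
no model correction): the diagnostic rests on raw nucleotide differences
between cloned repeat sequences, and a correction model would only blur the
intra/inter comparison.  Sites where either row carries a gap (and, by
default, ``N``) are excluded pairwise; ambiguity codes are handled by one
of two policies:

``strict``
    any symbol difference counts as a difference (appropriate for cloned
    or genomic sequences, which carry no ambiguity codes);
``set-overlap``
    a position counts as a difference only when the IUPAC expansions of the
    two symbols are disjoint (appropriate as soon as a consensus/ambiguous
    record participates, e.g. comparing a clone against a deposited Sanger
    sequence).

The *barcode gap* for a pair of taxa is the margin by which their smallest
between-taxon distance exceeds the larger of the two within-taxon maxima;
a positive gap means the barcode separates them.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .seqio import Alignment, SeqRecord, iupac_set

__all__ = [
    "AmbiguityPolicy",
    "DistancePolicy",
    "PairwiseDistance",
    "DistanceMatrix",
    "TaxonPairGap",
    "BarcodeGapReport",
    "UndefinedDistanceError",
    "pairwise_distance",
    "distance_matrix",
    "intra_inter_partition",
    "barcode_gap_report",
    "similarity_filter",
    "distance_histogram",
    "write_phylip",
]


class UndefinedDistanceError(ValueError):
    """No comparable (ungapped in both rows) sites between two sequences."""


class AmbiguityPolicy(str, enum.Enum):
    STRICT = "strict"
    SET_OVERLAP = "set-overlap"


@dataclass(frozen=True)
class DistancePolicy:
    """How ambiguity codes and N are scored; echoed into every output."""

    ambiguity: AmbiguityPolicy = AmbiguityPolicy.STRICT
    exclude_n: bool = True  # treat N like a gap (excluded site)

    def describe(self) -> str:
        n_mode = "N-excluded" if self.exclude_n else "N-compared"
        return f"{self.ambiguity.value}/{n_mode}"


@dataclass(frozen=True)
class PairwiseDistance:
    id_a: str
    id_b: str
    differences: int
    compared_sites: int

    @property
    def percent(self) -> float:
        return 100.0 * self.differences / self.compared_sites


def _positions_differ(a: str, b: str, policy: DistancePolicy) -> bool:
    if policy.ambiguity is AmbiguityPolicy.STRICT:
        return a != b
    return not (iupac_set(a) & iupac_set(b))


def _site_excluded(a: str, b: str, policy: DistancePolicy) -> bool:
    if a == "-" or b == "-":
        return True
    if policy.exclude_n and (a == "N" or b == "N"):
        return True
    return False


def pairwise_distance(
    a: SeqRecord, b: SeqRecord, policy: DistancePolicy = DistancePolicy()
) -> PairwiseDistance:
    """p-distance between two aligned rows under *policy* (pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError(
            f"aligned rows differ in length: {a.id!r}={len(a)}, {b.id!r}={len(b)}"
        )
    differences = 0
    compared = 0
    for ra, rb in zip(a.residues, b.residues):
        if _site_excluded(ra, rb, policy):
            continue
        compared += 1
        if _positions_differ(ra, rb, policy):
            differences += 1
    if compared == 0:
        raise UndefinedDistanceError(
            f"no comparable sites between {a.id!r} and {b.id!r}"
        )
    return PairwiseDistance(a.id, b.id, differences, compared)


@dataclass
class DistanceMatrix:
    """Labelled symmetric percent-distance matrix with per-pair site counts."""

    labels: list[str]
    percent: np.ndarray
    differences: np.ndarray
    compared_sites: np.ndarray
    policy: DistancePolicy = field(default_factory=DistancePolicy)

    def __post_init__(self):
        n = len(self.labels)
        if self.percent.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.percent, self.percent.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.percent) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.percent < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def value(self, a: str, b: str) -> float:
        return float(self.percent[self.index(a), self.index(b)])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in keep]
        return DistanceMatrix(
            labels=list(keep),
            percent=self.percent[np.ix_(idx, idx)].copy(),
            differences=self.differences[np.ix_(idx, idx)].copy(),
            compared_sites=self.compared_sites[np.ix_(idx, idx)].copy(),
            policy=self.policy,
        )

    @classmethod
    def from_square(
        cls, labels: Sequence[str], percent: np.ndarray,
        policy: DistancePolicy = DistancePolicy(),
    ) -> "DistanceMatrix":
        """Wrap a plain percent matrix (counts unknown, set to zero)."""
        n = len(labels)
        return cls(
            labels=list(labels),
            percent=np.asarray(percent, dtype=float),
            differences=np.zeros((n, n), dtype=int),
            compared_sites=np.zeros((n, n), dtype=int),
            policy=policy,
        )


def distance_matrix(
    aln: Alignment, policy: DistancePolicy = DistancePolicy()
) -> DistanceMatrix:
    """All unordered pairwise distances of an alignment."""
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows for a distance matrix")
    n = aln.n_rows
    percent = np.zeros((n, n))
    diffs = np.zeros((n, n), dtype=int)
    sites = np.zeros((n, n), dtype=int)
    recs = aln.records
    for i, j in itertools.combinations(range(n), 2):
        pd = pairwise_distance(recs[i], recs[j], policy)
        percent[i, j] = percent[j, i] = pd.percent
        diffs[i, j] = diffs[j, i] = pd.differences
        sites[i, j] = sites[j, i] = pd.compared_sites
    return DistanceMatrix([r.id for r in recs], percent, diffs, sites, policy)


@dataclass
class IntraInterPartition:
    """The C(n,2) pairwise distances split into within- and between-taxon sets."""

    intra: dict[str, list[float]]                 # taxon -> distances
    inter: dict[tuple[str, str], list[float]]     # sorted taxon pair -> distances

    def max_intra(self, taxon: str) -> float | None:
        vals = self.intra.get(taxon, [])
        return max(vals) if vals else None

    def min_inter(self, taxon_a: str, taxon_b: str) -> float | None:
        key = tuple(sorted((taxon_a, taxon_b)))
        vals = self.inter.get(key, [])
        return min(vals) if vals else None


def intra_inter_partition(
    dm: DistanceMatrix, taxon_map: Mapping[str, str]
) -> IntraInterPartition:
    """Partition every pair into exactly one intra- or inter-taxon multiset."""
    for label in dm.labels:
        if label not in taxon_map:
            raise KeyError(f"label {label!r} has no taxon mapping")
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    for i, j in itertools.combinations(range(dm.n), 2):
        ta = taxon_map[dm.labels[i]]
        tb = taxon_map[dm.labels[j]]
        d = float(dm.percent[i, j])
        if ta == tb:
            intra.setdefault(ta, []).append(d)
        else:
            inter.setdefault(tuple(sorted((ta, tb))), []).append(d)
    return IntraInterPartition(intra, inter)


@dataclass(frozen=True)
class TaxonPairGap:
    taxon_a: str
    taxon_b: str
    max_intra_a: float | None
    max_intra_b: float | None
    min_inter: float
    singleton: bool  # at least one taxon has <2 members (intra max undefined)

    @property
    def gap(self) -> float | None:
        if self.singleton:
            return None
        return self.min_inter - max(self.max_intra_a, self.max_intra_b)

    @property
    def gap_present(self) -> bool | None:
        g = self.gap
        return None if g is None else g > 0


@dataclass
class BarcodeGapReport:
    pairs: list[TaxonPairGap]
    policy: DistancePolicy

    @property
    def all_gaps_present(self) -> bool:
        evaluable = [p for p in self.pairs if not p.singleton]
        return bool(evaluable) and all(p.gap_present for p in evaluable)

    def pair(self, a: str, b: str) -> TaxonPairGap:
        key = tuple(sorted((a, b)))
        for p in self.pairs:
            if (p.taxon_a, p.taxon_b) == key:
                return p
        raise KeyError(key)

    def to_rows(self) -> list[dict]:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "taxon_a": p.taxon_a,
                    "taxon_b": p.taxon_b,
                    "max_intra_a": p.max_intra_a,
                    "max_intra_b": p.max_intra_b,
                    "min_inter": p.min_inter,
                    "gap": p.gap,
                    "gap_present": p.gap_present,
                    "singleton": p.singleton,
                }
            )
        return rows


def barcode_gap_report(
    dm: DistanceMatrix, taxon_map: Mapping[str, str]
) -> BarcodeGapReport:
    """Barcode-gap verdict for every unordered taxon pair in the matrix.

    Pairs involving a singleton taxon are reported with undefined intra
    maximum and flagged rather than dropped.
    """
    part = intra_inter_partition(dm, taxon_map)
    counts: dict[str, int] = {}
    for label in dm.labels:
        t = taxon_map[label]
        counts[t] = counts.get(t, 0) + 1
    pairs = []
    for (ta, tb), inter_vals in sorted(part.inter.items()):
        ma = part.max_intra(ta)
        mb = part.max_intra(tb)
        singleton = counts[ta] < 2 or counts[tb] < 2
        pairs.append(
            TaxonPairGap(
                taxon_a=ta,
                taxon_b=tb,
                max_intra_a=ma,
                max_intra_b=mb,
                min_inter=min(inter_vals),
                singleton=singleton,
            )
        )
    return BarcodeGapReport(pairs, dm.policy)


def _global_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def aligned_pair_distance(
    query: SeqRecord,
    candidate: SeqRecord,
    policy: DistancePolicy = DistancePolicy(AmbiguityPolicy.SET_OVERLAP),
) -> PairwiseDistance:
    """Globally align two unaligned sequences, then score the p-distance."""
    aligner = _global_aligner()
    alignment = aligner.align(query.ungapped, candidate.ungapped)[0]
    qrow, crow = str(alignment[0]), str(alignment[1])
    a = SeqRecord(id=query.id, residues=qrow, source=query.source)
    b = SeqRecord(id=candidate.id, residues=crow, source=candidate.source)
    return pairwise_distance(a, b, policy)


def similarity_filter(
    query: SeqRecord,
    candidates: Sequence[SeqRecord],
    max_percent: float,
    policy: DistancePolicy = DistancePolicy(AmbiguityPolicy.SET_OVERLAP),
) -> list[SeqRecord]:
    """Keep candidates within *max_percent* difference of *query*.

    Each candidate is globally aligned to the query (match +1, mismatch -1,
    gap -2), mirroring the database-search screening step that retains only
    sequences within a few percent of a type-strain barcode.  Input order is
    preserved.
    """
    kept = []
    for cand in candidates:
        if aligned_pair_distance(query, cand, policy).percent <= max_percent:
            kept.append(cand)
    return kept


def distance_histogram(
    values: Iterable[float], bin_width: float
) -> list[tuple[float, float, int]]:
    """Left-closed right-open bins from 0; returns (lo, hi, count) triples."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return []
    if np.any(vals < 0):
        raise ValueError("distances must be non-negative")
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    # np.histogram closes the last bin on the right; values equal to the last
    # edge cannot occur because n_bins covers max strictly.
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(n_bins)
    ]


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix (relaxed label width) for external tools."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        width = max(10, max(len(l) for l in dm.labels) + 2)
        for i, label in enumerate(dm.labels):
            row = " ".join(f"{dm.percent[i, j]:.6f}" for j in range(dm.n))
            fh.write(f"{label:<{width}}{row}\n")
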