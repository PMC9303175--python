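"""Mining assemblies for rDNA barcode units and multi-copy genes.

Genome assemblies of the strains under study do not keep their rDNA in one
tidy tandem array: repeats turn up dispersed across contigs, many of them
truncated.  :func:`scan_genome` finds them with a self-contained
seed-and-extend search — exact k-mer seeds grouped by diagonal, each seed
cluster resolved by a local alignment of the query against the windowed
genome segment — on both strands, reporting identity, query coverage and a
complete/truncate classification.  :func:`haplotype_groups` clusters
cloned or mined copies of a gene into haplotypes and counts the positions
distinguishing the group consensuses, and :func:`gene_copy_report`
assembles the per-genome copy counts and the intragenomic-versus-
interstrain similarity comparison that reveals mosaic (admixed) genomes.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .consensus import majority_consensus
from .seqio import Alignment, SeqRecord, Source, reverse_complement

_log = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "RepeatHit",
    "HaplotypeGrouping",
    "scan_genome",
    "classify_completeness",
    "repeat_table",
    "extract_hit",
    "haplotype_groups",
    "gene_copy_report",
    "GeneCopyReport",
]


@dataclass(frozen=True)
class ScanParams:
    """Knobs of the seed-and-extend scan; every report echoes them."""

    seed_length: int = 12
    min_identity: float = 0.80
    min_coverage: float = 0.30       # minimum query coverage to report at all
    completeness_threshold: float = 0.90  # coverage at/above which a hit is complete
    merge_distance: int = 50         # same-strand hits closer than this are merged
    window_pad: int = 100            # extension margin around a seed cluster
    band: int = 25                   # diagonal tolerance when clustering seeds


@dataclass(frozen=True)
class RepeatHit:
    """One located copy of a query in a contig (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str                      # '+' or '-'
    query: str
    identity: float                  # matches / aligned columns, in [0, 1]
    coverage: float                  # aligned query fraction, in [0, 1]
    score: float
    completeness: str = "complete"   # 'complete' | 'truncate'

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def classify_completeness(hit: RepeatHit, threshold: float = 0.90) -> str:
    """'complete' iff query coverage >= threshold (closed boundary)."""
    return "complete" if hit.coverage >= threshold else "truncate"


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def _seed_clusters(
    query: str, contig: str, params: ScanParams
) -> list[tuple[int, int]]:
    """Candidate genome windows [start, end) from diagonal-clustered exact
    k-mer seed matches."""
    k = params.seed_length
    index: dict[str, list[int]] = defaultdict(list)
    for qpos in range(len(query) - k + 1):
        kmer = query[qpos:qpos + k]
        if "-" not in kmer and "N" not in kmer:
            index[kmer].append(qpos)
    matches: list[tuple[int, int]] = []  # (diagonal, gpos)
    for gpos in range(len(contig) - k + 1):
        kmer = contig[gpos:gpos + k]
        for qpos in index.get(kmer, ()):
            matches.append((gpos - qpos, gpos))
    if not matches:
        return []
    matches.sort()
    qlen = len(query)
    clusters: list[list[tuple[int, int]]] = []
    for diag, gpos in matches:
        placed = False
        for cl in clusters:
            d0, g0 = cl[-1]
            if abs(diag - d0) <= params.band and abs(gpos - g0) <= qlen:
                cl.append((diag, gpos))
                placed = True
                break
        if not placed:
            clusters.append([(diag, gpos)])
    windows = []
    for cl in clusters:
        diags = [d for d, _ in cl]
        # diagonal ~ where the query start would sit in the contig: a tight
        # window per cluster so tandem neighbours stay in separate windows
        start = max(0, min(diags) - params.window_pad)
        end = min(len(contig), max(diags) + qlen + params.window_pad)
        windows.append((start, end))
    # duplicate windows from indel-split clusters collapse later via hit merging
    return sorted(set(windows))


def _align_window(
    query: str, contig: str, win: tuple[int, int]
) -> tuple[int, int, float, float, float] | None:
    """Best local alignment of query inside the window.

    Returns (genome start, genome end, identity, coverage, score).
    """
    segment = contig[win[0]:win[1]]
    aligner = _local_aligner()
    alignments = aligner.align(query, segment)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    if aln.score <= 0:
        return None
    q_aligned = aln.aligned[0]
    s_aligned = aln.aligned[1]
    if len(q_aligned) == 0:
        return None
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(q_aligned, s_aligned):
        for a, b in zip(query[qs:qe], segment[ss:se]):
            columns += 1
            if a == b:
                matches += 1
    # count gap columns between aligned blocks
    for (prev_q, prev_s), (next_q, next_s) in zip(
        zip(q_aligned[:-1], s_aligned[:-1]), zip(q_aligned[1:], s_aligned[1:])
    ):
        columns += (next_q[0] - prev_q[1]) + (next_s[0] - prev_s[1])
    identity = matches / columns if columns else 0.0
    q_span = q_aligned[-1][1] - q_aligned[0][0]
    coverage = q_span / len(query)
    g_start = int(win[0] + s_aligned[0][0])
    g_end = int(win[0] + s_aligned[-1][1])
    return g_start, g_end, float(identity), float(coverage), float(aln.score)


def _merge_hits(hits: list[RepeatHit], merge_distance: int) -> list[RepeatHit]:
    """Merge same-query same-strand hits within *merge_distance* bp, keeping
    the higher-scoring extension's identity/coverage."""
    out: list[RepeatHit] = []
    for hit in sorted(hits, key=lambda h: (h.contig, h.query, h.strand, h.start)):
        if out:
            last = out[-1]
            if (
                last.contig == hit.contig
                and last.query == hit.query
                and last.strand == hit.strand
                and hit.start - last.end <= merge_distance
            ):
                best = max((last, hit), key=lambda h: h.score)
                out[-1] = replace(
                    best, start=min(last.start, hit.start), end=max(last.end, hit.end)
                )
                continue
        out.append(hit)
    return out


def scan_genome(
    genome: Sequence[SeqRecord],
    query: SeqRecord,
    params: ScanParams = ScanParams(),
) -> list[RepeatHit]:
    """Locate all copies of *query* in the contigs of *genome*.

    Both strands are searched (the reverse complement of the query against
    the forward contig).  Hits below ``min_identity`` or ``min_coverage``
    are discarded; surviving hits are classified complete/truncate at the
    completeness threshold and sorted by (contig, start).
    """
    q_fwd = query.ungapped
    if len(q_fwd) < params.seed_length:
        raise ValueError(
            f"query {query.id!r} shorter than seed length {params.seed_length}"
        )
    strands = {"+": q_fwd, "-": reverse_complement(q_fwd)}
    hits: list[RepeatHit] = []
    for contig_rec in genome:
        contig = contig_rec.ungapped
        for strand, q in strands.items():
            for win in _seed_clusters(q, contig, params):
                res = _align_window(q, contig, win)
                if res is None:
                    continue
                g_start, g_end, identity, coverage, score = res
                if identity < params.min_identity or coverage < params.min_coverage:
                    continue
                hits.append(
                    RepeatHit(
                        contig=contig_rec.id,
                        start=g_start,
                        end=g_end,
                        strand=strand,
                        query=query.id,
                        identity=identity,
                        coverage=coverage,
                        score=score,
                    )
                )
    hits = _merge_hits(hits, params.merge_distance)
    hits = [
        replace(h, completeness=classify_completeness(h, params.completeness_threshold))
        for h in hits
    ]
    hits.sort(key=lambda h: (h.contig, h.start))
    return hits


def extract_hit(genome: Sequence[SeqRecord], hit: RepeatHit) -> SeqRecord:
    """The genomic sequence of a hit, reverse-complemented for '-' hits."""
    for contig in genome:
        if contig.id == hit.contig:
            seq = contig.ungapped[hit.start:hit.end]
            if hit.strand == "-":
                seq = reverse_complement(seq)
            return SeqRecord(
                id=f"{hit.contig}:{hit.start + 1}-{hit.end}({hit.strand})|{hit.query}",
                residues=seq,
                source=Source.GENOME,
            )
    raise KeyError(f"contig {hit.contig!r} not in genome")


def repeat_table(hits: Sequence[RepeatHit]) -> pd.DataFrame:
    """Per-contig complete/truncate tallies per query, with grand totals."""
    if not hits:
        return pd.DataFrame(
            columns=["contig", "query", "complete", "truncate"]
        ).set_index(["contig", "query"])
    rows = defaultdict(lambda: {"complete": 0, "truncate": 0})
    for h in hits:
        rows[(h.contig, h.query)][h.completeness] += 1
    df = pd.DataFrame(
        [
            {"contig": c, "query": q, **counts}
            for (c, q), counts in sorted(rows.items())
        ]
    ).set_index(["contig", "query"])
    return df


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class HaplotypeGrouping:
    """Partition of aligned gene copies into haplotype groups."""

    groups: list[list[str]]                      # member ids per group
    consensus: list[SeqRecord]
    distinguishing: dict[tuple[int, int], int]   # group index pair -> positions
    merge_threshold: int

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def distinguishing_positions(self, i: int = 0, j: int = 1) -> int:
        return self.distinguishing[(min(i, j), max(i, j))]


def haplotype_groups(
    seqs: Sequence[SeqRecord], merge_threshold: int = 0
) -> HaplotypeGrouping:
    """Single-linkage grouping of aligned sequences at <= threshold differences.

    At the default threshold 0 groups are identical-sequence classes.  The
    count of distinguishing positions between two groups is the number of
    columns where the group majority consensuses differ (majority ties
    resolve toward base order, i.e. deterministically toward the first
    group's orientation of the tie rule).
    """
    if not seqs:
        raise ValueError("no sequences to group")
    n = len(seqs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if _hamming(seqs[i].residues, seqs[j].residues) <= merge_threshold:
            parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        clusters[find(i)].append(i)
    # deterministic group order: by first member index
    ordered = sorted(clusters.values(), key=lambda ix: ix[0])
    groups = [[seqs[i].id for i in ix] for ix in ordered]
    consensi = []
    for g, ix in enumerate(ordered):
        aln = Alignment(records=[seqs[i] for i in ix])
        consensi.append(
            majority_consensus(aln, record_id=f"group{g + 1}_consensus")
        )
    distinguishing: dict[tuple[int, int], int] = {}
    for i, j in itertools.combinations(range(len(ordered)), 2):
        distinguishing[(i, j)] = _hamming(
            consensi[i].residues, consensi[j].residues
        )
    return HaplotypeGrouping(groups, consensi, distinguishing, merge_threshold)


@dataclass
class GeneCopyEntry:
    genome: str
    gene: str
    copy_count: int
    intragenomic_min_diff: int | None     # substitutions between closest copies
    intragenomic_max_diff: int | None
    best_external_genome: str | None
    best_external_diff: int | None
    admixture_signal: bool | None         # intragenomic diff > min external diff


@dataclass
class GeneCopyReport:
    entries: list[GeneCopyEntry]
    hits: dict[tuple[str, str], list[RepeatHit]] = field(default_factory=dict)

    def entry(self, genome: str, gene: str) -> GeneCopyEntry:
        for e in self.entries:
            if e.genome == genome and e.gene == gene:
                return e
        raise KeyError((genome, gene))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def _copy_diff(a: SeqRecord, b: SeqRecord) -> int:
    """Substitution count between two unaligned gene copies (global alignment,
    gap columns excluded)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aln = aligner.align(a.ungapped, b.ungapped)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sum(
        1 for x, y in zip(sa, sb) if x != "-" and y != "-" and x != y
    )


def gene_copy_report(
    genomes: Mapping[str, Sequence[SeqRecord]],
    gene_queries: Sequence[SeqRecord],
    params: ScanParams = ScanParams(),
    *,
    complete_only: bool = True,
) -> GeneCopyReport:
    """Copy counts per gene per genome and the admixture comparison.

    For every multi-copy gene the closest/farthest intragenomic copy pairs
    are compared (substitution counts) with the most similar copy in any
    other genome; ``admixture_signal`` is true when the smallest
    intragenomic difference exceeds the smallest difference to an external
    counterpart — copies less similar to each other than to another
    strain's gene, the hallmark of a mosaic genome.
    """
    all_hits: dict[tuple[str, str], list[RepeatHit]] = {}
    copies: dict[tuple[str, str], list[SeqRecord]] = {}
    for gname, contigs in genomes.items():
        for gene in gene_queries:
            hits = scan_genome(contigs, gene, params)
            if complete_only:
                hits = [h for h in hits if h.completeness == "complete"]
            all_hits[(gname, gene.id)] = hits
            copies[(gname, gene.id)] = [extract_hit(contigs, h) for h in hits]

    entries: list[GeneCopyEntry] = []
    for gname in genomes:
        for gene in gene_queries:
            own = copies[(gname, gene.id)]
            intra_min = intra_max = None
            if len(own) >= 2:
                diffs = [
                    _copy_diff(a, b) for a, b in itertools.combinations(own, 2)
                ]
                intra_min, intra_max = min(diffs), max(diffs)
            best_genome = None
            best_diff = None
            if own:
                for other in genomes:
                    if other == gname:
                        continue
                    for ext in copies[(other, gene.id)]:
                        for mine in own:
                            d = _copy_diff(mine, ext)
                            if best_diff is None or d < best_diff:
                                best_diff = d
                                best_genome = other
            signal = None
            if intra_min is not None and best_diff is not None:
                signal = intra_min > best_diff
            entries.append(
                GeneCopyEntry(
                    genome=gname,
                    gene=gene.id,
                    copy_count=len(own),
                    intragenomic_min_diff=intra_min,
                    intragenomic_max_diff=intra_max,
                    best_external_genome=best_genome,
                    best_external_diff=best_diff,
                    admixture_signal=signal,
                )
            )
    return GeneCopyReport(entries, all_hits)
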