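"""Forward simulator of multicopy rDNA and gene-copy evolution.

The study conditions this package diagnoses — concerted homogenization
keeping repeats uniform, birth-and-death turnover producing heterogeneous
dispersed pools with truncated pseudogenes, and hybridization leaving
mosaic genomes with repeats of mixed parentage — are generated here as
explicit mechanisms:

* an ancestral repeat array evolves down a species tree; substitutions are
  proposed per repeat at a Kimura-style rate (transition/transversion bias
  kappa) and accepted freely at unpaired sites but filtered at stem sites
  by wobble/CBC/mismatch acceptance probabilities, a mismatch at a
  designated CBC pair marking the repeat as a candidate pseudogene;
* homogenization overwrites a repeat with a donor from the same tandem
  array (dispersed repeats are never overwritten); an optional conversion
  tract length makes the overwrite partial, which is what creates chimeric
  repeats in hybrid arrays;
* birth-and-death events duplicate, delete, or terminally truncate
  repeats;
* a hybridization event merges two extant lineages' genomes block-wise
  (per-block retention, both-parent retention producing segmental
  diploidy) and can evolve the hybrid further.

Every sampled clone, emitted genome, Sanger-style consensus and truth
label is reproducible byte-for-byte from ``(config, seed)``.
"""

from __future__ import annotations

import copy
import itertools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import consensus as _consensus
from .seqio import Alignment, Region, SeqRecord, Source, reverse_complement, write_fasta
from .structure import CANONICAL_PAIRS, SecondaryStructure

__all__ = [
    "SpeciesTree",
    "SimulationConfig",
    "HybridizationEvent",
    "Repeat",
    "GeneCopy",
    "StrainGenome",
    "SimulatedDataset",
    "simulate_dataset",
    "sample_clones",
    "default_structure",
    "homogenized_config",
    "birth_death_config",
    "admixed_config",
    "matched_hybridization_configs",
    "emit_genome_fasta",
    "emit_clone_fasta",
    "emit_truth_tables",
]

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# species tree (minimal newick, names + branch lengths only)


@dataclass
class TreeNode:
    name: str
    length: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    def __init__(self, root: TreeNode):
        self.root = root

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        s = newick.strip().rstrip(";")
        pos = 0

        def parse() -> TreeNode:
            nonlocal pos
            node = TreeNode("", 0.0)
            if s[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse())
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
            m = re.match(r"[^(),:;]*", s[pos:])
            node.name = m.group(0)
            pos += len(node.name)
            if pos < len(s) and s[pos] == ":":
                pos += 1
                m = re.match(r"[0-9.eE+-]+", s[pos:])
                node.length = float(m.group(0))
                pos += len(m.group(0))
            return node

        root = parse()
        return cls(root)

    def leaves(self) -> list[str]:
        out = []

        def rec(n: TreeNode):
            if n.is_leaf:
                out.append(n.name)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class HybridizationEvent:
    """Merger of two extant (tip) lineages into a new mosaic strain."""

    parents: tuple[str, str]
    retention: float = 0.6        # per-block per-parent retention probability
    extra_time: float = 0.1       # further evolution of the hybrid, time units
    name: str = "HYB"
    label_as: str | None = None   # taxon label its clones are deposited under
                                  # (default: first parent, emulating
                                  # assignment to the phenotypically closest
                                  # species)


@dataclass
class SimulationConfig:
    """All rates and sizes of one simulated clade. Units: arbitrary time;
    rates are per repeat (or per site) per time unit."""

    seed: int = 0
    species_tree: str = "((A:0.6,B:0.6):0.5,(C:0.7,D:0.7):0.4);"
    mutation_rate: float = 0.03           # candidate substitutions /site /unit
    kappa: float = 4.0                    # transition:transversion rate ratio
    accept_wobble: float = 0.5            # stem change keeping a canonical/wobble pair
    accept_cbc: float = 0.25              # compensated double change at designated pair
    accept_mismatch: float = 0.3          # pair-breaking change
    homogenization_rate: float = 0.0      # overwrites /repeat /unit (arrayed only)
    conversion_tract: float | None = None # fraction of repeat copied; None = whole
    duplication_rate: float = 0.05
    deletion_rate: float = 0.05
    truncation_rate: float = 0.04
    truncation_span: tuple[float, float] = (0.1, 0.6)  # clipped terminal fraction
    placement: str = "dispersed"          # 'arrayed' | 'dispersed'
    n_repeats_initial: int = 8
    n_blocks: int = 20
    n_genes: int = 3
    gene_length: int = 300
    gene_mutation_rate: float = 0.005
    clones_per_strain: int = 8
    detect_threshold: float = _consensus.DEFAULT_DETECT_THRESHOLD
    hybridizations: list[HybridizationEvent] = field(default_factory=list)

    def __post_init__(self):
        for rate_name in (
            "mutation_rate", "homogenization_rate", "duplication_rate",
            "deletion_rate", "truncation_rate", "gene_mutation_rate",
        ):
            if getattr(self, rate_name) < 0:
                raise ValueError(f"{rate_name} must be >= 0")
        for p_name in ("accept_wobble", "accept_cbc", "accept_mismatch",
                       "detect_threshold"):
            if not (0 <= getattr(self, p_name) <= 1):
                raise ValueError(f"{p_name} must be in [0, 1]")
        if self.placement not in ("arrayed", "dispersed"):
            raise ValueError(f"unknown placement {self.placement!r}")
        tips = set(SpeciesTree.from_newick(self.species_tree).leaves())
        for ev in self.hybridizations:
            missing = set(ev.parents) - tips
            if missing:
                raise ValueError(
                    f"hybridization between non-coexisting lineages: "
                    f"{sorted(missing)} are not extant tips"
                )
            if not (0 <= ev.retention <= 1):
                raise ValueError("retention must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        events = [
            HybridizationEvent(
                parents=tuple(ev["parents"]),
                retention=ev.get("retention", 0.6),
                extra_time=ev.get("extra_time", 0.1),
                name=ev.get("name", "HYB"),
                label_as=ev.get("label_as"),
            )
            for ev in data.pop("hybridizations", [])
        ]
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "truncation_span" in data:
            data["truncation_span"] = tuple(data["truncation_span"])
        return cls(hybridizations=events, **data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "hybridizations"
        }
        data["truncation_span"] = list(self.truncation_span)
        data["hybridizations"] = [
            {
                "parents": list(ev.parents),
                "retention": ev.retention,
                "extra_time": ev.extra_time,
                "name": ev.name,
                "label_as": ev.label_as,
            }
            for ev in self.hybridizations
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# default secondary structure of the simulated barcode unit


def default_structure() -> tuple[SecondaryStructure, list[tuple[int, int]]]:
    """A 200-nt barcode unit with two hairpin domains and a third stem.

    Returns the structure (with loop annotations mimicking the D1/D2
    hairpin domains) and the designated CBC pairs — stem pairs treated as
    essential for folding, where a one-sided mismatch marks a pseudogene.
    """
    length = 200
    stems = [  # (left start, right start, stem length); right strand pairs back
        (20, 44, 12),   # D1: left 20-31, loop 32-43, right 44-55
        (80, 104, 12),  # D2: left 80-91, loop 92-103, right 104-115
        (140, 160, 10), # S3: left 140-149, loop 150-159, right 160-169
    ]
    pairs = set()
    for left, right, k in stems:
        for t in range(k):
            pairs.add((left + t, right + k - 1 - t))
    rng = np.random.default_rng(20210915)  # fixed: the reference is a constant
    seq = list(rng.choice(list(BASES), size=length))
    for i, j in pairs:
        seq[j] = WC[seq[i]]
    loops = [Region("D1", 20, 56), Region("D2", 80, 116), Region("S3", 140, 170)]
    ss = SecondaryStructure("".join(seq), frozenset(pairs), loops)
    # two designated pairs per stem, mid-stem
    designated = []
    for left, right, k in stems:
        for t in (3, 6 if k > 8 else 4):
            designated.append((left + t, right + k - 1 - t))
    return ss, sorted(designated)


# ---------------------------------------------------------------------------
# genome state


@dataclass
class Repeat:
    serial: int
    residues: list[str]          # length L; '-' marks truncated stretches
    origin: str                  # lineage of descent (tip name once at a tip)
    array: int                   # tandem array membership
    block: int

    def seq(self) -> str:
        return "".join(self.residues)

    def ungapped_positions(self) -> list[int]:
        return [i for i, ch in enumerate(self.residues) if ch != "-"]


@dataclass
class GeneCopy:
    serial: int
    gene: str
    residues: list[str]
    origin: str
    block: int

    def seq(self) -> str:
        return "".join(self.residues)


@dataclass
class StrainGenome:
    name: str
    repeats: list[Repeat]
    genes: list[GeneCopy]


@dataclass
class Placement:
    strain: str
    kind: str          # 'repeat' | 'gene'
    element_id: str
    contig: str
    start: int         # 0-based half-open
    end: int
    strand: str
    origin: str
    status: str
    block: int


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    structure: SecondaryStructure
    designated_pairs: list[tuple[int, int]]
    strains: dict[str, StrainGenome]
    clones: dict[str, list[SeqRecord]]        # aligned (gap-padded) clone rows
    clone_repeats: dict[str, list[Repeat]]
    sanger: dict[str, SeqRecord]
    taxon_map: dict[str, str]                 # clone id -> deposited taxon label
    genome_records: dict[str, list[SeqRecord]]
    placements: list[Placement]

    @property
    def reference_record(self) -> SeqRecord:
        return SeqRecord(
            id="REF", residues=self.structure.reference, source=Source.DATABASE
        )

    def clone_alignment(self, *, include_reference: bool = True) -> Alignment:
        """All strains' clones as one alignment (rows are gap-padded repeats
        of the common unit, so they are aligned by construction)."""
        rows = [self.reference_record] if include_reference else []
        for strain in sorted(self.clones):
            rows.extend(self.clones[strain])
        regions = list(self.structure.loops)
        return Alignment(records=rows, regions=regions)

    def strain_repeat_alignment(self, strain: str) -> Alignment:
        genome = self.strains[strain]
        rows = [
            SeqRecord(
                id=f"{strain}.r{r.serial}",
                residues=r.seq(),
                taxon=strain,
                source=Source.SIMULATED,
            )
            for r in genome.repeats
        ]
        return Alignment(records=rows)

    def repeat_status(self, repeat: Repeat) -> str:
        return _repeat_status(repeat, self.designated_pairs)

    def cbc_broken_clone_ids(self) -> set[str]:
        out = set()
        for strain, reps in self.clone_repeats.items():
            for rec, rep in zip(self.clones[strain], reps):
                if "cbc" in self.repeat_status(rep):
                    out.add(rec.id)
        return out

    def max_intragenomic_percent(self, strain: str) -> float:
        """Largest pairwise repeat distance within one genome; repeat pairs
        with no overlapping (untruncated) sites are skipped."""
        from .distance import UndefinedDistanceError, pairwise_distance

        aln = self.strain_repeat_alignment(strain)
        best = 0.0
        for i in range(aln.n_rows):
            for j in range(i + 1, aln.n_rows):
                try:
                    d = pairwise_distance(aln.records[i], aln.records[j])
                except UndefinedDistanceError:
                    continue
                best = max(best, d.percent)
        return best


def _repeat_status(repeat: Repeat, designated: Sequence[tuple[int, int]]) -> str:
    truncated = "-" in repeat.residues
    broken = False
    for i, j in designated:
        a, b = repeat.residues[i], repeat.residues[j]
        if a != "-" and b != "-" and (a, b) not in CANONICAL_PAIRS:
            broken = True
            break
    if broken and truncated:
        return "pseudogene_cbc+truncated"
    if broken:
        return "pseudogene_cbc"
    if truncated:
        return "pseudogene_truncated"
    return "intact"


# ---------------------------------------------------------------------------
# evolution mechanics


class _Evolver:
    def __init__(
        self,
        cfg: SimulationConfig,
        structure: SecondaryStructure,
        designated: Sequence[tuple[int, int]],
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        self.ss = structure
        self.designated = set(designated)
        self.rng = rng
        self.serial = itertools.count()

    # -- substitution proposal with structural acceptance

    def _propose_base(self, current: str) -> str:
        kappa = self.cfg.kappa
        p_ts = kappa / (kappa + 2.0)
        if self.rng.random() < p_ts:
            return TRANSITION[current]
        return TRANSVERSIONS[current][self.rng.integers(2)]

    def _mutate_repeat(self, rep: Repeat) -> None:
        positions = rep.ungapped_positions()
        if not positions:
            return
        site = positions[self.rng.integers(len(positions))]
        old = rep.residues[site]
        new = self._propose_base(old)
        partner = self.ss.partner.get(site)
        if partner is None or rep.residues[partner] == "-":
            rep.residues[site] = new
            return
        pair = (new, rep.residues[partner]) if site < partner else (
            rep.residues[partner], new
        )
        key = tuple(sorted((site, partner)))
        if pair in CANONICAL_PAIRS:
            if self.rng.random() < self.cfg.accept_wobble:
                rep.residues[site] = new
            return
        if key in self.designated and self.rng.random() < self.cfg.accept_cbc:
            # compensated double change: both sides move, pairing retained
            rep.residues[site] = new
            rep.residues[partner] = WC[new]
            return
        if self.rng.random() < self.cfg.accept_mismatch:
            rep.residues[site] = new   # pair broken; designated break = pseudogene

    def _mutate_gene(self, gene: GeneCopy) -> None:
        site = int(self.rng.integers(len(gene.residues)))
        gene.residues[site] = self._propose_base(gene.residues[site])

    # -- array events

    def _homogenize(self, genome: StrainGenome) -> None:
        if self.cfg.placement != "arrayed":
            return  # dispersed repeats are never overwritten
        if len(genome.repeats) < 2:
            return
        i, j = self.rng.choice(len(genome.repeats), size=2, replace=False)
        recipient, donor = genome.repeats[i], genome.repeats[j]
        if recipient.array != donor.array:
            return
        tract = self.cfg.conversion_tract
        if tract is None:
            recipient.residues = list(donor.residues)
            recipient.origin = donor.origin
        else:
            L = len(recipient.residues)
            span = max(1, int(round(tract * L)))
            start = int(self.rng.integers(0, L - span + 1))
            recipient.residues[start:start + span] = donor.residues[start:start + span]

    def _duplicate(self, genome: StrainGenome) -> None:
        i = int(self.rng.integers(len(genome.repeats)))
        src = genome.repeats[i]
        genome.repeats.append(
            Repeat(
                serial=next(self.serial),
                residues=list(src.residues),
                origin=src.origin,
                array=src.array,
                block=src.block,
            )
        )

    def _delete(self, genome: StrainGenome) -> None:
        if len(genome.repeats) <= 1:
            return
        i = int(self.rng.integers(len(genome.repeats)))
        del genome.repeats[i]

    def _truncate(self, genome: StrainGenome) -> None:
        i = int(self.rng.integers(len(genome.repeats)))
        rep = genome.repeats[i]
        lo, hi = self.cfg.truncation_span
        frac = lo + (hi - lo) * self.rng.random()
        L = len(rep.residues)
        span = max(1, int(round(frac * L)))
        if self.rng.random() < 0.5:     # 5' or 3' end
            rep.residues[:span] = ["-"] * span
        else:
            rep.residues[L - span:] = ["-"] * span

    # -- Gillespie loop over one branch

    def evolve(self, genome: StrainGenome, duration: float) -> None:
        cfg = self.cfg
        t = 0.0
        while True:
            n_rep = len(genome.repeats)
            rep_sites = sum(len(r.ungapped_positions()) for r in genome.repeats)
            gene_sites = sum(len(g.residues) for g in genome.genes)
            rates = np.array(
                [
                    cfg.mutation_rate * rep_sites,
                    cfg.gene_mutation_rate * gene_sites,
                    cfg.homogenization_rate * n_rep
                    if cfg.placement == "arrayed" else 0.0,
                    cfg.duplication_rate * n_rep,
                    cfg.deletion_rate * n_rep if n_rep > 1 else 0.0,
                    cfg.truncation_rate * n_rep,
                ]
            )
            total = rates.sum()
            if total <= 0:
                return
            t += self.rng.exponential(1.0 / total)
            if t >= duration:
                return
            kind = int(self.rng.choice(6, p=rates / total))
            if kind == 0:
                weights = np.array(
                    [len(r.ungapped_positions()) for r in genome.repeats], float
                )
                i = int(self.rng.choice(n_rep, p=weights / weights.sum()))
                self._mutate_repeat(genome.repeats[i])
            elif kind == 1:
                weights = np.array([len(g.residues) for g in genome.genes], float)
                i = int(self.rng.choice(len(genome.genes), p=weights / weights.sum()))
                self._mutate_gene(genome.genes[i])
            elif kind == 2:
                self._homogenize(genome)
            elif kind == 3:
                self._duplicate(genome)
            elif kind == 4:
                self._delete(genome)
            else:
                self._truncate(genome)


# ---------------------------------------------------------------------------
# top-level simulation


def _ancestral_genome(
    cfg: SimulationConfig,
    structure: SecondaryStructure,
    evolver: _Evolver,
    rng: np.random.Generator,
) -> StrainGenome:
    repeats = []
    for k in range(cfg.n_repeats_initial):
        array = 0 if cfg.placement == "arrayed" else k
        repeats.append(
            Repeat(
                serial=next(evolver.serial),
                residues=list(structure.reference),
                origin="root",
                array=array,
                block=int(rng.integers(cfg.n_blocks)),
            )
        )
    genes = []
    for g in range(cfg.n_genes):
        seq = rng.choice(list(BASES), size=cfg.gene_length)
        genes.append(
            GeneCopy(
                serial=next(evolver.serial),
                gene=f"GENE{g + 1}",
                residues=list(seq),
                origin="root",
                block=int(rng.integers(cfg.n_blocks)),
            )
        )
    return StrainGenome("root", repeats, genes)


def _hybridize(
    ev: HybridizationEvent,
    pa: StrainGenome,
    pb: StrainGenome,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    evolver: _Evolver,
) -> StrainGenome:
    """Block-wise merger with genome reduction.

    Each parent's copy of each block is retained independently with the
    event's retention probability; a block losing both copies keeps one
    uniformly chosen parent (full loss of a genome block is lethal)."""
    hybrid = StrainGenome(ev.name, [], [])
    for b in range(cfg.n_blocks):
        keep_a = rng.random() < ev.retention
        keep_b = rng.random() < ev.retention
        if not keep_a and not keep_b:
            if rng.random() < 0.5:
                keep_a = True
            else:
                keep_b = True
        for keep, parent in ((keep_a, pa), (keep_b, pb)):
            if not keep:
                continue
            for r in parent.repeats:
                if r.block == b:
                    hybrid.repeats.append(
                        replace(
                            copy.deepcopy(r), serial=next(evolver.serial)
                        )
                    )
            for g in parent.genes:
                if g.block == b:
                    hybrid.genes.append(
                        replace(
                            copy.deepcopy(g), serial=next(evolver.serial)
                        )
                    )
    if cfg.placement == "arrayed":
        for r in hybrid.repeats:
            r.array = 0   # merged into one nucleolar array
    if ev.extra_time > 0:
        evolver.evolve(hybrid, ev.extra_time)
    return hybrid


def sample_clones(
    genome: StrainGenome,
    n: int,
    rng: np.random.Generator | int,
    *,
    with_replacement: bool = False,
) -> list[Repeat]:
    """Uniform sample of repeat copies (the in-silico cloning step)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_rep = len(genome.repeats)
    if n > n_rep and not with_replacement:
        raise ValueError(
            f"cannot sample {n} clones from {n_rep} repeats without replacement"
        )
    idx = rng.choice(n_rep, size=n, replace=with_replacement)
    return [genome.repeats[int(i)] for i in sorted(idx)]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _build_genome_records(
    cfg: SimulationConfig,
    strains: dict[str, StrainGenome],
    designated: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[dict[str, list[SeqRecord]], list[Placement]]:
    records: dict[str, list[SeqRecord]] = {}
    placements: list[Placement] = []
    for strain in sorted(strains):
        genome = strains[strain]
        contigs: dict[str, list[str]] = {}
        cursor: dict[str, int] = {}

        def append(contig: str, seq: str) -> int:
            contigs.setdefault(contig, [])
            cursor.setdefault(contig, 0)
            contigs[contig].append(seq)
            start = cursor[contig]
            cursor[contig] += len(seq)
            return start

        def place(kind: str, element_id: str, seq: str, origin: str,
                  status: str, block: int, contig: str, strand: str):
            append(contig, _random_dna(rng, int(rng.integers(150, 400))))
            start = append(contig, seq)
            placements.append(
                Placement(
                    strain=strain, kind=kind, element_id=element_id,
                    contig=contig, start=start, end=start + len(seq),
                    strand=strand, origin=origin, status=status, block=block,
                )
            )

        if cfg.placement == "arrayed":
            for r in genome.repeats:
                seq = r.seq().replace("-", "")
                place(
                    "repeat", f"r{r.serial}", seq, r.origin,
                    _repeat_status(r, designated), r.block,
                    f"{strain}_chr_rdna", "+",
                )
            for g in genome.genes:
                place(
                    "gene", f"g{g.serial}", g.seq(), g.origin, "gene",
                    g.block, f"{strain}_chr_genes", "+",
                )
        else:
            n_contigs = 3
            for r in genome.repeats:
                seq = r.seq().replace("-", "")
                strand = "-" if rng.random() < 0.2 else "+"
                emitted = reverse_complement(seq) if strand == "-" else seq
                place(
                    "repeat", f"r{r.serial}", emitted, r.origin,
                    _repeat_status(r, designated), r.block,
                    f"{strain}_ctg{r.block % n_contigs + 1}", strand,
                )
            for g in genome.genes:
                place(
                    "gene", f"g{g.serial}", g.seq(), g.origin, "gene",
                    g.block, f"{strain}_ctg{g.block % n_contigs + 1}", "+",
                )
        recs = []
        for contig in sorted(contigs):
            contigs[contig].append(_random_dna(rng, int(rng.integers(150, 400))))
            recs.append(
                SeqRecord(
                    id=contig,
                    residues="".join(contigs[contig]),
                    taxon=strain,
                    source=Source.SIMULATED,
                )
            )
        records[strain] = recs
    return records, placements


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full forward simulation described in the module docstring."""
    rng = np.random.default_rng(cfg.seed)
    structure, designated = default_structure()
    evolver = _Evolver(cfg, structure, designated, rng)
    tree = SpeciesTree.from_newick(cfg.species_tree)

    strains: dict[str, StrainGenome] = {}

    def descend(node: TreeNode, genome: StrainGenome):
        evolver.evolve(genome, node.length)
        if node.is_leaf:
            genome.name = node.name
            for r in genome.repeats:
                r.origin = node.name
            for g in genome.genes:
                g.origin = node.name
            strains[node.name] = genome
            return
        for child in node.children:
            descend(child, copy.deepcopy(genome))

    descend(tree.root, _ancestral_genome(cfg, structure, evolver, rng))

    for ev in cfg.hybridizations:
        pa, pb = strains[ev.parents[0]], strains[ev.parents[1]]
        strains[ev.name] = _hybridize(ev, pa, pb, cfg, rng, evolver)

    label_of = {name: name for name in strains}
    for ev in cfg.hybridizations:
        label_of[ev.name] = ev.label_as or ev.parents[0]

    clones: dict[str, list[SeqRecord]] = {}
    clone_repeats: dict[str, list[Repeat]] = {}
    sanger: dict[str, SeqRecord] = {}
    taxon_map: dict[str, str] = {}
    for strain in sorted(strains):
        genome = strains[strain]
        n = min(cfg.clones_per_strain, len(genome.repeats))
        sampled = sample_clones(genome, n, rng)
        recs = []
        for i, rep in enumerate(sampled):
            rec = SeqRecord(
                id=f"{strain}.c{i:02d}.r{rep.serial}",
                residues=rep.seq(),
                taxon=label_of[strain],
                source=Source.SIMULATED,
            )
            recs.append(rec)
            taxon_map[rec.id] = label_of[strain]
        clones[strain] = recs
        clone_repeats[strain] = list(sampled)
        repeat_aln = Alignment(
            records=[
                SeqRecord(
                    id=f"{strain}.r{r.serial}", residues=r.seq(),
                    source=Source.SIMULATED,
                )
                for r in genome.repeats
            ]
        )
        result = _consensus.sanger_emulation(
            repeat_aln, detect_threshold=cfg.detect_threshold,
            record_id=f"{strain}.sanger",
        )
        sanger[strain] = rec_tagged = replace(
            result.record, taxon=label_of[strain]
        )
        taxon_map[rec_tagged.id] = label_of[strain]

    genome_records, placements = _build_genome_records(
        cfg, strains, designated, rng
    )
    return SimulatedDataset(
        config=cfg,
        structure=structure,
        designated_pairs=designated,
        strains=strains,
        clones=clones,
        clone_repeats=clone_repeats,
        sanger=sanger,
        taxon_map=taxon_map,
        genome_records=genome_records,
        placements=placements,
    )


# ---------------------------------------------------------------------------
# preset study conditions


def homogenized_config(seed: int = 0) -> SimulationConfig:
    """Concerted evolution: a contiguous array under strong gene conversion.

    Repeats stay near-identical within each genome while species diverge;
    the barcode gap between species is intact."""
    return SimulationConfig(
        seed=seed,
        placement="arrayed",
        mutation_rate=0.04,
        homogenization_rate=50.0,
        duplication_rate=0.01,
        deletion_rate=0.01,
        truncation_rate=0.0,
    )


def birth_death_config(seed: int = 0) -> SimulationConfig:
    """Birth-and-death turnover of dispersed repeats, no homogenization:
    heterogeneous pools with truncated pseudogene copies."""
    return SimulationConfig(
        seed=seed,
        placement="dispersed",
        homogenization_rate=0.0,
        duplication_rate=0.3,
        deletion_rate=0.2,
        truncation_rate=0.15,
    )


def admixed_config(seed: int = 0) -> SimulationConfig:
    """Hybridization between two species followed by mosaic retention and
    partial gene conversion between the co-arrayed parental repeats: the
    chimeric pool erases the barcode gap of the parent pair."""
    return SimulationConfig(
        seed=seed,
        placement="arrayed",
        homogenization_rate=3.0,
        conversion_tract=0.3,
        duplication_rate=0.02,
        deletion_rate=0.02,
        truncation_rate=0.0,
        hybridizations=[
            HybridizationEvent(parents=("B", "C"), retention=0.6, extra_time=0.4)
        ],
    )


def matched_hybridization_configs(
    seed: int = 0,
) -> tuple[SimulationConfig, SimulationConfig]:
    """(hybridization on, hybridization off) with otherwise identical
    parameters, for paired reticulation-signal comparisons."""
    on = admixed_config(seed)
    off = replace(on, hybridizations=[])
    return on, off


# ---------------------------------------------------------------------------
# emission


def emit_genome_fasta(dataset: SimulatedDataset, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain in sorted(dataset.genome_records):
        p = outdir / f"genome_{strain}.fasta"
        write_fasta(dataset.genome_records[strain], p, include_taxon=False)
        paths.append(p)
    return paths


def emit_clone_fasta(dataset: SimulatedDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / "clones.fasta"
    rows = []
    for strain in sorted(dataset.clones):
        rows.extend(dataset.clones[strain])
    write_fasta(rows, p)
    sanger_p = outdir / "sanger_consensus.fasta"
    write_fasta(
        [dataset.sanger[s] for s in sorted(dataset.sanger)], sanger_p
    )
    return p


def emit_truth_tables(dataset: SimulatedDataset, outdir: str | Path) -> Path:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    placements = pd.DataFrame([vars(p) for p in dataset.placements])
    placements.to_csv(outdir / "placements.tsv", sep="\t", index=False)
    clone_rows = []
    for strain in sorted(dataset.clones):
        for rec, rep in zip(dataset.clones[strain], dataset.clone_repeats[strain]):
            clone_rows.append(
                {
                    "clone_id": rec.id,
                    "strain": strain,
                    "taxon_label": dataset.taxon_map[rec.id],
                    "repeat_serial": rep.serial,
                    "origin": rep.origin,
                    "status": dataset.repeat_status(rep),
                }
            )
    pd.DataFrame(clone_rows).to_csv(outdir / "clones.tsv", sep="\t", index=False)
    with open(outdir / "taxon_map.tsv", "w") as fh:
        for cid, taxon in sorted(dataset.taxon_map.items()):
            fh.write(f"{cid}\t{taxon}\n")
    with open(outdir / "designated_pairs.tsv", "w") as fh:
        fh.write("# designated CBC pairs, 1-based reference coordinates\n")
        for i, j in dataset.designated_pairs:
            fh.write(f"{i + 1}\t{j + 1}\n")
    from .structure import write_dotbracket_file

    write_dotbracket_file(dataset.structure, outdir / "structure.dbn")
    dataset.config.to_yaml(outdir / "config.yaml")
    return outdir / "placements.tsv"
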