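"""Sequence input/output with strict IUPAC-DNA normalization.

All sequences in the pipeline pass through this module.  Residues are
uppercased and held in the DNA view (``U`` is mapped to ``T`` on input and
can be restored on output); anything outside the 16 IUPAC nucleotide codes
plus the gap character ``-`` is rejected with a position-accurate error.

Ambiguity symbols matter here: a Sanger read of a heterogeneous template
carries an IUPAC code wherever the basecaller saw two co-occurring peaks,
so the number of ambiguous positions in a deposited "taxonomic sequence"
is itself a measurement of intragenomic repeat diversity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Source",
    "SeqRecord",
    "Alignment",
    "Region",
    "SeqIOError",
    "EmptyFileError",
    "DuplicateIdError",
    "IllegalCharacterError",
    "LengthMismatchError",
    "IUPAC_SETS",
    "SET_TO_IUPAC",
    "iupac_set",
    "iupac_symbol",
    "read_fasta",
    "write_fasta",
    "read_taxon_map",
    "count_ambiguous_positions",
    "reverse_complement",
]

UNAMBIGUOUS = frozenset("ACGT-")

#: IUPAC nucleotide one-letter codes mapped to the set of bases they denote.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

SET_TO_IUPAC: Mapping[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

ALPHABET = frozenset(IUPAC_SETS) | {"U"}


class SeqIOError(ValueError):
    """Base class for sequence I/O failures."""


class EmptyFileError(SeqIOError):
    pass


class DuplicateIdError(SeqIOError):
    pass


class IllegalCharacterError(SeqIOError):
    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position  # 0-based internally
        self.char = char
        super().__init__(
            f"illegal character {char!r} in record {record_id!r} "
            f"at position {position + 1}"  # 1-based for humans
        )


class LengthMismatchError(SeqIOError):
    pass


class Source(str, enum.Enum):
    """Where a sequence came from."""

    CLONE = "clone"
    GENOME = "genome"
    DATABASE = "database"
    CONSENSUS = "consensus"
    SIMULATED = "simulated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def iupac_set(symbol: str) -> frozenset[str]:
    """Expand one IUPAC symbol to the set of bases it denotes ('-' -> {})."""
    s = symbol.upper().replace("U", "T")
    try:
        return IUPAC_SETS[s]
    except KeyError:
        raise SeqIOError(f"unknown IUPAC symbol {symbol!r}") from None


def iupac_symbol(bases: Iterable[str]) -> str:
    """Inverse of :func:`iupac_set`: the code denoting exactly *bases*."""
    key = frozenset(b.upper().replace("U", "T") for b in bases)
    try:
        return SET_TO_IUPAC[key]
    except KeyError:
        raise SeqIOError(f"no IUPAC symbol for base set {sorted(key)}") from None


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(residues: str) -> str:
    """IUPAC-aware reverse complement (DNA view)."""
    return residues.translate(_COMPLEMENT)[::-1]


def _normalize(residues: str, record_id: str) -> str:
    out = residues.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in IUPAC_SETS:
            raise IllegalCharacterError(record_id, i, ch)
    return out


@dataclass(frozen=True)
class SeqRecord:
    """One IUPAC-DNA sequence with identity and provenance.

    ``residues`` is always normalized (uppercase, T not U, validated).
    """

    id: str
    residues: str
    taxon: str = ""
    source: Source = Source.CLONE

    def __post_init__(self):
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r} has no residues")
        object.__setattr__(self, "residues", _normalize(self.residues, self.id))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def with_taxon(self, taxon: str) -> "SeqRecord":
        return replace(self, taxon=taxon)


def count_ambiguous_positions(seq: SeqRecord | str) -> int:
    """Number of positions carrying an ambiguity code (not A/C/G/T/-).

    For a Sanger-style consensus this counts the sites where the template
    pool was polymorphic above the basecaller's detection threshold.
    """
    residues = seq.residues if isinstance(seq, SeqRecord) else _normalize(seq, "<anon>")
    return sum(1 for ch in residues if ch not in UNAMBIGUOUS)


@dataclass(frozen=True)
class Region:
    """Named half-open [start, end) interval of alignment columns."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise SeqIOError(f"bad region interval {self.name}: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Alignment:
    """Equal-length rows plus optional region annotations (ITS1, 5.8S, ...)."""

    records: list[SeqRecord]
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise SeqIOError("alignment must contain at least one record")
        length = len(self.records[0])
        for rec in self.records:
            if len(rec) != length:
                raise LengthMismatchError(
                    f"row {rec.id!r} has length {len(rec)}, expected {length}"
                )
        for reg in self.regions:
            if reg.end > length:
                raise SeqIOError(f"region {reg.name} exceeds alignment length {length}")
        starts = sorted((r.start, r.end) for r in self.regions)
        for (s1, e1), (s2, _) in zip(starts, starts[1:]):
            if s2 < e1:
                raise SeqIOError("region intervals overlap")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(rec.residues[j] for rec in self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def region_named(self, name: str) -> Region:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(name)


def _taxon_from_header(description: str) -> str:
    # default convention: token after the last '|' in the header, else empty
    if "|" in description:
        return description.rsplit("|", 1)[1].strip()
    return ""


def read_fasta(
    path: str | Path,
    *,
    source: Source = Source.CLONE,
    allow_gaps: bool = True,
    taxon_map: Mapping[str, str] | None = None,
) -> list[SeqRecord]:
    """Read a FASTA file into normalized records.

    Taxon labels come from ``taxon_map`` (id -> taxon) when given, otherwise
    from the header convention (token after the last ``|``).  With
    ``allow_gaps=False`` the file is treated as unaligned and any ``-``
    raises :class:`IllegalCharacterError`.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DuplicateIdError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        residues = str(entry.seq)
        if not allow_gaps and "-" in residues:
            raise IllegalCharacterError(entry.id, residues.index("-"), "-")
        if taxon_map is not None:
            taxon = taxon_map.get(entry.id, "")
        else:
            taxon = _taxon_from_header(entry.description)
        records.append(SeqRecord(id=entry.id, residues=residues, taxon=taxon, source=source))
    if not records:
        raise EmptyFileError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Sequence[SeqRecord],
    path: str | Path,
    *,
    rna: bool = False,
    include_taxon: bool = True,
) -> None:
    """Write records to FASTA; ``rna=True`` restores the U view on output."""
    entries = []
    for rec in records:
        residues = rec.residues.replace("T", "U") if rna else rec.residues
        desc = f"|{rec.taxon}" if (include_taxon and rec.taxon) else ""
        entries.append(_BioSeqRecord(Seq(residues), id=rec.id, description=desc))
    with open(path, "w") as fh:
        _BioSeqIO.write(entries, fh, "fasta-2line")


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Two-column whitespace/tab-separated id -> taxon mapping file."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise SeqIOError(f"{path}:{lineno}: expected two columns, got {line!r}")
        seq_id, taxon = parts
        if seq_id in mapping and mapping[seq_id] != taxon:
            raise DuplicateIdError(f"{path}:{lineno}: conflicting taxon for {seq_id!r}")
        mapping[seq_id] = taxon.strip()
    if not mapping:
        raise EmptyFileError(f"no entries in taxon map {path}")
    return mapping
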