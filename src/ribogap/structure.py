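"""Variable alignment sites read against rRNA secondary structure.

Intragenomic rDNA variation is not uniform: in a functional repeat,
substitutions concentrate in unpaired (loop) segments, while changes in
helices must either keep a canonical pair — via the G·U wobble, a
hemi-compensatory single-side change, or a full compensatory base change
(CBC) on both sides — or break the helix.  A repeat carrying a broken
designated-CBC pair is a candidate pseudogene.

Structures are *inputs* (dot-bracket strings over a reference transcript);
this module never predicts folding.  Sequences are held in the DNA view
(T), pairing logic works on the RNA view (U) on the fly; classification is
invariant under the T/U representation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .seqio import Alignment, Region, SeqRecord

__all__ = [
    "SecondaryStructure",
    "VariableSite",
    "PairingEffect",
    "SubstitutionClass",
    "SiteClassificationReport",
    "StructureError",
    "parse_dotbracket",
    "read_dotbracket_file",
    "write_dotbracket_file",
    "find_variable_sites",
    "classify_pairing_effect",
    "flag_pseudogenes",
    "CANONICAL_PAIRS",
]

BASES = "ACGT"

#: Canonical pairs in the DNA view (T stands for U): Watson-Crick plus the
#: G·U wobble, the pair set tolerated in rRNA helices.
CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

_BRACKETS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


class StructureError(ValueError):
    pass


class SubstitutionClass(str, enum.Enum):
    PYRIMIDINE_TRANSITION = "pyrimidine_transition"
    PURINE_TRANSITION = "purine_transition"
    TRANSVERSION = "transversion"
    MIXED = "mixed"


class PairingEffect(str, enum.Enum):
    NEUTRAL_UNPAIRED = "neutral_unpaired"
    WOBBLE_NEUTRAL = "wobble_neutral"
    CBC = "CBC"
    HEMI_CBC = "hemi_CBC"
    MISMATCH = "mismatch"
    UNANCHORED = "unanchored"  # no reference coordinate -> no structural context


@dataclass
class SecondaryStructure:
    """Base-pair map over one reference transcript."""

    reference: str                      # DNA view internally
    pairs: frozenset[tuple[int, int]]   # (i, j), i < j, 0-based
    loops: list[Region] = field(default_factory=list)

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < len(self.reference)):
                raise StructureError(f"pair ({i}, {j}) out of range")
            if i in seen or j in seen:
                raise StructureError(f"position in more than one pair: ({i}, {j})")
            seen.update((i, j))
        self.partner: dict[int, int] = {}
        for i, j in self.pairs:
            self.partner[i] = j
            self.partner[j] = i

    def is_paired(self, i: int) -> bool:
        return i in self.partner

    @property
    def rna_reference(self) -> str:
        return self.reference.replace("T", "U")

    def unpaired_fraction(self) -> float:
        return 1.0 - len(self.partner) / len(self.reference)

    def loop_local(self, position: int) -> tuple[str, int] | None:
        """(loop name, 1-based position within loop) if inside a loop."""
        for reg in self.loops:
            if reg.start <= position < reg.end:
                return reg.name, position - reg.start + 1
        return None

    def check_noncrossing(self) -> None:
        """Raise if any two pairs cross (pseudoknot check over all tiers)."""
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i1, j1 = plist[a]
            for i2, j2 in plist[a + 1:]:
                if i1 < i2 < j1 < j2:
                    raise StructureError(
                        f"crossing pairs ({i1},{j1}) and ({i2},{j2})"
                    )


def parse_dotbracket(
    seq: str,
    structure: str,
    *,
    loops: Sequence[Region] = (),
    pseudoknot_free: bool = False,
) -> SecondaryStructure:
    """Build a pair map from a dot-bracket string (tiers ``()``, ``[]``, ``{}``)."""
    ref = seq.upper().replace("U", "T")
    if len(ref) != len(structure):
        raise StructureError(
            f"sequence length {len(ref)} != structure length {len(structure)}"
        )
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in _BRACKETS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise StructureError(f"unbalanced {ch!r} at position {pos + 1}")
            pairs.add((stacks[opener].pop(), pos))
        else:
            raise StructureError(f"unknown structure character {ch!r} at {pos + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced {opener!r} at position {stack[-1] + 1}"
            )
    ss = SecondaryStructure(ref, frozenset(pairs), list(loops))
    if pseudoknot_free:
        ss.check_noncrossing()
    return ss


def read_dotbracket_file(path: str | Path, **kwargs) -> SecondaryStructure:
    """Vienna-style file: optional ``>name`` line, sequence line, structure line."""
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError(f"{path}: expected sequence and structure lines")
    return parse_dotbracket(lines[0], lines[1], **kwargs)


def write_dotbracket_file(
    ss: SecondaryStructure, path: str | Path, *, name: str = "reference"
) -> None:
    chars = ["."] * len(ss.reference)
    for i, j in sorted(ss.pairs):
        chars[i], chars[j] = "(", ")"
    Path(path).write_text(f">{name}\n{ss.rna_reference}\n{''.join(chars)}\n")


@dataclass
class VariableSite:
    """One variable alignment column with its structural reading."""

    column: int                       # 0-based alignment column
    ref_position: int | None          # 0-based reference coordinate, None if ref-gapped
    state_counts: dict[str, int]      # DNA view, gaps excluded
    substitution_class: SubstitutionClass
    paired: bool
    partner_ref_position: int | None
    partner_column: int | None
    pairing_effect: PairingEffect
    hemi_cbc: bool = False            # single-side canonical-retaining change
    loop: tuple[str, int] | None = None      # (loop name, 1-based loop-local pos)

    @property
    def arity(self) -> int:
        return len(self.state_counts)

    @property
    def dimorphic(self) -> bool:
        """SND site: exactly two states alternate."""
        return self.arity == 2


def _substitution_class(states: frozenset[str]) -> SubstitutionClass:
    if len(states) > 2:
        return SubstitutionClass.MIXED
    if states == frozenset("CT"):
        return SubstitutionClass.PYRIMIDINE_TRANSITION
    if states == frozenset("AG"):
        return SubstitutionClass.PURINE_TRANSITION
    return SubstitutionClass.TRANSVERSION


def _column_to_ref(aln: Alignment, reference_row: int) -> list[int | None]:
    """Alignment column -> reference coordinate (None where reference gapped)."""
    ref = aln.records[reference_row].residues
    out: list[int | None] = []
    pos = 0
    for ch in ref:
        if ch == "-":
            out.append(None)
        else:
            out.append(pos)
            pos += 1
    return out


def classify_pairing_effect(
    site_states: Mapping[str, int] | frozenset[str],
    partner_states: Mapping[str, int] | frozenset[str],
    row_combinations: set[tuple[str, str]],
    canonical: frozenset[tuple[str, str]] = CANONICAL_PAIRS,
) -> tuple[PairingEffect, bool]:
    """Classify a paired variable site from per-sequence state combinations.

    ``row_combinations`` are the (site, partner) base combinations actually
    carried by individual sequences — read row-wise, not column-marginal,
    which is what separates a true CBC (groups of sequences each holding a
    different canonical combination) from coincidental double variability.

    Returns (effect, hemi_cbc_flag).
    """
    s_states = frozenset(site_states)
    p_states = frozenset(partner_states)
    combos = {c for c in row_combinations if c[0] in BASES and c[1] in BASES}
    if not combos:
        raise StructureError("no gap-free sequence spans the base pair")
    if any(c not in canonical for c in combos):
        return PairingEffect.MISMATCH, False
    site_varies = len(s_states) > 1
    partner_varies = len(p_states) > 1
    if site_varies and partner_varies:
        # every carried combination canonical, both sides vary: compensation
        return PairingEffect.CBC, False
    if site_varies or partner_varies:
        # one side varies and every combination still pairs: structurally
        # neutral; the wobble toggle C·G <-> U·G and the hemi-CBC
        # G-C -> G-U are the same single-side mechanism.  Flag hemi when the
        # variation swaps between two *distinct* canonical pairings.
        return PairingEffect.WOBBLE_NEUTRAL, len(combos) > 1
    return PairingEffect.WOBBLE_NEUTRAL, False


def find_variable_sites(
    aln: Alignment,
    structure: SecondaryStructure | None = None,
    min_minor_count: int = 3,
    *,
    reference_row: int = 0,
) -> list[VariableSite]:
    """Variable columns of *aln*, classified against *structure*.

    A column is variable iff >= 2 states occur among the gap-free rows and
    the minor (non-majority) states together reach ``min_minor_count``
    sequences (default 3: singletons and doubletons, the signature of
    amplification error, are excluded).  Columns where the reference row is
    gapped carry no structural context and are reported unanchored.
    """
    if aln.n_rows == 0:
        raise ValueError("empty alignment")
    col_to_ref = _column_to_ref(aln, reference_row)
    if structure is not None:
        n_ref = sum(1 for c in col_to_ref if c is not None)
        if n_ref != len(structure.reference):
            raise StructureError(
                f"reference row has {n_ref} residues but structure covers "
                f"{len(structure.reference)}"
            )
    ref_to_col = {r: c for c, r in enumerate(col_to_ref) if r is not None}
    sites: list[VariableSite] = []
    for j in range(aln.n_columns):
        counts: dict[str, int] = {}
        for rec in aln.records:
            ch = rec.residues[j]
            if ch in BASES:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) < 2:
            continue
        minor_total = sum(counts.values()) - max(counts.values())
        if minor_total < min_minor_count:
            continue
        states = frozenset(counts)
        ref_pos = col_to_ref[j]
        sub_class = _substitution_class(states)
        if ref_pos is None or structure is None:
            sites.append(
                VariableSite(
                    column=j,
                    ref_position=ref_pos,
                    state_counts=counts,
                    substitution_class=sub_class,
                    paired=False,
                    partner_ref_position=None,
                    partner_column=None,
                    pairing_effect=(
                        PairingEffect.UNANCHORED
                        if ref_pos is None
                        else PairingEffect.NEUTRAL_UNPAIRED
                    ),
                    loop=None if structure is None or ref_pos is None
                    else structure.loop_local(ref_pos),
                )
            )
            continue
        if not structure.is_paired(ref_pos):
            sites.append(
                VariableSite(
                    column=j,
                    ref_position=ref_pos,
                    state_counts=counts,
                    substitution_class=sub_class,
                    paired=False,
                    partner_ref_position=None,
                    partner_column=None,
                    pairing_effect=PairingEffect.NEUTRAL_UNPAIRED,
                    loop=structure.loop_local(ref_pos),
                )
            )
            continue
        p_ref = structure.partner[ref_pos]
        p_col = ref_to_col.get(p_ref)
        partner_counts: dict[str, int] = {}
        combos: set[tuple[str, str]] = set()
        if p_col is not None:
            for rec in aln.records:
                pc = rec.residues[p_col]
                if pc in BASES:
                    partner_counts[pc] = partner_counts.get(pc, 0) + 1
                sc = rec.residues[j]
                if sc in BASES and pc in BASES:
                    combos.add((sc, pc))
            effect, hemi = classify_pairing_effect(counts, partner_counts, combos)
        else:
            raise StructureError(
                f"partner column for reference position {p_ref} missing in alignment"
            )
        sites.append(
            VariableSite(
                column=j,
                ref_position=ref_pos,
                state_counts=counts,
                substitution_class=sub_class,
                paired=True,
                partner_ref_position=p_ref,
                partner_column=p_col,
                pairing_effect=effect,
                hemi_cbc=hemi,
                loop=structure.loop_local(ref_pos),
            )
        )
    return sites


@dataclass
class PseudogeneFlag:
    seq_id: str
    reasons: list[tuple[int, int, str, str]]  # (col, partner col, carried combo)


@dataclass
class SiteClassificationReport:
    sites: list[VariableSite]
    flags: list[PseudogeneFlag]
    region_variability: dict[str, float]   # region name -> variable cols / length

    @property
    def flagged_ids(self) -> set[str]:
        return {f.seq_id for f in self.flags}

    def sites_with_effect(self, effect: PairingEffect) -> list[VariableSite]:
        return [s for s in self.sites if s.pairing_effect is effect]


def flag_pseudogenes(
    aln: Alignment,
    structure: SecondaryStructure,
    sites: Sequence[VariableSite] | None = None,
    *,
    min_minor_count: int = 3,
    reference_row: int = 0,
    designated_pairs: set[tuple[int, int]] | None = None,
) -> SiteClassificationReport:
    """Flag sequences carrying broken designated-CBC pairs.

    When ``designated_pairs`` is given (reference coordinates, i < j) it is
    used as-is — the caller knows which pairs are essential.  Otherwise a
    pair is *CBC-designated* when the sequences collectively carry at least
    two distinct canonical combinations at it (the pair is seen to
    compensate).  A sequence is flagged iff it holds a non-canonical
    combination at a designated pair; each flag cites the offending pair
    and the carried combination.
    """
    if sites is None:
        sites = find_variable_sites(
            aln, structure, min_minor_count, reference_row=reference_row
        )
    col_to_ref = _column_to_ref(aln, reference_row)
    ref_to_col = {r: c for c, r in enumerate(col_to_ref) if r is not None}

    if designated_pairs is not None:
        designated = {tuple(sorted(p)) for p in designated_pairs}
    else:
        candidate_pairs: set[tuple[int, int]] = set()
        for s in sites:
            if s.paired and s.ref_position is not None:
                i, j = sorted((s.ref_position, s.partner_ref_position))
                candidate_pairs.add((i, j))
        designated = set()
        for (i, j) in candidate_pairs:
            ci, cj = ref_to_col.get(i), ref_to_col.get(j)
            if ci is None or cj is None:
                continue
            canonical_combos = set()
            for rec in aln.records:
                a, b = rec.residues[ci], rec.residues[cj]
                if a in BASES and b in BASES and (a, b) in CANONICAL_PAIRS:
                    canonical_combos.add((a, b))
            if len(canonical_combos) >= 2:
                designated.add((i, j))

    flags: list[PseudogeneFlag] = []
    for rec in aln.records:
        reasons = []
        for (i, j) in sorted(designated):
            ci, cj = ref_to_col.get(i), ref_to_col.get(j)
            if ci is None or cj is None:
                continue
            a, b = rec.residues[ci], rec.residues[cj]
            if a in BASES and b in BASES and (a, b) not in CANONICAL_PAIRS:
                reasons.append((ci, cj, a, b))
        if reasons:
            flags.append(PseudogeneFlag(rec.id, reasons))

    variable_cols = {s.column for s in sites}
    region_var: dict[str, float] = {}
    for reg in aln.regions:
        n_var = sum(1 for c in variable_cols if reg.start <= c < reg.end)
        region_var[reg.name] = n_var / len(reg)
    return SiteClassificationReport(list(sites), flags, region_var)
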