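"""Consensus barcodes over heterogeneous repeat pools.

Three related reductions of an aligned repeat set to one sequence:

* :func:`majority_consensus` — plain majority rule, the de facto output of
  routine Sanger basecalling pipelines;
* :func:`iupac_consensus` — "polymorphic" consensus in which every column
  whose minor states reach a proportion threshold is written as the IUPAC
  code of the full called state set (di-/tri-/tetramorphic columns become
  two-, three- and four-base codes);
* :func:`sanger_emulation` — abundance-weighted IUPAC consensus, an
  in-silico direct-sequencing read of a multicopy template: a minor repeat
  class stays invisible until its weighted proportion reaches the
  basecaller's detection threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

_log = logging.getLogger(__name__)

from .seqio import Alignment, SeqRecord, Source, iupac_symbol

__all__ = [
    "ConsensusResult",
    "iupac_consensus",
    "majority_consensus",
    "sanger_emulation",
    "DEFAULT_DETECT_THRESHOLD",
]

BASES = "ACGT"
BASE_ORDER = {b: i for i, b in enumerate(BASES)}

#: Minor-variant detection threshold of the emulated basecaller: a repeat
#: class must reach 25% weighted abundance before its divergent base shows
#: up as an ambiguity code (a 3:1 minority is just detectable).
DEFAULT_DETECT_THRESHOLD = 0.25


@dataclass
class ConsensusResult:
    """IUPAC consensus with per-column bookkeeping."""

    record: SeqRecord
    proportions: list[dict[str, float]]  # per column, base -> proportion (gaps excluded)
    called_sets: list[frozenset[str]]
    threshold: float
    fallback_columns: list[int]          # columns where no state reached threshold
    tie_columns: list[int]               # majority ties broken by base order

    @property
    def arity(self) -> list[int]:
        """Per-column number of called states (1=mono ... 4=tetramorphic)."""
        return [len(s) if s else 1 for s in self.called_sets]

    def to_rows(self) -> list[dict]:
        rows = []
        for j, props in enumerate(self.proportions):
            rows.append(
                {
                    "column": j + 1,  # 1-based for reports
                    "symbol": self.record.residues[j],
                    "arity": self.arity[j],
                    **{b: round(props.get(b, 0.0), 6) for b in BASES},
                }
            )
        return rows


def _column_proportions(
    aln: Alignment, weights: Sequence[float] | None
) -> list[tuple[dict[str, float], float]]:
    """Per column: (base -> gap-excluded proportion, gap weight fraction).

    Ambiguity codes in the input rows carry no weight toward any base.
    """
    n = aln.n_rows
    if weights is None:
        weights = [1.0 / n] * n
    out: list[tuple[dict[str, float], float]] = []
    for j in range(aln.n_columns):
        acc: dict[str, float] = {}
        gap_w = 0.0
        covered = 0.0
        for rec, w in zip(aln.records, weights):
            ch = rec.residues[j]
            if ch in BASES:
                acc[ch] = acc.get(ch, 0.0) + w
                covered += w
            elif ch == "-":
                gap_w += w
                covered += w
        gap_frac = gap_w / covered if covered > 0 else 0.0
        base_total = sum(acc.values())
        if base_total > 0:
            acc = {k: v / base_total for k, v in acc.items()}
        out.append((acc, gap_frac))
    return out


def _call_column(
    base_props: dict[str, float], gap_frac: float, threshold: float
) -> tuple[str, frozenset[str], bool, bool]:
    """Return (symbol, called base set, fallback?, tie?) for one column."""
    if gap_frac > 0.5 or not base_props:
        return "-", frozenset(), False, False
    called = frozenset(b for b, p in base_props.items() if p >= threshold)
    if called:
        return iupac_symbol(called), called, False, False
    # all states below threshold: fall back to the majority state
    best = max(base_props.values())
    winners = sorted((b for b, p in base_props.items() if p == best), key=BASE_ORDER.get)
    tie = len(winners) > 1
    return winners[0], frozenset(winners[:1]), True, tie


def iupac_consensus(
    aln: Alignment,
    min_proportion: float,
    *,
    weights: Sequence[float] | None = None,
    record_id: str = "consensus",
) -> ConsensusResult:
    """Polymorphic IUPAC consensus: call every state at proportion >= threshold.

    Gap columns emit '-' when the gap proportion exceeds 0.5 (keeps the
    consensus alignable with its inputs).  If no state reaches the threshold
    the majority state is called and the column flagged as a fallback.
    """
    if not (0 < min_proportion <= 1):
        raise ValueError("min_proportion must be in (0, 1]")
    props = _column_proportions(aln, weights)
    symbols = []
    called_sets = []
    fallbacks: list[int] = []
    ties: list[int] = []
    for j, (base_props, gap_frac) in enumerate(props):
        sym, called, fb, tie = _call_column(base_props, gap_frac, min_proportion)
        symbols.append(sym)
        called_sets.append(called)
        if fb:
            fallbacks.append(j)
        if tie:
            ties.append(j)
    record = SeqRecord(
        id=record_id, residues="".join(symbols), source=Source.CONSENSUS
    )
    return ConsensusResult(
        record, [p for p, _ in props], called_sets, min_proportion, fallbacks, ties
    )


def majority_consensus(aln: Alignment, *, record_id: str = "majority") -> SeqRecord:
    """Strict per-column majority; ties broken by base order A<C<G<T.

    Equivalent to :func:`iupac_consensus` at a threshold just above 0.5
    (every column is a fallback call).
    """
    result = iupac_consensus(aln, min_proportion=1.0, record_id=record_id)
    # threshold 1.0 only calls unanimous columns; everything else falls back
    # to the majority state, which is exactly majority rule.
    if result.tie_columns:
        _log.warning(
            "majority ties at columns %s broken toward base order A<C<G<T",
            [j + 1 for j in result.tie_columns],
        )
    return result.record


def sanger_emulation(
    repeats: Alignment,
    abundances: Sequence[float] | None = None,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    *,
    record_id: str = "sanger",
) -> ConsensusResult:
    """Emulated direct Sanger read of a multicopy template.

    Column proportions are weighted by repeat abundance; any state at or
    above ``detect_threshold`` enters the called set and the column is
    written as the corresponding IUPAC code.  Divergent repeats below the
    threshold leave no trace — the mechanism by which intragenomic rDNA
    diversity hides inside a clean-looking "taxonomic sequence".
    """
    n = repeats.n_rows
    if abundances is None:
        abundances = [1.0 / n] * n
    if len(abundances) != n:
        raise ValueError(
            f"{len(abundances)} abundances for {n} repeat records"
        )
    if any(a < 0 for a in abundances):
        raise ValueError("abundances must be non-negative")
    total = sum(abundances)
    if abs(total - 1.0) > 1e-9:
        if total == 0:
            raise ValueError("abundances sum to zero")
        abundances = [a / total for a in abundances]
    return iupac_consensus(
        repeats, detect_threshold, weights=abundances, record_id=record_id
    )
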