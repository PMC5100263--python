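"""Monomer and head-to-head dimer consensus scanning.

The default grammar is the SOX10 consensus: a monomer is ``ACACA`` or
``ACAAD`` (D = G/T/A). A dimeric site is a forward monomer followed, after a
spacer of 5-10 bp, by the reverse complement of a monomer (``TGTGT`` or
``HTTGT``, H = A/C/T) — two monomers facing head-to-head on opposite strands.

Scanning is lookahead-style: overlapping matches are all reported, and one
forward monomer may pair with several reverse monomers at different spacer
lengths. The dimer pattern family is closed under reverse complement, so
dimers are found in a single plus-strand pass (a both-strand pass would
count every site twice). ``N`` matches no consensus position but is allowed
inside spacers, whose content is unconstrained.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .sequence_io import GenomeSequence, GenomicInterval

__all__ = [
    "IUPAC_CLASSES",
    "MotifGrammar",
    "MonomerMatch",
    "DimerMatch",
    "MatchSummary",
    "pattern_to_regex",
    "reverse_complement_pattern",
    "scan_monomers",
    "scan_dimers",
    "count_matches",
]

# degeneracy classes over unambiguous bases; N deliberately excluded from
# every class so assembly padding can never match a consensus position
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHV", "TGCAYRSWMKVHDB")


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC degenerate pattern (D↔H, R↔Y, ...)."""
    bad = set(pattern) - set(IUPAC_CLASSES)
    if bad:
        raise ValueError(f"unknown pattern symbol {sorted(bad)[0]!r}")
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def pattern_to_regex(pattern: str) -> str:
    """Regex fragment matching a degenerate pattern on plain ACGT text."""
    parts = []
    for sym in pattern:
        bases = sorted(IUPAC_CLASSES[sym])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(parts)


@dataclass(frozen=True)
class MotifGrammar:
    """The consensus definition as data.

    ``forward_patterns`` are fixed-length IUPAC patterns; the reverse
    patterns are always derived by reverse complement, never user-supplied.
    """

    forward_patterns: tuple[str, ...] = ("ACACA", "ACAAD")
    spacer_min: int = 5
    spacer_max: int = 10

    def __post_init__(self) -> None:
        if not self.forward_patterns:
            raise ValueError("grammar needs at least one forward pattern")
        lengths = {len(p) for p in self.forward_patterns}
        if len(lengths) != 1:
            raise ValueError("all forward patterns must have equal length")
        for p in self.forward_patterns:
            reverse_complement_pattern(p)  # validates symbols
        if not (0 < self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 < spacer_min <= spacer_max")

    @property
    def monomer_length(self) -> int:
        return len(self.forward_patterns[0])

    @property
    def reverse_patterns(self) -> tuple[str, ...]:
        return tuple(reverse_complement_pattern(p) for p in self.forward_patterns)

    def forward_regex(self) -> re.Pattern[str]:
        alts = "|".join(pattern_to_regex(p) for p in self.forward_patterns)
        return re.compile(f"(?=({alts}))")  # lookahead: overlapping matches

    def reverse_regex(self) -> re.Pattern[str]:
        alts = "|".join(pattern_to_regex(p) for p in self.reverse_patterns)
        return re.compile(f"(?=({alts}))")


DEFAULT_GRAMMAR = MotifGrammar()


@dataclass(frozen=True, order=True)
class MonomerMatch(GenomicInterval):
    """One consensus monomer occurrence; matched_text is plus-strand text."""

    matched_text: str = ""

    @property
    def pattern_strand(self) -> str:
        return self.strand


@dataclass(frozen=True, order=True)
class DimerMatch(GenomicInterval):
    """A head-to-head dimer: forward monomer, spacer, reverse monomer."""

    forward_monomer: MonomerMatch = None  # type: ignore[assignment]
    reverse_monomer: MonomerMatch = None  # type: ignore[assignment]
    spacer_sequence: str = ""

    @property
    def spacer_length(self) -> int:
        return len(self.spacer_sequence)


def _find_pattern_starts(text: str, regex: re.Pattern[str]) -> list[int]:
    return [m.start() for m in regex.finditer(text)]


def scan_monomers(seq: GenomeSequence, grammar: MotifGrammar = DEFAULT_GRAMMAR,
                  strand_mode: Literal["plus", "both"] = "both"
                  ) -> list[MonomerMatch]:
    """Report every monomer consensus occurrence; overlaps all reported.

    In ``both`` mode a minus-strand match is a position where the plus-strand
    text matches a reverse (reverse-complement) pattern. Output is sorted by
    start, then strand.
    """
    if strand_mode not in ("plus", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    k = grammar.monomer_length
    text = seq.residues
    out: list[MonomerMatch] = []
    for start in _find_pattern_starts(text, grammar.forward_regex()):
        out.append(MonomerMatch(seq.name, start, start + k, name="monomer",
                                strand="+", matched_text=text[start:start + k]))
    if strand_mode == "both":
        for start in _find_pattern_starts(text, grammar.reverse_regex()):
            out.append(MonomerMatch(seq.name, start, start + k, name="monomer",
                                    strand="-",
                                    matched_text=text[start:start + k]))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def scan_dimers(seq: GenomeSequence, grammar: MotifGrammar = DEFAULT_GRAMMAR
                ) -> list[DimerMatch]:
    """Report every head-to-head dimer with spacer in the grammar's range.

    Single plus-strand pass; all (forward, spacer, reverse) pairings are
    reported, exact duplicates removed, output sorted by coordinate.
    """
    k = grammar.monomer_length
    text = seq.residues
    fwd_starts = _find_pattern_starts(text, grammar.forward_regex())
    rev_starts = set(_find_pattern_starts(text, grammar.reverse_regex()))
    seen: set[tuple[int, int]] = set()
    out: list[DimerMatch] = []
    for f in fwd_starts:
        for spacer in range(grammar.spacer_min, grammar.spacer_max + 1):
            r = f + k + spacer
            if r in rev_starts and (f, r) not in seen:
                seen.add((f, r))
                out.append(DimerMatch(
                    seq.name, f, r + k,
                    name="dimer", strand="+",
                    forward_monomer=MonomerMatch(
                        seq.name, f, f + k, name="monomer", strand="+",
                        matched_text=text[f:f + k]),
                    reverse_monomer=MonomerMatch(
                        seq.name, r, r + k, name="monomer", strand="-",
                        matched_text=text[r:r + k]),
                    spacer_sequence=text[f + k:r],
                ))
    out.sort(key=lambda d: (d.start, d.end))
    return out


@dataclass(frozen=True)
class MatchSummary:
    total: int
    by_strand: dict[str, int]
    by_pattern: dict[str, int]
    spacer_histogram: dict[int, int]


def count_matches(matches: Sequence[MonomerMatch | DimerMatch],
                  grammar: MotifGrammar = DEFAULT_GRAMMAR) -> MatchSummary:
    """Exact totals by strand, by matched text, and by spacer length."""
    by_strand: Counter[str] = Counter()
    by_pattern: Counter[str] = Counter()
    spacer_hist: Counter[int] = Counter(
        {s: 0 for s in range(grammar.spacer_min, grammar.spacer_max + 1)})
    for m in matches:
        by_strand[m.strand] += 1
        if isinstance(m, DimerMatch):
            by_pattern[f"{m.forward_monomer.matched_text}/"
                       f"{m.reverse_monomer.matched_text}"] += 1
            spacer_hist[m.spacer_length] += 1
        else:
            by_pattern[m.matched_text] += 1
    return MatchSummary(
        total=len(matches),
        by_strand=dict(by_strand),
        by_pattern=dict(by_pattern),
        spacer_histogram=dict(spacer_hist),
    )
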