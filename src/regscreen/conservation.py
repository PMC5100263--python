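"""Exact-identity multi-species conservation (phylogenetic footprinting).

Extracts maximal reference-coordinate runs of alignment columns that are
identical across a chosen species set — the classic exact-match footprinting
used to prioritise candidate regulatory elements. The default species set is
human/mouse/chicken with human as the reference and a minimum run length of
5 bp (the length of one consensus monomer).

Column policy: a column qualifies only when every species in the set is
present in the block and carries the *same* nucleotide — case-insensitive,
not ``N`` (absence of information is not identity), and not a gap in any
species. Because a reference gap disqualifies a column, a qualifying run's
reference-coordinate length always equals its column count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sequence_io import AlignmentBlock, GenomicInterval

__all__ = ["SpeciesSet", "ConservedSegment", "extract_identical_segments",
           "merge_segments"]


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered species identifiers with a designated reference."""

    species: tuple[str, ...] = ("hg18", "mm9", "galGal3")
    reference: str = "hg18"

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least 2 species")
        if self.reference not in self.species:
            raise ValueError(
                f"reference {self.reference!r} not in species set {self.species}"
            )


@dataclass(frozen=True, order=True)
class ConservedSegment(GenomicInterval):
    """Maximal run of columns identical across the species set."""

    species: SpeciesSet = None  # type: ignore[assignment]


def _column_identical(chars: Sequence[str]) -> bool:
    first = chars[0].upper()
    if first in ("-", "N"):
        return False
    return all(c.upper() == first for c in chars[1:])


def extract_identical_segments(blocks: Sequence[AlignmentBlock],
                               species: SpeciesSet = SpeciesSet(),
                               min_length: int = 5) -> list[ConservedSegment]:
    """Maximal exact-identity runs of reference length >= ``min_length``.

    Blocks missing any species of the set contribute nothing; a block whose
    rows do not include the reference species raises. Output is sorted and
    non-overlapping within each block.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    segments: list[ConservedSegment] = []
    for bi, block in enumerate(blocks):
        ref_row = block.row_for(species.reference)
        if ref_row is None:
            raise ValueError(
                f"block {bi}: reference species {species.reference!r} absent"
            )
        rows = [block.row_for(sp) for sp in species.species]
        if any(r is None for r in rows):
            continue
        texts = [r.text for r in rows]  # type: ignore[union-attr]
        ref_text = ref_row.text
        ref_pos = ref_row.start
        run_start: int | None = None
        run_len = 0

        def flush(end_pos: int) -> None:
            nonlocal run_start, run_len
            if run_start is not None and run_len >= min_length:
                segments.append(ConservedSegment(
                    ref_row.chrom or ref_row.species, run_start, end_pos,
                    name="exact:" + ",".join(species.species),
                    species=species))
            run_start, run_len = None, 0

        for col in range(block.width):
            ref_char = ref_text[col]
            ok = ref_char != "-" and _column_identical([t[col] for t in texts])
            if ok:
                if run_start is None:
                    run_start = ref_pos
                run_len += 1
            else:
                flush(ref_pos)
            if ref_char != "-":
                ref_pos += 1
        flush(ref_pos)
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    return segments


def merge_segments(segments: Sequence[ConservedSegment]
                   ) -> list[ConservedSegment]:
    """Union of book-ended or overlapping segments on the reference.

    Adjacent multiz blocks may abut on reference coordinates; merging makes
    the output a set of maximal disjoint intervals.
    """
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.end))
    out: list[ConservedSegment] = []
    for seg in ordered:
        if out and out[-1].chrom == seg.chrom and seg.start <= out[-1].end:
            prev = out[-1]
            if seg.end > prev.end:
                out[-1] = ConservedSegment(prev.chrom, prev.start, seg.end,
                                           name=prev.name, species=prev.species)
        else:
            out.append(seg)
    return out
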