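"""Sequence and interval I/O: FASTA, BED, genePred/BED12, MAF.

Coordinate conventions used throughout the package:

* Internal coordinates are **0-based, half-open** (BED convention) everywhere.
  1-based fully-closed "browser" coordinates appear only at I/O boundaries,
  via :func:`browser_to_internal` / :func:`internal_to_browser`.
* Lowercase (soft-masked) residues are uppercased on read; masking is not
  tracked — consensus scanning is case-insensitive by construction.
* ``N`` is retained but treated downstream as "no information": it never
  matches a consensus position and never counts as identical in conservation.
* MAF rows on the ``-`` source strand are flipped to ``+`` coordinates at read
  time for the *reference* row only; non-reference rows contribute column
  identity, not output coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "VALID_RESIDUES",
    "GenomeSequence",
    "GenomicInterval",
    "ScoredInterval",
    "GeneModel",
    "AlignmentRow",
    "AlignmentBlock",
    "SequenceFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "browser_to_internal",
    "internal_to_browser",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_maf",
    "write_maf",
]

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceFormatError(ValueError):
    """A file or sequence violates the format contract of a reader."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome (or contig): uppercase residues over {A,C,G,T,N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise SequenceFormatError("sequence name must be non-empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise SequenceFormatError(
                f"non-IUPAC residue {sorted(bad)[0]!r} in sequence {self.name!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                " (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class ScoredInterval(GenomicInterval):
    """Interval carrying a non-negative finite score (e.g. an F-Seq score)."""

    score: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (self.score >= 0.0 and self.score == self.score and self.score != float("inf")):
            raise ValueError(f"score must be finite and >= 0, got {self.score!r}")


@dataclass(frozen=True)
class GeneModel:
    """A transcript: span, ordered disjoint exons, optional CDS span."""

    gene: str
    transcript: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene model strand must be + or -, got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"invalid transcript span for {self.transcript}")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e or s < prev_end:
                raise ValueError(
                    f"exons of {self.transcript} must be sorted, disjoint and "
                    "within the transcript span"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"CDS of {self.transcript} outside transcript span")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end,
                               name=self.gene, strand=self.strand)

    def cds_exons(self) -> list[tuple[int, int]]:
        """Exon pieces that are protein-coding: exons ∩ CDS span."""
        if not self.is_coding:
            return []
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                out.append((lo, hi))
        return out


@dataclass(frozen=True)
class AlignmentRow:
    """One 's' line of a MAF block, in source-strand coordinates."""

    species: str
    chrom: str
    start: int          # 0-based on the source strand
    size: int           # ungapped length
    strand: str         # '+' or '-'
    src_size: int
    text: str           # aligned text, may contain '-'

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chrom}" if self.chrom else self.species


@dataclass(frozen=True)
class AlignmentBlock:
    """A MAF alignment block; ``rows[reference_index]`` is the reference."""

    rows: tuple[AlignmentRow, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment block must have >= 1 row")
        widths = {len(r.text) for r in self.rows}
        if len(widths) != 1:
            raise SequenceFormatError("alignment rows differ in aligned length")
        for r in self.rows:
            ungapped = sum(1 for c in r.text if c != "-")
            if ungapped != r.size:
                raise SequenceFormatError(
                    f"row {r.src}: declared size {r.size} != non-gap count {ungapped}"
                )

    @property
    def reference(self) -> AlignmentRow:
        return self.rows[self.reference_index]

    @property
    def width(self) -> int:
        return len(self.rows[0].text)

    def row_for(self, species: str) -> AlignmentRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into uppercase GenomeSequences.

    The header token before the first whitespace becomes the name. Empty
    files, records with no residues, and non-IUPAC characters are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceFormatError(f"{path}: empty or header-less FASTA")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceFormatError(f"{path}: record {rec.id!r} has no residues")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise SequenceFormatError(
                f"{path}: non-IUPAC character {sorted(bad)[0]!r} in record {rec.id!r}"
            )
        out.append(GenomeSequence(name=rec.id, residues=seq))
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Reverse complement and coordinate conversion
# ---------------------------------------------------------------------------

def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution. N maps to N."""
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"cannot complement non-nucleotide character {sorted(bad)[0]!r}")
    return sequence.translate(_COMPLEMENT)[::-1]


def browser_to_internal(coord: tuple[int, int]) -> tuple[int, int]:
    """1-based fully-closed browser coordinates → 0-based half-open."""
    start, end = coord
    if start < 1 or start > end:
        raise ValueError(f"invalid browser coordinates {coord!r}")
    return start - 1, end


def internal_to_browser(coord: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open → 1-based fully-closed browser coordinates."""
    start, end = coord
    if start < 0 or start >= end:
        raise ValueError(f"invalid internal coordinates {coord!r}")
    return start + 1, end


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, scored: bool = False
             ) -> list[GenomicInterval] | list[ScoredInterval]:
    """Read BED3/BED4/BED5; with ``scored`` column 5 is parsed as the score.

    ``#``/``track``/``browser`` lines are skipped. File order is preserved.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise SequenceFormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise SequenceFormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-." else "."
            if scored:
                if len(cols) < 5:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: scored BED needs >= 5 columns"
                    )
                out.append(ScoredInterval(chrom, start, end, name=name,
                                          strand=strand, score=float(cols[4])))
            else:
                out.append(GenomicInterval(chrom, start, end, name=name,
                                           strand=strand))
    return out


def _bed_line(iv: GenomicInterval) -> str:
    cols = [iv.chrom, str(iv.start), str(iv.end)]
    score = getattr(iv, "score", None)
    if score is not None or iv.name or iv.strand != ".":
        cols.append(iv.name)
    if score is not None:
        cols.append(format(score, "g"))
    elif iv.strand != ".":
        cols.append("0")
    if iv.strand != ".":
        cols.append(iv.strand)
    return "\t".join(cols)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              header: str | None = None) -> None:
    """Write BED, deterministically sorted by (chrom, start, end, name)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for iv in ivs:
            fh.write(_bed_line(iv) + "\n")


# ---------------------------------------------------------------------------
# Gene models (genePred and BED12)
# ---------------------------------------------------------------------------

def _parse_genepred(cols: list[str], where: str) -> GeneModel:
    # Standard genePred: name chrom strand txStart txEnd cdsStart cdsEnd
    #                    exonCount exonStarts exonEnds [name2 ...]
    if len(cols) < 10:
        raise SequenceFormatError(f"{where}: genePred needs >= 10 columns")
    name, chrom, strand = cols[0], cols[1], cols[2]
    tx_start, tx_end = int(cols[3]), int(cols[4])
    cds_start, cds_end = int(cols[5]), int(cols[6])
    n_exons = int(cols[7])
    starts = [int(x) for x in cols[8].rstrip(",").split(",") if x]
    ends = [int(x) for x in cols[9].rstrip(",").split(",") if x]
    if len(starts) != n_exons or len(ends) != n_exons:
        raise SequenceFormatError(
            f"{where}: exonCount {n_exons} does not match exon lists "
            f"({len(starts)} starts, {len(ends)} ends)"
        )
    gene = cols[10] if len(cols) > 10 and cols[10] else name
    coding = cds_start < cds_end
    return GeneModel(
        gene=gene, transcript=name, chrom=chrom, strand=strand,
        tx_start=tx_start, tx_end=tx_end,
        exons=tuple(zip(starts, ends)),
        cds_start=cds_start if coding else None,
        cds_end=cds_end if coding else None,
    )


def _parse_bed12(cols: list[str], where: str) -> GeneModel:
    if len(cols) < 12:
        raise SequenceFormatError(f"{where}: BED12 needs 12 columns")
    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
    name, strand = cols[3], cols[5]
    thick_start, thick_end = int(cols[6]), int(cols[7])
    n_blocks = int(cols[9])
    sizes = [int(x) for x in cols[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in cols[11].rstrip(",").split(",") if x]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise SequenceFormatError(
            f"{where}: blockCount {n_blocks} does not match block lists"
        )
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    coding = thick_start < thick_end  # thickStart == thickEnd marks non-coding
    return GeneModel(
        gene=name, transcript=name, chrom=chrom, strand=strand,
        tx_start=start, tx_end=end, exons=exons,
        cds_start=thick_start if coding else None,
        cds_end=thick_end if coding else None,
    )


def read_gene_models(path: str | Path, dialect: str = "genePred") -> list[GeneModel]:
    """Read transcript models from a genePred or BED12 file."""
    if dialect not in ("genePred", "BED12"):
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            where = f"{path}:{lineno}"
            out.append(_parse_genepred(cols, where) if dialect == "genePred"
                       else _parse_bed12(cols, where))
    return out


def write_gene_models(models: Sequence[GeneModel], path: str | Path,
                      header: str | None = None) -> None:
    """Write genePred (11 columns, with the gene symbol in name2)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.tx_start, m.tx_end,
                                               m.transcript)):
            cds_s = m.cds_start if m.is_coding else m.tx_end
            cds_e = m.cds_end if m.is_coding else m.tx_end
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write("\t".join([
                m.transcript, m.chrom, m.strand, str(m.tx_start), str(m.tx_end),
                str(cds_s), str(cds_e), str(len(m.exons)), starts, ends, m.gene,
            ]) + "\n")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    species, _, chrom = src.partition(".")
    return species, chrom


def read_maf(path: str | Path, reference: str | None = None
             ) -> list[AlignmentBlock]:
    """Read MAF alignment blocks.

    The reference row is the first 's' row of each block unless ``reference``
    names a species present in the block. Reference rows on the '-' source
    strand are flipped to '+' coordinates (sequence reverse-complemented in
    every row so columns keep correspondence).
    """
    path = Path(path)
    blocks: list[AlignmentBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in aln:
            species, chrom = _split_src(rec.id)
            ann = rec.annotations
            rows.append(AlignmentRow(
                species=species, chrom=chrom,
                start=int(ann["start"]), size=int(ann["size"]),
                strand="+" if int(ann["strand"]) == 1 else "-",
                src_size=int(ann["srcSize"]),
                text=str(rec.seq).upper(),
            ))
        if not rows:
            continue
        ref_idx = 0
        if reference is not None:
            idx = [i for i, r in enumerate(rows) if r.species == reference]
            if idx:
                ref_idx = idx[0]
        ref = rows[ref_idx]
        if ref.strand == "-":
            # flip whole block so reference coordinates are on '+'
            flipped = []
            for r in rows:
                flipped.append(AlignmentRow(
                    species=r.species, chrom=r.chrom,
                    start=(r.src_size - (r.start + r.size)),
                    size=r.size,
                    strand="+" if r.strand == "-" else "-",
                    src_size=r.src_size,
                    text=_rc_aligned(r.text),
                ))
            rows = flipped
        blocks.append(AlignmentBlock(rows=tuple(rows), reference_index=ref_idx))
    return blocks


def _rc_aligned(text: str) -> str:
    """Reverse complement aligned text, preserving gap characters."""
    comp = []
    for c in reversed(text):
        comp.append("-" if c == "-" else c.translate(_COMPLEMENT))
    return "".join(comp)


def write_maf(blocks: Sequence[AlignmentBlock], path: str | Path,
              header: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for b in blocks:
            fh.write("\na score=0.0\n")
            width = max(len(r.src) for r in b.rows)
            for r in b.rows:
                fh.write(
                    f"s {r.src:<{width}} {r.start} {r.size} {r.strand} "
                    f"{r.src_size} {r.text}\n"
                )
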