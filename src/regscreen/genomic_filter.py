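"""Candidate-element prioritization: conservation containment, coding
exclusion, gene proximity, scored-peak support, nearest-gene assignment.

The screen keeps a motif match when it is (1) fully contained — dimers
including the spacer — in an exact-identity conserved segment, (2) free of
any overlap with protein-coding (CDS) exon sequence, (3) within a gene's
transcript span or its 2.5-kb flanks, and (4) overlapped by every required
peak set at or above that set's score threshold (e.g. DNase peaks with
F-Seq score >= 0.08). Each filter returns an annotated subset of its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .motif_scan import DimerMatch, MonomerMatch
from .conservation import ConservedSegment
from .sequence_io import GeneModel, GenomicInterval, ScoredInterval

__all__ = [
    "GeneAssignment",
    "CandidateElement",
    "require_containment",
    "exclude_coding",
    "assign_genes",
    "intersect_peaks",
    "nearest_gene",
    "count_loci",
]

RELATIONS = ("intronic", "exonic-noncoding", "upstream-flank",
             "downstream-flank", "overlapping-span")


@dataclass(frozen=True)
class GeneAssignment:
    gene: str
    transcript: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class CandidateElement:
    """A motif match carrying its prioritization annotations."""

    match: MonomerMatch | DimerMatch
    conserved_segment: ConservedSegment | None = None
    noncoding: bool | None = None
    gene_assignments: tuple[GeneAssignment, ...] = ()
    peak_support: Mapping[str, float] = field(default_factory=dict)
    nearest: tuple[str, int] | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.match.chrom, self.match.start,
                               self.match.end, name=self.match.name,
                               strand=self.match.strand)

    @property
    def conserved(self) -> bool:
        return self.conserved_segment is not None

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({a.gene for a in self.gene_assignments}))


def _as_candidates(matches: Sequence) -> list[CandidateElement]:
    return [m if isinstance(m, CandidateElement) else CandidateElement(match=m)
            for m in matches]


def _tree_by_chrom(intervals: Sequence[GenomicInterval]
                   ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def require_containment(matches: Sequence, segments: Sequence[ConservedSegment]
                        ) -> list[CandidateElement]:
    """Keep matches fully contained in a conserved segment; link it.

    Containment is strict subset-or-equal of the whole match interval —
    for dimers both monomers and the spacer must sit inside one segment.
    """
    trees = _tree_by_chrom(segments)
    out = []
    for cand in _as_candidates(matches):
        iv = cand.match
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = [segments[h.data] for h in tree.overlap(iv.start, iv.end)
                if h.begin <= iv.start and iv.end <= h.end]
        if hits:
            hits.sort(key=lambda s: (s.start, s.end))
            out.append(replace(cand, conserved_segment=hits[0]))
    return out


def _cds_exon_intervals(gene_models: Sequence[GeneModel]
                        ) -> list[GenomicInterval]:
    out = []
    for gm in gene_models:
        for s, e in gm.cds_exons():
            out.append(GenomicInterval(gm.chrom, s, e, name=gm.gene))
    return out


def exclude_coding(matches: Sequence, gene_models: Sequence[GeneModel]
                   ) -> list[CandidateElement]:
    """Drop matches overlapping >= 1 bp of any CDS exon.

    UTR exons and introns do not exclude: "non-coding" means free of
    protein-coding sequence, not intergenic.
    """
    trees = _tree_by_chrom(_cds_exon_intervals(gene_models))
    out = []
    for cand in _as_candidates(matches):
        iv = cand.match
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            continue
        out.append(replace(cand, noncoding=True))
    return out


def _relation(iv: GenomicInterval, gm: GeneModel) -> str | None:
    """Relation label for a match overlapping span +/- flank (or None)."""
    if iv.start < gm.tx_end and gm.tx_start < iv.end:
        # overlaps the transcript span
        if iv.start < gm.tx_start or iv.end > gm.tx_end:
            return "overlapping-span"
        if any(iv.start < e and s < iv.end for s, e in gm.exons):
            return "exonic-noncoding"
        return "intronic"
    left = iv.end <= gm.tx_start
    if left:
        return "upstream-flank" if gm.strand == "+" else "downstream-flank"
    return "downstream-flank" if gm.strand == "+" else "upstream-flank"


def assign_genes(matches: Sequence, gene_models: Sequence[GeneModel],
                 flank: int = 2500) -> list[CandidateElement]:
    """Assign matches to every transcript whose span +/- flank overlaps.

    Relations are strand-aware (upstream/downstream in transcript
    orientation). Matches with no assignment are removed.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    spans = [GenomicInterval(gm.chrom, max(0, gm.tx_start - flank),
                             gm.tx_end + flank) for gm in gene_models]
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(spans):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    out = []
    for cand in _as_candidates(matches):
        iv = cand.match
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        assigns = []
        for hit in sorted(tree.overlap(iv.start, iv.end),
                          key=lambda h: h.data):
            gm = gene_models[hit.data]
            rel = _relation(iv, gm)
            if rel is not None:
                assigns.append(GeneAssignment(gm.gene, gm.transcript, rel))
        if assigns:
            out.append(replace(cand, gene_assignments=tuple(assigns)))
    return out


def intersect_peaks(matches: Sequence,
                    peak_sets: Mapping[str, Sequence[ScoredInterval]],
                    min_scores: Mapping[str, float] | None = None
                    ) -> list[CandidateElement]:
    """Keep matches supported by every peak set (>= 1 bp overlap, score
    at or above that set's threshold); record the best supporting score."""
    min_scores = dict(min_scores or {})
    unknown = set(min_scores) - set(peak_sets)
    if unknown:
        raise ValueError(f"unknown peak set(s) in thresholds: {sorted(unknown)}")
    set_trees = {name: _tree_by_chrom(peaks)
                 for name, peaks in peak_sets.items()}
    out = []
    for cand in _as_candidates(matches):
        iv = cand.match
        support: dict[str, float] = {}
        for name, trees in set_trees.items():
            threshold = min_scores.get(name, 0.0)
            tree = trees.get(iv.chrom)
            if tree is None:
                break
            best = None
            for hit in tree.overlap(iv.start, iv.end):
                score = peak_sets[name][hit.data].score
                if score >= threshold and (best is None or score > best):
                    best = score
            if best is None:
                break
            support[name] = best
        else:
            out.append(replace(cand, peak_support=support))
    return out


def nearest_gene(match: GenomicInterval, gene_models: Sequence[GeneModel]
                 ) -> tuple[str, int]:
    """Closest transcript span on the match's chromosome.

    Distance 0 when overlapping; otherwise the minimal gap, negative when
    the match lies 5' of the transcript in transcript orientation. Ties
    break by smaller |distance|, then alphabetical gene symbol.
    """
    on_chrom = [gm for gm in gene_models if gm.chrom == match.chrom]
    if not on_chrom:
        raise ValueError(f"no gene models on chromosome {match.chrom!r}")
    best: tuple[int, str, int] | None = None  # (|dist|, symbol, signed)
    for gm in on_chrom:
        if match.start < gm.tx_end and gm.tx_start < match.end:
            signed = 0
        elif match.end <= gm.tx_start:
            gap = gm.tx_start - match.end
            signed = -gap if gm.strand == "+" else gap
        else:
            gap = match.start - gm.tx_end
            signed = gap if gm.strand == "+" else -gap
        key = (abs(signed), gm.gene, signed)
        if best is None or key < best:
            best = key
    return best[1], best[2]


def count_loci(candidates: Sequence[CandidateElement]) -> tuple[int, int]:
    """(number of segments, number of distinct genes) — the funnel counts."""
    genes: set[str] = set()
    for cand in candidates:
        if cand.gene_assignments:
            genes.update(a.gene for a in cand.gene_assignments)
        elif cand.nearest is not None:
            genes.add(cand.nearest[0])
    return len(candidates), len(genes)
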