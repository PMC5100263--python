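"""Spacer (intervening-sequence) composition statistics for dimeric sites.

Dimeric SOX10-type sites sandwich a 5-10 bp spacer between the two
head-to-head monomers. Experimentally, spacer composition discriminates
active sites from inactive ones: the validated, consensus-required dimers
have GC-rich spacers (~61% pooled GC) of 5-8 bp, against ~35% GC in the
total predicted population. This module computes those descriptive
statistics: per-spacer GC, pooled (concatenated-bases) GC, per-site mean
GC, length summaries, and two-group comparisons.

``VALIDATED_SITE_SEQUENCES`` carries the consensus-bearing strings of the
luciferase-validated response elements (human loci PAX7/SOX6/SOX5/TCF7L2/
BCAS3/NFIB and rat loci Notch1/Hmga2/Hes1/Mycn/Id4/Id2) for use as scanner
fixtures; ``ACTIVE_REQUIRED_SPACERS`` is the seven-element spacer set of
the dimers that were both active and required for activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Mapping, Sequence

__all__ = [
    "VALIDATED_SITE_SEQUENCES",
    "GLIAL_REPRESSOR_SITE_SEQUENCES",
    "ACTIVE_REQUIRED_SPACERS",
    "SpacerGroup",
    "gc_content",
    "summarize_group",
    "compare_groups",
]

# Consensus-bearing sequences of validated human response elements
# (element id -> plus-strand sequence: forward monomer, spacer, reverse monomer)
VALIDATED_SITE_SEQUENCES: dict[str, str] = {
    "SOX10-CCS-01": "ACAAACTCATTAAACTTGT",   # PAX7
    "SOX10-CCS-13": "ACAATCAAGCATTGT",       # SOX6
    "SOX10-CCS-18": "ACAAAAATGTATTGT",       # SOX5
    "SOX10-CCS-19": "ACACAGAACATTATTGT",     # SOX5
    "SOX10-CCS-39": "ACAATCCCCAAGATTTTTGT",  # TCF7L2
    "SOX10-CCS-43": "ACACATTAATAACGTTTTGT",  # BCAS3
    "SOX10-CCS-51": "ACAATCTGTTCTTTGTGT",    # NFIB
}

# Consensus-bearing sequences at the six glial-differentiation-repressor
# loci (rat). Mycn-R1 carries a monomer plus a degenerate dimeric site whose
# second element (TTTCT) is outside the strict grammar; Id4-R1's dimer has a
# 20-bp spacer, beyond the scanner's 5-10 bp window.
GLIAL_REPRESSOR_SITE_SEQUENCES: dict[str, str] = {
    "Notch1-R1": "ACAATGGGGCCTCTGT",
    "Notch1-R2": "ACAATCGGCTTTGT",               # spacer 4: below the 5-bp floor
    "Hmga2-R2": "ACACAGGCCCCTCTTTGT",
    "Hes1-R1": "TGTGTGAGCGCCATGTGT",
    "Mycn-R1": "ACAATGGCCTCTTTCTACAGACAAT",
    "Id4-R1": "ACAAAAACAGCAGTAAATGGAGGCCTTTGT",  # 20-bp spacer
    "Id2-R1": "ACAAGAAACACATTGT",
}

# Spacers of the seven dimeric sites that were both active in reporter
# assays and required the consensus for that activity (spacer 5-8 bp).
ACTIVE_REQUIRED_SPACERS: dict[str, str] = {
    "SOX10-CCS-13": "CAAGC",
    "SOX10-CCS-19": "GAACATT",
    "SOX10-CCS-51": "CTGTTCTT",
    "Notch1-R1": "GGGGCC",
    "Hmga2-R2": "GGCCCCTC",
    "Mycn-R1": "GGCCTC",
    "Id2-R1": "AAACAC",
}


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T) of a nucleotide string; N is excluded entirely."""
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide character {sorted(bad)[0]!r}")
    seq = sequence.upper()
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("empty or all-N sequence has no defined GC content")
    return (seq.count("G") + seq.count("C")) / denom


@dataclass(frozen=True)
class SpacerGroup:
    """Descriptive statistics over a group of spacer sequences."""

    label: str
    spacers: tuple[str, ...]
    lengths: tuple[int, ...]
    min_length: int
    max_length: int
    mean_length: float
    pooled_gc: float        # (total G+C) / (total non-N bases), canonical
    per_site_gc: tuple[float, ...]
    mean_site_gc: float     # unweighted mean of per-spacer GC

    @property
    def n(self) -> int:
        return len(self.spacers)


def summarize_group(spacers: Sequence[str], label: str = "") -> SpacerGroup:
    """Lengths, pooled GC and per-site GC of a spacer group.

    Pooled GC treats the group as one concatenated sequence (the canonical
    group GC here); the unweighted per-site mean is reported alongside.
    """
    if not spacers:
        raise ValueError("spacer group must be non-empty")
    spacers = tuple(s.upper() for s in spacers)
    lengths = tuple(len(s) for s in spacers)
    if min(lengths) < 1:
        raise ValueError("spacers must be non-empty strings")
    per_site = tuple(gc_content(s) for s in spacers)
    pooled = gc_content("".join(spacers))
    return SpacerGroup(
        label=label, spacers=spacers, lengths=lengths,
        min_length=min(lengths), max_length=max(lengths),
        mean_length=fmean(lengths),
        pooled_gc=pooled, per_site_gc=per_site,
        mean_site_gc=fmean(per_site),
    )


@dataclass(frozen=True)
class GroupComparison:
    group_a: SpacerGroup
    group_b: SpacerGroup
    delta_pooled_gc: float   # b - a
    delta_mean_length: float  # b - a


def compare_groups(group_all: SpacerGroup, group_active: SpacerGroup
                   ) -> GroupComparison:
    """Descriptive comparison (no inferential test) of two spacer groups,
    e.g. the total dimer population against the active, consensus-required
    subset."""
    return GroupComparison(
        group_a=group_all, group_b=group_active,
        delta_pooled_gc=group_active.pooled_gc - group_all.pooled_gc,
        delta_mean_length=group_active.mean_length - group_all.mean_length,
    )


def rank_sum_length_test(group_a: SpacerGroup, group_b: SpacerGroup) -> float:
    """Two-sided Mann-Whitney U p-value on spacer lengths.

    An optional inferential extension; the canonical comparison is the
    descriptive :func:`compare_groups`.
    """
    from scipy import stats

    return float(stats.mannwhitneyu(group_a.lengths, group_b.lengths,
                                    alternative="two-sided").pvalue)
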