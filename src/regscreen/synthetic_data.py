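"""Seeded generators for every input the screen consumes, with truth records.

The simulator emulates the study conditions end to end on a reduced scale:
an i.i.d. background chromosome with human-like AT-rich base composition,
planted monomer/dimer consensus sites in chosen genomic compartments,
a gapless 3-species alignment whose declared conserved blocks copy the
reference exactly while all other columns diverge, transcript models with
exon/intron/CDS/flank structure, scored peak sets covering chosen truth
sites, and an annotation universe with one planted enriched category.

Every generator is bit-reproducible from ``(seed, config)``; the seed and a
config digest are recorded in file headers (where the format permits
comments) and in ``manifest.json``.

Determinism layout: each generator derives its own numpy stream from
``(seed, stream-id)``, so generators are reproducible independently of the
order in which they are called.

The alignment generator guarantees that *only* declared blocks are
conserved: background mutations that would create an exact-identity run of
``min_protected_length`` across all species are broken by forcing a
mismatch, and the columns flanking each declared block are forced to
mismatch so reported segments never extend past the truth coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .conservation import ConservedSegment, SpeciesSet
from .enrichment import AnnotationSet
from .sequence_io import (AlignmentBlock, AlignmentRow, GeneModel,
                          GenomeSequence, GenomicInterval, ScoredInterval,
                          write_bed, write_fasta, write_gene_models, write_maf)

__all__ = [
    "PlantSpec", "GeneSpec", "AlignmentSpec", "PeakSpec", "AnnotationSpec",
    "SimulationConfig", "TruthRecord",
    "plan_gene_models", "plan_placements",
    "simulate_genome", "simulate_alignment", "simulate_gene_models",
    "simulate_peaks", "simulate_annotation", "simulate_bundle",
    "expected_monomer_count", "expected_dimer_count",
]

BASES = np.array(list("ACGT"))

Compartment = Literal["intronic", "upstream-flank", "downstream-flank",
                      "cds", "intergenic"]


@dataclass(frozen=True)
class PlantSpec:
    """One family of planted sites."""

    kind: Literal["monomer", "dimer"] = "dimer"
    count: int = 5
    compartment: Compartment = "intronic"
    conserved: bool = True
    dnase: bool = True
    chip: bool = True
    spacer_length: int = 6
    spacer_gc: float = 0.6


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int = 5
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 3000
    flank: int = 2500
    intergenic_gap: int = 4000


@dataclass(frozen=True)
class AlignmentSpec:
    species: tuple[str, ...] = ("hg18", "mm9", "galGal3")
    reference: str = "hg18"
    divergence: float = 0.4          # per-base mutation probability, non-ref species
    conserved_pad: int = 8           # bp of declared conservation around a site
    min_protected_length: int = 5    # no accidental identity run >= this
    block_length: int = 10_000       # nominal MAF block tiling


@dataclass(frozen=True)
class PeakSpec:
    halfwidth: int = 150
    dnase_score_range: tuple[float, float] = (0.08, 1.0)
    chip_score_range: tuple[float, float] = (0.5, 1.0)
    decoy_score_range: tuple[float, float] = (0.005, 0.079)
    n_random_decoys: int = 10


@dataclass(frozen=True)
class AnnotationSpec:
    universe_size: int = 20_000
    n_categories: int = 50
    category_size: int = 50
    planted_category: str = "planted:glial-differentiation"
    planted_overlap: int = 10        # designated-list genes inside the category
    list_size: int = 191


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom: str = "chrSim"
    genome_length: int = 100_000
    # AT-rich human-like composition (A, C, G, T)
    base_probs: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    plants: tuple[PlantSpec, ...] = (
        PlantSpec(kind="dimer", count=5, compartment="intronic"),
        PlantSpec(kind="dimer", count=3, compartment="upstream-flank"),
        PlantSpec(kind="dimer", count=2, compartment="intergenic",
                  dnase=False, chip=False),
        PlantSpec(kind="dimer", count=2, compartment="cds"),
        PlantSpec(kind="dimer", count=2, compartment="intronic",
                  conserved=False),
        PlantSpec(kind="monomer", count=4, compartment="intronic"),
    )
    genes: GeneSpec = GeneSpec()
    alignment: AlignmentSpec = AlignmentSpec()
    peaks: PeakSpec = PeakSpec()
    annotation: AnnotationSpec = AnnotationSpec()

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base probabilities must sum to 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"regscreen simulate seed={self.seed} config={self.digest()}"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted site; flags are true by construction."""

    site_id: str
    interval: GenomicInterval
    kind: str
    spacer: str
    conserved: bool
    noncoding: bool
    gene_proximal: bool
    dnase: bool
    chip: bool
    gene: str          # assigned gene symbol, "" for intergenic

    @property
    def fully_supported(self) -> bool:
        """Passes every stage of the screen."""
        return (self.kind == "dimer" and self.conserved and self.noncoding
                and self.gene_proximal and self.dnase and self.chip)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Deterministic layout: gene models and site placements
# ---------------------------------------------------------------------------

def plan_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Deterministic transcript layout: alternating strands, CDS from the
    middle of the first exon to the middle of the last (UTR stubs remain)."""
    g = config.genes
    span = g.exons_per_gene * g.exon_length + (g.exons_per_gene - 1) * g.intron_length
    territory = 2 * g.flank + span + g.intergenic_gap
    models = []
    for i in range(g.n_genes):
        tx_start = g.flank + g.intergenic_gap // 2 + i * territory
        tx_end = tx_start + span
        if tx_end + g.flank > config.genome_length:
            raise ValueError(
                f"gene layout exceeds genome length ({g.n_genes} genes need "
                f"{g.n_genes * territory + g.flank} bp, have {config.genome_length})"
            )
        exons = tuple(
            (tx_start + j * (g.exon_length + g.intron_length),
             tx_start + j * (g.exon_length + g.intron_length) + g.exon_length)
            for j in range(g.exons_per_gene)
        )
        cds_start = exons[0][0] + g.exon_length // 2
        cds_end = exons[-1][0] + g.exon_length // 2
        models.append(GeneModel(
            gene=f"SIMG{i + 1:03d}", transcript=f"SIMT{i + 1:03d}",
            chrom=config.chrom, strand="+" if i % 2 == 0 else "-",
            tx_start=tx_start, tx_end=tx_end, exons=exons,
            cds_start=cds_start, cds_end=cds_end,
        ))
    return models


def _compartment_window(gm: GeneModel, compartment: Compartment,
                        flank: int) -> tuple[int, int]:
    if compartment == "intronic":
        s, e = gm.exons[0][1], gm.exons[1][0]     # first intron
        return s + 20, e - 20
    if compartment == "cds":
        # inside a fully-coding exon (middle exon)
        s, e = gm.exons[len(gm.exons) // 2]
        return s + 5, e - 5
    upstream = (compartment == "upstream-flank")
    left = upstream if gm.strand == "+" else not upstream
    if left:
        return gm.tx_start - flank + 20, gm.tx_start - 20
    return gm.tx_end + 20, gm.tx_end + flank - 20


def plan_placements(config: SimulationConfig, models: Sequence[GeneModel]
                    ) -> list[tuple[PlantSpec, int, GeneModel | None, int]]:
    """Assign each planted site a start coordinate.

    Returns (spec, site-index-within-spec, host gene or None, start).
    Placement is deterministic: sites cycle over host genes and are laid
    out left-to-right inside each compartment window with fixed stride.
    """
    g = config.genes
    placements = []
    occupied: list[tuple[int, int]] = []
    # per (gene, compartment) cursor so multiple sites in one window stack
    cursors: dict[tuple[str, str], int] = {}
    intergenic_cursor = 50
    for spec in config.plants:
        site_len = (10 + spec.spacer_length) if spec.kind == "dimer" else 5
        for j in range(spec.count):
            if spec.compartment == "intergenic":
                start = intergenic_cursor
                intergenic_cursor += site_len + 200
                gm = None
                if start + site_len > config.genome_length:
                    raise ValueError("intergenic sites exceed genome capacity")
            else:
                gm = models[len(placements) % len(models)]
                key = (gm.transcript, spec.compartment)
                lo, hi = _compartment_window(gm, spec.compartment, g.flank)
                cur = cursors.get(key, lo)
                start = cur
                cursors[key] = cur + site_len + 40
                if start + site_len > hi:
                    raise ValueError(
                        f"compartment {spec.compartment} of {gm.transcript} "
                        "cannot hold all requested sites"
                    )
            for s, e in occupied:
                if start < e and s < start + site_len:
                    raise ValueError("planted sites overlap; adjust config")
            occupied.append((start, start + site_len))
            placements.append((spec, j, gm, start))
    return placements


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_FORWARD_CONCRETE = ("ACACA", "ACAAG", "ACAAT", "ACAAA")
_REVERSE_CONCRETE = ("TGTGT", "CTTGT", "ATTGT", "TTTGT")


def _spacer_with_gc(length: int, gc: float, rng: np.random.Generator) -> str:
    n_gc = int(round(gc * length))
    chars = ([rng.choice(["G", "C"]) for _ in range(n_gc)]
             + [rng.choice(["A", "T"]) for _ in range(length - n_gc)])
    rng.shuffle(chars)
    return "".join(chars)


def _site_sequence(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, str]:
    """(site text, spacer) for one planted site."""
    fwd = _FORWARD_CONCRETE[rng.integers(len(_FORWARD_CONCRETE))]
    if spec.kind == "monomer":
        return fwd, ""
    rev = _REVERSE_CONCRETE[rng.integers(len(_REVERSE_CONCRETE))]
    spacer = _spacer_with_gc(spec.spacer_length, spec.spacer_gc, rng)
    return fwd + spacer + rev, spacer


def simulate_genome(config: SimulationConfig
                    ) -> tuple[GenomeSequence, list[TruthRecord]]:
    """I.i.d. background with planted sites overwritten at truth coordinates."""
    rng = _rng(config, 1)
    models = plan_gene_models(config)
    placements = plan_placements(config, models)
    arr = rng.choice(BASES, size=config.genome_length,
                     p=np.asarray(config.base_probs))
    pad = config.alignment.conserved_pad
    truth = []
    for spec, j, gm, start in placements:
        text, spacer = _site_sequence(spec, rng)
        arr[start:start + len(text)] = list(text)
        if spec.conserved:
            # inert padding (no A or T, hence no consensus submotif) so the
            # planted site is the only match its conserved window contains
            arr[max(0, start - pad):start] = "C"
            arr[start + len(text):
                min(config.genome_length, start + len(text) + pad)] = "C"
        site_id = f"{spec.kind}-{spec.compartment}-{len(truth) + 1:03d}"
        truth.append(TruthRecord(
            site_id=site_id,
            interval=GenomicInterval(config.chrom, start, start + len(text),
                                     name=site_id,
                                     strand="+" if spec.kind == "dimer" else "+"),
            kind=spec.kind, spacer=spacer,
            conserved=spec.conserved,
            noncoding=(spec.compartment != "cds"),
            gene_proximal=(spec.compartment != "intergenic"),
            dnase=spec.dnase, chip=spec.chip,
            gene=gm.gene if gm is not None else "",
        ))
    return GenomeSequence(config.chrom, "".join(arr)), truth


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _conserved_windows(config: SimulationConfig, truth: Sequence[TruthRecord]
                       ) -> list[tuple[int, int]]:
    pad = config.alignment.conserved_pad
    wins = []
    for t in truth:
        if t.conserved:
            lo = max(0, t.interval.start - pad)
            hi = min(config.genome_length, t.interval.end + pad)
            wins.append((lo, hi))
    wins.sort()
    return wins


def simulate_alignment(genome: GenomeSequence, config: SimulationConfig,
                       truth: Sequence[TruthRecord]
                       ) -> tuple[list[AlignmentBlock], list[ConservedSegment]]:
    """Gapless 3-species alignment; exactly the declared windows are
    identity runs >= the protected length."""
    a = config.alignment
    if not (0.0 < a.divergence < 1.0):
        raise ValueError("divergence must be in (0, 1)")
    rng = _rng(config, 2)
    L = genome.length
    ref = np.array(list(genome.residues))
    wins = _conserved_windows(config, truth)
    conserved_mask = np.zeros(L, dtype=bool)
    for lo, hi in wins:
        conserved_mask[lo:hi] = True

    non_ref = [sp for sp in a.species if sp != a.reference]
    seqs = {a.reference: ref}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for sp in non_ref:
        seq = ref.copy()
        mutate = (~conserved_mask) & (rng.random(L) < a.divergence)
        offs = rng.integers(1, 4, size=int(mutate.sum()))
        pos = np.flatnonzero(mutate)
        orig = np.array([base_idx[b] for b in seq[pos]])
        seq[pos] = BASES[(orig + offs) % 4]
        seqs[sp] = seq

    def force_mismatch(pos: int) -> None:
        # set the first non-reference species to a base that differs from
        # the reference, so the column can never count as identical
        sp = non_ref[0]
        seqs[sp][pos] = BASES[(base_idx[ref[pos]] + 1) % 4]

    # columns flanking each declared window must differ so reported
    # segments cannot extend past the truth coordinates
    for lo, hi in wins:
        if lo - 1 >= 0 and not conserved_mask[lo - 1]:
            force_mismatch(lo - 1)
        if hi < L and not conserved_mask[hi]:
            force_mismatch(hi)

    # break accidental background identity runs of >= min_protected_length
    k = a.min_protected_length
    identical = np.ones(L, dtype=bool)
    for sp in non_ref:
        identical &= (seqs[sp] == ref)
    identical &= ~conserved_mask
    run = 0
    for i in range(L):
        if identical[i] and not conserved_mask[i]:
            run += 1
            if run == k:
                force_mismatch(i)
                identical[i] = False
                run = 0
        else:
            run = 0

    # tile into MAF blocks, boundaries shifted off conserved windows
    blocks = []
    boundaries = [0]
    pos = a.block_length
    while pos < L:
        for lo, hi in wins:
            if lo < pos < hi:
                pos = hi
                break
        boundaries.append(min(pos, L))
        pos += a.block_length
    boundaries.append(L)
    boundaries = sorted(set(boundaries))
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        rows = []
        for sp in a.species:
            rows.append(AlignmentRow(
                species=sp, chrom=config.chrom, start=s, size=e - s,
                strand="+", src_size=L, text="".join(seqs[sp][s:e]),
            ))
        ref_idx = a.species.index(a.reference)
        blocks.append(AlignmentBlock(rows=tuple(rows), reference_index=ref_idx))

    species_set = SpeciesSet(species=a.species, reference=a.reference)
    segments = [ConservedSegment(config.chrom, lo, hi,
                                 name="exact:" + ",".join(a.species),
                                 species=species_set)
                for lo, hi in wins]
    return blocks, segments


# ---------------------------------------------------------------------------
# Gene models, peaks, annotation
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimulationConfig
                         ) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """Transcript models plus the CDS-exon BED intervals they imply."""
    models = plan_gene_models(config)
    cds = [GenomicInterval(gm.chrom, s, e, name=gm.gene)
           for gm in models for s, e in gm.cds_exons()]
    return models, cds


def simulate_peaks(config: SimulationConfig, truth: Sequence[TruthRecord]
                   ) -> dict[str, list[ScoredInterval]]:
    """Scored DNase/ChIP peaks covering the flagged truth sites.

    Truth sites not flagged for a set get a sub-threshold decoy peak, and
    random intergenic decoys are added, so peak *presence* alone never
    reproduces the truth — the score threshold and the other filters must
    do their work.
    """
    p = config.peaks
    rng = _rng(config, 3)
    out: dict[str, list[ScoredInterval]] = {"dnase": [], "chip": []}
    for t in truth:
        lo = max(0, t.interval.start - p.halfwidth)
        hi = min(config.genome_length, t.interval.end + p.halfwidth)
        if t.dnase:
            score = rng.uniform(*p.dnase_score_range)
        else:
            # sub-threshold decoy: exercises the score cutoff, not presence
            score = rng.uniform(*p.decoy_score_range)
        out["dnase"].append(ScoredInterval(
            config.chrom, lo, hi, name=f"dnase:{t.site_id}",
            score=round(float(score), 4)))
        if t.chip:
            out["chip"].append(ScoredInterval(
                config.chrom, lo, hi, name=f"chip:{t.site_id}",
                score=round(float(rng.uniform(*p.chip_score_range)), 4)))
    # random intergenic decoys, kept clear of every truth neighbourhood
    forbidden = [(max(0, t.interval.start - p.halfwidth - 400),
                  t.interval.end + p.halfwidth + 400) for t in truth]
    placed = 0
    while placed < p.n_random_decoys:
        start = int(rng.integers(0, config.genome_length - 400))
        if any(lo < start + 400 and start < hi for lo, hi in forbidden):
            continue
        for set_name, rng_range in (("dnase", p.dnase_score_range),
                                    ("chip", p.chip_score_range)):
            out[set_name].append(ScoredInterval(
                config.chrom, start, start + 400,
                name=f"{set_name}:decoy{placed + 1}",
                score=round(float(rng.uniform(*rng_range)), 4)))
        placed += 1
    return out


def simulate_annotation(config: SimulationConfig,
                        gene_list: Sequence[str] | None = None
                        ) -> tuple[AnnotationSet, list[str]]:
    """Annotation universe with one planted enriched category.

    The designated gene list (default: synthetic symbols topped up to the
    configured list size) shares ``planted_overlap`` genes with the planted
    category; all other categories are uniform draws from the universe.
    """
    spec = config.annotation
    rng = _rng(config, 4)
    universe = [f"UNIV{i + 1:05d}" for i in range(spec.universe_size)]
    if gene_list is None:
        gene_list = []
    gene_list = list(dict.fromkeys(gene_list))
    # ensure list genes are in the universe, then top up with universe genes
    universe_set = set(universe)
    for g in gene_list:
        if g not in universe_set:
            universe.append(g)
            universe_set.add(g)
    filler = [g for g in universe if g not in set(gene_list)]
    need = spec.list_size - len(gene_list)
    if need > 0:
        extra = rng.choice(np.array(filler), size=need, replace=False)
        gene_list = gene_list + [str(g) for g in extra]
    list_set = set(gene_list)

    categories: dict[str, frozenset[str]] = {}
    in_list = [g for g in gene_list]
    out_list = [g for g in universe if g not in list_set]
    planted = (list(rng.choice(np.array(in_list),
                               size=min(spec.planted_overlap, len(in_list)),
                               replace=False))
               + list(rng.choice(np.array(out_list),
                                 size=spec.category_size - spec.planted_overlap,
                                 replace=False)))
    categories[spec.planted_category] = frozenset(str(g) for g in planted)
    uni_arr = np.array(universe)
    for i in range(spec.n_categories - 1):
        members = rng.choice(uni_arr, size=spec.category_size, replace=False)
        categories[f"category{i + 1:03d}"] = frozenset(str(g) for g in members)
    return (AnnotationSet(universe=frozenset(universe), categories=categories),
            list(gene_list))


# ---------------------------------------------------------------------------
# Analytic oracles for the scan magnitudes
# ---------------------------------------------------------------------------

def _pattern_probability(pattern: str, base_probs: Sequence[float]) -> float:
    from .motif_scan import IUPAC_CLASSES

    p = dict(zip("ACGT", base_probs))
    prob = 1.0
    for sym in pattern:
        prob *= sum(p[b] for b in IUPAC_CLASSES[sym])
    return prob


def expected_monomer_count(length: int, base_probs: Sequence[float],
                           patterns: Sequence[str] = ("ACACA", "ACAAD"),
                           both_strands: bool = True) -> tuple[float, float]:
    """(expectation, std dev) of the monomer count on an i.i.d. genome.

    Per-position match probability summed over patterns (and both strands);
    the variance is approximated as binomial over start positions.
    """
    p_match = sum(_pattern_probability(pat, base_probs) for pat in patterns)
    if both_strands:
        from .motif_scan import reverse_complement_pattern

        p_match += sum(_pattern_probability(reverse_complement_pattern(pat),
                                            base_probs) for pat in patterns)
    n_pos = max(0, length - 4)
    mean = n_pos * p_match
    sd = float(np.sqrt(n_pos * p_match * (1 - p_match)))
    return mean, sd


def expected_dimer_count(length: int, base_probs: Sequence[float],
                         patterns: Sequence[str] = ("ACACA", "ACAAD"),
                         spacer_min: int = 5, spacer_max: int = 10
                         ) -> tuple[float, float]:
    """(expectation, std dev) of the plus-strand dimer count: for each
    start and spacer length, forward and reverse patterns must co-occur."""
    from .motif_scan import reverse_complement_pattern

    p_f = sum(_pattern_probability(pat, base_probs) for pat in patterns)
    p_r = sum(_pattern_probability(reverse_complement_pattern(pat), base_probs)
              for pat in patterns)
    n_spacers = spacer_max - spacer_min + 1
    p_pair = p_f * p_r
    n_pos = max(0, length - (10 + spacer_max)) * n_spacers
    mean = n_pos * p_pair
    sd = float(np.sqrt(n_pos * p_pair * (1 - p_pair)))
    return mean, sd


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, outdir: str | Path
                    ) -> dict[str, object]:
    """Generate and write every pipeline input; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()

    genome, truth = simulate_genome(config)
    blocks, segments = simulate_alignment(genome, config, truth)
    models, cds = simulate_gene_models(config)
    peaks = simulate_peaks(config, truth)
    screen_genes = sorted({t.gene for t in truth if t.fully_supported and t.gene})
    annotation, gene_list = simulate_annotation(config, screen_genes)

    write_fasta([genome], outdir / "genome.fa")
    write_maf(blocks, outdir / "alignment.maf", header=header)
    write_gene_models(models, outdir / "genes.genePred", header=header)
    write_bed(cds, outdir / "cds.bed", header=header)
    write_bed(peaks["dnase"], outdir / "dnase.bed", header=header)
    write_bed(peaks["chip"], outdir / "chip.bed", header=header)
    write_bed([t.interval for t in truth], outdir / "truth.bed", header=header)
    write_bed(segments, outdir / "truth_segments.bed", header=header)
    with open(outdir / "annotation.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        for cid, members in annotation.categories.items():
            for g in sorted(members):
                fh.write(f"{g}\t{cid}\n")
    with open(outdir / "universe.txt", "w") as fh:
        fh.write(f"# {header}\n")
        for g in sorted(annotation.universe):
            fh.write(g + "\n")
    with open(outdir / "gene_list.txt", "w") as fh:
        fh.write(f"# {header}\n")
        for g in gene_list:
            fh.write(g + "\n")

    # ready-to-run pipeline configuration over this bundle
    screen_yaml = "\n".join([
        f"# {header}",
        f"genome_fasta: {outdir / 'genome.fa'}",
        f"maf: {outdir / 'alignment.maf'}",
        f"gene_models: {outdir / 'genes.genePred'}",
        f"outdir: {outdir / 'out'}",
        "peak_sets:",
        f"  - {{name: dnase, path: {outdir / 'dnase.bed'}, min_score: 0.08}}",
        f"  - {{name: chip, path: {outdir / 'chip.bed'}, min_score: 0.0}}",
        f"annotation_tsv: {outdir / 'annotation.tsv'}",
        f"universe_list: {outdir / 'universe.txt'}",
        f"gene_list: {outdir / 'gene_list.txt'}",
        "log_level: WARNING",
    ]) + "\n"
    (outdir / "screen.yaml").write_text(screen_yaml)

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "genome_length": config.genome_length,
        "n_truth_sites": len(truth),
        "n_fully_supported": sum(t.fully_supported for t in truth),
        "n_conserved_segments": len(segments),
        "truth": [
            {"site_id": t.site_id, "chrom": t.interval.chrom,
             "start": t.interval.start, "end": t.interval.end,
             "kind": t.kind, "spacer": t.spacer,
             "conserved": t.conserved, "noncoding": t.noncoding,
             "gene_proximal": t.gene_proximal,
             "dnase": t.dnase, "chip": t.chip, "gene": t.gene}
            for t in truth
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
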