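"""End-to-end screen: scan → conserve → prioritize → enrich → spacer stats.

``run_screen`` chains the stages on file inputs, logs row-count telemetry at
every filter (the screen's funnel), and writes a report bundle: candidate
BED, a per-candidate TSV report, enrichment and spacer-statistics TSVs, and
a JSON manifest recording parameters, output digests and stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import enrichment as enr
from . import genomic_filter as gf
from . import spacer_stats as sps
from .conservation import SpeciesSet, extract_identical_segments, merge_segments
from .motif_scan import DimerMatch, MotifGrammar, scan_dimers, scan_monomers
from .sequence_io import (GenomicInterval, read_bed, read_fasta,
                          read_gene_models, read_maf, write_bed)

__all__ = ["PipelineConfig", "PipelineError", "run_screen"]

logger = logging.getLogger("regscreen")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class PeakSetConfig:
    name: str
    path: str
    min_score: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    genome_fasta: str
    maf: str
    gene_models: str
    outdir: str
    gene_dialect: str = "genePred"
    peak_sets: tuple[PeakSetConfig, ...] = ()
    annotation_tsv: str | None = None
    universe_list: str | None = None
    gene_list: str | None = None
    species: tuple[str, ...] = ("hg18", "mm9", "galGal3")
    reference: str = "hg18"
    min_conserved_length: int = 5
    flank: int = 2500
    spacer_min: int = 5
    spacer_max: int = 10
    max_p: float = 0.05
    min_fold: float = 5.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "peak_sets" in raw:
            raw["peak_sets"] = tuple(
                PeakSetConfig(**p) for p in raw["peak_sets"])
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        return cls(**raw)

    def grammar(self) -> MotifGrammar:
        return MotifGrammar(spacer_min=self.spacer_min,
                            spacer_max=self.spacer_max)


def _require(path: str | None, stage: str) -> Path:
    if path is None:
        raise PipelineError(f"stage {stage}: required input not configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"stage {stage}: missing input file {p}")
    return p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_gene_file(path: Path) -> list[str]:
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def _read_annotation(path: Path) -> dict[str, set[str]]:
    cats: dict[str, set[str]] = {}
    for line in path.read_text().splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        gene, cat = line.split("\t")[:2]
        cats.setdefault(cat, set()).add(gene)
    return cats


def run_screen(config: PipelineConfig) -> dict[str, object]:
    """Run every stage; returns the manifest (also written to the outdir)."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    grammar = config.grammar()

    # --- stage: scan ------------------------------------------------------
    stage = "scan"
    genome_path = _require(config.genome_fasta, stage)
    try:
        genomes = read_fasta(genome_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {genome_path}: {exc}") from exc
    monomers, dimers = [], []
    for g in genomes:
        monomers.extend(scan_monomers(g, grammar, strand_mode="both"))
        dimers.extend(scan_dimers(g, grammar))
    counts["monomers"] = len(monomers)
    counts["dimers"] = len(dimers)
    logger.info("scan: %d monomers, %d dimers on %d sequence(s)",
                len(monomers), len(dimers), len(genomes))

    # --- stage: conserve --------------------------------------------------
    stage = "conserve"
    maf_path = _require(config.maf, stage)
    species = SpeciesSet(species=config.species, reference=config.reference)
    try:
        blocks = read_maf(maf_path, reference=config.reference)
        segments = merge_segments(extract_identical_segments(
            blocks, species, min_length=config.min_conserved_length))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {maf_path}: {exc}") from exc
    counts["conserved_segments"] = len(segments)
    logger.info("conserve: %d exact-identity segments >= %d bp",
                len(segments), config.min_conserved_length)

    # --- stage: prioritize ------------------------------------------------
    stage = "prioritize"
    genes_path = _require(config.gene_models, stage)
    try:
        models = read_gene_models(genes_path, dialect=config.gene_dialect)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {genes_path}: {exc}") from exc

    cands = gf.require_containment(dimers, segments)
    counts["conserved_dimers"] = len(cands)
    logger.info("prioritize: %d of %d dimers fully conserved",
                len(cands), len(dimers))
    cands = gf.exclude_coding(cands, models)
    counts["noncoding_dimers"] = len(cands)
    logger.info("prioritize: %d after coding exclusion", len(cands))
    cands = gf.assign_genes(cands, models, flank=config.flank)
    counts["gene_proximal_dimers"] = len(cands)
    logger.info("prioritize: %d within a transcript span +/- %d bp",
                len(cands), config.flank)

    peak_sets: dict[str, list] = {}
    min_scores: dict[str, float] = {}
    for ps in config.peak_sets:
        path = _require(ps.path, stage)
        try:
            peak_sets[ps.name] = read_bed(path, scored=True)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {path}: {exc}") from exc
        min_scores[ps.name] = ps.min_score
    if peak_sets:
        cands = gf.intersect_peaks(cands, peak_sets, min_scores)
        counts["peak_supported_dimers"] = len(cands)
        logger.info("prioritize: %d supported by all %d peak set(s)",
                    len(cands), len(peak_sets))

    for i, cand in enumerate(cands):
        cands[i] = gf_replace_nearest(cand, models)
    n_segments, n_genes = gf.count_loci(cands)
    counts["final_segments"] = n_segments
    counts["unique_genes"] = n_genes
    logger.info("prioritize: %d segments at %d unique genes",
                n_segments, n_genes)

    candidate_bed = outdir / "candidates.bed"
    write_bed([c.interval for c in cands], candidate_bed)
    report_tsv = outdir / "candidates.tsv"
    _write_report(cands, report_tsv)

    # --- stage: enrich ----------------------------------------------------
    enrich_tsv = None
    if config.annotation_tsv:
        stage = "enrich"
        ann_path = _require(config.annotation_tsv, stage)
        cats = _read_annotation(ann_path)
        if config.universe_list:
            universe = set(_read_gene_file(_require(config.universe_list, stage)))
        else:
            universe = set().union(*cats.values())
        annotation = enr.AnnotationSet(
            universe=frozenset(universe),
            categories={c: frozenset(g) for c, g in sorted(cats.items())})
        if config.gene_list:
            genes = _read_gene_file(_require(config.gene_list, stage))
        else:
            genes = sorted({g for c in cands for g in c.genes})
        if not genes:
            raise PipelineError("stage enrich: empty gene list")
        results = enr.overrepresentation(genes, annotation)
        kept = enr.filter_results(results, config.max_p, config.min_fold)
        counts["enriched_categories"] = len(kept)
        logger.info("enrich: %d of %d categories pass p<%g and fold>%g",
                    len(kept), len(results), config.max_p, config.min_fold)
        enrich_tsv = outdir / "enrichment.tsv"
        _write_enrichment(results, enrich_tsv)

    # --- stage: spacer-stats ---------------------------------------------
    spacer_tsv = outdir / "spacer_stats.tsv"
    all_spacers = [d.spacer_sequence for d in dimers]
    kept_spacers = [c.match.spacer_sequence for c in cands
                    if isinstance(c.match, DimerMatch)]
    _write_spacer_stats(all_spacers, kept_spacers, spacer_tsv)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()
                   if not isinstance(v, tuple) or k == "species"},
        "parameters": {
            "spacer_min": config.spacer_min, "spacer_max": config.spacer_max,
            "min_conserved_length": config.min_conserved_length,
            "flank": config.flank,
            "peak_thresholds": {ps.name: ps.min_score
                                for ps in config.peak_sets},
        },
        "counts": counts,
        "outputs": {p.name: _sha256(p) for p in
                    [candidate_bed, report_tsv, spacer_tsv]
                    + ([enrich_tsv] if enrich_tsv else [])},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def gf_replace_nearest(cand: gf.CandidateElement,
                       models: Sequence) -> gf.CandidateElement:
    from dataclasses import replace

    try:
        nearest = gf.nearest_gene(cand.match, models)
    except ValueError:
        return cand
    return replace(cand, nearest=nearest)


def _write_report(cands: Sequence[gf.CandidateElement], path: Path) -> None:
    rows = []
    for c in cands:
        m = c.match
        spacer = m.spacer_sequence if isinstance(m, DimerMatch) else ""
        seg = c.conserved_segment
        rows.append([
            m.chrom, str(m.start), str(m.end), spacer,
            f"{seg.chrom}:{seg.start}-{seg.end}" if seg else "",
            ",".join(c.genes),
            ",".join(sorted({a.relation for a in c.gene_assignments})),
            ";".join(f"{k}={v:g}" for k, v in sorted(c.peak_support.items())),
            c.nearest[0] if c.nearest else "",
            str(c.nearest[1]) if c.nearest else "",
        ])
    rows.sort()
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tspacer\tconserved_segment\tgenes\t"
                 "relations\tpeak_scores\tnearest_gene\tdistance\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def _write_enrichment(results: Sequence[enr.EnrichmentResult],
                      path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tK\tk\texpected\tfold\tp_raw\tp_adj\n")
        for r in results:
            fold = "inf" if r.fold == float("inf") else f"{r.fold:.4g}"
            fh.write(f"{r.category}\t{r.K}\t{r.k}\t{r.expected:.4g}\t{fold}\t"
                     f"{r.p_raw:.6g}\t{r.p_adj:.6g}\n")


def _write_spacer_stats(all_spacers: Sequence[str],
                        kept_spacers: Sequence[str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tn\tmin_len\tmax_len\tmean_len\tpooled_gc\tmean_site_gc\n")
        for label, spacers in (("all_dimers", all_spacers),
                               ("screen_survivors", kept_spacers)):
            if not spacers:
                fh.write(f"{label}\t0\t\t\t\t\t\n")
                continue
            grp = sps.summarize_group(spacers, label)
            fh.write(f"{label}\t{grp.n}\t{grp.min_length}\t{grp.max_length}\t"
                     f"{grp.mean_length:.4g}\t{grp.pooled_gc:.4g}\t"
                     f"{grp.mean_site_gc:.4g}\n")
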