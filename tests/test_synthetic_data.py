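"""Synthetic-data generators: determinism, truth consistency, oracles."""

import json

import numpy as np
import pytest

from regscreen.conservation import SpeciesSet, extract_identical_segments
from regscreen.enrichment import overrepresentation
from regscreen.motif_scan import scan_dimers, scan_monomers
from regscreen.sequence_io import read_fasta
from regscreen.synthetic_data import (AnnotationSpec, GeneSpec, PlantSpec,
                                      SimulationConfig, expected_dimer_count,
                                      expected_monomer_count,
                                      plan_gene_models, simulate_alignment,
                                      simulate_annotation, simulate_bundle,
                                      simulate_gene_models, simulate_genome,
                                      simulate_peaks)

CFG = SimulationConfig(seed=5, genome_length=60_000,
                       genes=GeneSpec(n_genes=3))


class TestGenome:
    def test_seed_determinism_is_bytewise(self, tmp_path):
        a, _ = simulate_genome(CFG)
        b, _ = simulate_genome(SimulationConfig(**{**CFG.__dict__}))
        assert a.residues == b.residues
        c, _ = simulate_genome(SimulationConfig(**{**CFG.__dict__, "seed": 6}))
        assert a.residues != c.residues

    def test_planted_dimers_recovered_by_scanner(self):
        genome, truth = simulate_genome(CFG)
        found = {(d.start, d.end) for d in scan_dimers(genome)}
        for t in truth:
            if t.kind == "dimer":
                assert (t.interval.start, t.interval.end) in found
                assert t.spacer == genome.residues[
                    t.interval.start + 5:t.interval.end - 5]

    def test_truth_records_cover_all_plants(self):
        _, truth = simulate_genome(CFG)
        assert len(truth) == sum(p.count for p in CFG.plants)
        ivs = sorted((t.interval.start, t.interval.end) for t in truth)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2  # non-overlapping

    def test_capacity_error(self):
        tiny = SimulationConfig(seed=0, genome_length=5_000)
        with pytest.raises(ValueError):
            simulate_genome(tiny)

    def test_background_monomer_count_matches_analytic_oracle(self):
        cfg = SimulationConfig(seed=21, genome_length=100_000, plants=(),
                               base_probs=(0.25, 0.25, 0.25, 0.25))
        genome, _ = simulate_genome(cfg)
        observed = len(scan_monomers(genome, strand_mode="both"))
        mean, sd = expected_monomer_count(cfg.genome_length, cfg.base_probs)
        # uniform bases: 4/1024 per strand per position
        assert mean == pytest.approx(100_000 * (4 / 1024) * 2, rel=0.01)
        assert abs(observed - mean) < 3 * sd


class TestAlignment:
    def test_declared_blocks_are_recovered_exactly(self):
        genome, truth = simulate_genome(CFG)
        blocks, segments = simulate_alignment(genome, CFG, truth)
        sset = SpeciesSet(species=CFG.alignment.species,
                          reference=CFG.alignment.reference)
        got = [(s.start, s.end) for s in
               extract_identical_segments(blocks, sset, min_length=5)]
        want = sorted((s.start, s.end) for s in segments)
        assert sorted(got) == want
        # every conserved truth site is inside one declared segment
        for t in truth:
            if t.conserved:
                assert any(s <= t.interval.start and t.interval.end <= e
                           for s, e in want)

    def test_no_declared_blocks_means_no_segments(self):
        cfg = SimulationConfig(seed=9, genome_length=60_000,
                               genes=GeneSpec(n_genes=3),
                               plants=(PlantSpec(kind="dimer", count=3,
                                                 conserved=False),))
        genome, truth = simulate_genome(cfg)
        blocks, segments = simulate_alignment(genome, cfg, truth)
        assert segments == []
        sset = SpeciesSet(species=cfg.alignment.species,
                          reference=cfg.alignment.reference)
        assert extract_identical_segments(blocks, sset, min_length=5) == []

    def test_divergence_validation(self):
        genome, truth = simulate_genome(CFG)
        from dataclasses import replace

        bad = replace(CFG, alignment=replace(CFG.alignment, divergence=1.5))
        with pytest.raises(ValueError, match="divergence"):
            simulate_alignment(genome, bad, truth)

    def test_maf_bytes_seed_stable(self, tmp_path):
        genome, truth = simulate_genome(CFG)
        blocks1, _ = simulate_alignment(genome, CFG, truth)
        blocks2, _ = simulate_alignment(genome, CFG, truth)
        assert blocks1 == blocks2


class TestGeneModelsAndPeaks:
    def test_compartment_placement(self):
        _, truth = simulate_genome(CFG)
        models, cds = simulate_gene_models(CFG)
        for t in truth:
            if "intronic" not in t.site_id:
                continue
            gm = next(m for m in models if m.gene == t.gene)
            introns = [(e1, s2) for (_, e1), (s2, _) in
                       zip(gm.exons, gm.exons[1:])]
            assert any(s <= t.interval.start and t.interval.end <= e
                       for s, e in introns)

    def test_cds_sites_inside_cds_exons(self):
        _, truth = simulate_genome(CFG)
        _, cds = simulate_gene_models(CFG)
        for t in truth:
            if not t.noncoding:
                assert any(c.start <= t.interval.start and
                           t.interval.end <= c.end for c in cds)

    def test_peaks_respect_flags_and_thresholds(self):
        _, truth = simulate_genome(CFG)
        peaks = simulate_peaks(CFG, truth)
        dnase = peaks["dnase"]
        for t in truth:
            covering = [p for p in dnase if p.start <= t.interval.start
                        and t.interval.end <= p.end]
            assert covering
            best = max(p.score for p in covering)
            if t.dnase:
                assert best >= 0.08
            else:
                assert best < 0.08

    def test_layout_error_when_genes_do_not_fit(self):
        with pytest.raises(ValueError, match="genome length"):
            plan_gene_models(SimulationConfig(
                seed=0, genome_length=10_000, genes=GeneSpec(n_genes=5)))


class TestAnnotation:
    def test_planted_category_ranks_first(self):
        ann, gene_list = simulate_annotation(CFG, ["SIMG001", "SIMG002"])
        results = overrepresentation(gene_list, ann)
        assert results[0].category == CFG.annotation.planted_category
        assert results[0].k >= CFG.annotation.planted_overlap
        assert results[0].p_adj < 0.05

    def test_list_size_and_universe_membership(self):
        ann, gene_list = simulate_annotation(CFG, ["SIMG001"])
        assert len(gene_list) == CFG.annotation.list_size
        assert set(gene_list) <= ann.universe


class TestBundle:
    def test_bundle_files_and_manifest(self, bundle_dir):
        names = {p.name for p in bundle_dir.iterdir()}
        assert {"genome.fa", "alignment.maf", "genes.genePred", "cds.bed",
                "dnase.bed", "chip.bed", "annotation.tsv", "truth.bed",
                "manifest.json"} <= names
        manifest = json.loads((bundle_dir / "manifest.json").read_text())
        assert manifest["n_truth_sites"] == len(manifest["truth"])
        (genome,) = read_fasta(bundle_dir / "genome.fa")
        assert genome.length == manifest["genome_length"]

    def test_bundle_bit_reproducible(self, tmp_path):
        cfg = SimulationConfig(seed=4, genome_length=60_000,
                               genes=GeneSpec(n_genes=3))
        simulate_bundle(cfg, tmp_path / "a")
        simulate_bundle(cfg, tmp_path / "b")
        for name in ("genome.fa", "alignment.maf", "genes.genePred",
                     "dnase.bed", "annotation.tsv", "manifest.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name


class TestAnalyticDimerOracle:
    def test_background_dimer_rate(self):
        """Dimer count on plant-free genomes stays within 3 sigma of the
        i.i.d. expectation, aggregated over seeds."""
        total, mean_sum, var_sum = 0, 0.0, 0.0
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, genome_length=50_000, plants=(),
                                   genes=GeneSpec(n_genes=2))
            genome, _ = simulate_genome(cfg)
            total += len(scan_dimers(genome))
            mean, sd = expected_dimer_count(cfg.genome_length, cfg.base_probs)
            mean_sum += mean
            var_sum += sd ** 2
        assert abs(total - mean_sum) < 3 * np.sqrt(var_sum)
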