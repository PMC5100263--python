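# Methods

## The screen

`regscreen` predicts candidate response elements for transcription factors
of the SOXE family, whose members bind a short degenerate pentamer either
alone or as head-to-head dimers. The screen is deliberately *stringent*
rather than probabilistic: a position either matches the consensus grammar
or it does not, a genomic segment either is identical across the chosen
species or it is not, and a candidate either passes every downstream
filter or is discarded. This trades sensitivity for a short, high-
confidence candidate list — the regime in which each survivor is cheap to
test experimentally.

The stages, in execution order:

1. **Consensus scanning.** The grammar is data, not code: forward patterns
   (`ACACA`, `ACAAD`; default monomer length 5) with single-position IUPAC
   degeneracy, and a spacer range (default 5–10 bp). Reverse patterns are
   always derived by reverse complement (`TGTGT`, `HTTGT`), never supplied
   by the user, so the dimer family stays closed under strand flipping.
   Monomer scanning tests every position on both strands (a minus-strand
   match is a plus-strand occurrence of a reverse pattern); dimer scanning
   is a single plus-strand pass pairing each forward occurrence with every
   reverse occurrence at an admissible spacer offset. All overlapping
   matches and all pairings are reported; only exact duplicates are
   removed. A two-strand monomer scan and a one-strand dimer scan are the
   defaults because the dimer family is strand-symmetric — a two-strand
   dimer pass would double-count every site.
2. **Exact-identity conservation.** From a MAF alignment, maximal runs of
   columns in which *every* species of the set (default three species,
   one designated reference) carries the same nucleotide are emitted as
   reference-coordinate segments when at least 5 bp long (the length of
   one monomer). A gap in any species, an `N` in any species, or an
   absent species disqualifies the column; identity is case-insensitive
   (soft-masking is orthogonal to identity). Because a reference gap
   disqualifies a column, segment length always equals column count.
   Book-ended or overlapping segments from adjacent blocks are merged.
3. **Prioritization.** A dimer survives iff (a) its full interval —
   both monomers *and* the spacer — is contained in one conserved
   segment; (b) it overlaps no CDS-exon base (exons clipped to the CDS
   span; UTR exons and introns are non-coding and do not exclude); (c) it
   overlaps some transcript span ± 2.5 kb, with a strand-aware relation
   label (intronic / exonic-noncoding / upstream-flank / downstream-flank
   / overlapping-span); and (d) every required peak set overlaps it by
   ≥ 1 bp with a score at or above that set's threshold (DNase default
   0.08, the F-Seq score cutoff; ChIP default 0). Nearest genes are
   assigned by minimal gap to the transcript span, signed negative 5' of
   the gene, ties broken by distance then alphabetical symbol.
4. **Overrepresentation.** For a gene list of size *n* against a universe
   of *N* genes, a category with *K* members has expected count
   *nK/N* and raw p-value `P(X ≥ k)` for `X ~ Binomial(n, K/N)` — the
   classic PANTHER-style binomial overrepresentation test, computed by
   exact rational summation so deep tails carry no floating-point
   cancellation. Correction is Bonferroni over all categories tested. A
   hypergeometric variant (sampling without replacement) is available
   behind a flag; the binomial is the default because it is the test the
   era's annotation services ran, and because back-computation of the
   printed expected counts in the reference annotation table is
   consistent with a single universe size near 22,920 (`tests` verify all
   ten rows to one decimal — a consistency check, since the service's
   exact universe and category count are unrecoverable).
5. **Spacer statistics.** Group GC content is *pooled* — total G+C over
   total non-N bases, equivalently the length-weighted mean of per-spacer
   GC — with the unweighted per-site mean reported alongside. Pooled GC
   is canonical because it reproduces the printed 61% for the seven
   validated spacers (28/46 = 60.9%); the per-site mean (61.5%) is
   consistent but not the printed statistic. The seven-element
   "active and required" spacer set bundled as a fixture is the unique
   subset of the validated dimeric sites with 5–8 bp spacers that matches
   both printed statistics (the 20-bp-spacer site is excluded by the 5–8
   bp bound); its membership is a reconstruction, and is labelled as such.

Coordinates are 0-based half-open everywhere inside the package;
1-based fully-closed browser coordinates exist only at the conversion
helpers. `N` never matches a consensus position and never counts as
identical in conservation, but is permitted inside spacers, whose content
the grammar does not constrain.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the screen consumes, from one integer
seed, bit-reproducibly (each generator derives its own stream from
`(seed, stream-id)`, so outputs do not depend on call order):

* **Genome** — i.i.d. background with AT-rich human-like composition
  (default p = 0.295/0.205/0.205/0.295 for A/C/G/T), so background match
  counts extrapolate meaningfully to genome-scale magnitudes. Planted
  monomer/dimer sites overwrite the background at recorded coordinates;
  spacers are built to a target GC (default 0.6, the validated-site
  regime). Conserved sites are wrapped in short inert padding (`C` runs,
  default 8 bp) so the planted site is provably the only consensus match
  inside its conserved window.
* **Alignment** — gapless 3-species blocks. Declared conserved windows
  copy the reference exactly; every other column mutates per species with
  probability 0.4. Two guarantees make truth exact rather than
  approximate: columns flanking each declared window are forced to
  mismatch (reported segments cannot extend past truth coordinates), and
  any accidental background identity run reaching 5 bp is broken by a
  forced mismatch (zero false conserved segments by construction). Real
  alignments have indels, lineage-specific rates and tree structure; the
  simulator has none of these, so passing tests demonstrate correctness
  of the *extraction and filtering logic*, not robustness to alignment
  artifacts.
* **Gene models** — a deterministic layout of multi-exon transcripts with
  alternating strands, CDS from mid-first-exon to mid-last-exon (leaving
  real UTR stubs), 2.5-kb flanks and intergenic gaps. Planted sites are
  placed by compartment (intron / flank / CDS exon / intergenic), which
  fixes their truth flags.
* **Peaks** — scored intervals covering each flagged truth site
  (DNase scores ≥ 0.08, ChIP ≥ 0.5); unflagged sites receive
  *sub-threshold* DNase decoys so the score cutoff, not mere presence, is
  exercised; additional random decoys are kept clear of truth
  neighbourhoods so they cannot silently complete a predicate.
* **Annotation** — a universe (default 20,000 symbols), 50 categories of
  50 genes, one planted category sharing 10 genes with the designated
  191-gene list; all other categories are uniform draws.

Default plant mix: 5 conserved intronic dimers, 3 conserved upstream-flank
dimers, 2 intergenic dimers without peaks, 2 CDS dimers, 2 non-conserved
intronic dimers, 4 intronic monomers — every filter has both true
survivors and decoys that must be rejected. The fully-supported subset
(8 dimers at 5 genes per seed under the defaults) is what end-to-end
recovery is measured against.

## Numerical and design choices

* Scanning uses lookahead regular expressions; equality with brute-force
  window enumeration is asserted on random sequences in the tests, which
  keeps the oracle independent of the implementation.
* The binomial tail is summed in exact rational arithmetic
  (`fractions.Fraction`) and converted to float once; tests cross-check
  against `scipy.stats.binom.sf`, against the complement of the lower
  tail, and against Monte Carlo.
* Interval queries go through `intervaltree`; an all-pairs overlap oracle
  re-checks them in tests.
* Filters are subset-returning and idempotent; conservation-containment
  and CDS-exclusion commute, which the pipeline's tests assert so stage
  order is a presentation choice, not a semantic one.
* Degenerate inputs fail loudly: empty FASTA records, zero-length BED
  intervals, exon-count mismatches, MAF rows whose declared size
  disagrees with their non-gap count, empty spacer groups, and empty
  gene lists after universe filtering are all errors with located
  messages, not silent drops.
* Seed handling: file headers (where the format allows comments) and the
  bundle manifest record the seed and a SHA-256 digest of the full
  configuration. FASTA cannot carry a comment without confusing strict
  parsers, so the genome's provenance lives in the manifest only.

## Problem sizes

Tests and the acceptance script run at reduced scale chosen to keep the
whole suite fast while leaving every statistical check well-powered:
oracle equivalence on 200 random 10-kb sequences and 100 random toy
alignments; end-to-end recovery across 20 seeds of 100-kb genomes;
background-rate calibration aggregated over 10–20 plant-free genomes
(3σ bands from the analytic i.i.d. expectation); Monte-Carlo checks at
2×10⁵ draws. Genome-scale reproduction (whole-genome FASTA, 44-way MAF)
uses the same code paths via the CLI but requires external downloads and
is not part of the test suite.

## Known limitations

* The conservation stage implements exact identity only — no
  substitution-model scores (phastCons/phyloP), and no handling of
  duplicated reference coverage beyond interval union.
* The scanner is consensus-based by design; it does not rank matches by
  affinity and cannot find degenerate sites outside the grammar (the
  validated set contains one such site, whose second element departs from
  the strict reverse pattern — it is bundled as a fixture but is not a
  scanner output).
* The enrichment module does no GO-DAG propagation or term-ancestry
  closure; categories are flat gene sets, and Bonferroni is the only
  correction offered.
* Cross-assembly coordinate conversion (liftOver) is out of scope;
  intervals must arrive on the assembly being screened.
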