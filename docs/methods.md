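# Methods

`numtforge` identifies nuclear copies of mitochondrial DNA (NUMTs) in an
assembled nuclear genome, characterizes them, and screens a transcriptome
for NUMT–nuclear chimeras. This note documents the models, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Detection model

A NUMT candidate is a local alignment between the mitogenome (query) and
the nuclear assembly (subject). The built-in engine follows the classic
blastn strategy:

1. **Seeding.** Exact 11-mer matches on both strands (the query is
   reverse-complemented for the minus strand). Words containing N never
   seed, and N never counts as a match. Consecutive word matches on a
   diagonal are collapsed into seed runs.
2. **Ungapped extension.** Each seed run is extended along its diagonal in
   both directions with an X-drop of 30, vectorized in batches.
   Coinciding extensions on a diagonal are collapsed.
3. **Gapped extension.** Seeds whose ungapped score reaches the gap
   trigger (default 45) are extended with a banded affine-gap X-drop DP
   (band half-width 32 diagonals, X-drop 60), anchored at the centre of
   the exact-match run, with a full traceback to count matches and
   aligned columns. Gap cost is `gap_open + gap_extend·L` (5 + 2L).
4. **Scoring statistics.** E-values follow raw Karlin–Altschul theory,
   `E = K·m·n·exp(−λS)` with `m` the query length and `n` the total
   subject length times two strands. λ is the positive root of
   `Σ pᵢpⱼ exp(λ·s(i,j)) = 1`, solved by bracketed root-finding to
   better than 1e-9 against the subject genome's own base composition
   (AT-rich genomes therefore get composition-aware statistics). K uses
   the lattice-case series of Karlin & Altschul (1990) truncated at 60
   convolution terms, with the lattice span δ taken as the gcd of the
   score support values; the truncation error is far below 1e-6 for
   blastn-like schemes. The implementation reproduces the exact ladder
   closed form K = p(1−ρ)²/ρ for the ±1 walk and λ = ln 3 for the
   +1/−1 uniform scheme.

Two deliberate divergences from NCBI BLASTN, both conservative at the
thresholds used here: no effective-length (finite-size) correction is
applied, and gapped scores are assessed with the ungapped λ/K. No
low-complexity masking is performed. Threshold behaviour, not E-value
bit-compatibility, drives the pipeline.

The gap trigger and band half-width are throughput heuristics; for
exhaustive small-instance search (the Smith–Waterman equivalence checks)
the engine is run with `gap_trigger=0`, a wide band and a large X-drop, in
which configuration its top score equals the full affine-gap
Smith–Waterman optimum whenever an exact word seed lies inside the optimal
alignment.

## Filters and locus definition

* **E-value cutoff** 6e-14 (inclusive), a deliberately strict threshold
  for AT-rich genomes where spurious word matches are common.
* **Scaffold-end filter**: hits touching the first or last base of a
  scaffold are removed (configurable margin), since assembly ends
  concentrate alignment artifacts.
* **Locus merging**: hits on one scaffold whose subject intervals overlap
  or are bookended (gap 0) merge into one locus regardless of strand, so a
  single decayed insertion fragmented into several HSPs by indels is
  counted once. A 1 bp gap does not merge, to avoid fusing independent
  insertions. Merging can be disabled to count raw HSPs instead; both
  conventions appear in the literature and the count difference is
  reported by `support_hits`.

Because local alignment is score-maximal, a called locus may extend a few
matching random bases past the true insertion boundary (≈3 bp per side in
expectation), and in very AT-rich windows — where the mitogenome and the
nuclear flank share composition — a rare net-positive chance extension can
reach 10–50 bp (roughly one locus side in a few hundred at the default
simulation settings). Boundary accuracy is therefore a few bases in
typical sequence, not exact. This matters downstream: chimera screening
measures flank coverage from the locus boundary, so an over-extended
boundary eats into the measurable flank. The chimera benchmark accordingly
evaluates the ≥50 bp rule on the planted spans it is defined on, and
real-data fused-NUMT counts should be read as conservative where loci
border highly AT-rich sequence.

## Characterization

* **Length spectrum**: half-open 200 bp bins plus an open tail from 2 kb.
* **Gene of origin**: a NUMT is attributed to every mitochondrial
  protein-coding gene its source interval overlaps by ≥1 bp (so per-gene
  bars can sum to more than the NUMT count); copies from rRNA/tRNA or
  intergenic mtDNA go to a separate non-PCG bucket rather than being
  dropped. Origin intervals may wrap the circular origin and are treated
  modularly.
* **Flank composition**: AT content of up to 100 bp upstream and
  downstream of each locus, Ns ignored, flanks truncated (not discarded)
  at scaffold edges and undefined only when empty. The cohort summary
  pools bases (base-weighted); the upstream-vs-downstream comparison is
  reported descriptively (mean paired difference and sign counts), not as
  a hypothesis test.
* **Position classes** with precedence exonic > intronic > flank2kb >
  intergenic: ≥1 bp exon overlap is exonic; else any gene-span overlap is
  intronic; else a gap of ≤2000 bp to the nearest gene span (inclusive) is
  flank2kb. The nearest gene and its distance are always reported.
* **Correlation test**: Pearson r from the product-moment formula;
  `t = r·√((n−2)/(1−r²))`; two-sided p from the Student-t distribution
  with n−2 df via the regularized incomplete beta function, matching R's
  `cor.test`.

## Chimera screen

For each NUMT locus, a query is the locus plus up to 60 bp of genomic
flank per side. Queries are aligned to the transcriptome; evidence
requires E ≤ 1e-10, identity ≥ 0.98 over the whole alignment (gap columns
in the denominator), coverage of the full NUMT span, and ≥50 flank bases
contiguous with the NUMT within the same alignment — one side suffices,
since a single fused exon is the motivating case. The flank requirement is
the discriminator that excludes transcripts that are merely mitochondrial
sequence. Requiring full NUMT-span coverage is configurable
(`require_full_numt`). The headline count deduplicates to distinct NUMTs
with ≥1 supporting transcript, and reports carry the caveat that chimeric
reads can also arise during RNA-seq library preparation.

## Synthetic data: what it emulates

The simulator generates the statistical structure the analysis assumes,
with planted ground truth in final coordinates:

| Parameter | Default | Rationale |
| --- | --- | --- |
| mitogenome | 16.5 kb, 80% AT, 13 PCG + 2 rRNA + 22 tRNA | typical insect mitogenome; sizes within ±10% of typical values, typical gene order |
| nuclear genome | 10 × 2 Mb, 65% AT | AT-rich insect-like assembly at desk scale |
| window AT heterogeneity | Beta-distributed per 2 kb window, sd 0.12 | gives the insertion-site bias measurable signal; isochore-like heterogeneity |
| planted copies | 50 | inside the 32–72 per-genome range reported for bumblebee-like surveys |
| source bias | COX1 weight 5, others 1 | COX1 dominance of NUMT origins |
| lengths | 80% log-uniform 100–400 bp, 20% log-uniform 400–3000 bp | spectrum dominated by short copies with a long tail |
| site bias | P(site) ∝ (window AT)^β, β = 4 over 200 bp windows | simplest monotone AT-preference mechanism; β=0 is the exact null |
| decay | substitutions 0.02/bp, indels 0.002/bp (geometric lengths, mean 2) | recent, detectable copies consistent with a 0.98-identity regime |
| transcripts | exonic background + chimeras retaining 60 bp flank + pure-mito decoys | positive, boundary and negative controls for the chimera rule |

Planted sites keep ≥1 kb from scaffold ends and ≥3 kb mutual separation so
truth loci stay distinct after merging; insertion splices sequence and
lifts gene-model coordinates so detection faces realistic coordinates.

**What passing tests do not show.** The simulator draws i.i.d. bases
within windows: there are no repeats, no segmental duplications, no
assembly gaps, no heteroplasmy and no polymorphism. Real genomes contain
repeat-driven false-positive structure that the null calibration here
cannot probe, and real NUMT decay is not uniform in time. Recovery rates
on this benchmark are an upper bound on real-data performance.

## Benchmark scales

The test suite runs planted-truth recovery over 20 seeded replicates at
the default scale (10 × 2 Mb, 50 copies; ~15 s per replicate) and null
calibration on 20 seeded mito-free 20 Mb uniform genomes. Bias-recovery
cohorts use 3 × 400 kb genomes with 50 copies and chimera cohorts
2 × 200 kb with 12 copies (8 chimeric transcripts, 12 decoys) — sizes
chosen so the whole suite stays desk-scale while each property keeps the
statistical power it needs. `scripts/acceptance.py` re-runs the same
measurements at the same per-run scales with fewer replicates.

## Numerical and degenerate-input choices

* Ambiguity codes collapse to N on read; N never matches, seeds or counts
  toward identity or AT content.
* Internal coordinates are 0-based half-open everywhere; GFF3 converts at
  the I/O boundary (1-based inclusive); BED is native.
* Circular queries are linearized with min(L, 2000) bp wrapped past the
  origin; hits map back modulo L (a hit with query_end > L spans the
  origin) and wrap duplicates are removed by identical subject interval.
* Hit tie-breaking is fixed (higher score, then smaller subject start,
  then plus strand) and all outputs are deterministically ordered, so
  identical inputs give byte-identical outputs; reports contain no
  timestamps.
* Genome-fraction denominators include N bases by default (full assembly
  length), configurable.
* An all-N genome has undefined AT content and raises; constant vectors
  raise in the correlation test; empty cohorts are allowed everywhere
  downstream of detection.
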