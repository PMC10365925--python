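# Methods

This note documents the models and procedures implemented in `chromquant`,
the defaults chosen where the design was open, and what the synthetic data
do and do not establish about behaviour on real data.

## Coordinate and sequence conventions

All intervals are 0-based half-open internally; GTF's 1-based closed
coordinates are converted on load. Genomes are uppercase strings over
{A,C,G,T,N}; any other FASTA character becomes N. Multiple transcripts of a
gene are collapsed to the union of their exons — transcript-level structure
is out of scope. A gene's 3' terminus is the last base of the exon union
for `+` genes and the first base for `−` genes; all 3'-window arithmetic
uses the genomic (unspliced) gene span, and windows are clipped at the
gene's boundaries.

## Read simulator

The simulator emulates a Chromium 3' gene-expression library on a given
genome, annotation and barcode whitelist.

Expression structure, per cell:

| quantity | distribution | post-processing |
|---|---|---|
| expressed genes | Gamma(k = 4.5, θ = 550) | round, cap at catalogue size; genes drawn uniformly without replacement |
| UMIs per gene | Gamma(k = 1, θ = 6) | round, clamp at 1 |
| reads per UMI | Gamma(k = 2, θ = 2) | round, clamp at 1 |

Defaults: 10,000 cells; barcodes sampled without replacement from the
whitelist. Note that on the small catalogues used in the tests the
genes-per-cell draw is always capped, so every cell expresses every gene;
this is intentional desk-scaling and does not change the per-gene UMI/read
structure.

Each UMI is one cDNA molecule. Its fragment is a genomic window of the read
length (90 bases) whose 3'-most base lies *d* ~ Normal(350, 30) bases
upstream of the gene's 3' terminus, with *d* resampled until the window
fits inside the gene span (genes too short for any plausible placement —
span < read length + mean + 4 sd — are excluded up front). Germline-style
variants are planted once per molecule and shared by all its reads: per
base, a substitution with probability 9×10⁻⁴ (to a uniformly chosen other
base) and an indel initiation with probability 1×10⁻⁴ (insertion or
deletion at equal odds, length uniform in 1–3; "short" is not otherwise
constrained). The window carries 12 extra upstream bases so a deletion
cannot shorten the emitted read.

Sequencing errors are substitutions driven by a per-cycle Phred profile:
the emitted quality string and the injected error probability 10^(−q/10)
come from the same integer scores, so data and model are consistent by
construction. The default profile decays linearly from q=37 at cycle 1 to
q=25 at the last cycle — a parametric stand-in with the empirically
correct shape (more errors toward the 3' end); it is configurable because
real per-cycle quality tables vary by instrument and run. Errors are
applied to all three segments (I1, R1, R2) alike.

Read layout follows Chromium Next GEM v3.1 conventions: 16-base barcode +
12-base UMI in R1, 90-base cDNA in R2, one fixed 8-base sample index in I1.

UMI sequences are drawn uniformly over 4^12 with two resampling rules: a
new UMI must not equal any UMI already used in the same cell, and must not
lie within Hamming distance 1 of another UMI of the same (gene, cell).
Real libraries violate this with (very low) probability; the rule makes
planted molecules unambiguous, so that with noise disabled the
deduplicated matrix equals the planted truth *exactly* — a property the
test suite relies on. At the default 12-base UMI length the distortion of
the UMI distribution is negligible.

What the simulator does **not** emulate: spliced transcripts and junction
reads, doublets, ambient RNA contamination inside cell-containing droplets,
barcode-swapping artefacts, PCR-bias in read counts beyond the Gamma model,
and empirical per-cycle quality tables. Passing tests on this generator
therefore demonstrate correctness of the quantification logic under the
stated generative model, not robustness to every artefact of real data.
Ambient-only droplets for exercising the cell caller are generated
separately (`simulate_ambient_background`): droplet totals
1 + Poisson(mean−1) with gene identities multinomial from a skewed
(geometric-decay) profile.

## Aligner

Seed-and-vote with deliberately high sensitivity for short 3'-tag reads:

- 15 seeds of length k = 16 at offsets `round(i·(L−16)/14)`, deduplicated;
  seeds containing N are dropped. k = 16 is index seed length and is
  configurable in [8, 24].
- Both strands are queried (the reverse strand via the reverse-complemented
  read). Each seed hit implies a read-start position; implied starts within
  ±16 bases (the `max_indel` window) pool into one candidate whose votes
  are the number of distinct supporting seeds. **Minimum one vote** — all
  candidates are retained.
- The best 8 candidates by votes are extended. Extension is ungapped at the
  modal implied start; when the seed support disagrees about the start, a
  single-indel placement is also tried: prefix aligned at the start implied
  by the leftmost seed, suffix at the start implied by the rightmost seed,
  split point chosen to minimise mismatches via prefix/suffix mismatch
  sums. At most one indel per alignment; reads with more indels can still
  map with mismatches.
- Score = matched − mismatched; inserted or soft-clipped bases (past a
  chromosome end) count as neither. Ties prefer candidates overlapping an
  annotated gene's exons; remaining ties break on (chromosome order,
  position, strand `+` first) — a pinned, arbitrary but deterministic rule.
- Alignments scoring below `min_score` = 16 are reported unmapped.

No splice-aware alignment (the simulator is unspliced by design), no
mapping-quality model, no paired-end cDNA mode (R1 is technical only).
Optional SAM text output exists for interoperability and is validated with
pysam in the tests; it is not the primary data path.

## Quantifier

- **Barcode correction:** exact whitelist members pass; otherwise a unique
  whitelist member at Hamming distance 1 is adopted. Zero or ≥ 2 candidates
  reject the read — rejection of ambiguous corrections is the conservative
  choice (frequency-weighted resolution would need a prior pass over the
  data). A deliberately degraded `raw` mode (no correction or filtering)
  exists to quantify the value of correction; the test suite checks it
  strictly worsens RMSE.
- **Gene assignment:** genes whose exon union overlaps the aligned
  reference interval by ≥ 1 base are collected; a unique overlapper wins,
  otherwise the largest overlap in bases; exact ties are discarded as
  ambiguous. Reads wholly inside introns are unassigned.
- **UMI collapsing:** within one (gene, cell), UMIs at Hamming distance
  ≤ 1 form single-linkage connected components; each component is one
  molecule. The component representative is its highest-read member (ties:
  lexicographically smallest). Single linkage (rather than read-count
  directional adjacency) is the pinned choice.
- **Cross-gene resolution:** collapsing happens within gene first; then a
  representative UMI appearing under several genes of the same cell is kept
  only by the gene with the most supporting reads (ties: smallest
  gene_id). Each surviving (gene, UMI) adds exactly one count.

## Cell calling

The caller is the three-stage structure used by droplet-based pipelines;
its exact constants are pinned here and config-exposed, and bit-agreement
with any external implementation is explicitly not a goal.

1. **Cutoff:** 100 bootstrap resamples (with replacement, same size) of the
   per-barcode totals; per resample, the 0.99 quantile of the top
   `expected_cells` (default 3000) totals divided by 10; the cutoff is the
   mean. Totals are sorted first, so the cutoff is exactly invariant to
   barcode order at a fixed seed.
2. **Ambient profile:** gene counts summed over barcodes ranked
   10,000–100,000 by descending total (clipped to the available barcodes;
   an empty window falls back to uniform), add-one smoothed, normalised.
3. **Rescue:** candidates are barcodes below the cutoff with total ≥ 10.
   Each gets a Monte-Carlo p-value under a multinomial with the candidate's
   total and the ambient proportions, using the multinomial log-likelihood
   as the test statistic, 10,000 iterations, add-one corrected
   (r+1)/(N+1); Benjamini–Hochberg across candidates at FDR 0.01.
   Null draws are shared across candidates with the same total, which makes
   the stage fast at tens of thousands of candidates.

A practical interaction worth knowing: the Monte-Carlo p-value floor is
1/(iters+1), so with *n* candidates BH can only ever reject when
`(1/(iters+1))·n/rank < FDR`. With the defaults (10⁴ iterations, FDR 0.01)
a lone non-ambient barcode among thousands of null candidates is not
rescuable; rescue becomes decisive when many candidates deviate or when
iterations are raised. The FDR-calibration test and the marker-gene rescue
test exercise both regimes.

## Evaluation

- log2-cpm: `log2((count + 0.5)/libsize × 1e6)` with the *raw* (offset-free)
  column total as library size. Cells with zero library size are excluded.
- RMSE is taken jointly over all matched (gene, cell) entries (not averaged
  per cell first). Cells present in truth but missing from the estimate are
  scored as all-zero columns whose log2-cpm uses the offset-inclusive
  library size (n_genes × offset), i.e. a flat minimal-expression profile;
  a flag excludes them instead. This convention only matters when a caller
  drops true cells.
- Mixture concordance is computed on pseudo-bulk per-gene profiles: pure
  samples' cpm (with the 0.5 offset on pooled counts) combined as
  `ratio·cpm_A + (1−ratio)·cpm_B` on the linear cpm scale, compared on the
  log2 scale with the observed mixture profile, RMSE over genes.

## Determinism and seeding

All randomness flows through explicitly passed numpy Generators. The
pipeline derives per-stage streams from the global seed keyed by stage name
(CRC-32 of the name as a second seed word), so stages are individually
reproducible and a re-run with the same config produces byte-identical
FASTQ and matrix files — the test suite asserts this.

## Problem sizes used in the tests and acceptance script

The reference used throughout is a generated fixture: one 70 kb
chromosome, 25 disjoint single-exon genes of 700–1400 bases (so the
350 ± 30 window always fits), and whitelists of random barcodes with
pairwise Hamming distance ≥ 3 (making one-mismatch correction unambiguous
for single-error reads). The exact-recovery run uses 200 noise-free cells;
the recall run uses 500 default-noise cells plus 20,000 ambient-only
droplets and `expected_cells = 500`; distributional checks use 10⁴–10⁷
draws as appropriate for their tolerances. These sizes are the package's
own validation choices: large enough for the Monte-Carlo tolerances quoted
in the tests, small enough to run comfortably on a laptop.

## Known limitations

- Single-exon gene models dominate the fixtures; multi-exon genes are
  supported by the catalogue and assignment logic (exon-union overlap) but
  junction-spanning reads are not modelled or aligned.
- The aligner places at most one indel and infers it from seed-offset
  disagreement; closely spaced or long indels degrade to mismatch-heavy or
  unmapped alignments.
- The ambient rank window (10,000–100,000) assumes a dataset with a deep
  barcode rank curve; on small matrices the window clips or empties (then:
  uniform profile with a warning).
- BCL input, demultiplexing across sample indices, intronic/velocity
  counting and mapping-quality calibration are out of scope.
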