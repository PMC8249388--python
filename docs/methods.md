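# Methods

`rbnskit` implements the computational core of an RNA Bind-n-Seq (RBNS)
motif-discovery study of the RNA-binding protein Bicc1, together with the
two companion analyses such a study needs: a metagene scan that places one
3'-UTR inside a genome-wide background of proximal 3'-UTR regions, and the
percent-of-input arithmetic used to quantify RNA co-immunoprecipitation.
All stages are exercised end to end on synthetic data with known ground
truth, so no sequencing deposit is required to verify the pipeline.

## The Bind-n-Seq enrichment statistic

In RBNS a protein is incubated with a randomized RNA library; bound
molecules are pulled down and sequenced, and sequence preferences appear as
k-mers over-represented in the pulldown relative to a mock control. The
library here is a fixed construct: a constant 5' flank
(`GGACGTGACACGACGTGCGC`), a randomized 20-mer insert, and a constant 3'
flank (`GCGTACGTCGGACCTCAGGTCGACCATGGACGC`), handled internally as DNA
(U→T). Only the insert is analyzed; the 5' flank itself contains a
`GACGTGAC` octamer, so insert extraction is anchored on the flanks and
k-mers are never taken from flank sequence.

Per sample, extracted inserts are split into all overlapping k-mers
(k = 4, 5, 6; a 20-mer yields 15 hexamers). Counts are converted to
normalized frequencies over the full 4^k universe with a pseudocount of 1
added to every k-mer before normalization; the pseudocount guarantees
strictly positive control frequencies and hence finite ratios (the choice
is recorded in output metadata). The enrichment of k-mer *m* is

    relative_frequency(m) = freq_pulldown(m) / freq_control(m)

Ratios are standardized over the full 4^k universe using the sample mean
and n−1 standard deviation, computed on raw ratios (not log-ratios), and
hexamers with Z > 3.0 are called enriched. Full-universe standardization
and the n−1 denominator are pinned choices; with 4,096 hexamers they are
numerically negligible but tests require an exact definition. Ranking is
by ratio descending with lexicographic tie-breaks. If every ratio is equal
(degenerate input) all Z are defined as 0 and the selection is empty.

## Motif summarization

Enriched hexamers are summarized without an external aligner: 6-mers that
share a common core gain nothing from gapped alignment, so an ungapped
center-star offset alignment is used. Members are processed by enrichment
score descending (ties lexicographic); the first is the center, each
subsequent hexamer takes the offset in ±5 that maximizes positional
identity to the running profile (ties: smaller |offset|, then smaller
signed offset), and one refinement pass re-fits each member against the
profile of the others. The procedure is deterministic for a given input
multiset and score map.

From the alignment a position frequency matrix is built (each hexamer
counts once; no enrichment weighting), and the logo matrix uses the
standard information-content formulation: per column with coverage *c* and
base frequencies *f*, IC = 2 + Σ f·log2 f bits, letter height = f·IC. No
small-sample correction is applied — columns covered by fewer than 2
members are flagged low-confidence instead, and are trimmed from the ends
before the IUPAC consensus is read off (smallest degenerate code covering
all bases at frequency ≥ 0.25 per column).

## Bounded-gap motif scanning and the metagene analysis

Motif patterns are IUPAC strings with optional bounded spacers
(`GACR`, `YGAC`, `GACN{1,2}GAC`, `GACN{1,3}GAC`). Patterns are compiled to
lookahead regular expressions so that overlapping occurrences are found;
a match is counted per distinct start position, and a start counts once
even when several spacer lengths complete a match. IUPAC positions require
a known compatible base (never N); spacer positions match any base. U in
the input is treated as T.

For the metagene analysis, the proximal *n* = 200 nt of each 3'-UTR is
extracted 5'→3' in mRNA orientation (strand-aware when slicing a genome
with BED6 intervals; minus-strand intervals are reverse-complemented before
truncation; UTRs shorter than 200 nt are kept whole and flagged). Exact
duplicate sequences are removed (first occurrence kept). Matches are
counted per region, reported both as raw counts and counts per 100 nt
(short regions use their actual length), and the query region is placed in
the background by an add-one empirical upper-tail p:

    p = (1 + #{background regions with count >= query count}) / (n_background + 1)

with the query excluded from the background. This assumption-free
procedure stands in for the unstated significance assessment of the
original analysis and is exactly testable.

## Read QC

Processing order is fixed: adapter trim → mean-quality filter → insert
extraction. The 3' adapter (or a prefix of it at the read's 3' end) is
removed when its edit distance is ≤ floor(0.2 × matched adapter length)
with overlap ≥ 3, mirroring the cutadapt error-rate semantics (indels
allowed); edit-distance alignments are computed with edlib. Reads with
mean Phred < 30 are then discarded (strict-less-than rejection; a mean of
exactly 30 is kept). Finally the 5' flank is matched at read offsets 0–5
with ≤ 2 Hamming mismatches (no indels — the construct is fixed length) and
the following 20 bases are taken as the insert, additionally requiring the
first 4 bases of the 3' flank to follow with ≤ 1 mismatch when the read is
long enough. Reads failing flank identification are dropped and counted.
The QC report conserves counts: n_input = n_quality_failed +
n_flank_failed + n_inserts.

## RIP-qPCR quantification

Recovery in an immunoprecipitate is expressed as percent of input with a
correction for the input aliquot fraction f (default 2.5%):

    percent_input = 100 × 2^(Ct_input − log2(100/f) − Ct_IP) = f × 2^(Ct_input − Ct_IP)

Equal Ct values therefore return exactly f, one extra IP cycle halves the
result, and the result is linear in f. Fold enrichment is the
percent-input ratio of a sample over its empty-vector control; replicates
are aggregated mean-then-ratio at the percent level, matching the stated
normalization order of the assay.

## Synthetic data: what it emulates and what it does not

The simulator defines the study conditions under which the pipeline is
verified.

*Reads.* A candidate pool of `20 × n_pulldown` uniform random 20-mers is
generated; each insert's selection weight is `1 + Σ_m w_m ×
count_matches(insert, m)`, linear in motif content — the simplest model
producing the qualitative enrichment of motif-bearing k-mers, with
closed-form expectations. The pulldown draws `n_pulldown` inserts from the
pool with probability proportional to weight (exact weighted sampling with
replacement, bounded runtime); the control is i.i.d. from the base
composition. A mock-pulldown control and a sequenced input-library control
are generatively identical here (no protein, no selection), so the
`control_kind` flag only labels the manifest; mock is the default. Reads
are `flank5 + insert + flank3`, a configurable fraction (default 0.2)
reads through into the sequencing adapter, and all reads are padded to the
read length (default 150 nt) with poly-A: a random pad would produce
cutadapt-style spurious short 3'-overlap trims and make the planted
read-through fraction unrecoverable from the trim counter. Quality is a
two-level constant-Phred model (default Q37/Q20, low-quality fraction
0.05) — sufficient to exercise the mean-quality filter. Fixed seed gives
byte-identical FASTQ output.

*3'-UTRs.* Background regions (default 200 nt) are random sequence with
Poisson-distributed planted non-overlapping motif instances; the query
region carries an exact planted count. Rescanning recovers at least the
planted count (random background can add chance matches). Optional exact
duplicate records exercise deduplication.

The generator does not model PCR duplicates, substitution error profiles,
position-dependent quality decay, RNA secondary structure, or real 3'-UTR
base composition. Passing tests therefore demonstrate the correctness of
the statistics and plumbing under a clean generative model, not robustness
to every artifact of real libraries.

## Standard verification conditions and problem sizes

The planted-recovery experiment uses affinities {YGAC: 4, GACR: 4} at
50,000 reads per sample — a desk-scale analogue of the full assay chosen
so that enrichment signal dominates sampling noise while a run completes
in seconds. Under these conditions the Z > 3 selection is nonempty,
≥ 90% of selected hexamers contain a YGAC or GACR match, and the IUPAC
consensus over the aligned selection contains a contiguous `GAC`. Null
calibration (no affinities, 5 seeds at the same depth) keeps the Z > 3
selection rate ≤ 2% per seed with |mean Z| < 0.05. The metagene check
uses 999 background regions with no planted motifs against a query with 5
planted `GACGTGAC` copies, giving the exact add-one p of 1/1000.

## Known limitations

- The adapter trimmer resolves alignment-ambiguous starts via edlib's
  reported best location; cut positions can differ from an exhaustive
  search by up to the error budget when indel placements tie.
- Phred+33 is assumed; offset-64 input is detected only via out-of-range
  scores.
- Each k is analyzed independently; there is no joint model across k, no
  read deduplication before counting, and no streaming sketches (4^6
  counts fit trivially in memory).
- The center-star alignment is a deliberate, documented replacement for a
  gapped guide-tree aligner and is only appropriate for short ungapped
  cores like the hexamers selected here.
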