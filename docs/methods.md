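# Methods

This note documents the models, algorithms, parameter choices and
known limitations of `homoeolog`, a pipeline for quantifying and
classifying differential homoeologue contributions to the leaf
transcriptome of an allohexaploid (AABBDD) such as bread wheat.

## Problem setting

An allohexaploid carries three related subgenomes (A, B, D).  For a
gene present on all three, the homoeologous copies may contribute
unequally to the mRNA pool: one copy can be systematically more
abundant (dominance) or less abundant (repression) than the other
two, an effect known as expression-level dominance (ELD).  The
pipeline builds the resources needed to measure this from mRNA-Seq:
an ordered, genome-partitioned transcript reference; a table of
homoeologue triplets; normalized abundance matrices across a
diversity panel; per-triplet statistical classification; a colour
visualization; and an orthogonal validation from Sanger trace peak
heights.

## Similarity search engine (`simsearch`)

All sequence-similarity steps run through one deterministic
seed-and-extend engine:

* exact k-mer seeding (default word size 11) on both strands, using a
  4-letter k-mer index with N positions masked (N never matches and
  scores as a mismatch);
* seed diagonals grouped; a candidate group is pre-screened by the
  best ungapped segment score on its dominant diagonal (vectorized
  Kadane scan) and discarded when that score cannot plausibly reach
  the E-value threshold (a 30-point slack allows for hits spread over
  gap-separated segments);
* surviving candidates get a banded affine-gap local alignment
  (±15 diagonals around the seed group, scores +1/−2, gaps −5 open,
  −2 extend), via `biotite`'s C implementation;
* significance by Karlin–Altschul statistics: `E = K·m·n·exp(−λS)`.
  λ is solved exactly from the scoring scheme (1.333 for +1/−2 at
  uniform base composition, matching the published ungapped value);
  K defaults to the published ungapped constant 0.621 for this
  scheme.  K only rescales E-values, so ranking never depends on it.
  Gapped hits reuse the ungapped statistics — a declared
  approximation; parity with NCBI BLASTN statistics is a non-goal.
* fully specified tie-breaking (descending bit score, ascending
  E-value, then subject id) makes all outputs reproducible.

Short-read assignment uses a lighter path (`ReadMapper`): k-mer
votes pick candidate (reference, offset) placements, the read is
scored by ungapped identity (substitution errors only), and all
references tying for the best identity at ≥ 95% are returned.  Ties
are resolved uniformly at random under a fixed seed, which
intentionally reproduces the mild cross-mapping colour distortion
seen between near-identical homoeologue stretches.  Reads are treated
as sense-strand (strand-specific libraries); both-strand search is a
flag.

The default E-value threshold everywhere is 1e-30.

## Reference curing (`curing`)

When a subgenome's reference descends from a proxy taxon, reads from
a closer relative correct it iteratively: map reads (unique best
reference at ≥ 90% identity; ambiguous reads are dropped, not
guessed), pile up base counts, and replace the reference base wherever
coverage ≥ 4 and the consensus base reaches ≥ 50% of the column while
differing from the reference.  Consensus ties keep the reference
base, then fall back alphabetically; N never wins.  The cycle repeats
up to 6 times or until no base changes, re-mapping from scratch each
round so corrected references can recruit new reads.  Correction is
substitution-only, so lengths are preserved; indel curing is out of
scope.  The depth/fraction thresholds are package choices — the
procedure this emulates does not state its criterion — and are
configurable.

Terminal bases see few read starts and can stay below `min_depth`;
recovery guarantees therefore apply to covered, sufficiently deep
sites.

## Linkage map from scoring strings (`binmap`)

Each marker carries a scoring string: one call per mapping line from
{A, B, H, −}.  Similarity between strings is the fraction of
agreeing calls over co-called positions (undefined if none).  The map
is assembled without conventional multipoint software:

1. **Cluster** the unmapped pool by single-linkage at similarity
   ≥ 0.9 (markers close in the genome have near-identical strings).
   A lexicographic pre-sort makes clustering order-independent.
2. **Order** each cluster by the rank of its best model-species
   orthologue hit and chain markers into maximal runs of mutually
   consistent calls (no conflicting co-called position), which become
   candidate recombination bins.  Missing calls can only merge bins,
   never split them.
3. **Collinearity filter.** Each run is anchored at the median rank
   of its members; a singleton run whose calls match a larger run
   elsewhere is re-anchored at that run's median — a single marker
   whose inheritance pattern belongs to a distant locus most
   plausibly has a wrong orthologue rank.  The maximum-weight
   non-decreasing subsequence of run anchors is kept; all other
   markers return to the unmapped pool.  This keeps genuine pattern
   recurrences (double crossovers re-creating a mosaic across a run
   of ≥ 2 markers) while rejecting rank-discordant markers.
4. **Iterate** clustering and binning on the rejected pool until it
   stops shrinking (≤ 10 iterations).
5. **Segment and chain.** Accepted bin runs are split wherever model
   collinearity breaks: a jump in orthologue rank (> 5) or a drop in
   consecutive-bin consensus similarity (below the chain threshold).
   Segments within a linkage group are then ordered by genetic
   linkage: chain endpoints are greedily joined where their
   terminal-bin consensus strings are most similar (threshold 0.1
   below the clustering threshold, since joins happen exactly at the
   junctions where similarity dips).  Model-genome order therefore
   governs marker order only *within* collinear segments; order
   *between* segments comes from the recombination data, which is
   what lets a rearranged model genome be undone downstream.  Chains
   that cannot be connected genetically are ordered by mean rank.
6. **Orientation.** A mapping population cannot identify global
   chromosome orientation; each chain is oriented so terminal median
   ranks ascend, and recovery tests compare orders up to reversal.

Bin positions are ordinal (no centiMorgan scaling).  The consensus
call of a bin at a line is the unique non-missing member call;
conflicts are impossible by construction.

Resolution limits are intrinsic: a rearrangement junction with zero
crossovers among the lines is genetically invisible, and two markers
separated by no crossover share a bin.  With 47 lines, adjacent-bin
similarity is 1 − (crossovers between)/47, so the chaining threshold
of ~0.8 tolerates up to ~9 line differences at a junction.

## Pseudomolecule construction (`pseudomolecules`)

The model genome is split into collinearity blocks with cuts at
`floor((end_i + start_{i+1})/2)` between the outermost alignment
coordinates of consecutive blocks' distal markers; every model gene
falls in exactly one block (assignment by gene start coordinate; base
coordinates, not gene indices, following the midpoint rule).  Blocks
take a (first bin, last bin) span from the map positions of the
markers at their extremities, are sorted within each linkage group by
the smaller end of the span, and are inverted when the span
decreases along the model coordinate.  Unigenes are then placed by
best engine hit at E ≤ 1e-30 (unigenes with no passing hit are kept
in a side table — they remain usable as mapping reference).
Redundancy (splice forms) is reduced by keeping, per (genome, best-hit
model gene, placement position), only the longest unigene, ties by
lexicographic id; the operation is idempotent.  Coordinates are
0-based half-open internally and 1-based inclusive in exported
tables.  A collinearity dot plot with Kendall's tau is provided for
order-vs-order comparison.

## Triplets (`triplets`)

A homoeologue triplet (a, b, d) requires all three pairwise
reciprocal-best-hit relations (A↔B, A↔D, B↔D) at E ≤ 1e-30.
Best-hit uniqueness implies each unigene joins at most one triplet.
Triplet position is taken from the A member (the three subgenome
orders are essentially identical).  Panel comparison reports, per
genome, the percentage of one panel's members with a reciprocal best
hit among the other panel's members, in both directions.

## Quantification (`quantify`)

RPKM = count / (length/1000) / (mapped/1e6), with the denominator
counting reads aligned to the whole combined three-genome reference
per accession.  Because the three subgenome references descend from
proxies at different evolutionary distances, mapping efficiency can
differ per subgenome; the per-genome normalization multiplies genome
g's values by mean(per-genome totals)/total_g per accession, which
exactly removes a global per-genome efficiency bias.  Downsampling is
uniform without replacement under a seed.  Multi-mapping fractional
assignment (EM) and spliced alignment are non-goals.

## ELD classification (`eld`)

Per triplet, the three accession-level samples form a one-way layout
(k = 3, equal n).  MSE is pooled over groups (df = 3(n−1));
`q = |mean_i − mean_j| / sqrt(MSE/n)` for each pair, with p-values
from the studentized-range distribution.  The tail probability is
computed by direct two-dimensional Gauss–Legendre quadrature of

    P(Q ≤ q) = E_s[ k ∫ φ(z) (Φ(z) − Φ(z − q·s))^{k−1} dz ],
    s ~ sqrt(χ²_df / df)

vectorized over tens of thousands of triplets (48 × 64 nodes;
agrees with scipy's implementation to < 2e-4, and reproduces the
tabulated 5% critical value 3.486 for k = 3, df = 30 to three
decimals; scipy's own routine is used as the test oracle but is too
slow to run per-triplet at panel scale).

Classification: exactly two significant pairs (p < 0.05) name the
shared genome; direction is up if that genome's mean exceeds the
unweighted mean of the other two group means, else down.  Zero, one
or three significant pairs yield no call.  No multiple-testing
correction is applied across triplets.  Tests run on per-genome
normalized RPKM (normalization precedes both testing and
visualization, keeping the two consistent; whether to test raw or
normalized values was an open choice).  Degenerate all-zero triplets
are skipped and flagged.  Zero-variance groups give p = 1 at equal
means and p = 0 otherwise.

## Tile plots (`tileplot`)

For each homoeologue, expression is min-max normalized across the
panel to v ∈ [0, 1] with **1 marking the accession with the lowest
expression** and 0 the highest; a constant series maps to 0.5.  The
tile colour is R = round(255·v_A), G = round(255·v_B),
B = round(255·v_D) (round half up) — equivalently ink channels
C = 1 − v_A, M = 1 − v_B, Y = 1 − v_D with RGB = 1 − CMY.  This
mapping is the unique reconciliation of the two colour conventions it
implements (inverted normalization; black = CMY(1,1,1) and white =
CMY(0,0,0)) that reproduces the full control key: a diploid A row
renders cyan, B magenta, D yellow; in-silico A+B, A+D and B+D mixes
render blue, green and red hues; a triple mix renders grey; equal
channels are always greyscale.  Rendering is pixel-exact (PNG via
Pillow, plain-rectangle SVG); accession rows are ordered
alphabetically (cosmetic choice).

## IHP validation (`ihp`)

The three homoeologue transcripts are aligned progressively (A–B
globally, then D against the A–B consensus — A's base where present,
else B's — with D's gaps spliced into all rows; simsearch scoring,
terminal gaps penalized).  An interhomoeologue polymorphism (IHP) is
a gap-free column where exactly one genome's base differs from the
identical base of the other two; triallelic and gap columns are
skipped and counted.  Primer windows are alignment stretches of a
given length with no gaps and at most a set number of non-identical
columns; window runs are paired into candidate amplicons reported
with enclosed IHP counts.

Sanger peak heights at an IHP are modelled as proportional to the
variant genome's abundance (variant base) and to the pooled abundance
of the other two genomes (shared base).  The per-IHP ratio is
variant/ancestral; per-genome aggregation is the arithmetic mean
(median available).  Since `r_g = a_g/(S − a_g)` under this model,
the genome's abundance share is recovered as `r_g/(1 + r_g)` and
fold changes are quotients of shares — this back-transformation makes
the estimator exactly invert the peak model, so planted abundance
folds are recovered directly (the naive quotient of raw ratios would
overstate folds nonlinearly).  Peak heights are consumed from plain
tables; chromatogram file parsing and thermodynamic primer design are
non-goals.

## Synthetic data (`synthetic_data`)

The generators define the study conditions and ground truth:

* **Subgenomes.** Per triplet, one random ancestor sequence
  (length uniform in 400–800 bp by default) substituted independently
  per lineage (Jukes–Cantor-like: a hit site moves to a uniformly
  chosen different base).  The A and B lineages each receive half the
  configured A–B divergence (default 0.03 between them); D diverges
  at 0.02.  These defaults place the B reference as the most distant
  proxy, mirroring the biology the pipeline targets.  10% of genes
  are made genome-private (deleted from one or two subgenomes) to
  exercise non-triplet paths.  Divergences implying expected identity
  < 60% are refused (reciprocal-best orthology breaks down).
* **Expression.** Baseline abundance per triplet is log-normal
  (ln-mean 3, ln-sd 1), shared by the three homoeologues; dominance
  blocks multiply one genome by f, repression blocks divide by f;
  accession noise is multiplicative log-normal with sd 0.3 on the
  natural-log scale.  Log-normality of RPKM across accessions is an
  assumption, not an observation.
* **Reads.** Single-end, 100 bases, drawn with probability
  proportional to abundance × length, uniform starts, per-base
  substitution errors (default 0.005), constant qualities (the
  pipeline never consumes qualities).  Paired ends, introns and
  splice variants are not simulated.
* **SSD population.** 47 fully homozygous lines (a heterozygosity
  option exists for robustness tests); crossovers per marker interval
  are Poisson with mean 0.002 by default (odd counts flip the
  genotype), missing calls at 2%.  The default rate yields a few
  dozen bins over 500 markers, keeping adjacent-bin similarity high
  enough for string clustering while leaving enough recombination to
  order bins.
* **Rearranged reference.** The true gene order is cut into n blocks,
  permuted and optionally inverted to form the model genome order;
  the true block map is recorded.
* **Trace peaks.** Variant peak ∝ variant genome abundance, shared
  peak ∝ sum of the other two, each with multiplicative log-normal
  noise.

Panel dimensions default to 54 accessions and 47 SSD lines.  All
generators are deterministic per seed (independent named streams per
stage), and outputs parse cleanly with standard FASTA/FASTQ readers.

What passing on these simulations does **not** show: robustness to
indels and splice variation in reads, non-log-normal expression
noise, paralogy (ancestors are independent random sequences, so there
are no gene families), assembly artefacts, or base-composition bias.

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale:
2000 triplets for orthology recovery, 10 000 (suite) / 5000 (script)
null triplets for the classification false-call rate, 500 markers ×
47 lines for the map, 56 blocks for the pseudomolecule round trip,
and a single deep-coverage curing fixture.  These sizes were chosen
so each stage's statistical check is well-powered while the whole
suite stays conveniently re-runnable.

## Known limitations

* The engine's E-values approximate gapped statistics with ungapped
  λ/K; absolute E-values differ from NCBI BLASTN, rankings rarely do.
* The diagonal pre-screen can in principle drop a pathological hit
  whose score is spread across many short gap-separated segments;
  irrelevant for transcript-scale orthology but worth knowing.
* Map assembly assumes enough recombination to separate blocks; a
  junction with zero crossovers is invisible, and global chromosome
  orientation is conventional.
* The trace-peak model is linear in abundance; real chromatogram
  peaks saturate and carry dye/context biases, so real-data fold
  estimates are noisier than the simulation suggests.
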