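# Methods

This note documents the models, algorithms and numerical choices behind the
package, the conditions the synthetic-data generator emulates, and the known
limitations.

## Discovery model

A satellite array is a head-to-tail tandem repetition of a monomer. Over
error-free reads from such an array, the de Bruijn graph of k-mers is a
single simple cycle whose length equals the monomer length (one node per
monomer position; this holds both for monomers longer than k and, because the
k-mer sequence is periodic, for monomers shorter than k, provided the monomer
contains no internal repeated k-mer). Discovery exploits this directly:

1. **Counting.** All k-mers of a read subsample are counted canonically
   (a k-mer and its reverse complement share one count). Default k = 21 —
   long enough that random 2 Mb backgrounds share no k-mer with a monomer,
   short enough that monomer-length cycles survive 1% sequencing error plus
   2% per-copy divergence (a consensus 21-mer survives a copy with
   probability ≈ 0.97²¹ ≈ 0.5, keeping consensus counts far above noise).
2. **Thresholding.** Single-copy background k-mers occur at about the
   sequencing depth; satellite k-mers at copy-number multiples of it. When
   `min_kmer_count` is not set explicitly it is estimated from the data as
   3 × the mode of the k-mer count histogram over counts ≥ 3 (the mode
   estimates single-copy depth), with a floor of 5. This keeps the graph
   restricted to repetitive k-mers without requiring the caller to know
   satellite abundances in advance.
3. **Cycle hunting.** Retained k-mers form a directed overlap graph in both
   orientations (an observed adjacency also adds its reverse-complement
   mirror, making the graph strand-symmetric). Within each weakly connected
   component, a greedy heaviest-edge walk with backtracking (total steps
   bounded by 8 × component size, up to 20 start nodes ordered by node
   strength) searches for the maximum-mean-weight simple cycle; the cycle is
   spelled as the candidate monomer and its mean edge weight recorded as
   support. Acyclic components — dispersed, non-tandem repeats — are
   discarded, which is what confines the method to satellites. Cycles
   shorter than 4 nodes are rejected as homopolymer/dinucleotide artifacts.
4. **Iteration.** Male and female libraries are mined jointly (the union of
   their subsamples feeds one graph) so satellites private to either sex
   enter a single catalog. After each round the cumulative catalog is masked
   out of the working libraries and mining repeats, letting low-abundance
   satellites surface once dominant ones are removed. Mining stops when a
   round yields no novel candidate (novelty = below the variant threshold
   against everything found so far) or after `max_rounds` (default 10, with
   a warning).

Reads are QC'd as whole units — a pair is dropped if any base of either mate
falls below Phred `quality_threshold` (default 20) or contains an N — rather
than trimmed, preserving the fixed read length that haplotype extraction
requires.

## Identity between monomers

Monomers are circular sequences observed at arbitrary phase and strand, so
all comparisons must be rotation- and strand-invariant. Two metrics are
used, chosen by length:

- **Equal lengths: exact circular Hamming identity** — the maximum match
  fraction over all rotations of either strand. For substitution-diverged
  repeat units this recovers the planted identity exactly; for unrelated
  sequences it concentrates near 0.25 (maximum over ~2L rotations of a
  Binomial(L, ¼) match count), far below the 0.50 superfamily tier.
- **Unequal lengths: Smith–Waterman local alignment** of the shorter
  sequence against the dimerized longer one (match +1, mismatch −1, gap open
  −2, extend −1; both strands), with matched bases normalized by the longer
  length. Normalizing by the longer length prevents a short repeat embedded
  in a long one from being promoted to high identity.

A global unit-cost edit alignment ratio (matches / alignment columns) was
evaluated and rejected: for random DNA it saturates near 0.55 — above the
superfamily threshold — because once true identity drops below ~60% the
optimal edit script ignores homology, making the 50–80% tier unmeasurable.

The nested variant (≥ 0.95) / family (≥ 0.80) / superfamily (≥ 0.50)
partition uses single-linkage clustering (connectivity, matching how
homology-search-based grouping chains sequences); lower tier bounds are
closed. Nesting follows automatically from the threshold ordering and is
asserted on every run. Clustering iterates over monomers sorted by canonical
sequence, making the partition independent of input order. Superfamilies are
labelled SF1, SF2, … by decreasing summed mean abundance.

## Read-to-monomer alignment (masking, quantification)

Reads are aligned against a **tandem reference** — the monomer repeated until
it spans a read at any phase — on both strands, with a 13-mer exact-seed
prefilter (stride 4) so that only candidate reads reach the aligner. Masking
identity is edit-distance identity (1 − ed/read length); in the ≥ 0.8 regime
used here it is a faithful match fraction (unrelated reads score ~0.5).
Defaults: identity ≥ 0.80 over ≥ 0.50 of the read — stated cutoffs for the
masking step are not part of the published protocol, so these are this
package's choices, exposed in the configuration. A read failing as a whole
is retried as two halves, so reads straddling an array boundary still
contribute their satellite-derived half to the base-pair tally; the residual
abundance bias is about R/2A per array edge (read length R, array length A),
under 4% for the arrays simulated here.

Abundance is masked bp / library bp (the RepeatMasker convention), robust to
partial-read hits; a read-count mode (`count_mode="reads"`) is available for
comparability. Ties between monomers go to the higher identity, then the
lower catalog index.

For each hit, transitions and transversions are counted over the aligned
columns of the best infix alignment (gap and ambiguous columns excluded from
the denominator) and converted to a Kimura 2-parameter distance
K = −½ ln((1 − 2P − Q)√(1 − 2Q)). Hits outside the model's domain
(1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0, i.e. saturated divergence) are excluded and
counted in `saturated_hits`. Landscapes bin masked bp by K2P distance in 1%
bins from 0 to 50% (the last bin absorbs anything beyond).

The M/F bias call uses a configurable margin: male-biased when
M/F > `mf_bias_ratio`, female-biased below its reciprocal. The protocol
value 1.0 is the default; the synthetic evaluation uses 1.5 because with
finite library sizes an unbiased satellite exceeds 1.0 in half of all runs —
satellite bp arrives in fragment-sized clumps, so the sampling sd of the
ratio is ≈ √(2/F) with F the number of fragments overlapping the array,
several percent at desk scale.

## Haplotype networks

For a monomer of length m ≤ read length, each read is placed on the tandem
reference by **gapless sliding (Hamming) alignment** — the offset minimizing
mismatches, on the better strand — and accepted at identity ≥ 0.80 (again a
package choice, exposed as `min_identity_for_extraction`). Gapless placement
is deliberate: an edit-distance traceback may represent two substitutions as
an insertion + deletion pair at equal cost, silently discarding diverged
variants, whereas haplotypes must be equal-length and Hamming-comparable.
The first complete monomer window inside the read (window starts at
multiples of m in reference coordinates, i.e. in monomer phase) contributes
the haplotype, so identical variants from different read offsets collapse.
Haplotypes seen fewer than `min_haplotype_count` times (default 2 —
singletons removed) are dropped as likely sequencing errors.

The MST over the complete Hamming-distance graph uses Kruskal with edges
pre-sorted by (distance, endpoint pair) for deterministic tie-breaking; on
every instance with ≤ 6 nodes the tree weight is verified in the test suite
against exhaustive enumeration of all spanning trees. GraphML output stores
per-node sequence and per-sex counts and only the tree edges; true edge
distances are stored rather than unit-expanded intermediate nodes, leaving
rendering conventions to visualization tools.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the pipeline targets: one male and
one female genome of equal length sharing an identical i.i.d. background
(configurable GC, default 0.45) and identical autosomal satellite arrays,
with Y-linked arrays overwriting background in the male genome only — so a
satellite with `copies_y_linked > 0` and no autosomal copies has exactly
zero planted bp in the female genome. Arrays are uninterrupted tandem runs;
each copy is independently mutated by i.i.d. substitutions (never to the
same base) at `per_copy_divergence`, so expected copy-to-consensus identity
is exactly 1 − d and every satellite's true abundance and M/F ratio are
exactly computable from planted bp. Background windows sharing a 21-mer
with any monomer are re-drawn, so discovery cannot be seeded by chance
collisions. Reads are fixed-length pairs from normally distributed
fragments (default mean 350 bp, sd 50, clamped to [read length, genome
length]), uniform in position and strand, with i.i.d. substitution errors
and Phred+33 qualities from a constant-Q model (Q matched to the error rate)
or a two-state body/tail model.

Deliberately absent: indels (both in copy mutation and sequencing error),
higher-order repeat structure, GC-dependent coverage bias, PCR/optical
duplicates, quality miscalibration. Passing tests therefore demonstrate
correctness of the inference machinery under the substitution-only model,
not robustness to indel-rich satellites or biased real libraries; the
alignment tolerances (masking at 0.80 identity with edit distance, which
admits indels) provide slack but are not separately stress-tested.

**Default study panel** (`default_panel`): ten satellites with female-side
abundances 5, 3, 2, 1.2, 0.8, 0.5, 0.3, 0.2, 0.15 and 0.1% of a 2 Mb
genome; monomer lengths 150, 300, 50, 230, 20, 110, 270, 35, 190, 80 bp;
per-copy divergences between 0 and 2%; the fourth satellite carries a
Y-linked accumulation of twice its autosomal copy number, giving a true
M/F bp ratio of 3. Monomers are random sequences kept mutually dissimilar
(pairwise identity < 0.5, no shared 21-mers).

## Determinism and problem sizes

All randomness flows from one seed, expanded into independent per-stage
streams via `numpy.random.SeedSequence([seed, stage_index])`, so a single
stage can be re-run in isolation and reproduce its in-pipeline output; the
run manifest records a config snapshot and SHA-256 checksums of every
artifact, and re-running from the same config reproduces identical checksums
(asserted in the test suite).

The test suite and the acceptance script run the full study at 2 Mb per sex
and 10× coverage (≈ 67,000 pairs per sex), a size chosen so that the least
abundant satellite (0.1%) still yields consensus k-mer counts an order of
magnitude above background and abundance estimates with a few percent
sampling error; the sex-bias replicates use 300 kb genomes at 8×, where the
planted ratio 3 remains > 5 sd above the 1.5 calling margin. Coverage
uniformity is asserted on 2 kb window means (CV < 0.15): per-base depth at
10× is Poisson-distributed with CV ≈ 0.32 for any uniform sampler, so the
windowed statistic is the one that detects positional bias.

## Known limitations

- Monomers much longer than the read length are discoverable only through
  the k-mer cycle (cycle length may exceed read length); their consensus
  support comes from edge weights rather than any single read, and monomers
  with internal repeated k-mers (e.g. higher-order structure) may be
  reported as a shorter sub-cycle.
- The equal-length circular identity metric does not model length-changing
  mutations between monomers of the same family; unequal-length pairs fall
  back to local alignment, whose 50% tier behaviour for near-equal lengths
  is less sharply calibrated.
- Abundance is a library-bp fraction; genome-proportion units and
  genome-size normalization are out of scope.
- The haplotype extractor takes the first complete monomer window per read;
  reads spanning several copies contribute one window, a slight undercount
  of very short monomers' haplotype totals that cancels in proportions.
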