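# Methods

## Scope

`ampliturn` implements the analysis chain for a tagged 454 amplicon time
series: read preparation (demultiplexing, adapter/primer clipping,
quality filtering), exact-sequence OTU construction, analytic
rarefaction, and the occupancy/abundance/slope turnover statistics, plus
a reference-lineage affiliation step for morphotype analyses. A seeded
synthetic-data generator supplies ground-truthed inputs for all of it.
Taxonomic classification against public databases, flowgram-level (SFF)
processing, chimera detection and phylogenetic tree building are out of
scope.

## Synthetic communities

The generator emulates a ten-sample seasonal series dominated by two
guilds:

- a **persistent guild** (default 300 OTUs) present in every sample, with
  per-OTU mean relative weight `persistent_abundance = 0.0025` perturbed
  by log-normal noise (σ = 0.75, mean-1 parameterisation) independently
  per sample;
- a **seasonal guild** (default 700 OTUs), each restricted to k samples
  with k drawn from `seasonal_occupancy_dist` (default ∝ 1/k, so ~34% of
  seasonal OTUs are single-sample) and per-presence weight
  `seasonal_abundance = 0.0006`. Sample sets are drawn uniformly at
  random (or contiguously, configurable).

Counts per sample are a multinomial draw over the present OTUs' weights,
rescaled so every column sums to `reads_per_sample` (default 15 000).
Every designed presence receives a floor of 2 reads before the
multinomial remainder is allocated: presence is meant to be detectable,
and the dataset-wide duplicate filter removes raw-read singletons, so a
1-read presence would be designed to disappear. With these defaults the
seasonal guild carries a few percent of each sample's reads and
single-sample OTUs average ~2-3% of reads per sample, i.e. a rare but
OTU-rich seasonal fringe under an abundant stable core.

Template inserts are uniform-random DNA of length U[136, 156], giving a
primer-inclusive amplicon of 180–200 bp with the default primer pair
(fw `ATTAGGGTTCGATTCCGGAGAGG`, rv `CTGGAATTACCGCGGSTGCTG`, adapters
`GCCTCCCTCGCGCCATCAG`/`GCCTTGCCAGCCCGCTCAG`). Tags are 4-mers from a
single-parity-check code over GF(4), so any two tags differ in ≥ 2
positions; tag sequences are study-specific, and any valid set can be
supplied instead.

### Error model

Reads are corrupted with (defaults in parentheses):

- per-base substitutions (0.002) and N emissions (0.0002);
- homopolymer indels: every maximal single-base run of length ≥ 2 on the
  clean read suffers a ±1 length change with probability 0.001
  (insertion duplicates a base, deletion removes one, equal odds) — the
  characteristic pyrosequencing artefact the clipper must tolerate;
- Gaussian per-base Phred qualities (mean 30, SD 5) truncated to [0, 40].

These rates put roughly 40% of reads below the combined preparation
criteria, the attrition regime typical of stringent 454 quality
filtering. A single seed governs the community draw and the read stream;
the documented stream order (templates → occupancies → sample sets →
weights → one multinomial per sample; reads per (sample, OTU) batch in
row/column order) makes outputs byte-identical under a fixed seed.

### What the simulator does not emulate

No flowgram simulation, no chimeras/PCR recombinants, no
position-dependent error rates, no realistic rRNA sequence composition
(templates are i.i.d. uniform DNA), and lengths are uniform rather than
empirically distributed. Passing tests therefore demonstrate that the
pipeline's logic is correct under the stated error classes, not that the
error model reproduces any particular instrument run; conclusions about
real data rest on the filtering rules, not on these synthetic rates.

## Read preparation

Clipping order and rules:

1. Adapter A and the 4 bp tag must match exactly at position 0
   (`no_tag` otherwise). Tag matching has no error tolerance; with a
   distance-≥2 tag set a single substitution cannot cross-assign a
   sample.
2. The forward primer must match mutation-free (IUPAC codes expand, e.g.
   S ≡ C|G) at its expected offset. An intact primer found shifted by ≤ 3
   bp is classified `indel_at_primer_junction`; otherwise
   `mutated_primer`.
3. The reverse-primer reverse complement must be fully present and
   mutation-free (last occurrence taken); absence is `mutated_primer`.
4. Trailing bases after the reverse primer are adapter B (reverse
   complement), located by a homopolymer-tolerant pattern in which each
   run of length L may appear with length 1..2L. A displaced intact
   adapter implies `indel_at_primer_junction`; a truncated or degenerate
   adapter is trimmed silently (a read may also end inside the amplicon —
   tolerated as long as the reverse primer is complete).

Quality criteria are applied to clipped reads in a fixed order (first
failing rule is reported): no Ns in the insert; mean Phred over the
clipped read strictly > 24 (a read at exactly 24.0 fails — the threshold
is an open bound); primer-inclusive length (insert + 44 bp of primers)
≥ 200 bp; and ≥ 2 exact copies of the raw pre-clipping read string in the
entire dataset, counted across all samples before demultiplexing. The
duplicate criterion is order-independent, and accepted + per-reason
rejections always partition the input.

Note an interaction between defaults: the simulated amplicon spans
180–200 bp primer-inclusive, while the canonical length threshold is
200 bp. Round-trip and pattern-recovery analyses therefore run the prep
stage with `min_len=180` so the whole designed length range is
admissible; 200 remains the default for real 454 datasets, whose length
distribution extends beyond the targeted fragment.

## OTU construction

Within samples, identity is exact string equality and gaps are
informative: sequences differing by any indel are distinct non-redundant
units. Across samples, units are matched at 100% identity with gaps
disregarded: two sequences are one OTU iff an alignment exists whose
differences are exclusively indels (zero substitutions), which holds
exactly when the shorter sequence is a subsequence of the longer — checked
by a greedy linear scan, with an O(n²) LCS dynamic program serving as the
independent oracle in the tests. Equivalence classes are closed
transitively (A~B, B~C merges A with C even when A and C differ by
stacked indels), the most abundant member represents the class (ties
broken lexicographically), and merging conserves total counts. This
collapses the homopolymer-indel read variants that survive filtering into
their parent OTU while keeping substitution variants separate.

## Rarefaction

Expected richness uses the hypergeometric expectation with binomial
coefficient ratios evaluated as `exp(Σ log-gamma)` and clamped to [0, 1]
(totals of 10⁵ reads overflow direct binomials). Curves are computed per
sample and on the pooled column sums, on an evenly spaced grid (default
50 intervals from 0 to the total; the grid density only affects
plotting, not the expectation). E[S_g] is non-decreasing and concave in
g, equals the observed richness at full depth, and matches Monte-Carlo
subsampling within sampling error.

## Turnover statistics

- **Equal-depth subsampling**: each column is one seeded multivariate
  hypergeometric draw at the depth of the smallest sample (or a supplied
  depth); all-zero rows are dropped. Columns are drawn left to right from
  one generator, so results are reproducible and a depth equal to every
  column total is the identity.
- **Occupancy records**: N, n, A = n/N per OTU (A ≥ 1 for integer
  counts; A·N = n up to floating-point rounding).
- **Occupancy classes**: per class k, the number of OTUs and within-class
  mean/SD of N and A. The ANOVA compares, across classes, the per-sample
  counts of class-k OTUs detected in each sample (samples are the
  replicates — the only replicate structure a single series provides);
  empty classes are excluded. F comes from standard sums of squares;
  Tukey's HSD uses q = |Δmean|/SE with the Tukey–Kramer
  SE = √(MSW/2·(1/nᵢ+1/nⱼ)) and p-values from the studentized range
  distribution. No further multiplicity correction is applied beyond
  Tukey's family-wise procedure.
- **Slope statistic**: OTUs with dataset-wide n > 10 (strict) qualify.
  Nonzero counts are log₁₀-transformed (base is a parameter; it rescales
  m without changing signs or correlations), sorted descending, and
  regressed against ranks 1..k by OLS; zero counts are excluded because
  their log is undefined, so k equals the occupancy and occupancy-1 OTUs
  are undefined (excluded and reported). m ≤ 0 by construction.
- **Slope–occupancy correlation**: Pearson r over per-OTU (m, N) pairs
  with the two-sided t-transform p-value; per-class mean/SD of m is also
  reported for plotting. Zero variance raises an explicit
  "undefined" error rather than returning NaN.

## Morphotype affiliation

A query affiliates with a reference lineage when some reference matches
with ≤ `max_subs` substitutions (default 1) and zero indels over the
best full-length overlap of the shorter sequence; distance is
substitution-only Hamming, so a single indel disqualifies a reference.
Equidistant nearest references from different lineages are reported
ambiguous and excluded from abundance summaries — exclusion avoids
fabricating assignments. Lineage relative abundances are reported on two
bases, per affiliated reads (fractions sum to 1) and per all reads, since
either normalisation is defensible; OTUs below 0.01% of their sample are
pooled into a per-lineage "other" bin in the detailed table.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all inputs
programmatically. Pattern-recovery checks use twenty replicates of the
full default design (10 samples × 15 000 reads, 1 000 OTUs) — large
enough that the occupancy histogram, the A-versus-N contrast and the
slope trend are stable, while one replicate completes in seconds; the
acceptance script summarises three such replicates plus one zero-error
round trip. All stochastic stages consume a single user-supplied seed
through documented substreams.

## Known limitations

- The clipper cannot detect an indel exactly at the insert/primer
  boundary that leaves both primer copies intact; such reads pass with a
  one-base-shifted insert and are then handled by the gap-tolerant OTU
  matching.
- Cross-sample OTU matching is O(pairs) in the number of distinct
  sequences with different lengths; it is sized for exact-sequence OTU
  inventories (10³–10⁴ distinct sequences), not for 97%-style clustering
  of millions of variants.
- The duplicate filter counts raw strings including the sample tag, so
  identical templates sequenced in different samples do not protect each
  other from singleton removal; this mirrors counting "before clipping"
  and is why the generator's presence floor is 2 reads.
- A as n/N and the slope regression are computed in double precision;
  identities hold to rounding, not bit-exactly.
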