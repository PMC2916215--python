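# ampliturn

Seasonal turnover analysis for tagged amplicon time series, built around
the 454-pyrosequencing workflow: error-aware read preparation,
exact-sequence OTU tables, analytic rarefaction, and
occupancy/abundance/slope statistics that separate a persistent abundant
guild from a rare, seasonally restricted one. A synthetic-data generator
with full ground truth makes every stage testable without any sequencing
data.

## Who this is for

Microbial ecologists analysing amplicon time series (e.g. 18S SSU rRNA V3
fragments from freshwater protist communities) who want a reproducible,
seeded reimplementation of the classic 454 read-preparation and
rare-biosphere turnover statistics — and anyone who needs a ground-truthed
simulator of tagged pyrosequencing reads to validate such a pipeline.

## The model and statistics

Reads have the structure
`adapterA + 4bp tag + fwd primer + insert + rc(rev primer) + rc(adapterB)`.
Preparation demultiplexes on exact tags, requires mutation-free PCR
primers (one substitution or indel discards the read), locates adapter B
with a homopolymer-tolerant pattern (each run of length L may appear with
length 1..2L — the dominant 454 artefact), and then filters on four
criteria: no Ns; mean Phred quality > 24 over the clipped read;
primer-inclusive length ≥ 200 bp; and ≥ 2 exact copies of the raw read in
the whole dataset.

Within a sample every non-redundant sequence is an OTU (gaps treated as
informative); across samples two sequences are the same OTU when they
match at 100% identity with gaps disregarded (an alignment with zero
substitutions, i.e. the shorter is a subsequence of the longer).

For an OTU × sample table the package computes:

- **Analytic rarefaction** (Hurlbert): E[S_g] = Σ_i [1 − C(T−c_i, g)/C(T, g)],
  per sample and pooled, in log-gamma space.
- **Equal-depth subsampling**: each sample rarefied without replacement to
  the depth of the smallest sample (multivariate hypergeometric draw).
- **Occupancy statistics**: per OTU, occupancy N (samples where present),
  total reads n, and mean abundance when present A = n/N; per occupancy
  class, OTU counts compared by one-way ANOVA with Tukey's HSD.
- **Slope statistic m**: for OTUs with n > 10, the OLS slope of
  descending-sorted log10 counts against rank (m ≤ 0; steeper = stronger
  between-sample shifts), and the Pearson correlation between m and N.

## Worked example

```python
from ampliturn import CommunityDesign, ErrorModel
from ampliturn.pipeline import PipelineConfig, run_synthetic_analysis

design = CommunityDesign(seed=7)   # 10 samples, 300 persistent + 700
                                   # seasonal OTUs, 15 000 reads/sample
result = run_synthetic_analysis(design, ErrorModel(),
                                PipelineConfig(min_len=180, seed=7))

log = result.rejection_log
print(f"accepted {log.n_accepted}/{log.n_input} reads")
print(f"OTUs: {result.table.n_otus}, subsample depth: {result.depth}")
occ = result.occupancy
print(f"single-sample OTUs: {100 * (occ['N'] == 1).mean():.1f}%")
print(f"slope-occupancy Pearson r = {result.correlation.r:.3f}")
```

prints

```
accepted 86519/150000 reads
OTUs: 1268, subsample depth: 8517
single-sample OTUs: 41.3%
slope-occupancy Pearson r = 0.582
```

About 42% of the simulated reads are removed by clipping and the four
quality criteria (mutated primers, Ns, low quality, dataset-wide
singletons). Of the OTUs surviving equal-depth subsampling, 41% are
detected in a single sample — the rare, seasonally restricted guild —
while the positive correlation between the slope statistic m and
occupancy N (r ≈ 0.58) shows that OTUs present in more samples have
flatter, more stable abundance profiles.

The same pipeline is scriptable stage by stage:

```bash
ampliturn simulate --out sim/ --seed 7
ampliturn prep --reads sim/reads.fastq --layout sim/layout.yaml --out prep/ --min-len 180
ampliturn otu --inserts prep/inserts --out otu_table.tsv
ampliturn rarefy --table otu_table.tsv --out rarefaction.tsv --plot fig1.png
ampliturn turnover --table otu_table.tsv --depth auto --seed 7 --out turnover/
ampliturn morphotype --table otu_table.tsv --refs refs.fasta --out morph/
ampliturn run --config config.yaml       # everything, with a manifest
```

## Layout

- `src/ampliturn/simulate.py` — community + read simulator with ground truth
- `src/ampliturn/readprep.py` — demultiplex, clip, quality filter
- `src/ampliturn/otu.py` — dereplication and cross-sample OTU matching
- `src/ampliturn/morphotype.py` — reference-lineage affiliation
- `src/ampliturn/rarefaction.py` — Hurlbert rarefaction
- `src/ampliturn/turnover.py` — subsampling, N/n/A, ANOVA+Tukey, slopes
- `src/ampliturn/pipeline.py`, `cli.py` — orchestration and `ampliturn` CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
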