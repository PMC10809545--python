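# Methods

## Coordinate conventions

All in-memory intervals — chromosome split table (CST) chunks, presence
maps, labelled fragments, OCR regions — are 1-based inclusive, matching VCF
positions and the `chrom:start-end` interval strings variant callers accept.
BED files are converted at the boundary: `chr 4 5` (0-based half-open)
becomes the single base 5. A position equal to a chunk's end belongs to
that chunk, so chunk boundaries never orphan or double-assign a record.

## Genome Index Splitter

The chunk length is derived from the largest chromosome only and applied
uniformly: with largest length L and core budget m, the divisor is the
largest n ≤ m with n | L ("fair" equal chunks). When no divisor other
than 1 exists in range (a prime L) and m > 1, the splitter falls back to m
parts with chunk length ⌈L/m⌉ and an unequal final chunk — equal division
is impossible, and refusing the budget would waste cores. Ties for the
largest chromosome go to the first record in file order. Every chromosome,
nuclear or organellar, present in the index is chunked; excluding contigs
is the caller's job (filter the `.fai` first).

`read_cst` recovers the table's chunk length as the maximum chunk span:
this equals the length used to build the table whenever any chromosome
holds at least one full-size chunk, and degrades gracefully when every
chromosome is shorter than the chunk length (each is then a single
remainder chunk and any consistent bound validates).

A user-supplied fixed chunk length bypasses the divisor computation
entirely; fixed sizes from tens of kilobases to tens of megabases are the
practical operating range, trading scheduling granularity against per-job
overhead.

## Scatter, the reference combiner, and gather

Job manifests are pure string rendering: the command template must contain
`{interval}`, `{inputs}` and `{output}`, so the external combine/genotype
tool is entirely pluggable. The local executor (`run_local`) runs commands
sequentially or with a bounded thread pool and requires each output to be a
complete file before gather starts; cluster schedulers are out of scope.

The reference combiner implements union-site joint genotyping for explicit
per-site records: the output site set over an interval is the union of
in-interval per-sample sites, one genotype column per input sample, missing
(`./.`) where a sample has no record; ALT alleles are unioned per site and
genotype indexes remapped through allele strings. gVCF reference blocks are
**not** modelled — a sample without a record is "missing", not "homozygous
reference" — which is the correct reading of per-sample files that contain
only variant sites, and a documented approximation for true gVCF input.

Gather treats its guarantees as hard errors rather than repairs: a record
outside its declared chunk aborts (naming chunk and position), sample
columns must be identical across chunk files, and a duplicated
(chrom, pos, ref, alt) across chunks aborts unless first-wins
deduplication is explicitly enabled. Disjoint intervals can never produce
boundary duplicates, so a silent default dedupe would only mask upstream
interval bugs. Records are placed by POS alone; a deletion allele whose
span crosses a chunk boundary stays in the chunk containing its anchor
position.

## Hard filter

A site fails iff any of the six conditions holds, each a strict `<`
comparison: QUAL < 30, QD < 2, MQ < 20, MQRankSum < −3,
ReadPosRankSum < −3, DP < 5. Values exactly at a cutoff pass. A missing
annotation never fails its condition by default — rank-sum annotations are
undefined at sites with no heterozygous reads, and failing them would
discard precisely the well-behaved homozygous sites; `missing_fails=True`
inverts this for callers who want conservative behaviour. Failed-condition
codes are reported in a fixed order and written into FILTER (flag mode) or
used to drop records (pass-only mode); both modes exist because downstream
consumers differ on whether flagged records should survive.

SNP selection keeps a site iff REF and every ALT are single bases A/C/G/T;
multiallelic all-SNP sites are kept, and mixed SNP/indel sites are dropped
whole rather than allele-pruned, since pruning would require genotype
remapping with no principled treatment of the removed allele's carriers.

Because the filter is per-site, it commutes exactly with chunked
scatter/gather (verified as an invariant test): filtering the gathered
stream equals gathering per-chunk filtered streams.

## Pan-genome classification

Classification is a breakpoint sweep: the frame is fragmented at every
presence-interval start and end+1, each fragment's occupancy c is the
number of genomes covering it, and labels follow c out of N genomes — core
(c = N), dispensable (2 ≤ c ≤ N−1), specific (c = 1); c = 0 fragments are
unlabelled. Adjacent fragments are merged when **both** label and occupancy
match: merging on label alone would leave the occupancy column of the BED
output ill-defined across a dispensable run with varying c. Genome-absent
regions are computed per focal genome as fragments with zero focal coverage
and ≥ 1 other genome covering. Presence maps must arrive as disjoint sorted
intervals per genome; resolving overlapping raw alignment calls is upstream
of this package. The sweep costs O(k log k) in the number of interval
endpoints and is independent of genome length.

Gene groups use the same occupancy logic on membership sets: core
(|members| = N), private (= 1), dispensable (otherwise), and per-focal
"absent in a single genome" (= N−1, focal excluded).

## Population summaries

* **MAF** is the frequency of the second-most-common allele over
  non-missing called alleles (two per diploid call, one per haploid call).
  Missing calls are excluded from the denominator; a site with every call
  missing has no defined MAF and is reported as missing rather than 0.
* **Accession support** counts samples carrying ≥ 1 non-reference allele —
  heterozygous and homozygous carriers count identically, once each — and
  support validation reports the count and fraction of sites at or above a
  threshold (default 3 accessions).
* **Allele-status summaries** report counts and percentages per category
  (gene-absent plus one per allele label) over *all* accessions; the
  denominator includes gene-absent accessions. Percentages are computed in
  exact decimal arithmetic and rounded half-up to two decimals, so category
  percentages sum to 100.00 within ±0.02 of rounding slack.
* **Percentile tails** use nearest-rank selection: k = ⌈fraction × n⌉
  entries from each end of the score ordering, ties at the cut broken by
  site id for determinism; the two tails are returned as a union, so at
  n = 1 the single entry is selected once.

## Synthetic fixtures

Generators are deterministic: one integer seed plus a CRC32-derived stream
id per generator, so adding a generator never perturbs another's output.

* `synth_genome_index` defaults to 12 chromosomes of 20–45 Mb, the shape of
  a rice-class nuclear genome; tests use smaller frames.
* `synth_cohort` plants Binomial(L, rate) SNP sites per chromosome at
  uniform distinct positions. Site annotations are drawn per site and
  shared across carriers: QUAL ~ 20 + Exp(50), QD ~ N(10, 8) clipped at 0,
  MQ ~ N(30, 10) clipped at 0, both rank-sums ~ N(0, 2.5), DP ~ Poisson(7).
  These place every condition's failure mass in the 10–30% band (QUAL 18%,
  QD 16%, MQ 16%, rank-sums 11.5%, DP 17%), so both branches of every
  condition are exercised; a zero-centred rank-sum with unit variance would
  put only 0.13% of sites below −3 and leave that branch effectively
  untested, which is why the rank-sum scale is 2.5. Each site is carried by
  a random subset of samples (p = 0.5, at least one forced), het or hom-alt
  (p(hom) = 0.3). The truth table records annotations, the expected filter
  verdict (computed by independent spelled-out comparisons), and carrier
  counts. The generator does not emulate read-level errors, linkage,
  population structure, or gVCF blocks — passing tests demonstrate the
  bookkeeping and arithmetic are exact, not that the filter thresholds are
  well-calibrated for any real instrument.
* `synth_presence_maps` hits per-class base totals exactly by construction:
  the frame is linearised, rounded per-class totals are cut into blocks,
  shuffled, laid down contiguously, and each block is assigned to all / a
  random 2..N−1 subset / one / none of the genomes. Defaults
  (0.80, 0.15, 0.04, rest uncovered) mirror a crop pan-genome where ~80% of
  sequence is shared by every genome. The construction is the oracle: the
  classifier must recover the planted totals exactly.
* `synth_validation_manifest` crosses sampled insertions and deletions with
  query genomes, one row per (SV, query) pair.

## Problem sizes in the test suite

Tests run on synthetic frames of 50–600 kb and cohorts of ~100–1,000 sites
across 1–5 samples; the closed-form annotation checks use 10,000 sites, and
property suites draw hundreds of randomised cases (derandomised Hypothesis,
so runs are reproducible). The full suite completes in well under a minute
on one CPU. These sizes exercise every code path — boundary positions,
remainder chunks, empty chunks, missing genotypes — while the algorithms
themselves are O(n) or O(n log n) in records and interval endpoints and
scale to whole-genome inputs by construction.

## Known limitations

* The reference combiner is not a reimplementation of a production joint
  genotyper: no likelihood recomputation, no gVCF blocks, no spanning
  alleles.
* Gather detects duplicates only within a chromosome's record stream
  (sufficient for CST-shaped inputs, where chunks of one chromosome are
  contiguous in the file list).
* Indel filtering, genotype-level (FORMAT) filtering and VQSR-style
  recalibration are out of scope; the filter is site-level and SNP-focused.
* Region classification assumes pre-resolved disjoint presence intervals
  per genome and integer base resolution.
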