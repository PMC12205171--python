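# Methods

## Model

The engine treats an assembly as an explanation of its read set and
measures how much of the read set is explained, at which MAG quality
level. Inputs are the artefacts of an upstream pipeline: reads (FASTQ),
contigs (FASTA), read-to-contig alignments (PAF, 0-based half-open
coordinates), a contig→bin assignment, and per-bin completeness and
contamination estimates. All denominators come from the read set itself,
never from the alignment file, so reads absent from the PAF are unaligned
by definition.

### Tier classification

Bins are classified best-first with inclusive thresholds:
near complete (single contig, completeness ≥ 99, contamination ≤ 1),
high (≥ 90, ≤ 5), medium (≥ 50, ≤ 10), low otherwise. Because the
predicate sets are nested in completeness and contamination, best-first
evaluation equals picking the best satisfied predicate; the test suite
asserts this against an exhaustive oracle on the integer grid. The
single-contig gate uses the member-contig count from the bin map, since
CheckM2-style tables do not carry it. Contamination above 100 is legal and
not clamped. Unbinned contigs form a fifth category, ranked below low
quality (a contig in even a poor bin carries more signal than one in no
bin); unaligned reads form a sixth, used only for read accounting.

### Aligned read/base percentages

An alignment is *retained* when its length reaches the user threshold
(default 0 = keep everything). Length means query span
(`query_end − query_start`): the metric is about read sequence captured,
and the query span is robust to indels inflating the PAF block length; a
flag switches to block length. The threshold is inclusive (≥). Secondary
alignments (`tp:A:S`) count by default — "aligned to at least one contig"
is existential, and a read whose only placement is secondary is still
represented in the assembly — with a flag to restrict to primary.

Per read, retained alignments are bucketed by the tier of their target's
bin and each bucket's query intervals are merged (interval union), so
overlapping placements never double-count a base. The read is counted in
its best nonempty tier. Bases are attributed best-tier-first: each tier
receives only the bases not already claimed by a better tier, and the
remainder of the read is unaligned. This extends the read-level
highest-tier rule to bases in the unique way that preserves exact
conservation — category read counts sum to the total read count and base
counts to the total base count, which is what makes the stacked 100%
report bars meaningful. The per-base semantics are verified against a
brute-force oracle that labels every position of every read explicitly.

### Read partitioning

The aligned/unaligned FASTQ split uses the same retained-alignment
settings as the metrics, so "unaligned reads" means the same set in every
output. Records are copied verbatim (FASTQ, not FASTA, to keep qualities
for downstream read QC); `.gz` suffixes trigger gzip output.

### Median k-mer abundance

A read's abundance proxy is the median, over its k-mer windows, of each
window's canonical-k-mer count in the *full* dataset (aligned + unaligned
reads together). Canonical form is the lexicographic minimum of a window
and its reverse complement, making the statistic strand-independent.
Windows containing non-ACGT characters are skipped and tallied, matching
common counter behaviour. Default k = 27, a standard read-spectrum choice;
the value is a flag. For an even number of windows the median takes the
lower middle value — integral and conservative toward low abundance — with
an arithmetic-mean variant behind a flag. Counting is an exact hash table:
desk-scale datasets never need sketches, and memory grows with the number
of distinct k-mers (roughly the dataset size for error-free input).
Histograms share integer bins 1..max_bin plus one overflow bin; undefined
abundances (reads with no unambiguous window of length k) are excluded and
their count reported.

### Taxonomic resolution

Kraken2-style reports are parsed with parent links reconstructed from the
two-space indentation; containment invariants (children not exceeding
parents, no depth jumps) are enforced at parse time. *Rank resolution* of
a clade at a target rank is the percentage of the clade's reads whose
assignment sits at that rank or deeper: the sum of `direct_reads` over
subtree rows whose rank code is at or below the target on the ladder
R < D < K < P < C < O < F < G < S (suffixed codes such as P1 inherit the
base letter; no-rank rows belong to the subtree but never satisfy the
target). "At or deeper" is the default reading of "assigned at rank X";
an exact-rank mode is exposed as a flag since the phrase is ambiguous.
*Exclusive clades* applies a detection threshold (`clade_reads ≥
min_reads`) in each report before taking name-keyed set differences at a
fixed rank; names, not taxids, key the match because independently
generated reports need not agree on taxids.

## Synthetic samples

The generator emulates the artefact bundle of a real run with closed-form
truth: random contigs, bins with prescribed contig counts and quality
estimates (defaults span all four tiers: 99.5/0.5 single-contig, 95/2,
70/8, 30/15, plus two unbinned contigs), reads drawn as exact substrings
of contigs (kilobase lengths, a few per contig), a configurable count of
random unaligned reads, and the PAF written by the generator itself with
the true coordinates. A partial-coverage fraction shortens the alignment
of selected reads to a fixed fraction of their length, exercising the
unaligned-tail accounting. One `random.Random(seed)` stream drives
everything; a seed determines the bundle byte-for-byte.

What the fixtures do **not** model: sequencing error, chimeric or clipped
alignments, repeat-induced multi-mapping, abundance skew. Passing the
recovery tests therefore certifies the accounting — grouping, union,
tier attribution, conservation — not the behaviour of any aligner on real
data. The generator-side Kraken report writer computes clade counts as
subtree sums over a user-given profile and round-trips through the parser.

## Numerical choices

- All counts are integers end-to-end; percentages are derived at the edge.
- Display rounding to one decimal uses largest-remainder reconciliation so
  printed columns sum to exactly 100.0; TSV outputs keep full precision
  (`repr` of the float).
- Interval unions sort and sweep; touching intervals coalesce.
- Empty read set → error for percentage computations (undefined), while an
  empty alignment file is a valid input (everything unaligned).
- Test problem sizes (hundreds of random instances of ≤ 20 reads × ≤ 5
  contigs; 20-seed fixture sweeps) were chosen as the smallest scales at
  which every code path — multi-tier overlap, threshold filtering,
  secondary handling, partial coverage — is exercised; the whole suite
  runs in a few seconds.

## Limitations

- PAF is the alignment contract; SAM/BAM input would need conversion at
  the boundary (same half-open convention).
- Exact k-mer counting is memory-bound for multi-Gbp datasets; substitute
  an external counter upstream if needed — the median logic is unchanged.
- The highest-tier-per-base attribution is this package's design choice
  for base-level accounting under the read-level highest-tier rule; other
  evaluators may count overlapping bases differently (e.g. per alignment),
  which breaks conservation and inflates totals.
- Tier ordering LOW > UNBINNED is a convention; both categories are
  reported separately, so re-ordering would only change which tier a read
  aligned to both kinds of contig is counted under.
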