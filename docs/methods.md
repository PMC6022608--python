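# Methods

## The evaluation model

A binning assessment compares two partitions of a set of sequences
(contigs or reads): the gold standard Y, assigning every sequence to
the genome it came from, and a predicted binning X, assigning a subset
of the sequences to bins. The unit of assignment is the whole
sequence; sub-sequence (chimeric-contig) overlaps are out of scope.
All metrics are computed from the bin×genome contingency table
m_{x,y}, tallied in exact integer base pairs (and, in parallel, in
sequence counts), plus the unassigned tally U = gold base pairs in no
bin. Sequences in a query that do not appear in the gold standard are
excluded from evaluation with a counted warning — the metrics are
defined only over gold-standard content — and genomes removed by the
exclusion filter (e.g. viruses, plasmids) are treated as nonexistent,
never as unassigned.

## Bin-to-genome mapping

Each bin is mapped to exactly one genome; a genome may be mapped by
several bins or by none. Two criteria are provided:

- **majority overlap** (default): the genome contributing the most
  base pairs to the bin. Ties are broken toward the larger genome,
  then the lexicographically smaller genome id. The tie rule is a
  package choice (the criterion itself does not dictate one); it
  mirrors the fraction criterion's stated rule and makes results
  deterministic.
- **genome fraction**: the genome with the largest contained fraction
  m_{x,y}/|y|, compared as exact rationals. When several genomes are
  fully contained (fraction 1.0), the largest genome is mapped.

The mapping fixes per-bin TP/FP/FN and hence purity, completeness and
contamination. Size-weighted purity, size-weighted completeness and
accuracy always use the per-row/per-column maxima of the contingency
table — equivalent to the majority criterion — regardless of the
criterion selected for per-bin metrics, so switching criteria changes
only the per-bin and macro-averaged numbers.

## Numerical choices

- All ratios are formed in double precision from exact integer base-
  pair tallies; choose-2 sums for the ARI are exact integers and the
  final ARI is an exact `Fraction` converted to float once.
- The truncation rule for p̄_α sorts bins by evaluable size
  (ascending, ties by bin id), removes the smallest bins whose
  cumulative size stays within (100−α)% of the assigned base pairs,
  keeps the bin that straddles the threshold, and also keeps any
  removed bin equal in size to the smallest retained bin, so equally
  sized bins never straddle the cut arbitrarily. Truncation uses
  post-drop (evaluable) bin sizes for internal consistency. p̄ is
  summed in the same size order, making p̄_100 bit-identical to p̄.
- Standard errors use the unbiased sample standard deviation over the
  averaged set divided by √(set size); a single-element set reports 0.
- Degenerate ARI (fewer than two assigned items, or a zero
  chance-correction denominator): 1.0 if the two partitions of the
  assigned items are identical, else 0.0, logged either way. This
  preserves ARI = 1 for a perfect binning of a single genome.
- Empty binning (no evaluable sequences): purity is undefined; the
  summary reports every fraction as 0 with an `empty_binning` flag,
  and r̄ = 0 over n_r = number of genomes.
- Recovery bounds are strict (< contamination, > completeness); a
  genome counts once per threshold cell however many of its bins
  qualify.

## Defaults

| parameter | default | meaning |
|---|---|---|
| α | 99 | percentile for truncated average purity: the smallest bins totalling 1% of assigned bp are dropped |
| mapping criterion | majority overlap | bin-to-genome mapping for per-bin metrics |
| contamination bounds | 0.05, 0.10 | recovery-table thresholds (fractions) |
| completeness bounds | 0.5, 0.7, 0.9 | recovery-table thresholds (fractions) |

## Synthetic data

The generator emulates the structural features the metrics respond to:
genomes of varying sizes (uniform contig counts and contig lengths in
configurable ranges, defaults 5–20 contigs of 1–100 kb), and binnings
degraded from the perfect one-bin-per-genome solution by four error
modes applied in a fixed order — bin merges (underbinning), bin splits
(overbinning), per-sequence misassignment, per-sequence unassignment —
under a single seeded `numpy` generator, so identical specs give
byte-identical outputs and drop sets are nested across rates at a
fixed seed (which makes monotonicity testable). The fixed order keeps
expected-metric reasoning tractable: e.g. one merge yields exactly one
impure bin; unassignment at rate q leaves a Binomial(n, 1−q) assigned
count.

It does not emulate read-level noise, assembly chimerism, abundance or
coverage structure, or strain-level sequence similarity. Passing tests
therefore demonstrate the correctness of the metric computations on
partitions, not binner behaviour on real communities.

Test and acceptance problem sizes — instances of ≤30 sequences for the
pair-counting ARI oracle, 20–50 genomes for the null studies, 2,000
sequences for the degradation study — were chosen so the whole suite
runs in seconds while every code path and tie rule is exercised;
metrics are scale-free ratios, so small exact instances are as
probative as large ones.

## Design notes

- Reading the Bioboxes format is tolerant (any column order, `#`
  comments, case-insensitive header keys, gzip by magic bytes);
  writing is strict and sorted, so write→read→write is byte-identical.
- Duplicate sequence assignments are a hard error by default
  (`--keep-first` downgrades to a warning) because every metric
  assumes a sequence sits in at most one bin. A gold standard mapping
  one sequence to several genomes is likewise rejected.
- Lengths may come from FASTA/FASTQ files or from a `_LENGTH` column
  in the gold standard; when both name a sequence they must agree.
- Heat-map rows are bins sorted by true positives descending (ties:
  larger bin, then label); columns follow each row's mapped genome
  (first occurrence wins — repeated columns would break the
  column-sum-equals-genome-size invariant), with unmapped genomes
  appended by descending size; the last row holds per-genome
  unassigned base pairs. Cell values are raw base pairs; log scaling
  happens only at render time.
- The HTML summary is a static self-contained page (tables plus
  embedded images); if the plotting backend is unavailable the numeric
  TSVs are still written.

## Known limitations

- Taxonomic (TAXID-based) evaluation is out of scope; TAXID columns
  are carried through as metadata only.
- No marker-gene (reference-free) quality estimation: the tool
  requires a gold standard.
- Multi-sample aggregation is not built in; each gold standard is
  evaluated independently.
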