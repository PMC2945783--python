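# Methods

This note documents the models and procedures implemented in `phasemir`,
the parameters that matter, the synthetic-data generator's scope, and the
design decisions taken where the underlying procedure left genuine choices.

## Biological model

Plant miRNA precursors fold into stem-loop structures processed by
Dicer-like (DCL) RNase III enzymes. A single cleavage pair normally
releases one miRNA/miRNA\* duplex, but on long stems DCL enzymes can keep
cutting: each successive cut advances ~21 nt along the stem and releases
another duplex, each strand carrying the ~2-nt 3′ overhang that RNase III
activity leaves. The observable consequences in small-RNA sequencing data,
which this pipeline detects, are (i) read clusters beyond the annotated
miRNA/miRNA\*, (ii) cluster 5′ ends arranged in a ~21-nt register
("phasing"), possibly with empty slots where a product was degraded, and
(iii) cluster pairs across the stem with ~2-nt 3′ overhangs on both
strands. Such miRNA-like RNAs can occur between the miRNA duplex and the
loop (loop-side, "+"), between the duplex and the hairpin base ("−"), or on
both sides ("+/−") — the position classes reported per precursor.

## Pipeline stages and parameters

All coordinates in interfaces and reports are 1-based inclusive. T and U
are interchangeable on input; everything is U-normalized internally.

| Parameter | Default | Meaning |
|---|---|---|
| `min_read_len` | 17 nt | shortest read retained |
| `min_block_reads` | 5 | minimum total reads for a block to be reported |
| `overhang_tol` | 3 nt | how far a member read may extend past a block representative |
| `phase_len` / `phase_tol` | 21 / ±1 nt | dicing interval for phasing chains |
| `max_skip` | 1 | empty phase slots tolerated (gap 2·phase ± 2·tol) |
| `duplex_overhang` / `duplex_tol` | 2 / ±1 nt | expected 3′ overhang; "approximately two" is read as 1–3 nt |
| `star_fold` | 5 | duplex count ratio at which the minor strand is a star |
| `mismatch_penalty` / `wobble_penalty` | 1.0 / 0.5 | target-scoring penalties |
| seed region | sRNA positions 2–7 | penalties doubled here |
| `score_cutoff` | 4.5 | maximum penalty for a reported target site |
| `pvalue_cutoff` | 0.2 | degradome support threshold |
| `min_loop` | 3 nt | smallest hairpin loop in the fallback fold |

### Read processing

Adapter trimming removes from the leftmost position where the full adapter
occurs anywhere or a ≥ 6-nt adapter prefix runs through the read's 3′ end;
untrimmed reads are kept, as they may be adapter-free inserts. Blacklist
filtering is exact-substring against the supplied structural RNAs, checked
on both strands — consistent with the zero-mismatch regime used for
mapping. Mapping reports every exact occurrence on the sense strand of
every precursor; multi-locus reads are counted fully at each locus with
`n_loci` recorded, since per-precursor tallies (not genome-unique
fractional counts) are what the block statistics consume.

### Block building

Greedy, most-abundant-first: the highest-count unassigned hit seeds a
block and becomes its representative; every unassigned hit lying within
the representative's span ± `overhang_tol` joins it; repeat. Ties between
equal-count seeds break by smaller start, then shorter read, then
lexicographic sequence, making the partition invariant to input order. A
hit joins exactly one block, so block totals partition the mapped reads.

**Spanning filter.** A block straddling the junction between two
neighboring blocks is an artifact of reads bridging two real products and
is discarded. The operational rule here: a block is spanning when it
overlaps (≥ 1 nt) two distinct non-overlapping blocks *each at least as
abundant as itself*. The abundance qualifier is this package's design
choice: without it, any well-expressed product block flanked by one-read
degradation clusters on both sides would be classified as spanning and
removed, which inverts the filter's purpose. The spanning filter runs
before the minimum-read filter.

### Phasing

Phasing is defined by consecutive-gap chaining, not a significance test:
blocks sorted 5′→3′ are chained while each consecutive start-to-start gap
is `phase_len ± tol`, or one skipped slot (`2·phase_len ± 2·tol`) when
`max_skip ≥ 1`. Chains are maximal and greedy from the 5′-most unassigned
block; a block belongs to at most one chain; singletons are dropped. Each
member's register deviation is reported relative to the chain's first
block. A chain may legitimately continue across the loop onto the 3′ arm,
where partner products sit in (approximately) the same global register.

### Duplex calling

Partner regions are read off the pair table (supplied dot-bracket taking
precedence over the fallback fold), so bulged stems are handled without
arm-coordinate arithmetic. A block needs ≥ 50% of its bases paired to have
a usable partner region; loop blocks therefore drop out naturally. Two
blocks form a candidate duplex when each span overlaps the other's partner
region by ≥ 50% of its own length, and both 3′ overhangs — the number of
3′-end nucleotides extending past the position paired with the partner's
5′ end (nearest paired base, offset-corrected, when the 5′ end itself is
unpaired) — are within `duplex_overhang ± duplex_tol`. Each block joins at
most one duplex; candidates with overhangs closest to the expected value
win, ties going to the more abundant pairing.

### Naming

The annotated miRNA/miRNA\* duplex takes index 1. New duplexes and orphan
blocks share a single 5′→3′ ordering by 5′-most coordinate and receive
indices 2, 3, … in that order — so a duplex whose arms bracket an orphan
yields names like `.2-5p`, `.3`, `.2-3p` along the precursor. The
`star_fold` threshold of 5 is configurable; published naming choices are
not perfectly consistent with any single threshold, so suffix agreement
with external catalogs is not asserted by the tests. When no annotation
exists, the most 5′ duplex is promoted to `.1` with a warning, keeping the
numbering scheme total.

### Target scoring and degradome signatures

Scanning is ungapped: only mismatch and wobble penalties are defined, so
bulged alignments are out of scope (a deliberate simplification relative
to full degradome packages). The score is a penalty (lower = better) and
the 4.5 cutoff is a maximum. The predicted cleavage position is the
transcript nucleotide paired with sRNA position 10 (slicing between
positions 10–11). The degradome p-value is a transparent rank statistic:
the fraction of nonzero-count transcript positions whose count is ≥ the
count at the cleavage site; 1.0 when the site has no signal. It is
deliberately simple and conservative — ties give high p-values — and the
0.2 support threshold applies to this statistic.

## Synthetic data: what it emulates, and what it does not

`make_hairpin` builds a perfect-complement stem (3′ arm = reverse
complement of a random 5′ arm; default arm 70 nt, loop 8 nt, GC 0.5), so
overhang arithmetic is exact and oracle-checkable. `simulate_dicing` lays
`n_duplexes` (default 3) duplexes from a fixed entry point 3 nt from the
base, advancing 21 nt per cut, partners placed for exact 2-nt 3′ overhangs.
Product abundances are log-normal(0, 1.5), mimicking the orders-of-
magnitude spread seen in real per-product read counts. `sample_reads`
draws `depth` (default 2000) reads: each is background with probability
`background_rate` (default 0.05; a uniform random 17–25-nt precursor
substring, so background maps and genuinely stresses the block and
spanning filters), otherwise a product read whose ends are independently
shifted ±1–2 nt with probability `end_jitter_prob` (default 0.1). All
draws are deterministic given (config, seed).

Not modeled: bulged or imperfect stems, sequencing errors, and
ligation/PCR bias. Passing the recovery tests therefore shows the
pipeline's correctness under idealized stem geometry and honest sampling
noise — not robustness to bias or to structurally messy precursors, where
real data can behave differently.

**Recovery definition.** A simulated product is *detectable* when at least
`min_block_reads` (5) sampled reads fall in its neighborhood; with
log-normal abundances a small tail of products receives fewer than 5 reads
at depth 2000 and is excluded from the pipeline's output by the read
cutoff itself, by design. Recovery rates are therefore quoted over
detectable products (the raw denominator is also computed in the tests'
machinery); at the default noise settings recovery is ≥ 95% and noise-free
libraries recover every detectable product with 5′ ends within 1 nt.

## Numerical and degenerate-input choices

- The fallback fold maximizes pair count (Watson–Crick + G:U) by interval
  dynamic programming with a deterministic traceback: the 5′-most position
  pairs whenever pairing attains the optimum, taking the 3′-most optimal
  partner. It is a structural convenience, not a thermodynamic model, and
  a supplied structure always takes precedence.
- Empty inputs return empty outputs everywhere except
  `first_nt_fractions`, which raises (a composition over zero records is
  undefined).
- Ambiguous nucleotides score as mismatches in target scanning.
- Blocks on structures with multiple hairpin loops use the 5′-most
  innermost loop as the arm divider; multi-loop precursors are outside the
  intended scope.

## Packaged catalog

`data/mirna_like_catalog.tsv` transcribes the published summary of 19
Arabidopsis precursors (10 families) bearing 35 miRNA-like RNAs, with read
counts, AGO associations (AGO1/2/4/5/7 immunoprecipitation libraries), and
degradome-supported targets. Transcription notes are in the file header.
`catalog_stats` recomputes all catalog-level numbers (counts, first-
nucleotide composition, AGO association, position classes, abundance
ratios) from the table at run time; none are hard-coded.

## Known limitations

- Genome-scale pre-filtering (mapping reads to a genome before precursor
  mapping) is not implemented; reads map directly to the supplied
  precursors. With deeply sequenced, adapter-clean input the block
  composition is expected to match, but this is untestable without a
  genome.
- The phasing call is a deterministic chaining rule, not a p-value; use a
  dedicated phasing statistic if significance is needed.
- Ungapped target scanning misses bulged target sites.
- Per-library normalization and differential-expression analysis are out
  of scope; counts are raw.
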