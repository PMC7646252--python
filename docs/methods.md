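# Methods

## Cassette model and Cre event mechanics

The recombination substrate is an alternating token list: `n + 1` oriented
34-nt loxP sites enclosing `n` oriented, identified spacer segments (default
`n = 9`, site orientations strictly alternating `+,-,+,-,...`, i.e. five
converging pairs). Cre events act on a site pair `(i, j)`:

- **Inversion** (opposite orientations): tokens strictly between the sites are
  reversed in order and orientation-flipped; the boundary sites stay.
  Inversions are involutions.
- **Excision** (same orientation): tokens strictly between the sites are
  deleted together with one boundary site; one site of that orientation
  remains at the junction. Excisions are irreversible.

These are the standard Cre-loxP mechanics; the package commits to them
explicitly because the reachable barcode space and all simulation outputs
depend on them. A *barcode* is the oriented-segment sequence of a state with
the loxP sites dropped, rendered canonically as e.g. `1-4R-9` (`R` =
inverted) or `EX` for the empty arrangement, because sequencing distinguishes
products only by their spacer-block arrangement.

### Barcode-space enumeration

`enumerate_barcodes` computes the exact closure of the intact state under all
legal events. States are encoded as small integer rows (sites as sign bits,
segments as signed ids) and expanded level by level (level = segment count;
inversions stay within a level, excisions feed lower ones) with vectorised
numpy column arithmetic; visited sets are 64-bit keys combining the segment
arrangement and the site-orientation bits. The 9-segment alternating design
closes in about a minute on one core. Tests verify the result against an
independent, naively implemented tuple-set BFS on small designs, and check
that the closure is independent of exploration order.

### Recombination draw

`simulate_recombination` applies a Poisson(lambda) number of sequential
events (default lambda = 2, a short induction pulse yielding a handful of
events). Events are sampled proportionally to a configurable weight; the
default `SpanBias` assigns `exp(-beta * (j - i))` (beta = 1) with per-kind
multipliers, so short-range events dominate. This reproduces the qualitative
observation that a limited set of products is strongly over-represented,
without claiming measured kinetics, which are not available.

## Synthetic experiments

`simulate_experiment` emulates the wet-lab design end to end:

- **Founders.** Each founder carries one cassette integration (the low-MOI,
  single-integration design) with a UCI drawn from a library of distinct
  random 10-mers (default 5,000) with log-normal abundance weights
  (sigma = `uci_skew`, default 1). Founder UCIs are drawn without replacement
  by default (`unique_founder_ucis`), matching the regime in which the
  downstream statistics are meaningful; replacement draws are available for
  studying UCI collisions.
- **Timestamp.** Each founder's cassette is recombined once, at induction.
  With `induction_time="day0"` no lineage is committed at induction: every
  cell samples its terminal lineage independently from the global
  proportions, so all lineages share the founder pool. With `"day8"` the
  committed lineages (default `{PGC}`) are assigned to founders *before*
  barcoding: committed founders produce only their lineage, the rest only
  somatic lineages. Default terminal proportions are EN 0.25, S.Ect 0.20,
  MES 0.30, BP 0.13, PGC 0.12 — a single fixed choice giving every terminal
  EB population enough mass (>= ~10%) for pairwise sharing statistics to be
  estimable at moderate cell numbers.
- **Expansion.** Clones expand to a fixed per-founder cell count
  (default 50). A branching pedigree is deliberately not modelled: every
  downstream statistic depends only on which cells share a timestamp, not on
  pedigree depth.
- **Reads.** Each cell yields a negative-binomial number of reads
  (mean 50, size 10; a `None` dispersion gives exactly the mean), each read
  being the cell-barcode construct (20-nt flank + 12-nt barcode + 24-nt
  flank) followed by the rendered cassette. Amplicons outside the size
  window (default 700-2500 bp, the published purification window) are
  dropped before sequencing. Reads are strand-flipped uniformly, then
  noised: per-base substitution/insertion/deletion (defaults
  0.02/0.03/0.04), and with probability 0.1 truncated at a uniform position
  (prefix kept). Cross-contamination replaces a read's embedded cell barcode
  with another sampled cell's barcode (default rate 0.02). The noise and
  contamination defaults are plausible nanopore-era placeholders, exposed in
  `SimConfig`, not asserted as measured values.
- **Sequences.** Segment and flank sequences are synthetic, generated from a
  design seed with pairwise edit distance >= 10 so block mapping is
  unambiguous (the real block sequences are not published in a reusable
  form). Default lengths: 140-nt spacers, 550-nt pBC00 terminal block,
  74-nt M13F, 104-nt WPRE_M13R_HSV composite. With these choices the fully
  excised product is ~830 bp and the intact product ~2.4 kb, so both ends of
  the recombination spectrum survive the 700-2500 bp window — mirroring the
  real design, whose published intact/fully-recombined lengths are treated
  as metadata because the true component sequences are unavailable.

**What the generator does not emulate:** basecalling from raw signal,
homopolymer-structured error profiles, chimeric template switching, PCR
jackpotting, doublets, or the RNA arm of the protocol (lineage labels are
consumed as a table). Passing tests therefore demonstrate correctness of the
computation under an idealised nanopore error model, not performance on any
particular real flow cell.

## Barcode calling

Per read: (1) the read is re-oriented so the pBC00 terminal block lies on the
forward strand; (2) the cell barcode is assigned by aligning whitelist
flank-barcode-flank constructs (edit distance, both strands, unique best hit
within `cb_max_edits` = 8 of 56 nt; ties and misses are unassigned but
counted in QC); an anchor alignment of the shared flanks restricts the
per-entry search to a window, which is equivalent to the full scan for
well-formed reads and ~100x faster; (3) every reference block is matched on
both strands (edit distance <= 25% of block length — random-sequence nulls
sit near 45%, so the margin is wide), overlapping hits resolved to the
higher score; (4) the Polylox string is read off the position-sorted spacer
hits (hit strand = segment orientation), with duplicate spacer hits
discarding the read as chimeric, and `full_length` set when both terminal
flanks enclose the block run; (5) the UCI is the sequence between the M13F
and WPRE flanks, accepted at length 10 +- 2 (nanopore indels around a
10-mer).

Per cell, the most frequent candidate is called iff it passes all three
filters: detected in **more than 30 reads** (strict, per the published
wording); an **upper outlier** among the cell's candidate counts; and
(Polylox) observed **full length** in at least one supporting read
(configurable to majority) / (UCI) membership of the plasmid-library
whitelist. A timestamp is emitted only when both components pass; failing
cells keep their row with the failing filters named.

Numerical choices worth recording:

- **Outlier rule.** The published pipeline requires the top count to be "an
  outlier in statistics" without defining the statistic. The package uses
  Tukey's upper fence (Q3 + 1.5 IQR) of the *other* candidates' counts when
  there are >= 4 candidates, falling back to a dominance ratio top/second
  >= 3 (second = 0 passes) below that. Both constants are configurable; the
  rule is scale-free and matches the intent ("much more than other
  barcodes") but is a declared reconstruction, not the original rule.
- **UCI whitelist correction.** At the default error rates only ~40% of
  10-nt inserts are read error-free, so counting raw inserts would starve
  the >30-read filter at 50 reads/cell. Observed UCIs are therefore
  corrected to their unique whitelist neighbour within 2 edits before
  counting (ambiguous or distant inserts stay raw and simply fail the
  whitelist filter). Radius 2 keeps corrections essentially unambiguous in a
  5,000-entry library of random 10-mers; radius 3 would collide with ~30
  neighbours per entry.
- **Ties** at the top candidate are broken lexicographically for
  deterministic reporting; a tied top count always fails the outlier filter,
  so tie-breaking never creates a call.
- Coordinates are 0-based half-open; strands are `+`/`-`; all alignment is
  unit-cost edit distance (edlib).

## Clonal frequency filter

Component frequencies are relative frequencies of each called Polylox and
each called UCI among called cells, per EB when an EB mapping is given,
pooled otherwise (a read-weighted mode is available because the published
description is ambiguous between cells and reads; cells are the default).
The timestamp frequency is the **product** of the component frequencies —
the generation of the arrangement and the draw of the UCI are independent
events — and the empirical pair frequency is emitted alongside for
diagnostics. Cells whose timestamp frequency **strictly exceeds** the cutoff
(default 0.005) are excluded; the report covers the sweep
{1/1000, 3/1000, 5/1000, 1/100}. Filtering with a fixed frequency table is
idempotent; recomputing frequencies on a filtered table changes denominators
and is deliberately not hidden from the caller.

## Lineage linkage

Filtered calls are inner-joined with confident lineage labels. An edge
connects every unordered pair of cells with an identical timestamp; a
barcode is *shared* when >= 2 cells carry it. Coupling statistics:

- **Spearman correlation** between per-lineage count vectors over shared
  barcodes (undefined correlations from constant vectors are reported as
  missing, not zero).
- **Observed/expected enrichment**: for each unordered lineage pair, the
  observed cross-pair edge count against the mean over `n_perm = 1000`
  label permutations (barcode assignments fixed). The permutation null was
  chosen because the published enrichment procedure is named but not
  defined; it preserves clone sizes and lineage totals. The p-value is the
  add-one-corrected two-sided tail of the absolute deviation from the
  permutation mean; Benjamini-Hochberg q-values are reported across pairs.

Permutations are fully vectorised (edge endpoints as index arrays, pair
codes via bincount), so 1000 permutations over ~10^6 edges take seconds.

## Determinism and problem sizes

All pipeline randomness derives from one seed through named per-stage
substreams (`stage_rng`), and two runs with identical config and seed
reproduce every output file byte for byte (checked in the tests).

The test-suite and acceptance-script problem sizes are the package's own
choices: recovery experiments use 200 cells x 50 reads (above the >30-read
filter with margin, and matching the read depth at which UCI detection
saturates); linkage experiments use 1,000 founders x 50 cells without read
generation, which gives the permutation null a Monte-Carlo spread of ~2% so
the obs/exp calibration band is meaningful.

## Known limitations

- The reconstruction of the outlier rule and of the enrichment null are
  declared substitutes for procedures the source pipeline does not specify.
- Real amplicon component lengths/sequences are not recomputable from public
  information; synthetic sequences preserve the architecture, not the bases.
- The error model is i.i.d. per base; structured nanopore errors
  (homopolymers, strand bias) will degrade recovery relative to the rates
  quoted here.
- Multi-integration cells (MOI violations) and doublets are out of scope;
  one cassette per founder is assumed throughout.
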