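# Methods

This note documents the algorithms, exact threshold semantics, tie-break
rules, and numerical choices in `phylocurate`, plus the design and limits
of the synthetic benchmark generator.

## Data model

An orthologous group (OG) is a rectangular amino-acid alignment whose
members carry headers of the form `taxon|seqid`. The alphabet is the 20
standard residues plus `X` (ambiguity — treated as a *residue*, never as
missing data) and `-` (gap); `?` and `.` on input are normalized to `-`.
All coordinates in reports are 0-based half-open `[start, end)`; partition
coordinates in the supermatrix outputs are 1-based inclusive, following
the RAxML convention.

Every filter returns both the filtered data and a `FilterReport` listing
removed sequences, removed OGs, masked segments, and removed columns, each
with a reason string. The pipeline aggregates these into `filter_report.tsv`
and `manifest.json`, and verifies the bookkeeping identity
`input_sequences = survivors + removed + sequences_in_removed_OGs`.

## Threshold semantics

All thresholds are strict in the direction their wording implies, and the
boundary value survives:

| filter | rule | boundary behaviour |
|---|---|---|
| `min_length` = 100 | delete if non-gap residues < 100 | 100 kept |
| `min_taxa` = 35 | discard OG if distinct taxa < 35 | 35 kept |
| `max_change` = 75.0 | delete if % mismatch vs consensus > 75 | 75.0 kept |
| `review_change` = 50.0 | flag (not delete) if 50 < change ≤ 75 | — |
| `max_island` = 20 | mask run if length ≤ 20 | 21 kept |
| `min_flank` = 10 | flank must have ≥ 10 consecutive gaps | 10 qualifies |
| `min_column_occupancy` = 4 | delete column if non-gap < 4 | 4 kept |
| `min_aln_length` = 50 | discard OG if columns < 50 | 50 kept |
| `min_overlap` = 20 | pair must share ≥ 20 non-gap columns | 20 passes |
| `collapse_support` = 50 | collapse node if support < 50 | 50 kept |

## Per-sequence filters

**Deduplication.** Sequences are compared after gap stripping; identical
sequences from the same taxon are collapsed to the first occurrence
(cross-taxon deduplication is off by default, configurable).

**Terminal-X trimming.** For each end, the 20 *residues* (gaps excluded)
nearest that end form the terminal window. If any `X` lies in the window,
everything from the innermost such `X` through the end is masked to gaps.
Masking can pull a previously interior `X` into the window, so the pass is
iterated to a fixpoint; this makes the filter idempotent, which the test
suite asserts directly.

**Consensus and the change filter.** The consensus is the per-column
majority character over `{20 AA, X, Y…}` (gaps excluded; an all-gap column
has consensus `-`); ties break alphabetically, which is arbitrary but
deterministic. A sequence's *change* is the percentage of its own non-gap
positions that differ from the consensus (the denominator is the sequence,
not the alignment; configurable). The consensus is computed once from the
input alignment, so the outcome does not depend on removal order. Column
counts are accumulated with a vectorized `numpy` histogram per column.

**Overlap filter.** Pairwise non-gap co-occurrence counts are computed as
a boolean matrix product (`present @ present.T`). While any pair overlaps
by fewer than `min_overlap` columns, the failing sequence with the fewest
residues is deleted (tie: the one appearing later in the alignment), and
overlaps are recomputed — the iterative fixpoint mirrors the definition,
and a brute-force loop simulation is used as a test oracle on 500 random
instances. Alignments with a single member are left untouched.

## Alignment-level filters

**Island masking.** A candidate island is a maximal run of non-gap
characters of length ≤ `max_island`. It is masked when each side has
either ≥ `min_flank` consecutive gaps or (with `ends_count_as_flanks`,
the default) a gap block that runs to the alignment boundary; a run that
directly touches a boundary with zero gaps on that side is never masked,
since nothing separates it from the sequence proper. A single pass is
provably idempotent (masking converts islands to gaps and can only enlarge
flanks, and enlarged runs are re-examined in the optional cascade mode).

**Sparse columns** returns an old→new column map so segment coordinates
remain interpretable. **Minimum alignment length** and **minimum taxa**
act on whole OGs; the taxon filter runs both before the expensive
per-sequence stages and again afterwards, because sequence removal can
drop an OG below threshold.

## Paralog pruning

Input: an (unrooted) gene tree over the OG's sequence labels, with
bootstrap supports on internal nodes. Supports below `collapse_support`
are first contracted into polytomies (children are spliced into the parent
at the original position, preserving a deterministic leaf order).

For each taxon with > 1 sequence, monophyly is tested against the tree's
edge bipartitions (a set of copies is monophyletic on an unrooted tree iff
it equals one side of some edge, or the complement, or the full leaf set).

* **Monophyletic (inparalogs):** keep the copy with the most residues;
  tie → lexicographically smallest label. A node whose children mix two
  taxa (a "mixed polytomy") is *not* monophyletic for either taxon.
* **Non-monophyletic:** consider every edge bipartition, restricted to the
  leaves remaining after inparalog resolution. Among sides containing no
  duplicated taxon, keep the best by (most distinct taxa, most leaves,
  greatest total residue length, lexicographically smallest sorted label
  tuple); all other sequences are dropped as `paralog_pruned`.

The exhaustive edge scan is quadratic in leaves but gene trees are small;
determinism is guaranteed by the total tie-break order. Implementation
uses `dendropy`; the test suite re-derives the whole procedure on
`scikit-bio` trees as an independent oracle across 500 random multi-copy
trees. In the full pipeline, an OG with duplicated taxa but no supplied
tree is a hard error rather than a silent skip.

## Concatenation and occupancy

OGs are sorted by ID and concatenated over the sorted union of their taxa
(or a caller-supplied taxon universe); absent taxa receive all-gap blocks.
`matrix_stats` reports `pct_missing` as the percentage of gap cells over
`taxa × columns` (`X` counts as present). An alternative
`absent_taxon` definition counts only whole missing gene blocks. Both are
checked against a naive cell-by-cell recount to 1e-10 relative tolerance,
also at a realistic published-matrix scale (257 partitions, 54,596
columns, 49 taxa).

## Synthetic generator and scoring

`simulate_dataset` draws, per OG, an ancestor sequence (uniform over the
20 residues) and per-taxon descendants under iid per-site substitution
with probability `divergence` (uniform over the other 19 residues), so two
clean sequences mismatch with probability `2d(1−d) + d²·18/19` — verified
against the closed form in the tests. Taxon presence is iid Bernoulli
(`occupancy`). Artifact classes per sequence — `contaminant` (an
independent random sequence of the same length), `inparalog_extra` (a
second, extra-diverged copy for one taxon), `fragment` (a short
subsequence) — and segment artifacts on clean sequences — `island`
(a short run isolated by ≥10-gap flanks, kept ≥25 columns from the ends)
and `terminal_x` (an `X` placed within a terminal window) — are all
recorded in a `TruthLabels` object. One `numpy` `default_rng(seed)` stream
drives everything, so datasets are bit-reproducible.

`score_recovery` maps each artifact class to the stage expected to catch
it (fragment→`min_length`, contaminant→`change`, island→`islands`,
terminal_x→`xtrim`, inparalog_extra→`prune`). *Recall* credits removal by
the expected stage, by any other sequence-level stage, or by whole-OG
discard (the artifact is gone from the matrix either way). Segments match
when they overlap reciprocally by ≥ 50%. *Precision* is computed per
expected stage and is `None` (not 0) when that stage removed nothing.
Inparalogs are excluded from end-to-end synthetic runs by default
(`p_inparalog = 0`) because pruning requires externally inferred gene
trees; the pruner is exercised on constructed fixtures and random trees
instead.

## Limitations

* The generator's star phylogeny and iid substitution model are
  deliberately simple: they calibrate the *filters*, not phylogenetic
  inference. Real data have rate heterogeneity, indel structure from the
  aligner, and correlated missingness.
* Default thresholds are aggressive for small simulated datasets
  (`min_taxa = 35` discards most OGs at 90% occupancy with 40 taxa); they
  are tuned for transcriptome-scale inputs and are fully configurable.
* The consensus tie-break (alphabetical) and the overlap-victim tie-break
  (later input position) are conventions chosen for determinism, not
  biological claims.
* Alignment and gene-tree inference are out of scope; the pipeline
  consumes aligned FASTA and Newick produced by external tools.
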