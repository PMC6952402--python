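# phylocurate

Curation of amino-acid orthologous-group (OG) alignments into a partitioned
phylogenomic supermatrix.

Multi-gene ("phylogenomic") phylogenetics concatenates hundreds of
single-copy protein alignments into one matrix. The raw OGs produced by
orthology clustering of transcriptome data are contaminated in predictable
ways: mis-assigned (xenologous or misassembled) sequences, short spurious
fragments, mistranslated stretches near sequence ends, short mis-aligned
"islands" of residues stranded inside long gap regions, and lineage-specific
duplicates (inparalogs) that violate the single-copy assumption.
`phylocurate` implements a deterministic, fully audited filtering cascade
that removes these artifacts, selects single-copy representatives using gene
trees, and emits a concatenated supermatrix with a partition table and
occupancy statistics. Every residue that is deleted or masked is recorded in
a machine-readable report, and the pipeline maintains an exact bookkeeping
identity: *input sequences = surviving sequences + individually removed
sequences + sequences inside discarded OGs*.

## The filtering rules

Per sequence (within each OG alignment; `X` is an ambiguity residue and
counts as a residue, `-` is a gap; `?` and `.` are normalized to `-`):

1. **Minimum length** — delete sequences with fewer than 100 non-gap
   residues (exactly 100 is kept).
2. **Deduplication** — among identical unaligned sequences from the same
   taxon, keep the first.
3. **Terminal-X trimming** — if an `X` occurs within the 20 terminal
   residues of either end, mask from the innermost such `X` through that
   end; iterated to a fixpoint so the filter is idempotent.
4. **Divergence ("change") filter** — delete sequences differing from the
   OG consensus at more than 75% of their residues (exactly 75% is kept).
   Sequences between 50% and 75% are flagged for review, not deleted.
5. **Minimum pairwise overlap** — iteratively delete the sequence with the
   fewest residues among those sharing fewer than 20 aligned non-gap
   columns with some other member, until all pairs overlap by at least 20.

Per alignment:

6. **Island masking** — replace with gaps any maximal run of at most
   20 non-gap residues flanked on both sides by at least 10 consecutive
   gaps (runs touching the alignment ends are masked when the gap block
   on the inner side qualifies; a run with no terminal gaps is kept).
7. **Sparse columns** — delete columns with fewer than 4 non-gap
   characters (exactly 4 is kept).
8. **Alignment length** — discard OGs shorter than 50 columns after
   column filtering (exactly 50 is kept).
9. **Taxon occupancy** — discard OGs with fewer than 35 distinct taxa
   (applied both before and after the sequence filters); optionally
   discard OGs missing a designated focal taxon.

Paralog pruning (when gene trees are supplied): nodes with bootstrap
support below 50 are collapsed (exactly 50 is kept), then for each taxon
with multiple sequences the tree is inspected. If the taxon's copies are
monophyletic (inparalogs), the longest copy is kept. Otherwise the tree is
cut on the edge whose single-copy side retains the most distinct taxa
(ties broken by leaf count, then total residue length, then sequence
labels), and everything outside that side is dropped.

Surviving OGs are concatenated taxon-by-taxon (absent taxa padded with
gaps) into a supermatrix with a RAxML-style partition file, per-taxon
occupancy, and a percent-missing statistic.

## Worked example

The package ships a labelled synthetic data generator, so the whole
pipeline can be exercised without external data:

```bash
curate simulate --out sim --seed 7     # 50 OGs, 40 taxa, known artifacts
cat > config.yaml <<'YAML'
input_dir: sim/ogs
output_dir: curated
thresholds:
  focal_taxon: t01
YAML
curate run --config config.yaml
```

Output (seed 7, default thresholds):

```
stage             seqs_removed  ogs_removed  segments  columns
min_length                   0            0         0        0
min_taxa                   364           11         0        0
dedup                        0            0         0        0
xtrim                        0            0       127        0
change                     152            0         0        0
islands                      0            0       249        0
columns                      0            0         0        0
min_aln_len                  0            0         0        0
min_overlap                  0            0         0        0
min_taxa_post              960           30         0        0
focal                       70            2         0        0
final matrix: 7 genes totalling 1699 amino acids, 40 taxa, 14.73% missing data
```

`curated/` then contains `supermatrix.fasta`,
`supermatrix.partitions.txt` (`AUTO, og0000 = 1-292`, …),
`supermatrix.stats.json`, `supermatrix.occupancy.tsv`, the full
per-residue `filter_report.tsv`, and a `manifest.json` recording the
configuration fingerprint, per-stage counts, and the bookkeeping identity.
Re-running the same configuration reproduces every output byte-for-byte.

The same workflow is available programmatically:

```python
from phylocurate import SimParams, simulate_dataset, curate_dataset, FilterThresholds

ogs, truth, _ = simulate_dataset(SimParams(seed=7))
result = curate_dataset(ogs, FilterThresholds(focal_taxon="t01"))
print(result.manifest["matrix_stats"])   # {'n_taxa': 40, 'n_genes': 7, ...}
```

`curate prune` runs tree-based paralog pruning on a directory of OGs plus
matching Newick trees, `curate stats` recomputes occupancy statistics from
any supermatrix FASTA, and `curate thresholds` prints the default
thresholds.

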