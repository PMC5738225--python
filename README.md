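# repeatscape

Repetitive-landscape analysis for large plant genomes: segment-based
transposable-element (TE) annotation with explicit merge/bridge rules,
copy-number and chromosomal-niche statistics, gene-space association
analyses, TSS/TES-anchored metaprofiles, target-site preference matrices,
windowed bisulfite-methylation comparisons — plus a synthetic
genome/methylome simulator with full ground truth, so the whole pipeline is
testable offline.

## Pipeline overview

| module | what it does |
| --- | --- |
| `io_formats` | FASTA / GFF3 / BED / methylation-table readers & writers, domain types, flat config |
| `synthetic_data` | genome, gene, TE-library, planted-copy and methylome simulation with a `TruthSet` |
| `te_annotation` | 180 bp segmentation, k-mer seed + x-drop ungapped search, merge/bridge (<100 bp gaps; ≤80 bp N-gap extension), full-length detection, 80/80 family assignment, consensus building, ORF-based autonomy calls |
| `repeat_landscape` | copy numbers (total bp / consensus length), genome fractions, 20–40 Mb bin distributions, terminal-arm enrichment, per-chromosome contrasts |
| `gene_space` | gene clustering (<20 kb gaps) with a random-placement null, TE–gene distances, island vs ≥200 kb intergenic composition, orientation bias (χ², df=1) |
| `positional_profiles` | TSS/TES-anchored frequency profiles (every 20th bp over 10 kb, longest hit wins), Gypsy:Copia ratio curves, 30 bp target-site matrices and degenerate motif calls |
| `methylation` | 100 bp windowed CG/CHG/CHH levels (#C/(#C+#T), no coverage filter by default), promoter TE classification ([TSS−1500, TSS+500)), 12 × 1 kb binned group ratios |

## Coordinate and format conventions

* In memory everything is 0-based, half-open. On disk GFF3 is 1-based
  inclusive, BED is 0-based half-open.
* The methylation call table is tab-separated with a header line and columns
  `chromosome  position  strand  context  methylated  total`, positions
  1-based on disk, `context ∈ {CG, CHG, CHH}`. Rows with `total == 0` are
  kept on read and skipped by the windowed estimator. This is the shape a
  methratio-style extractor produces after column selection.
* TE library entries are named `XXX_name` where the three-letter prefix
  encodes the superfamily (RLG Gypsy, RLC Copia, DTT Mariner, DTH Harbinger,
  DHH Helitron, DTC CACTA, RIX LINE, RSX SINE, RLX/XXX other).

## CLI

```bash
repeatscape simulate   --config sim.cfg --out simdir --seed 1
repeatscape annotate   --genome g.fa --library lib.fa --out anndir
repeatscape landscape  --te te.gff3 --genome g.fa --centromeres cen.tsv --out lsdir
repeatscape genespace  --te te.gff3 --genes genes.gff3 --genome g.fa --out gsdir --seed 1
repeatscape profiles   --te te.gff3 --genes genes.gff3 --genome g.fa --out pfdir
repeatscape methylation --calls meth.tsv --genes genes.gff3 --te te.gff3 --out medir
```

Configs are flat `key = value` text files; every key has a default, so
`--config` is optional. Keys read by `simulate`: `n_chromosomes`,
`chromosome_length`, `n_families`, `n_genes`, `copies_per_family`,
`divergence`, `depth_mean`. `annotate` reads `segment_length`,
`min_identity`, `min_hit_length`, `bridge_gap`, `gap_extend`; `landscape`
reads `bin_size`, `terminal_fraction`; `genespace` reads `max_gap`,
`null_reps`.

## Notes on the aligner

The built-in search is an exact 12-mer seed + x-drop ungapped extension
(match +1, mismatch −2, drop 20) confined to each 180 bp segment, with hits
reported in forward-consensus coordinates on both strands. It is compiled
with numba and validated against a quadratic local-alignment oracle in the
test suite. An adapter (`te_annotation.read_external_hits`) ingests BLAST
`-outfmt 6` tabular output with `<chrom>:<segment_start>` query ids if you
prefer an external aligner.
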