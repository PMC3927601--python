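# islandscout

Comparative-genomics toolkit for circular bacterial chromosomes, built around
the analyses used to characterise rhizobial genomes and their horizontally
acquired islands:

* **genome_model** — GenBank / FASTA+GFF3 I/O for circular annotated genomes,
  modular-arithmetic intervals (wrapped intervals render as `start-0-end`),
  GC accounting, origin re-rooting at a restriction site.
* **digest** — in-silico restriction digestion (PmeI, SwaI, PacI built in,
  arbitrary palindromic enzymes supported) with circular-aware fragment
  tables in bp and rounded kb.
* **skew** — windowed GC-skew profiles, replication origin/terminus candidates
  from cumulative-skew extrema, and IUPAC motif search (e.g. a terminus
  *dif* 28-mer) with mismatch tolerance on both strands.
* **align** — k-mer seeded, two-hit triggered, X-drop gated local alignment
  with affine gaps (Biopython's C aligner as the extension engine) and
  Karlin–Altschul bit scores / E-values; optional BLAST+ parity adapter.
* **is_atlas** — insertion-sequence copy mapping against a family library and
  per-region count matrices (midpoint rule, wrapped regions supported).
* **island_scan** — tRNA-anchored genomic-island detection via exact
  3'-terminal duplications (stacked islands supported), duplication-free
  low-GC candidate islands, genome-wide partial tRNA 3'-portion search, and
  reconstruction of a split symbiosis island from three evidence lines
  (low GC, IS density, conserved-locus overlap).
* **conservation** — three-tier gene classification against a reference
  genome (bit ≥ 100 & identity > 99 → distinct-identical; bit ≥ 100 →
  significant similarity; else no similarity), identity histograms, and
  positional clustering of tier-1 genes into loci (origin-wrapping aware).
* **orthology** — reciprocal-best-hit ortholog pairs, three-way Venn
  partitioning of gene families, single-linkage protein clustering at
  identity/coverage thresholds.
* **synth** — deterministic synthetic genome pairs/triples carrying every
  feature class above, with machine-readable truth ledgers, so the whole
  pipeline is testable offline.

## CLI

```sh
islandscout simulate  --seed 17 --length 300000 --out sim/
islandscout convert   --in sim/genomeA.gb --out a.fa --features a.gff3
islandscout digest    --genome sim/genomeA.gb --enzymes PmeI,SwaI --out frags.tsv
islandscout skew      --genome sim/genomeA.gb --window 10000 --out skew.tsv
islandscout islands   --genome sim/genomeA.gb --out islands.tsv
islandscout ismap     --genome sim/genomeA.gb --families is.fa --out is.gff3
islandscout conserve  --query sim/genomeA.gb --ref sim/genomeB.gb --out cons/
islandscout symbiosis --genome sim/genomeA.gb --families is.fa --trnv trnV \
                      --tier1-bed loci.bed --out sym.json
islandscout orthovenn --sets a.faa b.faa c.faa --out venn.json
islandscout report    --genome-a sim/genomeA.gb --genome-b sim/genomeB.gb --out rep/
```

## Conventions

* Coordinates are 1-based inclusive everywhere in the API and reports;
  BED exports are 0-based half-open.
* Wrapped (origin-spanning) intervals serialize as `start-0-end`.
* N bases count toward length but are excluded from GC numerator and
  denominator.
* Fragment sizes in kb round half away from zero.
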