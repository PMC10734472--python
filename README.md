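# fgislands

Recruitment-based discovery and ecological typing of **flexible genomic
islands** (fGIs) in streamlined marine bacteria, as a tested, reusable
pipeline:

* **Metagenomic recruitment** — an internal ungapped seed-and-extend mapper
  (or ingested 12-column BLAST tabular), dual identity tiers (species:
  ≥98% identity / ≥50 nt; permissive: ≥70% / ≥50 nt), RPKG normalisation
  (reads per kb of genome per Gb of metagenome) and the presence rule
  (RPKG ≥ 10 and breadth ≥ 60%).
* **Island delimitation** — sliding-window depletion of the species-tier
  depth profile, base-resolution edge trimming, gene-boundary refinement,
  and conserved-vs-variable classification across samples.
* **Genomospecies** — fragment-based ANI (ANIb convention, 1,020 nt
  fragments), single-linkage dereplication (ANI > 99) and species clusters
  (ANI ≥ 95), combined with RPKG distribution patterns into genomospecies.
* **Island version typing** — built-in gene-content signatures for
  phosphate islands (fGIp, versions A–H around the pst operon) and
  phosphonate islands (fGIphn, versions A–D around the C-P lyase), marker
  (PstS+PstC+PstA) clustering with an NJ tree, and island-vs-genome AAI
  over bidirectional best hits.
* **Environment statistics** — exact small-n Wilcoxon signed-rank (full
  2^n sign enumeration for n ≤ 25), exact-permutation Spearman (n ≤ 9),
  Kruskal-Wallis with tie correction, and version-abundance matrices
  correlated against phosphate concentration.
* **Synthetic communities** — a simulator that builds clonal populations
  (core genome + islands at fixed loci between conserved border genes,
  substitution-only divergence) and shotgun metagenomes along a phosphate
  gradient, with full ground truth, so every stage is testable offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact statistic
values, simulator-truth recovery properties, threshold boundary behaviour).

## Command line

Every stage is exposed under the `fgi` entry point and communicates through
plain files (FASTA/FASTQ/GFF3/BED/TSV):

```bash
fgi run --out run_dir --seed 42          # full demo pipeline, bundled config
fgi simulate --out sim_dir               # synthetic community + metagenomes
fgi recruit --reads S.fastq --genome g.fasta --sample-id S --out rec/
fgi recruit --blast-tab hits.tsv --metagenome-size 1000000 --genome g.fasta --out rec/
fgi islands --profiles rec/ --gff g.gff3 --out islands.bed
fgi ani --genomes genomes/ --out ani.tsv
fgi genomospecies --ani ani.tsv --rpkg rpkg.tsv --out gs.tsv
fgi type-islands --gff g.gff3 --islands islands.bed --island-class fGIp --out versions.tsv
fgi aai --set-a island.faa --set-b genome.faa
fgi stats --abundance abundance.tsv --metadata samples.tsv --out stats.tsv
```

`fgi run` accepts a YAML config (see `tests/test_pipeline.py` for the
schema); without one it runs the bundled demo: one species, four strains
carrying fGIp versions A or E plus a per-strain hypervariable cassette,
sequenced in three samples along a phosphate gradient (1 µM → 0.002 µM).
The run directory contains genomes, reads, recruitment tables, island
calls, ANI/genomospecies tables, version assignments, abundance/statistics
tables and a `manifest.json` with parameters and output checksums.

## Package layout

```
src/fgislands/
  io_formats.py           FASTA/FASTQ/GFF3/BED6/BLAST-tabular/TSV, strict dialects
  signatures.py           built-in fGIp A–H and fGIphn A–D gene signatures
  synthetic_community.py  population + metagenome simulator with ground truth
  recruitment.py          mapper, tier filters, RPKG, breadth, presence calls
  island_scan.py          island detection, classification, boundary refinement
  genomospecies.py        fragment ANI, dereplication, genomospecies assignment
  island_typing.py        version assignment, marker clustering, AAI
  ecostats.py             exact Wilcoxon/Spearman, Kruskal-Wallis, abundance
  pipeline.py, cli.py     orchestration, manifest, `fgi` command line
```

Coordinates are 0-based half-open internally; GFF3 is written 1-based
inclusive and BED 0-based half-open. All thresholds are inclusive (≥).
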