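# cbestop

Design and audit toolkit for gene knock-out by **cytosine base editing** in
bacteria, built for high-GC genomes such as *Streptomyces*.

Cytosine base editors (CBEs) — a Cas9 nickase fused to a cytidine deaminase —
convert C•G to T•A within an *editing window* near the PAM-distal end of the
protospacer, without double-strand breaks. A single C→T edit can turn a codon
into a premature stop: on the coding strand CAA→TAA, CAG→TAG and CGA→TGA,
and for a TGG codon either C of the opposing template-strand CCA can be
edited (giving TGA or TAG). `cbestop` enumerates, genome-wide, every 20-mer
protospacer that places such a target C inside a configurable editing window
next to a configurable PAM, and annotates each candidate with the
sequence-context features that drive CBE efficiency in GC-rich genomes
(GC content of the spacer, a 5′-GC dinucleotide at an in-window C, bystander
C burden, PAM class). It also quantifies editing outcomes from barcoded
amplicon sequencing and audits genome-wide off-target SNVs against
non-treated controls.

## What it computes

* **Stop-codon scan** — for each non-partial CDS, codons 2..n−1 are screened
  for CAA/CAG/CGA/TGG; each target C is placed at every window position
  p ∈ [first, last] (positions 1–20, PAM-distal = 1) of a candidate spacer,
  kept when the 3-mer 3′ of the spacer matches the IUPAC PAM pattern
  (NGG for SpCas9, NGN for SpCas9-NG, …), then deduplicated on
  (sequence, PAM, strand, genomic interval).
* **Scope statistics** — fraction of genes with ≥1 candidate, deduplicated
  protospacer totals, per-gene unique-protospacer distributions (exact and
  cumulative), and the GC-context category fractions, with paired
  comparisons between PAM specificities.
* **Amplicon quantification** — exact 8-bp barcode demultiplexing,
  alignment-free anchored counting (two exact 12-mer flanks around the
  protospacer), per-position substitution frequencies = substitution reads /
  anchored reads, and cognate-to-bystander C→T ratios.
* **Off-target audit** — treated-private SNVs (control subtraction on the
  (contig, pos, ref, alt) identity), a strict depth filter (> 10 by
  default), C→T/G→A classification, 0.1-Mb genomic binning, and
  mean ± s.e.m. across replicates.
* **Synthetic data** — seeded generators for high-GC genomes with planted,
  string-verified protospacers (an exact truth manifest), amplicon read
  pools with planted editing frequencies, and treated/control SNV tables.

## Worked example

Generate a synthetic 10-kb genome (72% GC, five genes, one planted
CAG-targeting protospacer per gene) and scan it with the relaxed NGN PAM:

```
$ cbestop simulate genome --seed 1 --outdir fixture
$ cbestop scan --fasta fixture/genome.fasta --gff fixture/genes.gff3 \
      --pam NGN --window 4:8 --outdir scan_ngn
scanning 5 CDS features with PAM NGN, window 4:8
5/5 genes editable (100.00%), 10 unique protospacers
```

All five genes are editable and the NGN scan finds ten unique candidates —
the five planted NGG placements plus five NGN-only placements of the same
target Cs. `scan_ngn/guides.tsv` holds one row per candidate:

```
gene_id   contig              spacer                pam  strand  start_1based  end_1based  target_c_pos  codon_index  codon_seq  resulting_stop  gc_percent  gc_motif_in_window  bystander_c_count  pam_class
gene_001  synthetic_contig_1  ATCCAGGACGCCGTCGCTTC  GGA  +       1561          1580        4             50           CAG        TAG             65.00       false               0                  NGA
gene_001  synthetic_contig_1  GATCCAGGACGCCGTCGCTT  CGG  +       1560          1579        5             50           CAG        TAG             65.00       false               1                  NGG
```

Each row reads: editing the C at spacer position 4 (or 5) converts codon 50
(CAG) of `gene_001` into the TAG stop. `scan_ngn/summary.json` aggregates
the scope report (`fraction_editable: 100.0`, `n_protospacers_total: 10`,
category fractions, and the per-k gene counts); `guides.bed` places the
candidates for genome browsers. Scanning the same genome with `--pam NGG`
and feeding both summaries to `cbestop compare-pams` tabulates the gain in
targeting scope from the relaxed PAM.

The other subcommands follow the same pattern: `cbestop quant` turns a
FASTQ plus a design table into per-position substitution frequencies and
bystander ratios, `cbestop offtarget` audits treated/control VCFs, and
`cbestop simulate reads|snvs` builds the matching fixtures.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on seeded synthetic inputs — genome
generation and both PAM scans checked against the planted truth manifest,
amplicon simulation and quantification with a bystander ratio, and a
three-replicate off-target audit — and writes its results JSON. A non-zero
exit means a stage failed its internal consistency checks.

See `docs/methods.md` for the model details, parameter defaults, numerical
conventions, and what the synthetic-data generator does and does not
emulate.
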