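# Methods

## The editing model

A cytosine base editor deaminates cytosines on the single-stranded,
non-Cas9-bound strand of the R-loop, within an editing window near the
PAM-distal end of the 20-nt protospacer. Positions are numbered 1–20 with
position 1 PAM-distal; the default window is 4–8, matching the window
commonly used for rAPOBEC1-based editors in genome-wide scans. Engineered
hAPOBEC3A-based editors measure slightly PAM-proximal (5–9), available via
`--window 5:9`.

A premature stop codon arises from a single C→T edit in two ways:

| codon (coding strand) | edited base | result |
|---|---|---|
| CAA | C at codon base 1 (coding strand) | TAA |
| CAG | C at codon base 1 (coding strand) | TAG |
| CGA | C at codon base 1 (coding strand) | TGA |
| TGG | first C of the opposing CCA (template strand) | TGA |
| TGG | second C of the opposing CCA (template strand) | TAG |

The scanner excludes codon 1 (no stop can be created in a start codon) and
the native terminal stop (editing it is not a *premature* stop). No
3′-proximity filter is applied: a stop in the last internal codon is still
counted. Candidates whose 23-mer (spacer + PAM) contains an N are dropped,
and placements that would run off a linear contig end are skipped
(wraparound is allowed for circular topology; the default is linear,
appropriate for the linear *Streptomyces* chromosome).

### Uniqueness and attribution

The deduplication key is (spacer sequence, PAM, strand, genomic interval):
the two template Cs of one TGG codon often share a physical placement and
collapse to a single candidate, keeping the first in (codon index, window
position) order. A protospacer is attributed to every gene whose editable
codon generated it — per-gene counts answer "how many guides for this
gene", so an overlapping-gene placement may appear twice there — while
genome-level totals and category fractions are computed on the deduplicated
union across genes. Both conventions are isolated in `scope.py` so the
alternative (sequence-only uniqueness) is a one-line change.

### Sequence-context annotation

* **GC content** is computed on the 20-mer spacer only (the PAM is a Cas9
  binding requirement, not a deaminase substrate).
* **GC motif**: a C at a window position whose 5′ neighbour is G. Only the C
  must lie in the window; the G may sit at window.first − 1, because the
  deaminase context is the 5′ neighbour of the edited base. The stricter
  reading (both bases in-window) is available via `require_g_in_window`.
* **Category fractions** use strict comparisons as printed in common
  practice ("≤ 75%" / "> 75%"). The three reported categories (no motif and
  GC ≤ 75; GC motif; GC > 75) deliberately overlap; the exact complement
  identity is no-motif-and-≤75 versus motif-or->75.
* **PAM class** is NGx when the middle base is G, else "other".

## Amplicon quantification

Reads carry an 8-bp barcode at the 5′ end; demultiplexing is an exact
prefix match (no mismatch rescue — at Illumina error rates an 8-mer loses
few reads, and determinism is worth more than the rescue). Counting is
alignment-free: a read is *anchored* when the two fixed 12-mer flanks
around the protospacer match the reference exactly at the expected spacing.
This excludes reads with indels in or near the window, which is acceptable
for base editors (no double-strand breaks, hence rare indels), and makes
every count exactly reproducible. Reads with mean phred < 15 are discarded
first, echoing a common read-level QC threshold; per-base masking is not
applied. For every amplicon, assigned = anchored + anchor-failed +
quality-failed.

Substitution frequency at a position is substitution reads / anchored
reads; with zero anchored reads frequencies are reported as missing (NaN),
never as 0. The cognate-to-bystander ratio divides the C→T frequencies of
two reference-C positions; equal frequencies (including 0/0) give 1.0, and
a zero bystander frequency under a positive cognate frequency is reported
as an infinite sentinel rather than an arbitrary large number.

## Off-target audit

SNV identity is the 4-tuple (contig, pos, ref, alt); a different alt allele
at a control position does not shield a treated SNV. The depth filter is
strict (depth > 10 with the default threshold 10). C→T and G→A are counted
together as deamination-consistent — strand is irrelevant because C→T on
one strand reads G→A on the other. Depth and frequency are read from VCF
INFO DP/AF, falling back to the first sample's FORMAT DP, AF, then the AD
ratio; multiallelic rows are split into biallelic records on read.

Genomic binning uses half-open bins over 0-based coordinates: a 1-based
position p falls in bin (p − 1) // bin_size, so the 100,000th base is the
last position of the first 0.1-Mb bin and all bins except a short final one
have equal width. Replicate summaries report mean, sample s.d. (ddof = 1)
and s.e.m. = s.d./√n; with a single replicate the dispersion statistics are
undefined and reported as missing rather than 0.

## Synthetic data

The generators state a fixed world: background bases are i.i.d. with
P(G or C) = 0.72 by default — the hallmark GC content of *Streptomyces*
genomes — and the default genome is 10 kb with five 300-bp single-interval
ATG…TAA genes on alternating strands, each carrying one planted CAG codon
with a CGG PAM placing the target C at window position 5.

Planted genes are built from filler codons that are never editable and
never stops, so the only scanner targets inside a gene are the planted
codons. The intended PAM trinucleotide is written next to each planted
target, competing PAM middle bases at the other window offsets are scrubbed,
and the attempt is accepted only when a brute-force truth scan — direct
string inspection implemented inside the generator, sharing no code with
the scanner — finds exactly the intended placements under the first
declared (PAM, window) combination. Rejected attempts regenerate from a
perturbed sub-seed, so identical specs are byte-identical across runs.
Secondary combinations carry truthful manifests that include every real
hit, intended or not.

One constraint is intrinsic: the placements one window position either side
of the intended one reuse the intended PAM's first and third bases as their
own PAM middle, and those bases sit inside the protected PAM footprint. A
planted PAM whose first or third base itself satisfies the primary pattern
(e.g. G at either position under an NGN primary, or a GG-initial PAM under
NGG) is therefore unrealizable, and the generator reports it after its
attempt budget instead of silently emitting a wrong manifest.

Amplicon read generation offers an exact-allocation mode (read j carries
the edit iff j < round(freq·n), so planted frequencies that are rationals
of n are recovered exactly — used for equality assertions) and a seeded
binomial mode (statistical realism — tested within 3 binomial s.d.).
Quality strings are a constant phred offset; the generator does not emulate
quality decay along the read, PCR chimeras, indels, or paired-end overlap,
so a green amplicon test establishes the counting arithmetic, not
robustness to those artefacts. Likewise the genome generator has no codon
usage, operons, or repeats: a green scan test establishes coordinate and
rule correctness, not performance on real annotation quirks (those are
covered by the GenBank/GFF readers' own tests).

## Numerical and format conventions

* Internal coordinates are 0-based half-open everywhere; GenBank and GFF3
  (1-based inclusive) are converted on read, BED is written 0-based
  half-open, and tabular reports print 1-based inclusive.
* Compound (joined) CDS locations and lengths not divisible by three are
  flagged partial and excluded from codon scanning — bacterial CDSs are
  overwhelmingly single-interval, and silently concatenating parts risks
  frame errors.
* Gene universes for scope statistics are all non-partial CDS features,
  including pseudogene-annotated CDSs when present as CDS rows.
* Lowercase input is uppercased; characters outside {A,C,G,T,N} become N
  with a warning (tolerant ingestion, strict internal alphabet).
* Scope fractions are kept at full precision internally and rounded only
  in written reports (two decimals).
* All randomness flows through explicitly seeded NumPy generators; there is
  no hidden global state.

## Known limitations

* No on-target activity scoring and no mismatch-based off-target site
  prediction: the scan enumerates possibilities, it does not rank by
  predicted efficiency.
* The amplicon module does not merge paired-end reads and produces no
  indel/allele tables.
* The audit consumes already-called SNV tables; read mapping and variant
  calling are out of scope.
* Whole-genome scans of real assemblies depend on the annotation's CDS
  conventions (which features count as ORFs, how pseudogenes are marked);
  the per-gene TSV exposes raw counts so alternative conventions can be
  compared.
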