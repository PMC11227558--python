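"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline stages:

* genomes — high-GC background (default 72%, emulating *Streptomyces*) with
  planted single-interval CDSs whose editable codons, PAM placements and
  editing-window positions are declared up front and verified by direct
  string inspection, yielding an exact truth manifest;
* amplicon read pools with planted per-position C-to-T frequencies, in an
  exact-allocation mode (frequencies are exact rationals) or a binomial
  sampling mode;
* treated/control SNV tables with planted shared and private variants.

The truth manifest is computed by a brute-force enumeration local to this
module. The small amount of duplicated sequence arithmetic is deliberate:
the manifest must not share code with the scanner it validates.
"""

from __future__ import annotations


from dataclasses import dataclass
from types import SimpleNamespace
from typing import Sequence

import numpy as np

from cbestop.amplicon import AmpliconDesign, Read
from cbestop.genome_io import CdsFeature, GenomeRecord
from cbestop.offtarget import SnvRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Independent IUPAC table (see module docstring on deliberate duplication).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _pam_ok(trimer: str, pattern: str) -> bool:
    return len(trimer) == 3 and all(b in _IUPAC[p] for b, p in zip(trimer, pattern))


_EDITABLE = {"CAA", "CAG", "CGA", "TGG"}
_STOPS = {"TAA", "TAG", "TGA"}
# Filler codons: anything that is neither editable nor a stop is safe because
# the scanner only inspects in-frame codons. A GC-leaning subset keeps planted
# genes visually consistent with a high-GC genome.
_SAFE_CODONS = (
    "GGC", "GGT", "GCC", "GCT", "ACC", "GTC", "GTG", "CTG", "CTC", "TCC",
    "GAC", "GAG", "TTC", "ATC", "AAC", "CAC", "CGC", "CGG", "CCG", "GCG",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedTarget:
    """One editable codon planted in a synthetic gene.

    ``codon_index`` is 1-based within the CDS; ``pam`` is the concrete
    trinucleotide written next to the planted protospacer; ``window_pos`` is
    the intended spacer position (1..20, PAM-distal = 1) of the target C.
    """

    codon_seq: str
    codon_index: int
    pam: str
    window_pos: int

    def __post_init__(self) -> None:
        if self.codon_seq not in _EDITABLE:
            raise SimulationError(f"codon {self.codon_seq} is not editable")
        if len(self.pam) != 3 or any(b not in "ACGT" for b in self.pam):
            raise SimulationError(f"planted PAM must be a concrete 3-mer, got {self.pam!r}")
        if not (1 <= self.window_pos <= 20):
            raise SimulationError(f"window position {self.window_pos} outside 1..20")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Declarative description of a synthetic genome with planted features."""

    seed: int
    length: int = 10_000
    gc_fraction: float = 0.72
    n_genes: int = 5
    gene_length: int = 300  # bases, multiple of 3, >= 30
    planted_targets: tuple[tuple[PlantedTarget, ...], ...] = ()  # one tuple per gene
    strands: tuple[str, ...] = ()  # default: alternate + / -
    combos: tuple[tuple[str, tuple[int, int]], ...] = (("NGG", (4, 8)), ("NGN", (4, 8)))
    contig_id: str = "synthetic_contig_1"

    def __post_init__(self) -> None:
        if self.gene_length < 30 or self.gene_length % 3 != 0:
            raise SimulationError("gene_length must be a multiple of 3 and >= 30")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise SimulationError("gc_fraction outside [0, 1]")
        if self.planted_targets and len(self.planted_targets) != self.n_genes:
            raise SimulationError("planted_targets must list one tuple per gene")
        if self.strands and len(self.strands) != self.n_genes:
            raise SimulationError("strands must list one strand per gene")


@dataclass(frozen=True)
class ManifestEntry:
    """One expected scanner hit, fully specified."""

    gene_id: str
    contig_id: str
    spacer: str
    pam: str
    strand: str
    start: int
    end: int
    target_c_pos: int
    codon_index: int
    codon_seq: str
    resulting_stop: str

    def key(self) -> tuple:
        return (
            self.gene_id, self.spacer, self.pam, self.strand,
            self.start, self.end, self.target_c_pos,
        )


@dataclass
class TruthManifest:
    """Expected scanner output per (PAM pattern, editing window) combination."""

    entries: dict[str, list[ManifestEntry]]

    @staticmethod
    def combo_key(pam_pattern: str, window: tuple[int, int]) -> str:
        return f"{pam_pattern}:{window[0]}-{window[1]}"

    def key_set(self, pam_pattern: str, window: tuple[int, int]) -> set[tuple]:
        return {e.key() for e in self.entries[self.combo_key(pam_pattern, window)]}


def _default_planted(spec: SyntheticGenomeSpec) -> tuple[tuple[PlantedTarget, ...], ...]:
    if spec.planted_targets:
        return spec.planted_targets
    mid = spec.gene_length // 6  # a codon comfortably inside the gene
    return tuple(
        (PlantedTarget("CAG", mid, "CGG", 5),) for _ in range(spec.n_genes)
    )


def _gene_targets_truth(coding: str, gene: dict) -> list[dict]:
    """Editable-codon targets of one gene, by direct string inspection."""
    targets = []
    n_codons = len(coding) // 3
    for i in range(1, n_codons - 1):
        codon = coding[3 * i : 3 * i + 3]
        if codon in ("CAA", "CAG", "CGA"):
            stop = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}[codon]
            targets.append({"codon_index": i + 1, "codon": codon, "offset": 3 * i,
                            "template": False, "stop": stop})
        elif codon == "TGG":
            targets.append({"codon_index": i + 1, "codon": codon, "offset": 3 * i + 2,
                            "template": True, "stop": "TGA"})
            targets.append({"codon_index": i + 1, "codon": codon, "offset": 3 * i + 1,
                            "template": True, "stop": "TAG"})
    for t in targets:
        t["c_pos"], t["c_strand"] = _target_coords(gene, t["offset"], t["template"])
    return targets


def _target_coords(gene: dict, offset: int, template: bool) -> tuple[int, str]:
    if gene["strand"] == "+":
        pos = gene["start"] + offset
        strand = "-" if template else "+"
    else:
        pos = gene["end"] - 1 - offset
        strand = "+" if template else "-"
    return pos, strand


def _placement(seq: str, c_pos: int, c_strand: str, p: int) -> tuple[str, str, int, int] | None:
    """Spacer/PAM strings for the target C at spacer position p, or None."""
    if c_strand == "+":
        s0 = c_pos - (p - 1)
        if s0 < 0 or s0 + 23 > len(seq):
            return None
        return seq[s0 : s0 + 20], seq[s0 + 20 : s0 + 23], s0, s0 + 20
    end = c_pos + p
    start = end - 20
    if start - 3 < 0 or end > len(seq):
        return None
    return _rc(seq[start:end]), _rc(seq[start - 3 : start]), start, end


def _truth_scan(
    seq: str, genes: Sequence[dict], pam_pattern: str, window: tuple[int, int], contig_id: str
) -> list[ManifestEntry]:
    """Brute-force enumeration of expected scanner hits (local, independent)."""
    first, last = window
    entries: list[ManifestEntry] = []
    for gene in genes:
        coding = seq[gene["start"] : gene["end"]]
        if gene["strand"] == "-":
            coding = _rc(coding)
        seen: set[tuple] = set()
        for t in _gene_targets_truth(coding, gene):
            for p in range(first, last + 1):
                placed = _placement(seq, t["c_pos"], t["c_strand"], p)
                if placed is None:
                    continue
                spacer, pam, start, end = placed
                if "N" in spacer or "N" in pam or not _pam_ok(pam, pam_pattern):
                    continue
                k = (spacer, pam, t["c_strand"], start, end)
                if k in seen:
                    continue
                seen.add(k)
                entries.append(
                    ManifestEntry(
                        gene_id=gene["gene_id"],
                        contig_id=contig_id,
                        spacer=spacer,
                        pam=pam,
                        strand=t["c_strand"],
                        start=start,
                        end=end,
                        target_c_pos=p,
                        codon_index=t["codon_index"],
                        codon_seq=t["codon"],
                        resulting_stop=t["stop"],
                    )
                )
    return entries


def generate_genome(
    spec: SyntheticGenomeSpec, max_attempts: int = 200
) -> tuple[GenomeRecord, list[CdsFeature], TruthManifest]:
    """Generate a genome with planted stop-editable protospacers plus its truth.

    Background bases are i.i.d. with P(G or C) = ``gc_fraction``. Genes are
    single-interval ATG...TAA CDSs built from filler codons that can never be
    editable, so the only scanner targets are the planted codons. The
    intended PAM is written next to each planted target and competing PAM
    placements inside the first declared window are scrubbed; the attempt is
    accepted only when the brute-force truth scan finds exactly the intended
    placements for the first combo. Failed attempts perturb the seed and
    regenerate, so identical specs always yield identical output.

    Some specs are intrinsically unrealizable and fail every attempt: the
    window placements one position either side of the intended one reuse the
    intended PAM's first and third base as their PAM middle, so those bases
    must not themselves satisfy the primary pattern (e.g. under an NGN
    primary pattern a planted PAM may not carry G at position 1 or 3).
    Secondary combos carry no such constraint: their manifests simply record
    every true hit.
    """
    planted = _default_planted(spec)
    strands = spec.strands or tuple("+-"[i % 2] for i in range(spec.n_genes))
    gap = (spec.length - spec.n_genes * spec.gene_length) // (spec.n_genes + 1)
    if gap < 30:
        raise SimulationError(
            f"infeasible spec: {spec.n_genes} genes of {spec.gene_length} bp do not "
            f"fit in {spec.length} bp with 30 bp margins"
        )
    primary_pam, primary_window = spec.combos[0]

    last_error = "no attempts made"
    for attempt in range(max_attempts):
        rng = np.random.default_rng([spec.seed % (2**31), attempt])
        result = _attempt_genome(spec, planted, strands, gap, rng, primary_pam, primary_window)
        if isinstance(result, str):
            last_error = result
            continue
        seq, genes, intended = result
        entries = {}
        for pam_pattern, window in spec.combos:
            key = TruthManifest.combo_key(pam_pattern, window)
            entries[key] = _truth_scan(seq, genes, pam_pattern, window, spec.contig_id)
        primary_key = TruthManifest.combo_key(primary_pam, primary_window)
        got = {e.key() for e in entries[primary_key]}
        if got != intended:
            last_error = "accidental extra or missing placements under the primary combo"
            continue
        genome = GenomeRecord(spec.contig_id, seq, "linear")
        cds_list = [
            CdsFeature(g["gene_id"], spec.contig_id, g["start"], g["end"], g["strand"])
            for g in genes
        ]
        return genome, cds_list, TruthManifest(entries)
    raise SimulationError(
        f"could not realize spec after {max_attempts} attempts ({last_error})"
    )


def _attempt_genome(spec, planted, strands, gap, rng, primary_pam, primary_window):
    """One generation attempt; returns (seq, genes, intended keys) or an error string."""
    bases = np.array(list("ACGT"))
    probs = [
        (1 - spec.gc_fraction) / 2,
        spec.gc_fraction / 2,
        spec.gc_fraction / 2,
        (1 - spec.gc_fraction) / 2,
    ]
    seq = list(rng.choice(bases, size=spec.length, p=probs))

    n_codons = spec.gene_length // 3
    genes: list[dict] = []
    for i in range(spec.n_genes):
        start = gap * (i + 1) + spec.gene_length * i
        codons = ["ATG"] + list(rng.choice(_SAFE_CODONS, size=n_codons - 2)) + ["TAA"]
        for t in planted[i]:
            if not (2 <= t.codon_index <= n_codons - 1):
                raise SimulationError(
                    f"codon index {t.codon_index} outside scannable range 2..{n_codons - 1}"
                )
            codons[t.codon_index - 1] = t.codon_seq
        coding = "".join(codons)
        genes.append(
            {
                "gene_id": f"gene_{i + 1:03d}",
                "start": start,
                "end": start + spec.gene_length,
                "strand": strands[i],
            }
        )
        insert = coding if strands[i] == "+" else _rc(coding)
        seq[start : start + spec.gene_length] = list(insert)

    # Write intended PAMs, remember every planted C and PAM footprint.
    pam_footprint: set[int] = set()
    planted_cs: list[tuple[int, str, dict, PlantedTarget]] = []
    for gene, targets in zip(genes, planted):
        for t in targets:
            offset = 3 * (t.codon_index - 1)
            template = t.codon_seq == "TGG"
            if template:
                offset += 2  # first C of the opposing CCA; yields a TGA stop
            c_pos, c_strand = _target_coords(gene, offset, template)
            w = t.window_pos
            if c_strand == "+":
                pam_lo = c_pos - (w - 1) + 20
                written = t.pam
            else:
                pam_lo = c_pos + w - 23
                written = _rc(t.pam)
            if pam_lo < 0 or pam_lo + 3 > spec.length:
                return "intended PAM outside genome"
            seq[pam_lo : pam_lo + 3] = list(written)
            pam_footprint.update(range(pam_lo, pam_lo + 3))
            planted_cs.append((c_pos, c_strand, gene, t))

    protected = set(pam_footprint)
    for c_pos, _, gene, t in planted_cs:
        protected.update(range(gene["start"] + 3 * (t.codon_index - 1),
                               gene["start"] + 3 * (t.codon_index - 1) + 3)
                         if gene["strand"] == "+"
                         else range(gene["end"] - 3 * t.codon_index,
                                    gene["end"] - 3 * t.codon_index + 3))

    # Scrub competing PAM middle bases inside the primary window.
    first, last = primary_window
    for c_pos, c_strand, gene, t in planted_cs:
        for p in range(first, last + 1):
            if p == t.window_pos:
                continue
            mid = c_pos - (p - 1) + 21 if c_strand == "+" else c_pos + p - 22
            if mid in protected or not (0 <= mid < spec.length):
                continue
            seq[mid] = "T" if c_strand == "+" else "A"

    seq_str = "".join(seq)

    # Integrity of every gene: start/stop intact, editable codons only where planted.
    for gene, targets in zip(genes, planted):
        coding = seq_str[gene["start"] : gene["end"]]
        if gene["strand"] == "-":
            coding = _rc(coding)
        if coding[:3] != "ATG" or coding[-3:] != "TAA":
            return f"{gene['gene_id']}: start/stop codon clobbered by PAM writes"
        planted_idx = {t.codon_index: t.codon_seq for t in targets}
        for ci in range(2, len(coding) // 3):
            codon = coding[3 * (ci - 1) : 3 * ci]
            want = planted_idx.get(ci)
            if want is not None:
                if codon != want:
                    return f"{gene['gene_id']}: planted codon {ci} clobbered"
            elif codon in _EDITABLE or codon in _STOPS:
                return f"{gene['gene_id']}: accidental {codon} codon at {ci}"

    # Intended placement keys for the primary combo.
    intended: set[tuple] = set()
    for c_pos, c_strand, gene, t in planted_cs:
        placed = _placement(seq_str, c_pos, c_strand, t.window_pos)
        if placed is None:
            return "intended placement outside genome"
        spacer, pam, start, end = placed
        if pam != t.pam:
            return "intended PAM overwritten by a later plant"
        if not _pam_ok(pam, primary_pam):
            return "planted PAM does not satisfy the primary PAM pattern"
        intended.add(
            (gene["gene_id"], spacer, pam, c_strand, start, end, t.window_pos)
        )
    return seq_str, genes, intended


def generate_reads(
    design: AmpliconDesign,
    planted: dict[int, float],
    n_reads: int,
    seed: int = 0,
    error_rate: float = 0.0,
    mode: str = "exact",
    phred: int = 35,
) -> list[Read]:
    """Amplicon reads with planted C-to-T frequencies at spacer positions.

    Each read is barcode + full reference. ``planted`` maps spacer positions
    (1..20, PAM-distal = 1) to C-to-T frequencies; every planted position
    must be a reference C on the spacer strand. In ``exact`` mode read j
    carries the edit at position p iff j < round(freq * n_reads), so
    frequencies that are exact rationals of n_reads are recovered exactly;
    ``binomial`` mode draws each edit independently. Sequencing errors are
    uniform substitutions at ``error_rate`` per base.
    """
    if mode not in ("exact", "binomial"):
        raise SimulationError(f"unknown mode {mode!r}")
    for p, f in planted.items():
        if not (0.0 <= f <= 1.0):
            raise SimulationError(f"planted frequency {f} at position {p} outside [0, 1]")
    start, end = design.protospacer_interval
    edit_coords: dict[int, int] = {}  # spacer position -> coordinate within the read
    for p in planted:
        coord = start + (p - 1) if design.spacer_strand == "+" else end - p
        ref_base = design.reference[coord]
        expected = "C" if design.spacer_strand == "+" else "G"
        if ref_base != expected:
            raise SimulationError(
                f"spacer position {p} is not a reference C on the spacer strand"
            )
        edit_coords[p] = len(design.barcode) + coord

    rng = np.random.default_rng(seed % (2**31))
    template = design.barcode + design.reference
    edited_base = "T" if design.spacer_strand == "+" else "A"
    quals = tuple([phred] * len(template))
    reads: list[Read] = []
    for j in range(n_reads):
        seq = list(template)
        for p, f in planted.items():
            if mode == "exact":
                hit = j < round(f * n_reads)
            else:
                hit = rng.random() < f
            if hit:
                seq[edit_coords[p]] = edited_base
        if error_rate > 0.0:
            for i in range(len(seq)):
                if rng.random() < error_rate:
                    seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
        reads.append(Read(f"{design.amplicon_id}_read_{j}", "".join(seq), quals))
    return reads


def write_fastq(reads: Sequence[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")


def generate_snv_tables(
    genome_length: int,
    n_shared: int,
    n_private_treated: int,
    depth_range: tuple[int, int] = (11, 100),
    seed: int = 0,
    contig: str = "synthetic_contig_1",
    private_depths: Sequence[int] | None = None,
    ct_ga_fraction: float = 0.7,
) -> tuple[list[SnvRecord], list[SnvRecord], SimpleNamespace]:
    """Treated and control SNV tables with planted shared and private variants.

    Shared variants appear in both tables (germline-like background); private
    variants only in the treated table. ``ct_ga_fraction`` of variants carry
    the deamination signature (C>T or G>A). ``private_depths`` overrides the
    drawn depths of the private variants, e.g. to plant records below the
    audit's depth threshold. Returns (treated, control, truth) where truth
    holds the exact shared and private record lists.
    """
    if n_shared < 0 or n_private_treated < 0:
        raise SimulationError("variant counts must be non-negative")
    if private_depths is not None and len(private_depths) != n_private_treated:
        raise SimulationError("private_depths must match n_private_treated")
    rng = np.random.default_rng(seed % (2**31))
    n = n_shared + n_private_treated
    positions = rng.choice(genome_length, size=n, replace=False) + 1

    def make(pos: int, depth: int) -> SnvRecord:
        if rng.random() < ct_ga_fraction:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        else:
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return SnvRecord(
            contig=contig,
            pos=int(pos),
            ref=ref,
            alt=alt,
            freq=round(float(rng.uniform(0.05, 0.95)), 4),
            depth=depth,
        )

    lo, hi = depth_range
    shared = [make(p, int(rng.integers(lo, hi + 1))) for p in positions[:n_shared]]
    private = []
    for i, p in enumerate(positions[n_shared:]):
        depth = private_depths[i] if private_depths is not None else int(rng.integers(lo, hi + 1))
        private.append(make(p, depth))
    treated = sorted(shared + private, key=lambda r: r.pos)
    control = sorted(shared, key=lambda r: r.pos)
    truth = SimpleNamespace(shared=shared, private=private)
    return treated, control, truth
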