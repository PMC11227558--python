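"""Genome-wide enumeration of stop-codon-introducing protospacers.

A cytosine base editor converts C to T within an editing window near the
PAM-distal end of the protospacer. Three codons on the coding strand become
stops through a single C-to-T edit of their first base (CAA -> TAA,
CAG -> TAG, CGA -> TGA). A TGG codon offers two editable cytosines on the
template strand (the CCA triplet read 5'->3' on that strand): editing the
first C gives TGA, the second gives TAG.

The scanner places each editable C at every allowed window position of a
20-mer protospacer on the strand that carries the C, keeps placements whose
3' trinucleotide matches the PAM specification, and deduplicates coincident
placements.

Positions within the protospacer are numbered 1..20 with position 1
PAM-distal (furthest from the PAM), matching common base-editing usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from cbestop.genome_io import CdsFeature, GenomeRecord, extract_cds

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Single C-to-T edit of the first base turns these coding-strand codons into
# premature stops.
CODING_STRAND_RULES = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}
# TGG: the opposing template-strand CCA carries two editable Cs. Keyed by the
# 0-based offset of the opposing G within the TGG codon.
TGG_RULES = {2: "TGA", 1: "TAG"}  # first C of CCA pairs with the third G

SPACER_LEN = 20
PAM_LEN = 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class PamSpec:
    """A 3-letter IUPAC PAM pattern, e.g. NGG for SpCas9, NGN for SpCas9-NG."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if len(pat) != PAM_LEN or any(c not in IUPAC for c in pat):
            raise ScanError(f"invalid PAM pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def matches(self, trimer: str) -> bool:
        if len(trimer) != PAM_LEN:
            return False
        return all(base in IUPAC[p] for base, p in zip(trimer, self.pattern))


@dataclass(frozen=True)
class EditingWindow:
    """Protospacer positions (1-based, PAM-distal = 1) where editing occurs."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not (1 <= self.first <= self.last <= SPACER_LEN):
            raise ScanError(f"invalid editing window {self.first}:{self.last}")

    def positions(self) -> range:
        return range(self.first, self.last + 1)

    def __contains__(self, pos: int) -> bool:
        return self.first <= pos <= self.last


@dataclass(frozen=True)
class EditableTarget:
    """One cytosine whose C-to-T conversion creates a premature stop codon.

    ``c_genomic_pos`` is the 0-based reference coordinate of the base pair
    carrying the C; ``c_strand`` is the genomic strand on which the base
    reads C (for template-strand targets this is the strand opposite the
    gene).
    """

    gene_id: str
    contig_id: str
    codon_index: int  # 1-based codon number within the CDS
    codon_seq: str  # CAA | CAG | CGA | TGG (coding strand)
    target_strand: str  # "coding" | "template"
    c_genomic_pos: int
    c_strand: str  # "+" | "-"
    resulting_stop: str  # TAA | TAG | TGA


@dataclass
class Protospacer:
    """A 20-mer guide candidate with its PAM and target-C bookkeeping.

    ``spacer`` reads 5'->3' on the strand carrying the target C; ``pam`` is
    the trinucleotide immediately 3' of it on that strand. ``start``/``end``
    give the 0-based half-open reference interval of the 20-mer.
    """

    spacer: str
    pam: str
    contig_id: str
    start: int
    end: int
    spacer_strand: str
    target_c_pos: int  # 1..20, PAM-distal = 1
    target: EditableTarget
    gene_id: str
    annotation: object | None = field(default=None, compare=False)

    def key(self) -> tuple:
        """Uniqueness key: sequence plus genomic placement."""
        return (self.spacer, self.pam, self.spacer_strand, self.contig_id, self.start, self.end)


def match_pattern(seq: str, pattern: str) -> bool:
    """Positionwise IUPAC membership of a 23-mer (protospacer + PAM)."""
    if len(seq) != len(pattern):
        raise ScanError(f"sequence length {len(seq)} != pattern length {len(pattern)}")
    seq = seq.upper()
    pattern = pattern.upper()
    try:
        return all(b in IUPAC[p] for b, p in zip(seq, pattern))
    except KeyError as exc:
        raise ScanError(f"invalid IUPAC code in pattern {pattern!r}") from exc


def find_editable_targets(cds_seq: str, cds: CdsFeature) -> list[EditableTarget]:
    """Scan codons 2..(n-1) of a CDS for stop-introducing cytosines.

    The start codon and the native terminal stop are excluded: no stop can be
    created at codon 1, and editing the native stop is not a premature stop.
    CAA/CAG/CGA yield one coding-strand target each; TGG yields two
    template-strand targets (the two Cs of the opposing CCA).
    """
    n = len(cds_seq)
    if n % 3 != 0:
        raise ScanError(f"CDS {cds.gene_id}: length {n} not divisible by 3")
    targets: list[EditableTarget] = []
    n_codons = n // 3
    for i in range(1, n_codons - 1):  # 0-based codon index; skip first and last
        codon = cds_seq[3 * i : 3 * i + 3]
        codon_number = i + 1
        if codon in CODING_STRAND_RULES:
            offset = 3 * i  # the C is the first codon base
            targets.append(
                EditableTarget(
                    gene_id=cds.gene_id,
                    contig_id=cds.contig_id,
                    codon_index=codon_number,
                    codon_seq=codon,
                    target_strand="coding",
                    c_genomic_pos=_coding_offset_to_genomic(cds, offset),
                    c_strand=cds.strand,
                    resulting_stop=CODING_STRAND_RULES[codon],
                )
            )
        elif codon == "TGG":
            # Template-strand CCA: first C opposes the third G, second C the
            # second G. Emit in template 5'->3' order (TGA then TAG).
            for g_offset_in_codon in (2, 1):
                offset = 3 * i + g_offset_in_codon
                targets.append(
                    EditableTarget(
                        gene_id=cds.gene_id,
                        contig_id=cds.contig_id,
                        codon_index=codon_number,
                        codon_seq=codon,
                        target_strand="template",
                        c_genomic_pos=_coding_offset_to_genomic(cds, offset),
                        c_strand="-" if cds.strand == "+" else "+",
                        resulting_stop=TGG_RULES[g_offset_in_codon],
                    )
                )
    return targets


def _coding_offset_to_genomic(cds: CdsFeature, offset: int) -> int:
    """Map a 0-based offset within the coding sequence to a reference coordinate."""
    if cds.strand == "+":
        return cds.start + offset
    return cds.end - 1 - offset


def _fetch(genome: GenomeRecord, start: int, end: int) -> str | None:
    """Reference slice honouring topology; None when off a linear contig."""
    n = len(genome)
    if 0 <= start and end <= n:
        return genome.seq[start:end]
    if genome.topology != "circular" or end - start > n:
        return None
    return "".join(genome.seq[i % n] for i in range(start, end))


def enumerate_protospacers(
    genome: GenomeRecord,
    target: EditableTarget,
    pam: PamSpec,
    window: EditingWindow,
) -> list[Protospacer]:
    """All protospacer placements putting the target C inside the window.

    For each window offset p the candidate places the target C at spacer
    position p on the C-carrying strand and reads the PAM 3' of the 20-mer.
    Candidates whose PAM fails the specification, whose 23-mer contains an N,
    or whose 23-mer would run off a linear contig end are skipped.
    """
    out: list[Protospacer] = []
    g = target.c_genomic_pos
    for p in window.positions():
        if target.c_strand == "+":
            s0 = g - (p - 1)
            raw = _fetch(genome, s0, s0 + SPACER_LEN + PAM_LEN)
            if raw is None:
                continue
            spacer, pamseq = raw[:SPACER_LEN], raw[SPACER_LEN:]
            start, end = s0, s0 + SPACER_LEN
        else:
            end = g + p  # spacer position 1 sits at reference coord g+p-1
            start = end - SPACER_LEN
            raw = _fetch(genome, start - PAM_LEN, end)
            if raw is None:
                continue
            spacer = revcomp(raw[PAM_LEN:])
            pamseq = revcomp(raw[:PAM_LEN])
        if "N" in spacer or "N" in pamseq:
            continue
        if not pam.matches(pamseq):
            continue
        if genome.topology == "circular":
            # normalize so start lies in [0, n); end may exceed n to denote
            # a wraparound placement
            shift = (start % len(genome)) - start
            start, end = start + shift, end + shift
        out.append(
            Protospacer(
                spacer=spacer,
                pam=pamseq,
                contig_id=target.contig_id,
                start=start,
                end=end,
                spacer_strand=target.c_strand,
                target_c_pos=p,
                target=target,
                gene_id=target.gene_id,
            )
        )
    return out


def dedupe(protospacers: Sequence[Protospacer]) -> list[Protospacer]:
    """Drop duplicate placements, keeping the first of each uniqueness key.

    The key is (spacer, PAM, strand, genomic interval); the two target Cs of
    a TGG codon can produce coincident placements, which collapse here.
    """
    seen: set[tuple] = set()
    out: list[Protospacer] = []
    for p in protospacers:
        k = p.key()
        if k not in seen:
            seen.add(k)
            out.append(p)
    return out


def scan_genome(
    genomes: Sequence[GenomeRecord],
    cds_list: Sequence[CdsFeature],
    pam: PamSpec,
    window: EditingWindow,
    pattern: str | None = None,
) -> list[Protospacer]:
    """Enumerate stop-introducing protospacers over all non-partial CDSs.

    Composition of :func:`find_editable_targets`, :func:`enumerate_protospacers`
    and per-gene :func:`dedupe`. A protospacer is attributed to every gene
    whose editable codon generated it; genome-level totals should deduplicate
    across genes (see :mod:`cbestop.scope`). Output order is deterministic:
    contig, gene start, codon index, window position.

    ``pattern`` optionally restricts candidates to a 23-mer IUPAC pattern
    over spacer + PAM (an experimental-design filter).
    """
    by_contig = {g.contig_id: g for g in genomes}
    ordered = sorted(
        (c for c in cds_list if not c.partial),
        key=lambda c: (c.contig_id, c.start, c.end, c.gene_id),
    )
    result: list[Protospacer] = []
    for cds in ordered:
        genome = by_contig.get(cds.contig_id)
        if genome is None:
            raise ScanError(f"CDS {cds.gene_id} references unknown contig {cds.contig_id}")
        cds_seq = extract_cds(genome, cds)
        hits: list[Protospacer] = []
        for target in find_editable_targets(cds_seq, cds):
            hits.extend(enumerate_protospacers(genome, target, pam, window))
        hits.sort(key=lambda p: (p.target.codon_index, p.target_c_pos))
        hits = dedupe(hits)
        if pattern is not None:
            hits = [p for p in hits if match_pattern(p.spacer + p.pam, pattern)]
        result.extend(hits)
    return result
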