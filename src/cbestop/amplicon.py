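"""Amplicon-sequencing quantification of base-editing outcomes.

Reads carry an 8-bp barcode at the 5' end followed by the amplicon sequence.
Demultiplexing is an exact 8-mer prefix match. Counting is alignment-free:
a read contributes when the two fixed 12-mer flanks around the protospacer
match the reference exactly, which excludes reads with indels in or around
the window — acceptable for base editors, which act without double-strand
breaks. Per-position substitution frequencies are substitution reads over
total anchored reads; positions are numbered 1..20 with PAM-distal = 1 on
the spacer strand.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from cbestop.scanner import SPACER_LEN, revcomp

FLANK_LEN = 12
BARCODE_LEN = 8
BASES = ("A", "C", "G", "T")


class AmpliconError(ValueError):
    pass


@dataclass(frozen=True)
class Read:
    """A single sequencing read: id, sequence, per-base phred scores."""

    read_id: str
    seq: str
    quals: tuple[int, ...]

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass(frozen=True)
class AmpliconDesign:
    """One amplicon: reference, 5' barcode and protospacer placement.

    ``protospacer_interval`` is 0-based half-open within the reference (which
    excludes the barcode); ``spacer_strand`` says whether the protospacer
    reads 5'->3' on the reference (+) or its reverse complement (-).
    """

    amplicon_id: str
    reference: str
    barcode: str
    protospacer_interval: tuple[int, int]
    spacer_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.barcode) != BARCODE_LEN:
            raise AmpliconError(f"{self.amplicon_id}: barcode must be {BARCODE_LEN} bp")
        start, end = self.protospacer_interval
        if end - start != SPACER_LEN:
            raise AmpliconError(f"{self.amplicon_id}: protospacer interval must span 20 bp")
        if not (0 <= start and end <= len(self.reference)):
            raise AmpliconError(f"{self.amplicon_id}: protospacer interval outside reference")
        if self.spacer_strand not in ("+", "-"):
            raise AmpliconError(f"{self.amplicon_id}: bad strand {self.spacer_strand!r}")

    @property
    def left_flank(self) -> str:
        start, _ = self.protospacer_interval
        if start < FLANK_LEN:
            raise AmpliconError(f"{self.amplicon_id}: fewer than {FLANK_LEN} bp 5' of spacer")
        return self.reference[start - FLANK_LEN : start]

    @property
    def right_flank(self) -> str:
        _, end = self.protospacer_interval
        if end + FLANK_LEN > len(self.reference):
            raise AmpliconError(f"{self.amplicon_id}: fewer than {FLANK_LEN} bp 3' of spacer")
        return self.reference[end : end + FLANK_LEN]

    @property
    def ref_spacer(self) -> str:
        """Reference protospacer, oriented 5'->3' on the spacer strand."""
        start, end = self.protospacer_interval
        s = self.reference[start:end]
        return revcomp(s) if self.spacer_strand == "-" else s

    def validate_anchors(self) -> None:
        """Anchor flanks must occur exactly once in the reference."""
        for name, flank in (("left", self.left_flank), ("right", self.right_flank)):
            if "N" in flank:
                raise AmpliconError(f"{self.amplicon_id}: {name} anchor contains N")
            if self.reference.count(flank) != 1:
                raise AmpliconError(
                    f"{self.amplicon_id}: {name} anchor {flank} not unique in reference"
                )


@dataclass
class PositionBaseFrequencies:
    """Per-position base counts over anchored reads for one amplicon.

    ``counts`` is a 20 x 4 table (rows = spacer positions 1..20, PAM-distal
    = 1; columns = A/C/G/T) on the spacer-strand orientation. Frequencies
    divide by the anchored-read total and are undefined (NaN) when it is 0.
    """

    amplicon_id: str
    ref_spacer: str
    counts: pd.DataFrame
    n_assigned: int
    n_anchored: int
    n_anchor_failed: int
    n_quality_failed: int

    def frequency(self, pos: int, base: str) -> float:
        """Fraction of anchored reads carrying ``base`` at spacer position ``pos``."""
        if self.n_anchored == 0:
            return math.nan
        return self.counts.at[pos, base] / self.n_anchored

    def substitution_frequency(self, pos: int, from_base: str, to_base: str) -> float:
        if self.ref_spacer[pos - 1] != from_base:
            raise AmpliconError(
                f"reference base at position {pos} is {self.ref_spacer[pos - 1]}, not {from_base}"
            )
        return self.frequency(pos, to_base)

    def substitution_table(self) -> pd.DataFrame:
        """Tidy table of all non-reference base frequencies per position."""
        rows = []
        for pos in range(1, SPACER_LEN + 1):
            ref = self.ref_spacer[pos - 1]
            for base in BASES:
                if base == ref:
                    continue
                rows.append(
                    {
                        "amplicon_id": self.amplicon_id,
                        "position": pos,
                        "ref": ref,
                        "alt": base,
                        "count": int(self.counts.at[pos, base]),
                        "total": self.n_anchored,
                        "frequency": self.frequency(pos, base),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BystanderRatio:
    """Cognate-to-bystander C-to-T editing ratio, a selectivity measure."""

    cognate_pos: int
    bystander_pos: int
    cognate_freq: float
    bystander_freq: float
    ratio: float  # math.inf when bystander frequency is 0 and cognate > 0


def read_fastq(path: str | Path) -> list[Read]:
    """Read a FASTQ file (gzip allowed) into :class:`Read` records."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [
            Read(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def demultiplex(
    reads: Iterable[Read], designs: Sequence[AmpliconDesign]
) -> tuple[dict[str, list[Read]], int]:
    """Assign reads to amplicons by exact match of the first 8 bases.

    Returns the per-amplicon read lists plus the number of unassigned reads.
    Duplicate barcodes across designs are fatal.
    """
    by_barcode: dict[str, str] = {}
    for d in designs:
        if d.barcode in by_barcode:
            raise AmpliconError(
                f"duplicate barcode {d.barcode} ({by_barcode[d.barcode]} and {d.amplicon_id})"
            )
        by_barcode[d.barcode] = d.amplicon_id
    assignments: dict[str, list[Read]] = {d.amplicon_id: [] for d in designs}
    n_unassigned = 0
    for read in reads:
        amplicon = by_barcode.get(read.seq[:BARCODE_LEN])
        if amplicon is None:
            n_unassigned += 1
        else:
            assignments[amplicon].append(read)
    return assignments, n_unassigned


def quantify(
    reads: Sequence[Read], design: AmpliconDesign, min_qual: float = 15.0
) -> PositionBaseFrequencies:
    """Per-position base counts for one amplicon's assigned reads.

    Reads with mean phred below ``min_qual`` are quality-failed; reads where
    the two 12-mer anchor flanks do not match exactly at the expected spacing
    are anchor-failed. Anchored reads form the frequency denominator.
    Order-invariant: shuffling the input leaves all counts unchanged.
    """
    design.validate_anchors()
    left, right = design.left_flank, design.right_flank
    counts = np.zeros((SPACER_LEN, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    n_anchored = n_anchor_failed = n_quality_failed = 0
    for read in reads:
        if read.mean_quality < min_qual:
            n_quality_failed += 1
            continue
        i = read.seq.find(left)
        if i < 0 or read.seq[i + FLANK_LEN + SPACER_LEN : i + FLANK_LEN + SPACER_LEN + FLANK_LEN] != right:
            n_anchor_failed += 1
            continue
        window = read.seq[i + FLANK_LEN : i + FLANK_LEN + SPACER_LEN]
        if design.spacer_strand == "-":
            window = revcomp(window)
        ok = True
        for pos, base in enumerate(window):
            if base not in base_index:  # N in window: treat as anchor failure
                ok = False
                break
        if not ok:
            n_anchor_failed += 1
            continue
        for pos, base in enumerate(window):
            counts[pos, base_index[base]] += 1
        n_anchored += 1
    df = pd.DataFrame(counts, index=range(1, SPACER_LEN + 1), columns=list(BASES))
    return PositionBaseFrequencies(
        amplicon_id=design.amplicon_id,
        ref_spacer=design.ref_spacer,
        counts=df,
        n_assigned=len(reads),
        n_anchored=n_anchored,
        n_anchor_failed=n_anchor_failed,
        n_quality_failed=n_quality_failed,
    )


def bystander_ratio(
    freqs: PositionBaseFrequencies, cognate_pos: int, bystander_pos: int
) -> BystanderRatio:
    """Ratio of C-to-T frequencies at the cognate versus a bystander position.

    Both positions must be reference Cs with a nonzero denominator. The ratio
    is 1 when the frequencies are equal (including both zero) and infinite
    when only the bystander frequency is zero.
    """
    for pos in (cognate_pos, bystander_pos):
        if freqs.ref_spacer[pos - 1] != "C":
            raise AmpliconError(
                f"position {pos} reference base is {freqs.ref_spacer[pos - 1]}, not C"
            )
    if freqs.n_anchored == 0:
        raise AmpliconError("no anchored reads: frequencies undefined")
    fc = freqs.frequency(cognate_pos, "T")
    fb = freqs.frequency(bystander_pos, "T")
    if fc == fb:
        ratio = 1.0
    elif fb == 0.0:
        ratio = math.inf
    else:
        ratio = fc / fb
    return BystanderRatio(cognate_pos, bystander_pos, fc, fb, ratio)


def read_designs_tsv(path: str | Path) -> list[AmpliconDesign]:
    """Design table: amplicon_id, reference, barcode, spacer_start, spacer_end, strand.

    Coordinates in the table are 1-based inclusive within the reference.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"amplicon_id", "reference", "barcode", "spacer_start", "spacer_end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise AmpliconError(f"design table missing columns: {sorted(missing)}")
    designs = []
    for row in df.itertuples(index=False):
        designs.append(
            AmpliconDesign(
                amplicon_id=row.amplicon_id,
                reference=row.reference.upper(),
                barcode=row.barcode.upper(),
                protospacer_interval=(int(row.spacer_start) - 1, int(row.spacer_end)),
                spacer_strand=row.strand,
            )
        )
    return designs


def write_frequency_tsv(freqs_list: Sequence[PositionBaseFrequencies], path: str | Path) -> None:
    tables = [f.substitution_table() for f in freqs_list]
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    out.to_csv(path, sep="\t", index=False)
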