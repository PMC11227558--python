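"""Genome and CDS annotation I/O.

Reads GenBank flatfiles or FASTA + GFF3 pairs into a minimal internal model
(one :class:`GenomeRecord` per contig, one :class:`CdsFeature` per CDS) and
writes guide candidates back out as FASTA / BED6 / TSV / JSON.

Coordinate conventions: everything internal is 0-based half-open. GenBank and
GFF3 (1-based inclusive) are converted on read; BED is written 0-based
half-open; tabular reports print 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class GenomeIOError(ValueError):
    """Raised for unreadable inputs or inconsistent genome/annotation pairs."""


def _clean_seq(raw: str, contig_id: str) -> str:
    """Uppercase a sequence; replace characters outside {A,C,G,T,N} by N."""
    seq = str(raw).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        warnings.warn(
            f"contig {contig_id}: {len(bad)} non-ACGTN character(s) "
            f"({', '.join(sorted(bad))}) converted to N"
        )
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: an uppercase DNA sequence over {A,C,G,T,N} plus topology."""

    contig_id: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise GenomeIOError(f"contig {self.contig_id}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise GenomeIOError(f"contig {self.contig_id}: bad topology {self.topology!r}")
        if set(self.seq) - VALID_BASES:
            raise GenomeIOError(f"contig {self.contig_id}: alphabet outside ACGTN")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding interval, 0-based half-open, with strand and gene id.

    ``partial`` marks features excluded from codon scanning: compound (joined)
    locations, and lengths not divisible by three.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(f"CDS {self.gene_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"CDS {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _feature_gene_id(qualifiers: dict) -> str | None:
    for key in ("locus_tag", "gene", "protein_id"):
        vals = qualifiers.get(key)
        if vals:
            return str(vals[0])
    return None


def read_genbank(path: str | Path) -> tuple[list[GenomeRecord], list[CdsFeature]]:
    """Read a GenBank flatfile into genome records and CDS features.

    One :class:`GenomeRecord` per LOCUS; one :class:`CdsFeature` per CDS
    feature. Gene ids come from locus_tag, falling back to gene then
    protein_id; CDSs without any identifier are skipped with a warning.
    Compound (joined) locations and lengths not divisible by three are
    flagged ``partial``.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenomeIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeIOError(f"no LOCUS records found in {path}")

    genomes: list[GenomeRecord] = []
    features: list[CdsFeature] = []
    for rec in records:
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        genomes.append(GenomeRecord(rec.id, _clean_seq(rec.seq, rec.id), topology))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            gene_id = _feature_gene_id(feat.qualifiers)
            if gene_id is None:
                warnings.warn(
                    f"{path.name}: CDS at {feat.location} has no locus_tag/gene/"
                    "protein_id; skipped"
                )
                continue
            parts = feat.location.parts
            partial = len(parts) > 1
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            if not partial and (end - start) % 3 != 0:
                warnings.warn(
                    f"CDS {gene_id}: length {end - start} not divisible by 3; flagged partial"
                )
                partial = True
            features.append(CdsFeature(gene_id, rec.id, start, end, strand, partial))
    return genomes, features


def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeRecord]:
    """Read FASTA contigs into :class:`GenomeRecord` objects."""
    records = [
        GenomeRecord(rec.id, _clean_seq(rec.seq, rec.id), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return records


def read_fasta_gff(
    fasta: str | Path, gff: str | Path, topology: str = "linear"
) -> tuple[list[GenomeRecord], list[CdsFeature]]:
    """Read FASTA contigs plus GFF3 CDS rows into the internal model.

    CDS rows sharing one GFF ID (multi-exon style) are collapsed into a
    single feature spanning their extremes, flagged ``partial``. A GFF seqid
    absent from the FASTA is a fatal error. Nonzero phase triggers a warning
    only (frame is taken from the interval).
    """
    genomes = read_fasta(fasta, topology=topology)
    contig_lengths = {g.contig_id: len(g) for g in genomes}

    try:
        db = gffutils.create_db(
            str(gff),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            sort_attribute_values=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return genomes, []

    # Group CDS rows by the ID attribute as written in the file (gffutils
    # uniquifies its own db keys, but leaves the attributes untouched), so
    # multi-part features sharing one ID are detected.
    by_id: dict[str, list] = {}
    order: list[str] = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by=("seqid", "start"))):
        fid = feat.attributes.get("ID", [f"_anon_cds_{i}"])[0]
        if fid not in by_id:
            order.append(fid)
        by_id.setdefault(fid, []).append(feat)

    features: list[CdsFeature] = []
    for fid in order:
        parts = by_id[fid]
        first = parts[0]
        if first.seqid not in contig_lengths:
            raise GenomeIOError(f"GFF seqid {first.seqid!r} not present in FASTA")
        gene_id = None
        for key in ("locus_tag", "gene", "Name", "ID"):
            vals = first.attributes.get(key)
            if vals:
                gene_id = vals[0]
                break
        if gene_id is None:
            warnings.warn(f"GFF CDS at {first.seqid}:{first.start} has no identifier; skipped")
            continue
        start = min(int(p.start) - 1 for p in parts)
        end = max(int(p.end) for p in parts)
        if end > contig_lengths[first.seqid]:
            raise GenomeIOError(
                f"CDS {gene_id} end {end} exceeds contig {first.seqid} length"
            )
        strand = first.strand if first.strand in ("+", "-") else "+"
        partial = len(parts) > 1
        if first.frame not in (".", "0", None):
            warnings.warn(f"CDS {gene_id}: nonzero GFF phase {first.frame}; interval used as-is")
        if not partial and (end - start) % 3 != 0:
            warnings.warn(
                f"CDS {gene_id}: length {end - start} not divisible by 3; flagged partial"
            )
            partial = True
        features.append(CdsFeature(gene_id, first.seqid, start, end, strand, partial))
    return genomes, features


def extract_cds(genome: GenomeRecord, cds: CdsFeature) -> str:
    """Return the coding-strand sequence (5'->3') of a CDS.

    For minus-strand features this is the reverse complement of the genomic
    slice. Out-of-bounds intervals are fatal.
    """
    if cds.end > len(genome):
        raise GenomeIOError(
            f"CDS {cds.gene_id} interval [{cds.start}, {cds.end}) exceeds "
            f"contig {genome.contig_id} length {len(genome)}"
        )
    chunk = genome.seq[cds.start : cds.end]
    if cds.strand == "-":
        chunk = str(Seq(chunk).reverse_complement())
    return chunk


def write_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.contig_id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def write_bed(protospacers: Iterable, path: str | Path) -> None:
    """Write protospacers as BED6: name = gene_id|codon_index|PAM."""
    with open(path, "w") as fh:
        for p in protospacers:
            name = f"{p.gene_id}|{p.target.codon_index}|{p.pam}"
            fh.write(
                f"{p.contig_id}\t{p.start}\t{p.end}\t{name}\t0\t{p.spacer_strand}\n"
            )


GUIDE_TSV_COLUMNS = [
    "gene_id",
    "contig",
    "spacer",
    "pam",
    "strand",
    "start_1based",
    "end_1based",
    "target_c_pos",
    "codon_index",
    "codon_seq",
    "resulting_stop",
    "gc_percent",
    "gc_motif_in_window",
    "bystander_c_count",
    "pam_class",
]


def write_guide_tsv(protospacers: Iterable, path: str | Path) -> None:
    """Write annotated protospacers as a TSV with a fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(GUIDE_TSV_COLUMNS) + "\n")
        for p in protospacers:
            ann = p.annotation
            if ann is None:
                raise GenomeIOError(
                    f"protospacer {p.spacer} for {p.gene_id} lacks annotation; "
                    "run cbestop.classify.annotate first"
                )
            row = [
                p.gene_id,
                p.contig_id,
                p.spacer,
                p.pam,
                p.spacer_strand,
                str(p.start + 1),
                str(p.end),
                str(p.target_c_pos),
                str(p.target.codon_index),
                p.target.codon_seq,
                p.target.resulting_stop,
                f"{ann.gc_percent:.2f}",
                str(ann.gc_motif_in_window).lower(),
                str(ann.bystander_c_count),
                ann.pam_class,
            ]
            fh.write("\t".join(row) + "\n")


def write_json_summary(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
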