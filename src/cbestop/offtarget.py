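"""Off-target SNV auditing for base-editor-treated genomes.

Whole-genome or RNA sequencing of treated populations yields per-sample SNV
tables. The audit subtracts variants also seen in non-treated controls,
keeps variants with sequencing depth above a threshold (default: strictly
greater than 10), classifies the deamination-consistent C-to-T / G-to-A
events (strand-symmetric: C-to-T on one strand is G-to-A on the other),
bins variants along the genome (default bin 0.1 Mb), and summarizes counts
across biological replicates as mean +/- s.e.m.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam


class AuditError(ValueError):
    pass


@dataclass(frozen=True)
class SnvRecord:
    """One biallelic single-nucleotide variant with allele frequency and depth."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    freq: float
    depth: int

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise AuditError(f"{self.contig}:{self.pos}: not a SNV ({self.ref}>{self.alt})")
        if self.ref == self.alt:
            raise AuditError(f"{self.contig}:{self.pos}: ref equals alt")
        if self.depth < 0:
            raise AuditError(f"{self.contig}:{self.pos}: negative depth")
        if not (math.isnan(self.freq) or 0.0 <= self.freq <= 1.0):
            raise AuditError(f"{self.contig}:{self.pos}: frequency {self.freq} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def _record_depth(rec, alt_index: int) -> int:
    """Depth fallback order: INFO/DP, first sample DP, sum of first sample AD."""
    info = dict(rec.info)
    if "DP" in info:
        dp = info["DP"]
        return int(dp[0] if isinstance(dp, tuple) else dp)
    for sample in rec.samples.values():
        if sample.get("DP") is not None:
            return int(sample["DP"])
        ad = sample.get("AD")
        if ad is not None and all(a is not None for a in ad):
            return int(sum(ad))
        break
    return 0


def _record_freq(rec, alt_index: int, depth: int) -> float:
    """Frequency fallback order: INFO/AF (per alt), first sample AF, AD ratio."""
    info = dict(rec.info)
    if "AF" in info:
        af = info["AF"]
        if isinstance(af, tuple):
            return float(af[alt_index])
        return float(af)
    for sample in rec.samples.values():
        af = sample.get("AF")
        if af is not None:
            return float(af[alt_index] if isinstance(af, tuple) else af)
        ad = sample.get("AD")
        if ad is not None and all(a is not None for a in ad):
            total = sum(ad)
            if total > 0:
                return float(ad[alt_index + 1]) / total
        break
    return math.nan


def read_vcf(path: str | Path) -> list[SnvRecord]:
    """Read SNVs from a VCF; multiallelic rows are split, non-SNVs skipped."""
    out: list[SnvRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for i, alt in enumerate(rec.alts):
                if len(rec.ref) != 1 or alt is None or len(alt) != 1 or alt == "*":
                    continue
                depth = _record_depth(rec, i)
                freq = _record_freq(rec, i, depth)
                out.append(
                    SnvRecord(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        freq=freq,
                        depth=depth,
                    )
                )
    return out


def write_vcf(records: Sequence[SnvRecord], path: str | Path, contig_lengths: dict[str, int]) -> None:
    """Write SNV records as a minimal VCF 4.2 text file (INFO DP and AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.contig, r.pos, r.alt)):
            af = "." if math.isnan(r.freq) else f"{r.freq:.4f}"
            fh.write(
                f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tDP={r.depth};AF={af}\n"
            )


def subtract_control(
    treated: Sequence[SnvRecord],
    control: Sequence[SnvRecord],
    min_depth: int = 10,
) -> list[SnvRecord]:
    """Treated-private SNVs above the depth threshold.

    Keeps treated records with depth strictly greater than ``min_depth``
    whose (contig, pos, ref, alt) identity is absent from the control set;
    a different alt allele at a control position does not shield a treated
    SNV. Input order is preserved.
    """
    control_keys = {r.key for r in control}
    return [r for r in treated if r.depth > min_depth and r.key not in control_keys]


def classify_ct_ga(snvs: Sequence[SnvRecord]) -> tuple[list[SnvRecord], list[SnvRecord]]:
    """Partition SNVs into deamination-consistent (C>T or G>A) and other."""
    ct_ga = [r for r in snvs if (r.ref, r.alt) in (("C", "T"), ("G", "A"))]
    other = [r for r in snvs if (r.ref, r.alt) not in (("C", "T"), ("G", "A"))]
    return ct_ga, other


def bin_density(
    snvs: Sequence[SnvRecord], genome_length: int, bin_size: int = 100_000
) -> np.ndarray:
    """SNV counts per half-open genomic bin [i*bin, (i+1)*bin).

    The last bin may be short. Counts sum to the input size; a position
    beyond the genome length is an error.
    """
    if bin_size <= 0:
        raise AuditError("bin size must be positive")
    n_bins = max(1, math.ceil(genome_length / bin_size))
    counts = np.zeros(n_bins, dtype=np.int64)
    for r in snvs:
        if r.pos > genome_length:
            raise AuditError(f"SNV position {r.pos} beyond genome length {genome_length}")
        counts[(r.pos - 1) // bin_size] += 1
    return counts


@dataclass
class AuditSummary:
    """Replicate-level off-target accounting for one editor.

    ``n_ct_ga``/``n_total`` are per-replicate counts; the mean, sample
    standard deviation and standard error (s.d. / sqrt(n)) summarize the
    C-to-T/G-to-A counts across replicates. ``site_frequencies`` lists the
    union of deamination-consistent sites with one frequency column per
    replicate (0 where a site was not called).
    """

    n_ct_ga: list[int]
    n_total: list[int]
    mean_ct_ga: float
    sd_ct_ga: float | None
    sem_ct_ga: float | None
    site_frequencies: pd.DataFrame


def summarize(replicates: Sequence[Sequence[SnvRecord]]) -> AuditSummary:
    """Mean +/- s.e.m. of C-to-T/G-to-A counts across replicates.

    With a single replicate the dispersion statistics are undefined and
    reported as None.
    """
    if len(replicates) == 0:
        raise AuditError("at least one replicate is required")
    n_ct_ga: list[int] = []
    n_total: list[int] = []
    per_rep_ct: list[list[SnvRecord]] = []
    for rep in replicates:
        ct, other = classify_ct_ga(rep)
        n_ct_ga.append(len(ct))
        n_total.append(len(rep))
        per_rep_ct.append(ct)

    counts = np.asarray(n_ct_ga, dtype=float)
    mean = float(counts.mean())
    if len(counts) > 1:
        sd = float(counts.std(ddof=1))
        sem = sd / math.sqrt(len(counts))
    else:
        sd = sem = None

    sites = sorted({r.key for ct in per_rep_ct for r in ct})
    data = {}
    for i, ct in enumerate(per_rep_ct):
        freqs = {r.key: (0.0 if math.isnan(r.freq) else r.freq) for r in ct}
        data[f"rep{i + 1}"] = [freqs.get(site, 0.0) for site in sites]
    site_df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(sites, names=["contig", "pos", "ref", "alt"])
        if sites
        else pd.MultiIndex.from_arrays([[], [], [], []], names=["contig", "pos", "ref", "alt"]),
    )
    return AuditSummary(
        n_ct_ga=n_ct_ga,
        n_total=n_total,
        mean_ct_ga=mean,
        sd_ct_ga=sd,
        sem_ct_ga=sem,
        site_frequencies=site_df,
    )
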