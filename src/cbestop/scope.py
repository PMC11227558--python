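"""Genome-wide targeting-scope statistics.

Aggregates scanned protospacers into the quantities used to compare PAM
specificities across a genome: the fraction of genes that admit at least one
stop-introducing protospacer, the deduplicated protospacer total, the
distribution of unique protospacers per gene (exact and cumulative), and the
GC-context category fractions.

Category fractions are computed over the deduplicated protospacer set of the
scan at hand, and the three printed categories (no motif and GC <= 75%;
GC motif in window; GC > 75%) are not mutually exclusive — the exact
complement identity is no-motif-and-<=75 versus motif-or->75.
"""

from __future__ import annotations


from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd

from cbestop.genome_io import CdsFeature
from cbestop.scanner import Protospacer, ScanError, dedupe


@dataclass(frozen=True)
class GeneScopeSummary:
    gene_id: str
    n_unique_protospacers: int

    @property
    def editable(self) -> bool:
        return self.n_unique_protospacers >= 1


@dataclass
class ScopeReport:
    n_genes: int
    n_editable: int
    fraction_editable: float  # percent
    n_protospacers_total: int  # deduplicated union across genes
    fraction_no_motif_le75: float  # percent of protospacers
    fraction_motif: float
    fraction_gc_gt75: float
    per_k_exact: dict[int, int]
    per_k_cumulative: dict[int, int]
    genome_id: str | None = None
    pam: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_k_exact"] = {str(k): v for k, v in sorted(self.per_k_exact.items())}
        d["per_k_cumulative"] = {str(k): v for k, v in sorted(self.per_k_cumulative.items())}
        return d


def summarize_genes(
    protospacers: Sequence[Protospacer], genes: Sequence[CdsFeature | str]
) -> list[GeneScopeSummary]:
    """Per-gene unique protospacer counts over a gene universe.

    The universe includes genes with zero protospacers; a protospacer
    referencing a gene outside the universe is an error.
    """
    universe = [g if isinstance(g, str) else g.gene_id for g in genes]
    known = set(universe)
    counts: dict[str, set] = {g: set() for g in universe}
    for p in protospacers:
        if p.gene_id not in known:
            raise ScanError(f"protospacer references unknown gene {p.gene_id}")
        counts[p.gene_id].add(p.key())
    return [GeneScopeSummary(g, len(counts[g])) for g in universe]


def build_report(
    summaries: Sequence[GeneScopeSummary],
    protospacers: Sequence[Protospacer],
    genome_id: str | None = None,
    pam: str | None = None,
    gc_threshold: float = 75.0,
) -> ScopeReport:
    """Assemble the genome-wide scope report from per-gene summaries.

    ``n_protospacers_total`` and the category fractions are computed on the
    deduplicated union across genes: a physical 23-mer shared by two
    overlapping genes counts once. Fractions are kept at full precision;
    rounding happens only at presentation time.
    """
    n_genes = len(summaries)
    n_editable = sum(1 for s in summaries if s.editable)
    unique = dedupe(protospacers)
    n_total = len(unique)

    n_motif = n_gt = n_neither = 0
    for p in unique:
        ann = p.annotation
        if ann is None:
            raise ScanError(f"protospacer {p.spacer} lacks annotation; run annotate() first")
        if ann.gc_motif_in_window:
            n_motif += 1
        if ann.gc_percent > gc_threshold:
            n_gt += 1
        if not ann.gc_motif_in_window and ann.gc_percent <= gc_threshold:
            n_neither += 1

    def pct(x: int, denom: int) -> float:
        return 100.0 * x / denom if denom else 0.0

    per_k_exact: dict[int, int] = {}
    for s in summaries:
        if s.n_unique_protospacers >= 1:
            per_k_exact[s.n_unique_protospacers] = per_k_exact.get(s.n_unique_protospacers, 0) + 1
    per_k_cumulative: dict[int, int] = {}
    if per_k_exact:
        for k in range(1, max(per_k_exact) + 1):
            per_k_cumulative[k] = sum(v for j, v in per_k_exact.items() if j >= k)

    return ScopeReport(
        n_genes=n_genes,
        n_editable=n_editable,
        fraction_editable=pct(n_editable, n_genes),
        n_protospacers_total=n_total,
        fraction_no_motif_le75=pct(n_neither, n_total),
        fraction_motif=pct(n_motif, n_total),
        fraction_gc_gt75=pct(n_gt, n_total),
        per_k_exact=per_k_exact,
        per_k_cumulative=per_k_cumulative,
        genome_id=genome_id,
        pam=pam,
    )


_COMPARE_METRICS = [
    "n_genes",
    "n_editable",
    "fraction_editable",
    "n_protospacers_total",
    "fraction_no_motif_le75",
    "fraction_motif",
    "fraction_gc_gt75",
]


def compare_pams(report_narrow: ScopeReport, report_broad: ScopeReport) -> pd.DataFrame:
    """Paired metric table for two PAM specificities on the same genome.

    The broader PAM (e.g. NGN) must not reach fewer editable genes than the
    narrower one (e.g. NGG) — a violation of this monotonicity indicates
    inconsistent inputs and raises.
    """
    if (
        report_narrow.genome_id is not None
        and report_broad.genome_id is not None
        and report_narrow.genome_id != report_broad.genome_id
    ):
        raise ScanError(
            f"reports come from different genomes: "
            f"{report_narrow.genome_id!r} vs {report_broad.genome_id!r}"
        )
    if report_broad.fraction_editable < report_narrow.fraction_editable:
        raise ScanError(
            "PAM monotonicity violated: broader PAM reports fewer editable genes "
            f"({report_broad.fraction_editable:.2f}% < {report_narrow.fraction_editable:.2f}%)"
        )
    name_a = report_narrow.pam or "narrow"
    name_b = report_broad.pam or "broad"
    if name_a == name_b:
        name_a, name_b = f"{name_a}_narrow", f"{name_b}_broad"
    df = pd.DataFrame(
        {
            "metric": _COMPARE_METRICS,
            name_a: [getattr(report_narrow, m) for m in _COMPARE_METRICS],
            name_b: [getattr(report_broad, m) for m in _COMPARE_METRICS],
        }
    )
    df["difference"] = df[name_b] - df[name_a]
    return df


def write_gene_summary_tsv(summaries: Sequence[GeneScopeSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_unique_protospacers\teditable\n")
        for s in summaries:
            fh.write(f"{s.gene_id}\t{s.n_unique_protospacers}\t{str(s.editable).lower()}\n")


def plot_gene_counts(report: ScopeReport, path) -> None:
    """Bar charts of genes per unique-protospacer count, exact and cumulative."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    ks = sorted(report.per_k_exact)
    axes[0].bar(ks, [report.per_k_exact[k] for k in ks], color="#4477aa")
    axes[0].set_xlabel("unique protospacers per gene")
    axes[0].set_ylabel("genes (exact)")
    kc = sorted(report.per_k_cumulative)
    axes[1].bar(kc, [report.per_k_cumulative[k] for k in kc], color="#66ccee")
    axes[1].set_xlabel("unique protospacers per gene (at least k)")
    axes[1].set_ylabel("genes (cumulative)")
    title = report.pam or ""
    if title:
        fig.suptitle(f"PAM {title}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
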