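"""Shared fixtures: random genomes for oracle comparisons and a planted
synthetic genome reused across scanner/scope tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from cbestop.genome_io import CdsFeature, GenomeRecord
from cbestop.simulate import SyntheticGenomeSpec, generate_genome


def random_genome(seed: int, length: int = 3000, n_genes: int = 3, gc: float = 0.72):
    """A fully random genome with random single-interval CDSs.

    Unlike the package's planted generator, gene content here is arbitrary
    (editable codons arise by chance), which is what the brute-force oracle
    comparisons want.
    """
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
    genome = GenomeRecord(f"rand_{seed}", seq, "linear")
    cds_list = []
    slot = length // n_genes
    for i in range(n_genes):
        gene_len = 3 * int(rng.integers(20, min(80, (slot - 60) // 3)))
        start = slot * i + int(rng.integers(30, slot - gene_len - 30))
        strand = "+" if rng.random() < 0.5 else "-"
        cds_list.append(
            CdsFeature(f"rg_{seed}_{i}", genome.contig_id, start, start + gene_len, strand)
        )
    return genome, cds_list


@pytest.fixture(scope="session")
def planted_genome():
    """Planted 10 kb genome: 5 genes, one CAG+CGG protospacer each at window
    position 5, with the exact truth manifest."""
    spec = SyntheticGenomeSpec(seed=1, length=10_000, gc_fraction=0.72, n_genes=5)
    return generate_genome(spec)


def scan_key_set(protospacers):
    """Comparison key including the target window position (matches the
    manifest's tie-breaking)."""
    return {
        (p.gene_id, p.spacer, p.pam, p.spacer_strand, p.start, p.end, p.target_c_pos)
        for p in protospacers
    }


def placement_key_set(protospacers):
    """Comparison key without the window position (matches the oracle)."""
    return {
        (p.gene_id, p.spacer, p.pam, p.spacer_strand, p.start, p.end) for p in protospacers
    }
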