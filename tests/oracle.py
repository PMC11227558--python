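"""Independent brute-force reference scanner used only by the tests.

Enumerates every 23-mer on both strands of a genome, checks PAM membership,
and asks whether any in-window C is a stop-introducing target cytosine of a
non-partial CDS. Implemented purely with string operations and deliberately
shares no code with the package's scanner.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _pam_ok(trimer: str, pattern: str) -> bool:
    return all(b in _IUPAC[p] for b, p in zip(trimer, pattern))


def target_c_map(seq: str, cds_list) -> dict[tuple[int, str], set[str]]:
    """Map (reference position, strand of the C) -> gene ids for every
    stop-introducing cytosine, by direct codon inspection."""
    targets: dict[tuple[int, str], set[str]] = {}

    def add(pos: int, strand: str, gene: str) -> None:
        targets.setdefault((pos, strand), set()).add(gene)

    for cds in cds_list:
        if cds.partial:
            continue
        coding = seq[cds.start : cds.end]
        if cds.strand == "-":
            coding = rc(coding)
        n_codons = len(coding) // 3
        for i in range(1, n_codons - 1):
            codon = coding[3 * i : 3 * i + 3]
            if codon in ("CAA", "CAG", "CGA"):
                offsets = [(3 * i, cds.strand)]
            elif codon == "TGG":
                other = "-" if cds.strand == "+" else "+"
                offsets = [(3 * i + 1, other), (3 * i + 2, other)]
            else:
                continue
            for offset, strand in offsets:
                pos = cds.start + offset if cds.strand == "+" else cds.end - 1 - offset
                add(pos, strand, cds.gene_id)
    return targets


def brute_force_scan(genome, cds_list, pam_pattern: str, window: tuple[int, int]) -> set[tuple]:
    """Set of (gene_id, spacer, pam, strand, start, end) placements.

    Considers linear topology only (the package default).
    """
    seq = genome.seq
    n = len(seq)
    first, last = window
    targets = target_c_map(seq, [c for c in cds_list if c.contig_id == genome.contig_id])
    hits: set[tuple] = set()
    for s in range(0, n - 22):
        # plus strand: spacer [s, s+20), PAM [s+20, s+23)
        spacer = seq[s : s + 20]
        pam = seq[s + 20 : s + 23]
        if "N" not in spacer and "N" not in pam and _pam_ok(pam, pam_pattern):
            for p in range(first, last + 1):
                if spacer[p - 1] == "C":
                    for gene in targets.get((s + p - 1, "+"), ()):
                        hits.add((gene, spacer, pam, "+", s, s + 20))
        # minus strand: spacer occupies [s+3, s+23), PAM [s, s+3) on the reference
        spacer_m = rc(seq[s + 3 : s + 23])
        pam_m = rc(seq[s : s + 3])
        if "N" not in spacer_m and "N" not in pam_m and _pam_ok(pam_m, pam_pattern):
            for p in range(first, last + 1):
                if spacer_m[p - 1] == "C":
                    # spacer position p sits at reference coordinate s+23-p
                    for gene in targets.get((s + 23 - p, "-"), ()):
                        hits.add((gene, spacer_m, pam_m, "-", s + 3, s + 23))
    return hits
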