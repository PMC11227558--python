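"""Stop-codon target discovery and protospacer enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbestop.genome_io import CdsFeature, GenomeRecord
from cbestop.scanner import (
    EditingWindow,
    PamSpec,
    ScanError,
    dedupe,
    enumerate_protospacers,
    find_editable_targets,
    match_pattern,
    revcomp,
    scan_genome,
)

from conftest import placement_key_set, random_genome, scan_key_set
from oracle import brute_force_scan

W48 = EditingWindow(4, 8)


class TestFindEditableTargets:
    def test_cag_codon_yields_one_coding_strand_target(self):
        cds = CdsFeature("g", "c", 0, 9, "+")
        (t,) = find_editable_targets("ATGCAGTAA", cds)
        assert (t.codon_index, t.codon_seq, t.target_strand) == (2, "CAG", "coding")
        assert t.resulting_stop == "TAG"
        assert (t.c_genomic_pos, t.c_strand) == (3, "+")

    def test_tgg_codon_yields_two_template_strand_targets(self):
        cds = CdsFeature("g", "c", 0, 9, "+")
        targets = find_editable_targets("ATGTGGTAA", cds)
        assert [t.resulting_stop for t in targets] == ["TGA", "TAG"]
        assert all(t.target_strand == "template" and t.c_strand == "-" for t in targets)
        # the template Cs oppose the third and second G of TGG
        assert [t.c_genomic_pos for t in targets] == [5, 4]

    def test_no_editable_codon(self):
        cds = CdsFeature("g", "c", 0, 9, "+")
        assert find_editable_targets("ATGGGTTAA", cds) == []

    def test_start_and_terminal_stop_excluded(self):
        # CAG as codon 1 substitute and native stop are never targets
        cds = CdsFeature("g", "c", 0, 9, "+")
        assert find_editable_targets("CAGGGTTGA", cds) == []

    def test_minus_strand_coordinates(self):
        # coding ATGCAGTAA on -, genomic slice is its reverse complement
        cds = CdsFeature("g", "c", 0, 9, "-")
        (t,) = find_editable_targets("ATGCAGTAA", cds)
        # coding offset 3 maps to genomic end-1-3 = 5 on the minus strand
        assert (t.c_genomic_pos, t.c_strand) == (5, "-")

    def test_length_not_divisible_by_three_errors(self):
        cds = CdsFeature("g", "c", 0, 10, "+", partial=True)
        with pytest.raises(ScanError):
            find_editable_targets("ATGCAGTAAC", cds)


def _single_hit_fixture():
    """40-nt genome holding one CAG gene whose target C can only pair with
    an NGG PAM at window position 5 (verified against the brute-force
    oracle below)."""
    seq = list("A" * 40)
    gene_start, gene_len = 1, 36  # 12 codons
    codons = ["ATG"] + ["GTT"] * 10 + ["TAA"]
    codons[3] = "CAG"  # codon 4, C at reference position 1 + 9 = 10
    seq[gene_start : gene_start + gene_len] = list("".join(codons))
    # intended NGG PAM for window position 5: spacer [6, 26), PAM [26, 29)
    seq[26:29] = list("AGG")
    seq[29] = "T"  # break NGG at window position 4 (middle base 28 is G)
    genome = GenomeRecord("fix", "".join(seq))
    cds = CdsFeature("gfix", "fix", gene_start, gene_start + gene_len, "+")
    return genome, cds


class TestEnumerateProtospacers:
    def test_single_ngg_placement_at_window_position_5(self):
        genome, cds = _single_hit_fixture()
        (target,) = find_editable_targets(genome.seq[cds.start : cds.end], cds)
        hits = enumerate_protospacers(genome, target, PamSpec("NGG"), W48)
        assert len(hits) == 1
        (h,) = hits
        assert h.target_c_pos == 5
        assert h.spacer == genome.seq[6:26] and h.pam == "AGG"
        assert h.spacer[h.target_c_pos - 1] == "C"

    def test_ngn_superset_matches_oracle(self):
        genome, cds = _single_hit_fixture()
        ngg = scan_genome([genome], [cds], PamSpec("NGG"), W48)
        ngn = scan_genome([genome], [cds], PamSpec("NGN"), W48)
        assert placement_key_set(ngg) <= placement_key_set(ngn)
        assert placement_key_set(ngn) == brute_force_scan(genome, [cds], "NGN", (4, 8))

    def test_window_exclusion_gives_zero(self):
        genome, cds = _single_hit_fixture()
        (target,) = find_editable_targets(genome.seq[cds.start : cds.end], cds)
        # window 6-8 excludes the only PAM-compatible placement (position 5)
        assert enumerate_protospacers(genome, target, PamSpec("NGG"), EditingWindow(6, 8)) == []

    def test_candidates_near_contig_end_skipped(self):
        # C close to the 3' end: placements running off the contig vanish
        seq = "ATGCAGTAA" + "G" * 5
        genome = GenomeRecord("edge", seq)
        cds = CdsFeature("g", "edge", 0, 9, "+")
        (target,) = find_editable_targets("ATGCAGTAA", cds)
        hits = enumerate_protospacers(genome, target, PamSpec("NNN"), W48)
        assert hits == []  # every 23-mer placement needs bases left of position 0

    def test_circular_topology_allows_wraparound(self):
        seq = "ATGCAGTAA" + "G" * 20  # 29 nt: only the p=4 placement fits linearly
        linear = GenomeRecord("c", seq, "linear")
        circular = GenomeRecord("c", seq, "circular")
        cds = CdsFeature("g", "c", 0, 9, "+")
        (target,) = find_editable_targets("ATGCAGTAA", cds)
        assert len(enumerate_protospacers(linear, target, PamSpec("NNN"), W48)) == 1
        hits = enumerate_protospacers(circular, target, PamSpec("NNN"), W48)
        assert len(hits) == 5  # the other window offsets wrap around the origin


class TestDedupe:
    def test_identical_records_collapse(self):
        genome, cds = _single_hit_fixture()
        hits = scan_genome([genome], [cds], PamSpec("NGG"), W48)
        assert dedupe(hits + hits) == hits

    def test_same_spacer_different_location_kept(self, planted_genome):
        genome, cds_list, _ = planted_genome
        hits = scan_genome([genome], cds_list, PamSpec("NGG"), W48)
        keys = {(h.spacer, h.pam, h.spacer_strand, h.start) for h in hits}
        assert len(dedupe(hits)) == len(keys)

    def test_empty(self):
        assert dedupe([]) == []


class TestMatchPattern:
    def test_experimental_site_pattern(self):
        assert match_pattern("AAGATCAGAAAAAAAAAAAACGG", "NNDDTCDDDNNNNNNNNNNNCGN")

    def test_position5_mismatch(self):
        assert not match_pattern("AAGAGCAGAAAAAAAAAAAACGG", "NNDDTCDDDNNNNNNNNNNNCGN")

    @given(st.text(alphabet="ACGT", min_size=23, max_size=23))
    def test_all_n_pattern_matches_everything(self, seq):
        assert match_pattern(seq, "N" * 23)

    def test_length_mismatch_errors(self):
        with pytest.raises(ScanError):
            match_pattern("ACGT", "N" * 23)


class TestScanGenome:
    def test_planted_truth_recovery(self, planted_genome):
        genome, cds_list, manifest = planted_genome
        hits = scan_genome([genome], cds_list, PamSpec("NGG"), W48)
        assert scan_key_set(hits) == manifest.key_set("NGG", (4, 8))

    def test_zero_cds_features(self, planted_genome):
        genome, _, _ = planted_genome
        assert scan_genome([genome], [], PamSpec("NGN"), W48) == []

    def test_pam_monotonicity(self, planted_genome):
        genome, cds_list, _ = planted_genome
        ngg = placement_key_set(scan_genome([genome], cds_list, PamSpec("NGG"), W48))
        ngn = placement_key_set(scan_genome([genome], cds_list, PamSpec("NGN"), W48))
        assert ngg <= ngn

    def test_window_monotonicity(self):
        genome, cds_list = random_genome(seed=7)
        narrow = placement_key_set(scan_genome([genome], cds_list, PamSpec("NGN"), EditingWindow(5, 8)))
        wide = placement_key_set(scan_genome([genome], cds_list, PamSpec("NGN"), W48))
        assert narrow <= wide

    def test_strand_symmetry(self):
        """Scanning the reverse-complemented genome with mirrored CDSs yields
        the coordinate-mirrored protospacer set."""
        genome, cds_list = random_genome(seed=13)
        n = len(genome.seq)
        mirrored_genome = GenomeRecord(genome.contig_id, revcomp(genome.seq))
        mirrored_cds = [
            CdsFeature(c.gene_id, c.contig_id, n - c.end, n - c.start,
                       "-" if c.strand == "+" else "+")
            for c in cds_list
        ]
        fwd = scan_genome([genome], cds_list, PamSpec("NGN"), W48)
        rev = scan_genome([mirrored_genome], mirrored_cds, PamSpec("NGN"), W48)
        mirrored = {
            (p.gene_id, p.spacer, p.pam, "+" if p.spacer_strand == "-" else "-",
             n - p.end, n - p.start)
            for p in rev
        }
        assert placement_key_set(fwd) == mirrored

    def test_emitted_protospacers_satisfy_invariants(self):
        genome, cds_list = random_genome(seed=21)
        pam = PamSpec("NGA")
        for p in scan_genome([genome], cds_list, pam, W48):
            assert len(p.spacer) == 20 and len(p.pam) == 3
            assert p.spacer[p.target_c_pos - 1] == "C"
            assert 4 <= p.target_c_pos <= 8
            assert pam.matches(p.pam)
            assert p.end - p.start == 20

    @pytest.mark.parametrize("seed", [101, 102, 103])
    @pytest.mark.parametrize("pam", ["NGG", "NGN"])
    def test_oracle_equivalence_random_genomes(self, seed, pam):
        genome, cds_list = random_genome(seed=seed)
        hits = scan_genome([genome], cds_list, PamSpec(pam), W48)
        assert placement_key_set(hits) == brute_force_scan(genome, cds_list, pam, (4, 8))


def test_invalid_pam_and_window():
    with pytest.raises(ScanError):
        PamSpec("NGGG")
    with pytest.raises(ScanError):
        PamSpec("NQX")
    with pytest.raises(ScanError):
        EditingWindow(9, 4)
    with pytest.raises(ScanError):
        EditingWindow(0, 8)
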