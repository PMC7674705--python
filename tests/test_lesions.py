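import random

import pytest

from dolloscan import (
    GeneModel,
    ScanParams,
    check_splice_sites,
    detect_frameshifts,
    detect_nonsense,
    detect_start_loss,
    extract_cds,
    quality_check,
    scan_gene,
    slice_first_exons,
    translate,
)
from dolloscan.lesions import project_to_reference
from dolloscan.simulate import SimConfig, generate_dataset, random_orf


class TestExtractCds:
    def test_single_exon(self):
        m = GeneModel("g", "s", "c", "+", exons=[(0, 9)])
        assert extract_cds("ATGAAATGAC", m) == "ATGAAATGA"

    def test_two_exons_spliced(self):
        m = GeneModel("g", "s", "c", "+", exons=[(0, 3), (6, 9)])
        assert extract_cds("ATGCCCTGA", m) == "ATGTGA"

    def test_minus_strand_revcomp(self):
        m = GeneModel("g", "s", "c", "-", exons=[(0, 3)])
        assert extract_cds("CAT", m) == "ATG"

    def test_out_of_bounds_is_error(self):
        m = GeneModel("g", "s", "c", "+", exons=[(0, 99)])
        with pytest.raises(ValueError, match="outside"):
            extract_cds("ATG", m)


class TestSliceFirstExons:
    def test_plus_strand_takes_lowest_coordinates(self):
        m = GeneModel("g", "s", "c", "+", exons=[(i * 20, i * 20 + 10) for i in range(16)])
        sliced = slice_first_exons(m, 3)
        assert sliced.exons == [(0, 10), (20, 30), (40, 50)]

    def test_minus_strand_takes_highest_coordinates(self):
        m = GeneModel("g", "s", "c", "-", exons=[(0, 10), (20, 30), (40, 50), (60, 70)])
        sliced = slice_first_exons(m, 2)
        assert sliced.exons == [(40, 50), (60, 70)]

    def test_k_at_least_n_exons_is_identity(self):
        m = GeneModel("g", "s", "c", "+", exons=[(0, 10), (20, 30)])
        assert slice_first_exons(m, 5) is m

    def test_k_one(self):
        m = GeneModel("g", "s", "c", "+", exons=[(0, 10), (20, 30)])
        assert slice_first_exons(m, 1).exons == [(0, 10)]


class TestTranslate:
    @pytest.mark.parametrize(
        "cdna,expected",
        [("ATGTTTTGA", "MF*"), ("", ""), ("ATGNNNTGA", "MX*"), ("ATGAA", "M")],
    )
    def test_examples(self, cdna, expected):
        assert translate(cdna) == expected


class TestDetectNonsense:
    def test_clean_orf(self):
        assert detect_nonsense("ATGAAATGA") == []

    def test_premature_stop_position(self):
        (les,) = detect_nonsense("ATGTAAAAATGA")
        assert les.kind == "NONSENSE" and les.cds_pos == 1

    def test_terminal_stop_never_a_lesion(self):
        assert detect_nonsense("ATGTGA") == []

    def test_injected_stops_recovered_exactly(self):
        # n random ORFs, stops injected at known codons: detected == injected
        rng = random.Random(7)
        for _ in range(100):
            orf = random_orf(120, rng)
            codons = sorted(rng.sample(range(2, 110), 3))
            seq = list(orf)
            for ci in codons:
                seq[3 * ci : 3 * ci + 3] = list(rng.choice(["TAA", "TAG", "TGA"]))
            found = [l.cds_pos for l in detect_nonsense("".join(seq))]
            assert found == codons


class TestDetectFrameshifts:
    def test_identical_rows(self):
        assert detect_frameshifts("ACGTACGT", "ACGTACGT") == []

    def test_in_frame_gap_ignored(self):
        assert detect_frameshifts("ACG---TT", "ACGTACTT") == []

    def test_each_gap_run_counts_even_if_frame_restored(self):
        # 1-nt deletion at 30, 2-nt insertion at 90 (net frame restored)
        target_row = "A" * 30 + "-" + "A" * 59 + "AA" + "A" * 30
        ref_row = "A" * 30 + "A" + "A" * 59 + "--" + "A" * 30
        lesions = detect_frameshifts(target_row, ref_row)
        assert [(l.kind, l.cds_pos, l.detail) for l in lesions] == [
            ("FRAMESHIFT", 30, "-1"),
            ("FRAMESHIFT", 90, "+2"),
        ]

    def test_unequal_rows_error(self):
        with pytest.raises(ValueError):
            detect_frameshifts("AC", "ACG")

    def test_compensating_3k_indels_yield_nothing(self):
        target_row = "AAA---CCCGGGTTT"
        ref_row = "AAACCC---GGGTTT"
        assert detect_frameshifts(target_row, ref_row) == []


class TestCheckSpliceSites:
    def _model(self, strand="+"):
        return GeneModel("g", "s", "c", strand, exons=[(0, 6), (26, 32)])

    def test_canonical_gt_ag(self):
        contig = "ATGAAA" + "GT" + "C" * 16 + "AG" + "AAATGA"
        assert check_splice_sites(contig, self._model()) == []

    def test_bad_donor_reported_with_observed_dinucleotide(self):
        contig = "ATGAAA" + "GA" + "C" * 16 + "AG" + "AAATGA"
        (les,) = check_splice_sites(contig, self._model())
        assert les.kind == "SPLICE_DONOR" and les.detail == "GA"
        assert les.cds_pos == 6  # boundary offset in the spliced CDS

    def test_minor_spliceosome_at_ac_accepted(self):
        contig = "ATGAAA" + "AT" + "C" * 16 + "AC" + "AAATGA"
        assert check_splice_sites(contig, self._model()) == []

    def test_minus_strand_orientation(self):
        # same gene on the minus strand: mirror the plus construct
        plus = "ATGAAA" + "GT" + "C" * 16 + "AG" + "AAATGA"
        from dolloscan.lesions import revcomp

        contig = revcomp(plus)
        n = len(contig)
        m = GeneModel("g", "s", "c", "-", exons=[(n - 32, n - 26), (n - 6, n)])
        assert check_splice_sites(contig, m) == []

    def test_short_intron_is_truncation(self):
        m = GeneModel("g", "s", "c", "+", exons=[(0, 6), (8, 14)])
        (les,) = check_splice_sites("ATGAAACCAAATGAAA", m)
        assert les.kind == "TRUNCATION"


class TestDetectStartLoss:
    def test_intact_start(self):
        assert detect_start_loss("ATGAAATGA") == []

    def test_lost_start_with_downstream_rescue(self):
        (les,) = detect_start_loss("CTGAAAATGGGGTGA", rescue_window=50)
        assert les.kind == "START_LOSS" and les.rescuable

    def test_lost_start_no_rescue(self):
        seq = "CTG" + "AAA" * 200
        (les,) = detect_start_loss(seq, rescue_window=50)
        assert not les.rescuable


class TestQualityCheck:
    def test_clean_full_length_passes(self):
        qc = quality_check("ACGT" * 100, 400)
        assert qc.passed and qc.coverage == 1.0 and qc.n_fraction == 0.0

    def test_half_n_fails(self):
        qc = quality_check("AN" * 200, 400)
        assert not qc.passed and qc.n_fraction == 0.5

    def test_half_length_fails_coverage(self):
        qc = quality_check("ACGT" * 50, 400)
        assert not qc.passed and qc.coverage == 0.5

    def test_empty_sequence(self):
        qc = quality_check("", 400)
        assert not qc.passed and qc.coverage == 0.0


class TestProjection:
    def test_insertion_dropped_deletion_masked(self):
        #      target: ACGTTT with TT inserted; ref: ACG-del
        target_row = "ACGTT-T"
        ref_row = "ACG--AT"
        assert project_to_reference(target_row, ref_row) == "ACGNT"


class TestScanGene:
    def test_simulated_intact_gene_has_no_lesions(self, default_dataset):
        ds = default_dataset
        sp = "sp12"  # outside both loss clades in the default dataset
        for gene in ds.config.genes:
            assert ds.truth.true_status(sp, gene) == "INTACT"
            rep = scan_gene(
                ds.contigs[(sp, gene)], ds.models[(sp, gene)], ds.references[gene]
            )
            assert rep.lesions == [] and not rep.excluded

    def test_injected_stop_and_deletion_both_found(self):
        rng = random.Random(11)
        ref = random_orf(200, rng)
        seq = list(ref)
        seq[3 * 50 : 3 * 50 + 3] = list("TAA")  # stop at codon 50
        del seq[360]  # 1-nt deletion at position 360
        contig = "".join(seq)
        model = GeneModel("g", "s", "c", "+", exons=[(0, len(contig))])
        rep = scan_gene(contig, model, ref)
        kinds = sorted((l.kind, l.cds_pos) for l in rep.lesions)
        assert ("NONSENSE", 50) in kinds
        assert any(k == "FRAMESHIFT" and abs(p - 360) <= 6 for k, p in kinds)
        assert len(kinds) == 2

    def test_heavily_masked_sequence_is_excluded(self):
        rng = random.Random(3)
        ref = random_orf(100, rng)
        contig = "N" * 120 + ref[120:]
        model = GeneModel("g", "s", "c", "+", exons=[(0, len(contig))])
        rep = scan_gene(contig, model, ref)
        assert rep.excluded and rep.lesions == []

    def test_all_positions_within_cds_bounds(self, default_dataset):
        ds = default_dataset
        for (sp, gene), model in ds.models.items():
            rep = scan_gene(ds.contigs[(sp, gene)], model, ds.references[gene])
            for les in rep.lesions:
                nt = les.cds_pos * 3 if les.kind == "NONSENSE" else les.cds_pos
                assert 0 <= nt < len(ds.references[gene]) + 30
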