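"""Indel profiling, motif scanning, proximity enrichment, probe drop-off."""

import numpy as np
import pysam
import pytest
from scipy import stats

from abcquant import (
    AmpliconRef,
    EditModel,
    IndelProfile,
    parse_alignments,
    probe_window_dropoff,
    proximity_enrichment,
    scan_motifs,
    simulate_reads,
)
from abcquant import fixtures


def write_sam(path, ref_name, ref_len, records):
    """records: (qname, pos, cigar, seq)"""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for qname, pos, cigar, seq, flag in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            sam.write(a)


@pytest.fixture
def tiny_ref():
    seq = "ACGTACGTACGTACGTACGT"  # 20 bp, no CpG
    return AmpliconRef(name="tiny", chrom="chr1", start=0, end=20, sequence=seq)


class TestParseAlignments:
    def test_deletion_cigar_semantics(self, tiny_ref, tmp_path):
        """10M2D10M starting at 0 -> deletion counted at positions 10, 11."""
        seq = tiny_ref.sequence[:10] + tiny_ref.sequence[12:]
        sam = tmp_path / "d.sam"
        write_sam(sam, "tiny", 20, [("r1", 0, "10M2D8M", seq, 0)])
        prof = parse_alignments(sam, tiny_ref)
        expected = np.zeros(20, dtype=int)
        expected[10:12] = 1
        assert np.array_equal(prof.del_cov, expected)
        assert prof.del_start[10] == 1 and prof.del_start.sum() == 1
        assert prof.depth.sum() == 20  # deletion included in the footprint
        assert prof.ins_count.sum() == 0

    def test_insertion_cigar_semantics(self, tiny_ref, tmp_path):
        """5M1I5M -> insertion assigned to reference position 5."""
        seq = tiny_ref.sequence[:5] + "A" + tiny_ref.sequence[5:10]
        sam = tmp_path / "i.sam"
        write_sam(sam, "tiny", 20, [("r1", 0, "5M1I5M", seq, 0)])
        prof = parse_alignments(sam, tiny_ref)
        assert prof.ins_count[5] == 1 and prof.ins_count.sum() == 1
        assert prof.del_cov.sum() == 0
        assert np.array_equal(prof.depth[:10], np.ones(10, dtype=int))

    def test_secondary_and_unmapped_skipped(self, tiny_ref, tmp_path):
        sam = tmp_path / "s.sam"
        write_sam(
            sam, "tiny", 20,
            [
                ("r1", 0, "20M", tiny_ref.sequence, 0),
                ("r2", 0, "20M", tiny_ref.sequence, 256),  # secondary
                ("r3", 0, "20M", tiny_ref.sequence, 4),  # unmapped
            ],
        )
        prof = parse_alignments(sam, tiny_ref)
        assert prof.n_reads == 1 and prof.n_skipped == 2

    def test_footprint_outside_reference_rejected(self, tiny_ref, tmp_path):
        sam = tmp_path / "o.sam"
        write_sam(sam, "tiny", 20, [("r1", 10, "15M", "A" * 15, 0)])
        prof = parse_alignments(sam, tiny_ref)
        assert prof.n_rejected == 1 and prof.n_reads == 0

    def test_profile_matches_simulator_truth(self, crlf2_amplicon, tmp_path):
        """Per-position deletion frequency agrees with ground truth within
        binomial 3-sigma at 50,000 reads."""
        model = EditModel(
            p_edit=0.15,
            hotspot_centers=crlf2_amplicon.cpg_positions,
            hotspot_weights=(0.45, 0.45, 0.10),
            kernel_sd=3.0,
        )
        n_reads = 50_000
        sam = tmp_path / "big.sam"
        truth = simulate_reads(crlf2_amplicon, n_reads, model, seed=77, sam_path=sam)
        prof = parse_alignments(sam, crlf2_amplicon)
        assert prof.n_reads == n_reads
        L = len(crlf2_amplicon)
        true_cov = truth.deletion_cov_counts(L)
        # exact agreement: CIGARs encode the truth
        assert np.array_equal(prof.del_cov, true_cov)
        assert np.array_equal(prof.ins_count, truth.insertion_counts(L))
        # total deletion events within binomial 3-sigma of the model rate
        p_del_read = model.p_edit * model.deletion_prob
        sigma = np.sqrt(n_reads * p_del_read * (1 - p_del_read))
        n_dels = prof.del_start.sum()
        assert abs(n_dels - n_reads * p_del_read) < 3 * sigma + truth.n_skipped_edits
        # the kernel confines deletions to the hotspot neighborhoods
        near = np.zeros(L, dtype=bool)
        for c in model.hotspot_centers:
            near[max(0, c - 12) : c + 13] = True
        assert prof.del_start[near].sum() / n_dels > 0.99


class TestScanMotifs:
    def test_amigo1_control_locus_has_one_cpg(self):
        # the AMIGO1 control 16-mer: single CpG at offset 9
        assert scan_motifs("CACAATGGGCGTATCA", "CpG") == [9]

    def test_plekha5_control_locus_has_no_cpg(self):
        assert scan_motifs("TGACTGTGGAAGAGCA", "CpG") == []

    def test_empty_sequence(self):
        assert scan_motifs("", "CpG") == []
        assert scan_motifs("", "WGCW") == []

    def test_cpg_is_strand_symmetric(self, crlf2_amplicon):
        seq = crlf2_amplicon.sequence
        assert scan_motifs(seq, "CpG", both_strands=True) == scan_motifs(
            seq, "CpG", both_strands=False
        )

    def test_wgcw_reverse_strand_projection(self):
        # forward: AGCT matches WGCW at 0; reverse complement of TGCA is TGCA
        assert scan_motifs("AGCT", "WGCW", both_strands=False) == [0]
        # reverse-complement-only match: forward AACG has no WGCW,
        # its RC CGTT has none either; use WRC: forward TACC -> [0]? T A C -> WRC at 0
        assert 0 in scan_motifs("TACC", "WRC", both_strands=False)

    def test_rcg_subset_of_cpg_context(self):
        seq = "AACGTTGCGA"
        rcg = scan_motifs(seq, "RCG", both_strands=False)
        cpg = scan_motifs(seq, "CpG")
        assert all(p + 1 in cpg for p in rcg)

    def test_n_never_matches(self):
        assert scan_motifs("CNGCG", "CpG") == [3]

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("ACGT", "XYZ")

    def test_overlapping_matches_found(self):
        assert scan_motifs("CGCG", "CpG", both_strands=False) == [0, 2]


def make_profile(n_pos, depth, del_start=None, ins=None):
    del_start = del_start if del_start is not None else np.zeros(n_pos, dtype=int)
    ins = ins if ins is not None else np.zeros(n_pos, dtype=int)
    return IndelProfile(
        ref_name="x",
        depth=np.full(n_pos, depth, dtype=int),
        del_cov=del_start.copy(),
        del_start=del_start,
        ins_count=ins,
        n_reads=depth,
    )


class TestProximityEnrichment:
    def test_events_on_cpgs_give_fraction_one(self):
        del_start = np.zeros(200, dtype=int)
        del_start[[50, 120]] = 30
        prof = make_profile(200, 1000, del_start=del_start)
        res = proximity_enrichment(prof, [50, 120], window=8, n_perm=500, seed=1)
        assert res.observed_fraction == 1.0
        assert res.fold_enrichment > 1
        assert res.p_value < 0.01

    def test_no_events_not_evaluable(self):
        prof = make_profile(100, 1000)
        res = proximity_enrichment(prof, [50], n_perm=100, seed=1)
        assert not res.evaluable and "no indel events" in res.reason

    def test_no_cpgs_not_evaluable(self):
        del_start = np.zeros(100, dtype=int)
        del_start[10] = 5
        prof = make_profile(100, 1000, del_start=del_start)
        res = proximity_enrichment(prof, [], n_perm=100, seed=1)
        assert not res.evaluable and "CpG" in res.reason

    def test_null_calibration(self):
        """Uniformly placed events give fold ~1 and uniform p-values."""
        rng = np.random.default_rng(2024)
        n_pos, n_events = 300, 150
        cpgs = [60, 150, 240]
        pvals, folds = [], []
        for rep in range(200):
            placed = rng.multinomial(n_events, np.full(n_pos, 1 / n_pos))
            prof = make_profile(n_pos, 2000, del_start=placed)
            res = proximity_enrichment(prof, cpgs, window=8, n_perm=400, seed=rep)
            pvals.append(res.p_value)
            folds.append(res.fold_enrichment)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)
        # p-values uniform or super-uniform under the null
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3 or np.mean(np.asarray(pvals) < 0.05) <= 0.07

    def test_focal_editing_is_enriched(self, crlf2_amplicon, tmp_path):
        """Kernel sd = 3 bp around CpGs -> strong, significant enrichment."""
        model = EditModel(
            p_edit=0.1, hotspot_centers=crlf2_amplicon.cpg_positions, kernel_sd=3.0
        )
        sam = tmp_path / "e.sam"
        simulate_reads(crlf2_amplicon, 10_000, model, seed=9, sam_path=sam)
        prof = parse_alignments(sam, crlf2_amplicon)
        res = proximity_enrichment(
            prof, crlf2_amplicon.cpg_positions, window=8, n_perm=2000, seed=10
        )
        assert res.fold_enrichment > 1.5
        assert res.p_value < 0.01


class TestProbeWindowDropoff:
    def test_no_edits_zero_everywhere(self, crlf2_amplicon, tmp_path):
        model = EditModel(p_edit=0.0, hotspot_centers=crlf2_amplicon.cpg_positions)
        sam = tmp_path / "z.sam"
        simulate_reads(crlf2_amplicon, 200, model, seed=11, sam_path=sam)
        panel = fixtures.crlf2_panel()
        out = probe_window_dropoff(
            sam, fixtures.probe_intervals_local(panel, crlf2_amplicon), crlf2_amplicon
        )
        assert all(v["fraction"] == 0.0 for v in out.values())
        assert all(v["n_spanning"] == 200 for v in out.values())

    def test_single_deletion_inside_probe(self, tiny_ref, tmp_path):
        sam = tmp_path / "p.sam"
        seq = tiny_ref.sequence[:10] + tiny_ref.sequence[12:]
        write_sam(sam, "tiny", 20, [("r1", 0, "10M2D8M", seq, 0)])
        out = probe_window_dropoff(sam, [("hit", 9, 14), ("miss", 0, 5)], tiny_ref)
        assert out["hit"] == {"fraction": 1.0, "n_dropped": 1, "n_spanning": 1}
        assert out["miss"]["fraction"] == 0.0

    def test_insertion_overlap_window(self, tiny_ref, tmp_path):
        """Insertion at p counts against a probe covering [p-1, p+1)."""
        sam = tmp_path / "pi.sam"
        seq = tiny_ref.sequence[:5] + "A" + tiny_ref.sequence[5:]
        write_sam(sam, "tiny", 20, [("r1", 0, "5M1I15M", seq, 0)])
        out = probe_window_dropoff(sam, [("left", 0, 5), ("right", 5, 10), ("far", 10, 15)], tiny_ref)
        assert out["left"]["fraction"] == 1.0  # overlaps [4, 6)
        assert out["right"]["fraction"] == 1.0
        assert out["far"]["fraction"] == 0.0

    def test_probe_outside_amplicon_rejected(self, tiny_ref, tmp_path):
        sam = tmp_path / "x.sam"
        write_sam(sam, "tiny", 20, [("r1", 0, "20M", tiny_ref.sequence, 0)])
        with pytest.raises(ValueError, match="outside"):
            probe_window_dropoff(sam, [("bad", 10, 25)], tiny_ref)

    def test_cross_modality_consistency(self, crlf2_amplicon, tmp_path):
        """Probe-window drop-off from reads tracks the simulated edit rate
        at the targeted probe."""
        panel = fixtures.crlf2_panel()
        # edit only the second CpG (TAMRA probe), tight kernel
        model = EditModel(
            p_edit=0.10,
            hotspot_centers=(crlf2_amplicon.cpg_positions[1],),
            kernel_sd=1.5,
            deletion_prob=0.8,
        )
        sam = tmp_path / "c.sam"
        simulate_reads(crlf2_amplicon, 20_000, model, seed=13, sam_path=sam)
        out = probe_window_dropoff(
            sam, fixtures.probe_intervals_local(panel, crlf2_amplicon), crlf2_amplicon
        )
        # nearly every edit falls inside the 20-bp TAMRA probe window
        assert out["CRLF2_cpg2"]["fraction"] == pytest.approx(0.10, abs=0.015)
        assert out["CRLF2_cpg3"]["fraction"] < 0.005
        assert out["CRLF2_ref"]["fraction"] < 0.005
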