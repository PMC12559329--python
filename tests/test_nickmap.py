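"""Alignment, cut calling, loop rescue, bookkeeping and export."""

import numpy as np
import pytest

from nickloop import (
    LoopSpec,
    align_reads,
    build_reference,
    call_cuts,
    export_profile,
    finalize_profile,
    generate_plasmid,
    make_heteroduplex,
    multi_peak_profile,
    preset_profile,
    rescue_loop_reads,
    run_nickmap,
    simulate_reads,
)
from nickloop.gloesim import FastqRead, truth_to_counts
from nickloop.nickmap import (
    KmerAligner,
    export_reference,
    read_profile_tsv,
    read_sam_alignments,
)
from nickloop.substrates import revcomp


def brute_force_align(ref: str, seq: str):
    """Oracle: scan every offset of both orientations, dedupe circular loci."""
    unit = len(ref) // 3
    best = {}
    for orientation, query in (("+", seq), ("-", revcomp(seq))):
        for s in range(len(ref) - len(seq) + 1):
            mm = sum(a != b for a, b in zip(ref[s:s + len(seq)], query))
            key = (orientation, s % unit)
            if key not in best or mm < best[key]:
                best[key] = mm
    return best


@pytest.fixture(scope="module")
def sub():
    return make_heteroduplex(generate_plasmid(500, 0.5, seed=21),
                             LoopSpec("top", 200, "CAG" * 4))


class TestAligner:
    def test_forward_substring_maps_uniquely(self, sub):
        bundle = build_reference(sub)
        read = FastqRead("f", sub.plasmid.sequence[100:160], "I" * 60)
        rec = align_reads([read], bundle)[0]
        assert rec.status == "unique" and rec.ref_strand == "top"
        assert rec.start - bundle.duplex_unit == 100

    def test_reverse_complement_maps_to_bottom(self, sub):
        bundle = build_reference(sub)
        read = FastqRead("r", revcomp(sub.plasmid.sequence[100:160]), "I" * 60)
        rec = align_reads([read], bundle)[0]
        assert rec.status == "unique" and rec.ref_strand == "bottom"
        assert rec.start - bundle.duplex_unit == 100

    def test_origin_spanning_read_matches_brute_force(self, sub):
        """A read across the circular origin only exists inside the
        concatenation; the internal aligner must agree with an exhaustive
        scan of all offsets in both orientations."""
        bundle = build_reference(sub)
        seq = (sub.plasmid.sequence * 2)[470:530]  # spans the origin
        rec = align_reads([FastqRead("o", seq, "I" * 60)], bundle)[0]
        oracle = brute_force_align(bundle.duplex_ref, seq)
        best_mm = min(oracle.values())
        winners = [k for k, v in oracle.items() if v == best_mm]
        assert best_mm == 0 and len(winners) == 1
        assert rec.status == "unique"
        assert (("+" if rec.ref_strand == "top" else "-"),
                rec.start % bundle.duplex_unit) == winners[0]

    @pytest.mark.parametrize("n_mm,expected", [(1, "unique"), (2, "unique"), (5, "unmapped")])
    def test_mismatch_budget(self, sub, n_mm, expected):
        bundle = build_reference(sub)
        seq = list(sub.plasmid.sequence[50:125])
        for j in range(n_mm):
            pos = 5 + 13 * j
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        rec = align_reads([FastqRead("m", "".join(seq), "I" * 75)], bundle)[0]
        assert rec.status == expected
        if expected == "unique":
            assert rec.start - bundle.duplex_unit == 50 and rec.mismatches == n_mm

    def test_repeated_segment_is_ambiguous(self):
        plasmid = generate_plasmid(600, 0.5, seed=5)
        dup = plasmid.sequence[:300] + plasmid.sequence[100:160] + plasmid.sequence[360:]
        sub = make_heteroduplex(type(plasmid)("dup", dup), LoopSpec("top", 500, ""))
        bundle = build_reference(sub)
        rec = align_reads([FastqRead("a", dup[110:150], "I" * 40)], bundle)[0]
        assert rec.status == "ambiguous"

    def test_too_short_read_unmapped(self, sub):
        aligner = KmerAligner(build_reference(sub).duplex_ref, k=20)
        assert aligner.align("ACGTACGT") == "unmapped"


class TestReferenceBundle:
    def test_lengths(self, small_substrate):
        bundle = build_reference(small_substrate)
        assert len(bundle.duplex_ref) == 3 * small_substrate.N
        assert len(bundle.loop_ref) == 3 * (small_substrate.N + small_substrate.L)

    def test_empty_loop_references_identical(self):
        sub = make_heteroduplex(generate_plasmid(200, 0.5, 1), LoopSpec("top", 50, ""))
        bundle = build_reference(sub)
        assert bundle.loop_ref == bundle.duplex_ref


class TestCutCalling:
    def test_round_trip_against_truth(self, small_substrate):
        """Every error-free read's inferred (strand, position) equals its
        simulation truth row."""
        sub = small_substrate
        peaks = [("top", 30, 1.0), ("bottom", 60, 2.0), ("bottom", 200, 1.0)]
        rs = simulate_reads(multi_peak_profile(sub, peaks), 2000, seed=8)
        profile = run_nickmap(sub, rs.reads)
        ct, cb, ll = truth_to_counts(rs.truth, sub)
        assert np.array_equal(profile.counts_top, ct)
        assert np.array_equal(profile.counts_bottom, cb)
        assert np.array_equal(profile.loop_local_counts, ll)

    def test_top_aligned_reads_give_bottom_cuts(self, small_substrate):
        sub = small_substrate
        # nicks on the bottom strand emit top-strand (forward-mapping) reads
        rs = simulate_reads(multi_peak_profile(sub, [("bottom", 250, 1.0)]), 300, seed=3)
        bundle = build_reference(sub)
        recs = align_reads(rs.reads, bundle)
        assert all(r.ref_strand == "top" for r in recs if r.status == "unique")
        profile = run_nickmap(sub, rs.reads)
        assert profile.counts_top.sum() == 0
        assert profile.counts_bottom.sum() == profile.n_mapped

    def test_zero_alignments_zero_profile(self, small_substrate):
        primary = call_cuts([], small_substrate)
        profile = finalize_profile(primary)
        assert profile.counts_top.sum() == 0 and profile.n_mapped == 0
        assert np.all(profile.cpm_top == 0)  # no division error

    def test_loop_crossing_reads_rescued_at_true_position(self, small_substrate):
        sub = small_substrate
        n, i = sub.N, sub.loop.insertion_point
        # opposite-strand nick whose read starts 20 nt 5' of the loop on the
        # looped strand and therefore crosses it
        nick_pos = n - 1 - (i - 20)
        rs = simulate_reads(multi_peak_profile(sub, [("bottom", nick_pos, 1.0)]),
                            200, read_length=60, seed=13)
        bundle = build_reference(sub)
        primary = call_cuts(align_reads(rs.reads, bundle), sub)
        assert len(primary.leftover_ids) == 200  # all fail the duplex pass
        rescue = rescue_loop_reads(rs.reads, sub, bundle)
        profile = finalize_profile(primary, rescue)
        assert profile.totals["n_rescued"] == 200
        ct, cb, ll = truth_to_counts(rs.truth, sub)
        assert np.array_equal(profile.counts_bottom, cb)

    def test_rescue_empty_input_no_calls(self, small_substrate):
        rescue = rescue_loop_reads([], small_substrate)
        assert rescue.calls == [] and rescue.statuses == {}

    def test_conservation_identity_with_errors(self, small_substrate):
        """n_input == unique + rescued + ambiguous + unmapped, every run."""
        prof = preset_profile("mutl_opposite_5prime", small_substrate)
        rs = simulate_reads(prof, 1500, error_rate=0.05, seed=17)
        profile = run_nickmap(small_substrate, rs.reads)
        t = profile.totals
        assert t["n_input"] == 1500
        assert t["n_input"] == (t["n_unique_primary"] + t["n_rescued"]
                                + t["n_ambiguous"] + t["n_unmapped_final"])
        called = (profile.counts_top.sum() + profile.counts_bottom.sum()
                  + profile.loop_local_counts.sum())
        assert called == t["n_unique_primary"] + t["n_rescued"]

    def test_cpm_sums_to_one_million(self, small_substrate):
        prof = preset_profile("fan1_loop3prime", small_substrate)
        rs = simulate_reads(prof, 800, seed=1)
        profile = run_nickmap(small_substrate, rs.reads)
        total_cpm = profile.cpm_top.sum() + profile.cpm_bottom.sum() + profile.cpm_loop.sum()
        assert total_cpm == pytest.approx(1e6)


class TestEquivariance:
    def test_rotation_of_origin_rotates_profile(self, small_substrate):
        """Same reads, origin moved by k: counts vectors roll by -k."""
        sub = small_substrate
        rs = simulate_reads(preset_profile("mutl_opposite_5prime", sub), 1000, seed=23)
        base = run_nickmap(sub, rs.reads)
        k = 123
        rotated_sub = make_heteroduplex(
            sub.plasmid.rotate(k),
            LoopSpec(sub.loop.carrier_strand,
                     (sub.loop.insertion_point - k) % sub.N,
                     sub.loop.loop_sequence))
        rotated = run_nickmap(rotated_sub, rs.reads)
        assert np.array_equal(rotated.counts_top, np.roll(base.counts_top, -k))
        assert np.array_equal(rotated.counts_bottom, np.roll(base.counts_bottom, -k))
        assert rotated.totals == base.totals

    def test_strand_flip_involution_on_plain_duplex(self):
        """Swapping the nick profile's strands flips the planted cut
        distribution, and the pipeline reproduces the flipped truth exactly
        (loop-free substrate, where the strands are geometrically symmetric)."""
        from nickloop.gloesim import profile_to_bin_distribution, truth_to_counts

        sub = make_heteroduplex(generate_plasmid(400, 0.5, 31), LoopSpec("top", 0, ""))
        peaks = [("top", 40, 1.0), ("top", 90, 2.0), ("bottom", 300, 1.5)]
        prof = multi_peak_profile(sub, peaks)
        top_d, bottom_d, _ = profile_to_bin_distribution(prof)
        ftop_d, fbottom_d, _ = profile_to_bin_distribution(prof.swap_strands())
        # native position q on top becomes q on bottom: plasmid bin j -> N-1-j
        assert np.allclose(fbottom_d, top_d[::-1])
        assert np.allclose(ftop_d, bottom_d[::-1])
        rs_flip = simulate_reads(prof.swap_strands(), 1200, seed=7)
        pf = run_nickmap(sub, rs_flip.reads)
        ct, cb, _ = truth_to_counts(rs_flip.truth, sub)
        assert np.array_equal(pf.counts_top, ct)
        assert np.array_equal(pf.counts_bottom, cb)


class TestExportImport:
    def test_tsv_round_trip_and_artifacts(self, small_substrate, tmp_path):
        rs = simulate_reads(preset_profile("fan1_loop3prime", small_substrate), 500, seed=2)
        profile = run_nickmap(small_substrate, rs.reads)
        paths = export_profile(profile, tmp_path / "out")
        ct, cb, ll = read_profile_tsv(paths["tsv"])
        assert np.array_equal(ct, profile.counts_top)
        assert np.array_equal(cb, profile.counts_bottom)
        assert np.array_equal(ll, profile.loop_local_counts)
        n_rows = sum(1 for _ in open(paths["tsv"])) - 1
        assert n_rows == 2 * small_substrate.N + small_substrate.L
        bed_lines = [l.split("\t") for l in open(paths["bed"])]
        assert len(bed_lines) == np.count_nonzero(profile.counts_top) + \
            np.count_nonzero(profile.counts_bottom)
        assert (tmp_path / "out.polar.svg").exists()
        assert (tmp_path / "out.summary.json").exists()


class TestSamImport:
    def test_sam_path_matches_internal_aligner(self, small_substrate, tmp_path):
        """SAM records built from the internal aligner's placements must
        reproduce the internal pipeline's cut profile bit for bit."""
        sub = small_substrate
        rs = simulate_reads(preset_profile("mutl_opposite_5prime", sub), 400, seed=19)
        bundle = build_reference(sub)
        recs = align_reads(rs.reads, bundle)
        ref_fa = tmp_path / "ref3x.fasta"
        export_reference(bundle, ref_fa)
        ref_name = open(ref_fa).readline()[1:].split()[0]
        sam = tmp_path / "aln.sam"
        by_id = {r.id: r for r in rs.reads}
        with open(sam, "w") as fh:
            fh.write(f"@SQ\tSN:{ref_name}\tLN:{len(bundle.duplex_ref)}\n")
            for rec in recs:
                read = by_id[rec.read_id]
                if rec.status != "unique":
                    fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t{read.qualities}\n")
                    continue
                flag = 0 if rec.ref_strand == "top" else 16
                seq = read.sequence if flag == 0 else revcomp(read.sequence)
                fh.write(f"{rec.read_id}\t{flag}\t{ref_name}\t{rec.start + 1}\t60\t"
                         f"{rec.mapped_length}M\t*\t0\t0\t{seq}\t{read.qualities}\n")
        imported = read_sam_alignments(sam, bundle)
        assert sorted((r.read_id, r.status, r.start, r.ref_strand) for r in imported) \
            == sorted((r.read_id, r.status, r.start, r.ref_strand) for r in recs)
        internal = run_nickmap(sub, rs.reads)
        via_sam = run_nickmap(sub, rs.reads, sam_path=sam)
        assert np.array_equal(internal.counts_top, via_sam.counts_top)
        assert np.array_equal(internal.counts_bottom, via_sam.counts_bottom)
        assert internal.totals == via_sam.totals
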