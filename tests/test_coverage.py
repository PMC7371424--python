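import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import orifire as ofr
from orifire.coverage import MASK_NONE, MASK_ZERO_BOTH, MASK_ZERO_G1

from conftest import brute_force_bin_counts


def frags(intervals, layout, phase="S"):
    return ofr.FragmentSet.from_intervals(intervals, layout, phase=phase)


class TestLayout:
    def test_bin_geometry(self):
        layout = ofr.GenomeLayout((("chrI", 1001),), bin_size=250)
        assert layout.n_bins("chrI") == 5
        assert layout.bin_widths("chrI").tolist() == [250, 250, 250, 250, 1]

    @pytest.mark.parametrize("alias", ["chrVI", "VI", "chr6", "6", "chrvi"])
    def test_chromosome_aliases_resolve(self, alias):
        layout = ofr.GenomeLayout((("chrVI", 1000),), bin_size=250)
        assert layout.canonical(alias) == "chrVI"

    def test_unknown_chromosome_is_an_error_not_a_drop(self, toy_layout):
        with pytest.raises(KeyError, match="chrZ"):
            toy_layout.canonical("chrZ")

    def test_rejects_duplicate_names_and_bad_lengths(self):
        with pytest.raises(ValueError):
            ofr.GenomeLayout((("chrI", 100), ("chrI", 200)))
        with pytest.raises(ValueError):
            ofr.GenomeLayout((("chrI", 0),))


class TestBinCounts:
    def test_midpoint_direct_placement(self, toy_layout):
        fs = frags([("chrI", 0, 50), ("chrI", 100, 150), ("chrI", 600, 650)],
                   toy_layout)
        track = ofr.bin_counts(fs, toy_layout, mode="midpoint")
        # [0,50) and [100,150) both midpoint into bin 0; [600,650) into bin 2
        assert track.values["chrI"].tolist() == [2, 0, 1, 0]
        assert track.total == 3

    def test_boundary_fragment_modes_differ(self, toy_layout):
        fs = frags([("chrI", 240, 260)], toy_layout)
        mid = ofr.bin_counts(fs, toy_layout, mode="midpoint")
        ov = ofr.bin_counts(fs, toy_layout, mode="overlap")
        assert mid.values["chrI"].tolist() == [1, 0, 0, 0]  # midpoint 249
        assert ov.values["chrI"].tolist() == [1, 1, 0, 0]

    def test_midpoint_conserves_fragment_count_overlap_exceeds(
            self, two_chrom_layout):
        rng = np.random.default_rng(11)
        ivals = []
        for chrom, length in two_chrom_layout.chromosomes:
            starts = rng.integers(0, length - 30, size=60)
            ivals += [(chrom, int(s), int(s) + int(rng.integers(1, 400)))
                      for s in starts]
        ivals = [(c, s, min(e, two_chrom_layout.length(c))) for c, s, e in ivals]
        fs = frags(ivals, two_chrom_layout)
        mid = ofr.bin_counts(fs, two_chrom_layout, mode="midpoint")
        ov = ofr.bin_counts(fs, two_chrom_layout, mode="overlap")
        assert sum(v.sum() for v in mid.values.values()) == len(ivals)
        assert sum(v.sum() for v in ov.values.values()) >= len(ivals)

    @pytest.mark.parametrize("mode", ["midpoint", "overlap"])
    def test_agrees_with_per_base_brute_force(self, mode):
        rng = np.random.default_rng(5)
        layout = ofr.GenomeLayout((("chrI", 3130), ("chrII", 990)), bin_size=250)
        ivals = []
        for chrom in layout.names:
            length = layout.length(chrom)
            for _ in range(100):
                s = int(rng.integers(0, length - 1))
                e = int(min(length, s + rng.integers(1, 600)))
                ivals.append((chrom, s, e))
        got = ofr.bin_counts(frags(ivals, layout), layout, mode=mode)
        want = brute_force_bin_counts(ivals, layout, mode)
        for chrom in layout.names:
            np.testing.assert_array_equal(got.values[chrom], want[chrom])

    def test_out_of_bounds_fragment_rejected(self, toy_layout):
        with pytest.raises(ValueError, match="out of bounds"):
            frags([("chrI", 900, 1100)], toy_layout)
        with pytest.raises(KeyError, match="chrXLII"):
            frags([("chrXLII", 0, 10)], toy_layout)


class TestNormalizeAndRatio:
    def test_normalize_arithmetic(self, toy_layout):
        fs = frags([("chrI", 0, 10), ("chrI", 5, 15), ("chrI", 300, 310),
                    ("chrI", 800, 810)], toy_layout)
        norm = ofr.normalize_track(ofr.bin_counts(fs, toy_layout))
        assert norm.values["chrI"].tolist() == [0.5, 0.25, 0, 0.25]
        assert abs(sum(v.sum() for v in norm.values.values()) - 1.0) < 1e-9

    def test_empty_sample_rejected(self, toy_layout):
        empty = ofr.BinnedTrack(layout=toy_layout,
                                values={"chrI": np.zeros(4, dtype=np.int64)},
                                total=0.0, kind="raw")
        with pytest.raises(ValueError, match="empty sample"):
            ofr.normalize_track(empty)

    def test_identical_inputs_give_unit_ratio(self, toy_layout):
        fs = frags([("chrI", i * 10, i * 10 + 5) for i in range(99)], toy_layout)
        norm = ofr.normalize_track(ofr.bin_counts(fs, toy_layout))
        rt = ofr.ratio_track(norm, norm)
        ok = rt.unmasked("chrI")
        np.testing.assert_allclose(rt.values["chrI"][ok], 1.0)

    def test_zero_g1_bins_masked_with_reason(self, toy_layout):
        s = ofr.BinnedTrack(toy_layout, {"chrI": np.array([2, 1, 0, 1])}, 4, "raw")
        g1 = ofr.BinnedTrack(toy_layout, {"chrI": np.array([2, 0, 0, 2])}, 4, "raw")
        rt = ofr.ratio_track(ofr.normalize_track(s), ofr.normalize_track(g1))
        assert rt.mask_reason["chrI"].tolist() == [
            MASK_NONE, MASK_ZERO_G1, MASK_ZERO_BOTH, MASK_NONE]
        assert np.isnan(rt.values["chrI"][1]) and np.isnan(rt.values["chrI"][2])

    def test_scale_invariance_of_ratio(self, toy_layout):
        s = np.array([4, 3, 2, 1])
        g1 = np.array([1, 2, 3, 4])
        def ratio_of(scale):
            st = ofr.BinnedTrack(toy_layout, {"chrI": s * scale}, float(s.sum() * scale), "raw")
            gt = ofr.BinnedTrack(toy_layout, {"chrI": g1 * scale}, float(g1.sum() * scale), "raw")
            return ofr.ratio_track(ofr.normalize_track(st),
                                   ofr.normalize_track(gt)).values["chrI"]
        np.testing.assert_allclose(ratio_of(1), ratio_of(7))

    def test_uniform_doubling_is_invisible(self, toy_layout):
        g1 = np.array([5, 8, 2, 5])
        st = ofr.BinnedTrack(toy_layout, {"chrI": 2 * g1}, float(2 * g1.sum()), "raw")
        gt = ofr.BinnedTrack(toy_layout, {"chrI": g1}, float(g1.sum()), "raw")
        rt = ofr.ratio_track(ofr.normalize_track(st), ofr.normalize_track(gt))
        np.testing.assert_allclose(rt.values["chrI"], 1.0)

    def test_layout_mismatch_names_the_difference(self, toy_layout):
        other = ofr.GenomeLayout((("chrII", 1000),), bin_size=250)
        a = ofr.normalize_track(
            ofr.BinnedTrack(toy_layout, {"chrI": np.ones(4, dtype=np.int64)}, 4, "raw"))
        b = ofr.normalize_track(
            ofr.BinnedTrack(other, {"chrII": np.ones(4, dtype=np.int64)}, 4, "raw"))
        with pytest.raises(ValueError, match="layout mismatch"):
            ofr.ratio_track(a, b)


class TestBedGraph:
    def test_masked_bins_omitted_and_roundtrip(self, toy_layout, tmp_path):
        values = {"chrI": np.array([1.0, 1.2, np.nan, 0.9])}
        reasons = {"chrI": np.array([0, 0, MASK_ZERO_BOTH, 0], dtype=np.uint8)}
        rt = ofr.RatioTrack(toy_layout, values, reasons)
        path = tmp_path / "r.bedgraph"
        ofr.write_bedgraph(rt, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        back = ofr.read_bedgraph(path, toy_layout)
        ok = back.unmasked("chrI")
        np.testing.assert_allclose(back.values["chrI"][ok],
                                   values["chrI"][[0, 1, 3]], atol=5e-7)
        assert np.isnan(back.values["chrI"][2])

    def test_roundtrip_random_track_to_6_decimals(self, two_chrom_layout, tmp_path):
        rng = np.random.default_rng(3)
        values, reasons = {}, {}
        for c in two_chrom_layout.names:
            n = two_chrom_layout.n_bins(c)
            v = rng.uniform(0.2, 2.5, size=n)
            m = np.zeros(n, dtype=np.uint8)
            m[rng.random(n) < 0.2] = MASK_ZERO_BOTH
            v[m != 0] = np.nan
            values[c], reasons[c] = v, m
        rt = ofr.RatioTrack(two_chrom_layout, values, reasons)
        path = tmp_path / "r.bedgraph"
        ofr.write_bedgraph(rt, path)
        back = ofr.read_bedgraph(path, two_chrom_layout)
        for c in two_chrom_layout.names:
            ok = rt.unmasked(c)
            np.testing.assert_allclose(back.values[c][ok], values[c][ok], atol=5e-7)
            assert (back.mask_reason[c] != 0).tolist() == (~ok).tolist()

    def test_empty_track_reads_back_fully_masked(self, toy_layout, tmp_path):
        values = {"chrI": np.full(4, np.nan)}
        reasons = {"chrI": np.full(4, MASK_ZERO_BOTH, dtype=np.uint8)}
        path = tmp_path / "empty.bedgraph"
        ofr.write_bedgraph(ofr.RatioTrack(toy_layout, values, reasons), path)
        assert path.read_text() == ""
        back = ofr.read_bedgraph(path, toy_layout)
        assert back.n_masked == 4

    @pytest.mark.parametrize("line,err", [
        ("chrI\t0\t250", "expected 4 fields"),
        ("chrI\t10\t260\t1.0", "not aligned"),
        ("chrI\t0\t200\t1.0", "does not match bin end"),
    ])
    def test_malformed_lines_report_line_number(self, toy_layout, tmp_path,
                                                line, err):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chrI\t250\t500\t1.0\n" + line + "\n")
        with pytest.raises(ValueError, match=err):
            ofr.read_bedgraph(path, toy_layout)


class TestIngest:
    def test_bed_and_chrom_sizes(self, tmp_path):
        sizes = tmp_path / "sizes.tsv"
        sizes.write_text("chrI\t1000\nchrII\t500\n")
        layout = ofr.read_chrom_sizes(sizes, bin_size=250)
        bed = tmp_path / "frags.bed"
        bed.write_text("chrI\t0\t50\nchr2\t100\t200\n")  # alias on purpose
        fs = ofr.FragmentSet.from_bed(bed, layout)
        assert fs.n_fragments == 2
        assert set(fs.fragments) == {"chrI", "chrII"}

    def test_sam_ingest_via_pysam(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chrI\tLN:1000\n"
            "r1\t0\tchrI\t1\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r2\t0\tchrI\t301\t60\t40M\t*\t0\t0\t" + "A" * 40 + "\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")  # unmapped, skipped
        layout = ofr.GenomeLayout((("chrI", 1000),), bin_size=250)
        fs = ofr.FragmentSet.from_bam(sam, layout, phase="G1")
        starts, ends = fs.fragments["chrI"]
        assert starts.tolist() == [0, 300]
        assert ends.tolist() == [50, 340]

    def test_bin_table_columns(self, toy_layout):
        fs = frags([("chrI", 0, 10)], toy_layout)
        raw = ofr.bin_counts(fs, toy_layout)
        norm = ofr.normalize_track(raw)
        rt = ofr.ratio_track(norm, norm)
        df = ofr.bin_table(raw, raw, rt)
        assert list(df.columns) == ["chrom", "start", "end", "raw_S",
                                    "raw_G1", "ratio", "mask"]
        assert len(df) == 4


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 980), st.integers(1, 300)),
                min_size=1, max_size=40))
def test_property_midpoint_mode_conserves_count(pairs):
    """Total midpoint-mode counts always equal the number of fragments."""
    layout = ofr.GenomeLayout((("chrI", 1300),), bin_size=250)
    ivals = [("chrI", s, min(1300, s + l)) for s, l in pairs]
    fs = ofr.FragmentSet.from_intervals(ivals, layout)
    track = ofr.bin_counts(fs, layout, mode="midpoint")
    assert track.values["chrI"].sum() == len(ivals)
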