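"""Window enumeration, cross-scaffold match engine and region merging."""

import difflib

import numpy as np
import pytest

import sexscaff as ss
from sexscaff import io as sio
from sexscaff.uniqueness import (
    GenomeWindow,
    flag_unique_windows_from_blast,
    parse_blast_tabular,
    reverse_complement,
)


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEnumerateWindows:
    def test_offset_tiling_with_terminal_truncation(self):
        """Truncated terminal windows are kept iff at least one offset long."""
        ws = ss.enumerate_windows({"s": 2_500}, 1_000, 500)
        assert [(w.start, w.end) for w in ws] == [
            (0, 1_000), (500, 1_500), (1_000, 2_000), (1_500, 2_500),
            (2_000, 2_500),  # exactly offset long, so emitted
        ]

    def test_short_scaffold_single_truncated_window(self):
        ws = ss.enumerate_windows({"s": 900}, 1_000, 500)
        assert [(w.start, w.end) for w in ws] == [(0, 900)]

    def test_window_equal_to_scaffold_plus_offset_tail(self):
        ws = ss.enumerate_windows({"s": 1_000}, 1_000, 500)
        assert [(w.start, w.end) for w in ws] == [(0, 1_000), (500, 1_000)]

    def test_scaffold_shorter_than_offset_yields_whole_scaffold(self):
        ws = ss.enumerate_windows({"s": 300}, 1_000, 500)
        assert [(w.start, w.end) for w in ws] == [(0, 300)]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ss.enumerate_windows({"s": 5_000}, 500, 1_000)

    def test_windows_cover_all_but_a_sub_offset_tail(self):
        """Tiling covers the scaffold contiguously from 0; at most a
        terminal tail shorter than the offset (dropped by the truncation
        rule) is left uncovered."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(100, 20_000))
            w = int(rng.integers(50, 2_000))
            o = int(rng.integers(1, w + 1))
            ws = ss.enumerate_windows({"s": L}, w, o)
            covered = np.zeros(L, dtype=bool)
            for win in ws:
                assert 0 <= win.start < win.end <= L
                covered[win.start : win.end] = True
            uncovered = np.flatnonzero(~covered)
            if uncovered.size:
                assert uncovered.size < o  # only a short terminal tail
                assert uncovered[0] > 0 and uncovered[-1] == L - 1
                assert np.all(np.diff(uncovered) == 1)


def difflib_matches(window_seq, genome, own, min_len):
    """Independent oracle: longest common substring via difflib, either
    strand, against every other scaffold."""
    out = set()
    for sid, seq in genome.items():
        if sid == own:
            continue
        for q in (window_seq, reverse_complement(window_seq)):
            sm = difflib.SequenceMatcher(None, q.upper(), seq.upper(), autojunk=False)
            m = sm.find_longest_match(0, len(q), 0, len(seq))
            if m.size >= min_len:
                out.add(sid)
                break
    return out


class TestMatchEngine:
    def test_shared_repeat_copy_is_reported(self):
        rng = np.random.default_rng(3)
        repeat = rand_seq(rng, 60)
        a = rand_seq(rng, 400) + repeat + rand_seq(rng, 540)
        b = rand_seq(rng, 200) + repeat + rand_seq(rng, 800)
        genome = {"a": a, "b": b}
        win = GenomeWindow("a", 0, 1_000)
        got = ss.find_cross_scaffold_matches(win, genome)
        assert got == {"b"}
        assert got == difflib_matches(a[0:1_000], genome, "a", 50)

    def test_private_window_matches_nothing(self):
        rng = np.random.default_rng(4)
        genome = {"a": rand_seq(rng, 1_000), "b": rand_seq(rng, 1_000)}
        win = GenomeWindow("a", 0, 1_000)
        assert ss.find_cross_scaffold_matches(win, genome) == set()
        assert difflib_matches(genome["a"], genome, "a", 50) == set()

    def test_own_scaffold_duplicate_is_ignored(self):
        """A second copy elsewhere on the same scaffold does not
        disqualify the window."""
        rng = np.random.default_rng(5)
        dup = rand_seq(rng, 200)
        a = dup + rand_seq(rng, 800) + dup
        genome = {"a": a, "b": rand_seq(rng, 500)}
        win = GenomeWindow("a", 0, 1_000)
        assert ss.find_cross_scaffold_matches(win, genome) == set()

    def test_reverse_strand_match_detected(self):
        rng = np.random.default_rng(6)
        repeat = rand_seq(rng, 80)
        a = rand_seq(rng, 100) + repeat + rand_seq(rng, 120)
        b = rand_seq(rng, 300) + reverse_complement(repeat) + rand_seq(rng, 200)
        win = GenomeWindow("a", 0, 300)
        assert ss.find_cross_scaffold_matches(win, {"a": a, "b": b}) == {"b"}

    def test_strand_symmetry(self):
        """Reverse-complementing a non-window scaffold changes nothing."""
        rng = np.random.default_rng(7)
        repeat = rand_seq(rng, 70)
        a = rand_seq(rng, 500) + repeat + rand_seq(rng, 430)
        b = rand_seq(rng, 250) + repeat + rand_seq(rng, 250)
        win = GenomeWindow("a", 0, 1_000)
        fwd = ss.find_cross_scaffold_matches(win, {"a": a, "b": b})
        rev = ss.find_cross_scaffold_matches(
            win, {"a": a, "b": reverse_complement(b)}
        )
        assert fwd == rev == {"b"}

    def test_min_match_monotonicity(self):
        """Raising the minimum match length never makes a window unique
        -> non-unique."""
        rng = np.random.default_rng(8)
        repeat = rand_seq(rng, 55)
        a = rand_seq(rng, 300) + repeat + rand_seq(rng, 300)
        b = rand_seq(rng, 100) + repeat + rand_seq(rng, 100)
        genome = {"a": a, "b": b}
        win = GenomeWindow("a", 0, len(a))
        params50 = ss.MatchEngineParams(min_shared_exact_match_bp=50)
        params60 = ss.MatchEngineParams(min_shared_exact_match_bp=60)
        m50 = ss.find_cross_scaffold_matches(win, genome, params50)
        m60 = ss.find_cross_scaffold_matches(win, genome, params60)
        assert m60 <= m50
        assert m50 == {"b"} and m60 == set()

    def test_n_bases_never_match(self):
        genome = {"a": "N" * 200, "b": "N" * 200}
        win = GenomeWindow("a", 0, 200)
        params = ss.MatchEngineParams(min_shared_exact_match_bp=20)
        assert ss.find_cross_scaffold_matches(win, genome, params) == set()

    def test_softmasked_lowercase_matches_uppercase(self):
        rng = np.random.default_rng(9)
        repeat = rand_seq(rng, 60)
        a = rand_seq(rng, 100) + repeat.lower() + rand_seq(rng, 100)
        b = rand_seq(rng, 100) + repeat + rand_seq(rng, 100)
        win = GenomeWindow("a", 0, len(a))
        assert ss.find_cross_scaffold_matches(win, {"a": a, "b": b}) == {"b"}

    def test_out_of_bounds_window_rejected(self):
        genome = {"a": "ACGT" * 100}
        with pytest.raises(ValueError, match="exceeds"):
            ss.find_cross_scaffold_matches(GenomeWindow("a", 0, 500), genome)


class TestFlagAndMerge:
    def test_all_repeat_scaffold_has_no_unique_windows(self):
        rng = np.random.default_rng(10)
        unit = rand_seq(rng, 500)
        genome = {"y": unit * 6, "x": rand_seq(rng, 1_000) + unit}
        ws = ss.enumerate_windows({"y": 3_000}, 1_000, 500)
        ss.flag_unique_windows(ws, genome)
        assert all(not w.is_unique for w in ws)

    def test_fully_private_scaffold_all_unique(self):
        rng = np.random.default_rng(11)
        genome = {"y": rand_seq(rng, 3_000), "x": rand_seq(rng, 3_000)}
        ws = ss.enumerate_windows({"y": 3_000}, 1_000, 500)
        ss.flag_unique_windows(ws, genome)
        assert all(w.is_unique for w in ws)

    def test_private_core_flanked_by_shared_repeats(self):
        """Interior windows over a 3 kb private core are unique; windows
        touching the flanking shared repeats are not."""
        rng = np.random.default_rng(12)
        repeat = rand_seq(rng, 1_000)
        core = rand_seq(rng, 3_000)
        genome = {"y": repeat + core + repeat, "x": repeat + rand_seq(rng, 500)}
        ws = ss.enumerate_windows({"y": 5_000}, 1_000, 500)
        ss.flag_unique_windows(ws, genome)
        for w in ws:
            # >=50 bp overlap with the repeat blocks [0,1000) or [4000,5000)
            overlaps_repeat = w.start <= 950 or w.end >= 4_050
            assert w.is_unique == (not overlaps_repeat), (w.start, w.end)

    def test_merge_overlapping_windows(self):
        ws = [
            GenomeWindow("s", 0, 1_000, is_unique=True),
            GenomeWindow("s", 500, 1_500, is_unique=True),
        ]
        regions = ss.merge_unique_regions(ws)
        assert [(r.start, r.end, r.n_windows_merged) for r in regions] == [
            (0, 1_500, 2)
        ]

    def test_merge_disjoint_windows(self):
        ws = [
            GenomeWindow("s", 0, 1_000, is_unique=True),
            GenomeWindow("s", 2_000, 3_000, is_unique=True),
        ]
        regions = ss.merge_unique_regions(ws)
        assert [(r.start, r.end) for r in regions] == [(0, 1_000), (2_000, 3_000)]

    def test_merge_empty_input(self):
        assert ss.merge_unique_regions([]) == []

    def test_merged_regions_disjoint_and_sorted(self):
        rng = np.random.default_rng(13)
        ws = [
            GenomeWindow("s", int(s), int(s) + 1_000, is_unique=True)
            for s in rng.integers(0, 50_000, 200)
        ]
        regions = ss.merge_unique_regions(ws)
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end < r2.start  # disjoint, non-abutting, sorted

    def test_count_scaffolds_with_unique(self):
        regions = [
            ss.UniqueRegion("a", 0, 1_000, 1),
            ss.UniqueRegion("a", 5_000, 6_000, 1),
            ss.UniqueRegion("b", 0, 2_000, 2),
        ]
        assert ss.scaffold_has_unique_region("a", regions)
        assert not ss.scaffold_has_unique_region("zzz", regions)
        assert ss.count_scaffolds_with_unique(regions) == 2
        assert ss.count_scaffolds_with_unique(regions, {"a", "c"}) == 1
        assert ss.count_scaffolds_with_unique([]) == 0


class TestSelectAssayRegions:
    def test_min_length_filter(self):
        regions = [
            ss.UniqueRegion("s", 0, 3_000, 5),
            ss.UniqueRegion("s", 10_000, 10_400, 1),
        ]
        chosen = ss.select_assay_regions(regions, min_region_bp=1_000)
        assert [(r.start, r.end) for r in chosen] == [(0, 3_000)]

    def test_per_scaffold_cap_with_coordinate_tiebreak(self):
        regions = [
            ss.UniqueRegion("s", 8_000, 10_000, 3),
            ss.UniqueRegion("s", 1_000, 3_000, 3),
        ]
        chosen = ss.select_assay_regions(
            regions, min_region_bp=1_000, max_regions_per_scaffold=1
        )
        assert [(r.start, r.end) for r in chosen] == [(1_000, 3_000)]

    def test_probe_mode_region_covers_planted_private_block(self):
        """A 10 kb-window scan of an X scaffold with a 30 kb private block
        yields a selected region containing the whole block."""
        rng = np.random.default_rng(14)
        repeat = rand_seq(rng, 2_000)
        x = (
            rand_seq(rng, 8_000)
            + repeat                 # [8000, 10000)
            + rand_seq(rng, 30_000)  # private block [10000, 40000)
            + repeat                 # [40000, 42000)
            + rand_seq(rng, 8_000)
        )
        other = repeat + rand_seq(rng, 3_000)
        genome = {"x": x, "other": other}
        ws = ss.enumerate_windows({"x": len(x)}, 10_000, 5_000)
        ss.flag_unique_windows(ws, genome)
        regions = ss.merge_unique_regions(ws)
        chosen = ss.select_assay_regions(regions, min_region_bp=10_000)
        assert any(r.start <= 10_000 and r.end >= 40_000 for r in chosen)


class TestBlastImport:
    def test_import_flags_cross_scaffold_hits_only(self, tmp_path):
        rows = [
            # self-hit only -> unique
            "y:0-1000\ty\t100.0\t1000\t0\t0\t1\t1000\t1\t1000\t0.0\t1800",
            # hit to another scaffold -> not unique
            "y:500-1500\ty\t100.0\t1000\t0\t0\t1\t1000\t1\t1000\t0.0\t1800",
            "y:500-1500\tx\t95.0\t200\t5\t0\t1\t200\t50\t249\t1e-50\t300",
        ]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(rows) + "\n")
        ws = [GenomeWindow("y", 0, 1_000), GenomeWindow("y", 500, 1_500)]
        flag_unique_windows_from_blast(ws, str(path))
        assert ws[0].is_unique and not ws[1].is_unique
        assert ws[1].matched_scaffolds == {"x"}

    def test_malformed_query_id_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("badid\tx\t100\t1\t0\t0\t1\t1\t1\t1\t0\t1\n")
        with pytest.raises(ValueError, match="scaffold:start-end"):
            parse_blast_tabular(str(path))

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a:0-10\tx\t100\n")
        with pytest.raises(ValueError, match="12"):
            parse_blast_tabular(str(path))


class TestBedRoundTrip:
    def test_written_bed_reads_back_identically(self, tmp_path):
        regions = [
            ss.UniqueRegion("a", 0, 1_500, 3),
            ss.UniqueRegion("b", 2_000, 9_000, 14),
        ]
        path = tmp_path / "regions.bed"
        sio.write_bed(regions, str(path))
        back = sio.read_bed(str(path))
        assert [(r.scaffold_id, r.start, r.end) for r in back] == [
            (r.scaffold_id, r.start, r.end) for r in regions
        ]
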