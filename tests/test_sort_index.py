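import random

import pysam
import pytest

from gafpan import (GAFIndex, SortOrderError, build_index, node_interval,
                    parse_gaf_line, query_interval, sort_gaf, write_gaf_line)
from gafpan.errors import GafpanError, IndexMissingError
from gafpan.fixtures import random_gaf_records
from gafpan.sort_index import (DEFAULT_MIN_SHIFT, depth_for_max_id, read_gaf,
                               reg2bin, reg2bins)


def _line(name, path_text):
    return f"{name}\t4\t0\t4\t+\t{path_text}\t1000\t0\t4\t4\t4\t60\n"


def _sorted_file(tmp_path, lines, name="s.gaf.gz", **kw):
    out = str(tmp_path / name)
    report = sort_gaf(lines, out, **kw)
    return out, report


class TestSortGaf:
    def test_comparator_order(self, tmp_path):
        lines = [_line("a", ">5>9"), _line("b", ">2>3"), _line("c", ">2>7")]
        out, _ = _sorted_file(tmp_path, lines)
        names = [r.query_name for r in read_gaf(out)]
        assert names == ["b", "c", "a"]

    def test_matches_in_memory_sort(self, tmp_path):
        records = random_gaf_records(2000, 3000, seed=11)
        lines = [write_gaf_line(r) for r in records]
        out, report = _sorted_file(tmp_path, lines, chunk_records=128)
        assert report.written == 2000

        def key(i):
            iv = node_interval(records[i])
            return (iv.min_id, iv.max_id, i)

        expected = [write_gaf_line(records[i])
                    for i in sorted(range(len(records)), key=key)]
        assert [write_gaf_line(r) for r in read_gaf(out)] == expected

    def test_idempotent_on_sorted_input(self, tmp_path):
        lines = [write_gaf_line(r) for r in random_gaf_records(300, 500, seed=2)]
        out1, _ = _sorted_file(tmp_path, lines, name="a.gaf.gz")
        sorted_lines = [write_gaf_line(r) for r in read_gaf(out1)]
        out2, _ = _sorted_file(tmp_path, sorted_lines, name="b.gaf.gz")
        assert [write_gaf_line(r) for r in read_gaf(out2)] == sorted_lines

    def test_chunk_size_independence(self, tmp_path):
        lines = [write_gaf_line(r) for r in random_gaf_records(500, 800, seed=5)]
        outputs = []
        for chunk in (1, 7, 128, 10**6):
            out, _ = _sorted_file(tmp_path, lines, name=f"c{chunk}.gaf.gz",
                                  chunk_records=chunk)
            outputs.append([write_gaf_line(r) for r in read_gaf(out)])
        assert outputs[0] == outputs[1] == outputs[2] == outputs[3]

    def test_permutation_and_monotonicity(self, tmp_path):
        lines = [write_gaf_line(r) for r in random_gaf_records(800, 2000, seed=9)]
        out, _ = _sorted_file(tmp_path, lines)
        result = [write_gaf_line(r) for r in read_gaf(out)]
        assert sorted(result) == sorted(lines)
        keys = [(node_interval(r).min_id, node_interval(r).max_id)
                for r in read_gaf(out)]
        assert keys == sorted(keys)

    def test_skips_are_counted_not_dropped(self, tmp_path):
        lines = [_line("a", ">5"),
                 "stable\t4\t0\t4\t+\tchr1\t1000\t0\t4\t4\t4\t60\n",
                 _line("b", ">2")]
        out, report = _sorted_file(tmp_path, lines)
        assert report.skipped_stable_path == 1
        assert report.written == 2
        assert {r.query_name for r in read_gaf(out)} == {"a", "b"}

    def test_unparseable_raises_by_default_skips_with_flag(self, tmp_path):
        lines = [_line("a", ">5"), "garbage\n"]
        with pytest.raises(GafpanError):
            _sorted_file(tmp_path, lines)
        out, report = _sorted_file(tmp_path, lines, name="ok.gaf.gz",
                                   on_error="skip")
        assert report.skipped_unparseable == 1 and report.written == 1


class TestBinning:
    def test_smallest_containing_bin(self):
        depth = depth_for_max_id(2**40)
        rng = random.Random(0)
        for _ in range(200):
            lo = rng.randint(1, 2**30)
            hi = lo + rng.randint(0, 10**5)
            bin_id = reg2bin(lo, hi + 1, DEFAULT_MIN_SHIFT, depth)
            assert bin_id in reg2bins(lo, hi + 1, DEFAULT_MIN_SHIFT, depth)

    def test_query_bins_cover_record_bins(self):
        depth = depth_for_max_id(2**40)
        rng = random.Random(1)
        for _ in range(200):
            a = rng.randint(1, 10**6)
            b = a + rng.randint(0, 500)
            q_lo = rng.randint(max(1, a - 300), b + 300)
            q_hi = q_lo + rng.randint(0, 600)
            if a <= q_hi and b >= q_lo:  # overlapping record must be findable
                assert reg2bin(a, b + 1, DEFAULT_MIN_SHIFT, depth) in \
                    reg2bins(q_lo, q_hi + 1, DEFAULT_MIN_SHIFT, depth)


class TestBuildIndex:
    def test_single_record(self, tmp_path):
        out, _ = _sorted_file(tmp_path, [_line("a", ">5")])
        idx = build_index(out)
        assert idx.n_records == 1
        (chunks,) = idx.bin_table.values()
        begin, end = chunks[0]
        assert begin < end

    def test_far_apart_records_in_different_bins_and_windows(self, tmp_path):
        out, _ = _sorted_file(tmp_path, [_line("a", ">1"), _line("b", ">1000000")])
        idx = build_index(out)
        assert len(idx.bin_table) == 2
        w1, w2 = 1 >> idx.min_shift, 1000000 >> idx.min_shift
        assert w1 != w2
        assert idx.linear_index[w1] != idx.linear_index[w2]

    def test_unsorted_input_rejected(self, tmp_path):
        path = str(tmp_path / "bad.gaf.gz")
        with pysam.BGZFile(path, "wb") as fh:
            fh.write(_line("a", ">9").encode())
            fh.write(_line("b", ">2").encode())
        with pytest.raises(SortOrderError):
            build_index(path)

    def test_sidecar_round_trip(self, tmp_path):
        lines = [write_gaf_line(r) for r in random_gaf_records(100, 10**6, seed=4)]
        out, _ = _sorted_file(tmp_path, lines)
        idx = build_index(out)
        loaded = GAFIndex.load(out + ".gai")
        assert loaded == idx

    def test_linear_index_non_decreasing(self, tmp_path):
        lines = [write_gaf_line(r) for r in random_gaf_records(500, 10**5, seed=6)]
        out, _ = _sorted_file(tmp_path, lines)
        idx = build_index(out)
        assert idx.linear_index == sorted(idx.linear_index)


class TestQueryInterval:
    def test_example(self, tmp_path):
        lines = [_line("a", ">2>3"), _line("b", ">2>7"), _line("c", ">5>9")]
        out, _ = _sorted_file(tmp_path, lines)
        build_index(out)
        assert {r.query_name for r in query_interval(out, 4, 6)} == {"b", "c"}

    def test_beyond_all_records_empty(self, tmp_path):
        out, _ = _sorted_file(tmp_path, [_line("a", ">5>9")])
        build_index(out)
        assert list(query_interval(out, 10, 11)) == []

    def test_missing_index(self, tmp_path):
        out, _ = _sorted_file(tmp_path, [_line("a", ">5")])
        with pytest.raises(IndexMissingError):
            list(query_interval(out, 1, 2))

    def test_lo_greater_than_hi(self, tmp_path):
        out, _ = _sorted_file(tmp_path, [_line("a", ">5")])
        build_index(out)
        with pytest.raises(ValueError):
            list(query_interval(out, 5, 2))

    def test_random_queries_match_linear_scan(self, tmp_path):
        records = random_gaf_records(2000, 5000, seed=13)
        out, _ = _sorted_file(tmp_path, [write_gaf_line(r) for r in records])
        build_index(out)
        intervals = [(min(s.node_id for s in r.path), max(s.node_id for s in r.path))
                     for r in records]
        rng = random.Random(99)
        for _ in range(100):
            lo = rng.randint(1, 5200)
            hi = lo + rng.randint(0, 400)
            got = sorted(write_gaf_line(r) for r in query_interval(out, lo, hi))
            expect = sorted(write_gaf_line(records[i])
                            for i, (mn, mx) in enumerate(intervals)
                            if mn <= hi and mx >= lo)
            assert got == expect

    def test_shared_endpoint_counts_as_overlap(self, tmp_path):
        out, _ = _sorted_file(tmp_path, [_line("a", ">5>9")])
        build_index(out)
        assert [r.query_name for r in query_interval(out, 9, 20)] == ["a"]
        assert [r.query_name for r in query_interval(out, 1, 5)] == ["a"]
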