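import io
import random

import numpy as np
import pytest

from gafpan import (ConsistencyError, FormatError, bin_node_coverage,
                    compute_coverage_from_gaf, coverage_track, extend_segments,
                    load_pack_table, parse_gaf_line, write_gaf_line)
from gafpan.coverage import CoverageBinSpec, CoverageSegment
from gafpan.fixtures import FixtureSpec, make_bubble_graph, simulate_reads
from gafpan.graph_model import OrientedStep, load_gfa

SPEC = CoverageBinSpec()  # default breakpoints 1, 5, 30


def diamond_graph():
    """1 -> {2,3} -> 4, all nodes 3 bases."""
    gfa = ("S\t1\tAAA\nS\t2\tCCC\nS\t3\tGGG\nS\t4\tTTT\n"
           "L\t1\t+\t2\t+\t0M\nL\t1\t+\t3\t+\t0M\n"
           "L\t2\t+\t4\t+\t0M\nL\t3\t+\t4\t+\t0M\n")
    return load_gfa(io.StringIO(gfa))


class TestLoadPackTable:
    def test_dense_fill(self, tiny_graph):
        cov = load_pack_table(["1\t0\t3\n", "1\t1\t3\n"], tiny_graph)
        assert cov[1].tolist() == [3, 3, 0]

    def test_header_tolerated_and_absent_offsets_zero(self, tiny_graph):
        cov = load_pack_table(["node.id\toffset\tcoverage\n", "3\t2\t7\n"],
                              tiny_graph)
        assert cov[3].tolist() == [0, 0, 7, 0]

    def test_duplicate_rows_last_wins(self, tiny_graph):
        cov = load_pack_table(["1\t0\t3\n", "1\t0\t9\n"], tiny_graph)
        assert cov[1][0] == 9

    @pytest.mark.parametrize("row,err", [
        ("1\t0\t-2\n", FormatError),
        ("1\t5\t3\n", ConsistencyError),   # offset >= node length
    ])
    def test_rejects(self, tiny_graph, row, err):
        with pytest.raises(err):
            load_pack_table([row], tiny_graph)


class TestComputeCoverage:
    def test_single_spanning_read(self, tiny_graph):
        read = parse_gaf_line("r\t8\t0\t8\t+\t>1>2>3\t8\t0\t8\t8\t8\t60")
        cov = compute_coverage_from_gaf(tiny_graph, [read], 1)
        assert cov[1].tolist() == [1, 1, 1]
        assert cov[2].tolist() == [1]
        assert cov[3].tolist() == [1, 1, 1, 1]

    def test_path_start_offset(self, tiny_graph):
        read = parse_gaf_line("r\t7\t0\t7\t+\t>1>2>3\t8\t1\t8\t7\t7\t60")
        cov = compute_coverage_from_gaf(tiny_graph, [read], 1)
        assert cov[1].tolist() == [0, 1, 1]

    def test_reverse_orientation_maps_to_forward_offsets(self, tiny_graph):
        read = parse_gaf_line("r\t1\t0\t1\t+\t<2\t1\t0\t1\t1\t1\t60")
        cov = compute_coverage_from_gaf(tiny_graph, [read], 1)
        assert cov[2].tolist() == [1]

    def test_reverse_partial_node(self, tiny_graph):
        # <1 spells CGT; covering its first 2 bases = forward bases [1,3)
        read = parse_gaf_line("r\t2\t0\t2\t+\t<1\t3\t0\t2\t2\t2\t60")
        cov = compute_coverage_from_gaf(tiny_graph, [read], 1)
        assert cov[1].tolist() == [0, 1, 1]

    def test_min_mapq_filter(self, tiny_graph):
        read = parse_gaf_line("r\t8\t0\t8\t+\t>1>2>3\t8\t0\t8\t8\t8\t0")
        cov = compute_coverage_from_gaf(tiny_graph, [read], 1)
        assert cov[1].sum() == 0


class TestBinNodeCoverage:
    def test_run_segmentation(self):
        segs = bin_node_coverage({1: np.array([0, 0, 3, 3, 7.0])}, SPEC)
        assert [(s.start, s.end, s.class_id, s.mean_cov) for s in segs] == \
            [(2, 4, 1, 3.0), (4, 5, 2, 7.0)]

    def test_all_zero_node_emits_nothing(self):
        assert bin_node_coverage({1: np.zeros(5)}, SPEC) == []

    def test_uniform_node_single_segment(self):
        (seg,) = bin_node_coverage({1: np.full(6, 10.0)}, SPEC)
        assert (seg.start, seg.end, seg.class_id) == (0, 6, 2)

    @pytest.mark.parametrize("value,expect_class", [
        (0, 0), (1, 1), (4, 1), (5, 2), (29, 2), (30, 3), (31, 3)])
    def test_half_open_breakpoint_boundaries(self, value, expect_class):
        segs = bin_node_coverage({1: np.array([float(value)])}, SPEC)
        if expect_class == 0:
            assert segs == []
        else:
            assert segs[0].class_id == expect_class


class TestExtendSegments:
    def test_adjacent_full_nodes_merge(self, tiny_graph):
        segs = [CoverageSegment(1, 0, 3, 1, 2.0), CoverageSegment(2, 0, 1, 1, 3.0)]
        (path,) = extend_segments(tiny_graph, segs, SPEC)
        assert [s.node_id for s in path.steps] == [1, 2]

    def test_non_touching_boundary_stays_separate(self, tiny_graph):
        # [0,2) of 3-base node 1 does not reach the node-2 boundary
        segs = [CoverageSegment(1, 0, 2, 1, 2.0), CoverageSegment(2, 0, 1, 1, 3.0)]
        paths = extend_segments(tiny_graph, segs, SPEC)
        assert len(paths) == 2

    def test_branch_prefers_smallest_node_id(self):
        graph = diamond_graph()
        segs = [CoverageSegment(n, 0, 3, 1, 2.0) for n in (1, 2, 3, 4)]
        paths = extend_segments(graph, segs, SPEC)
        assert [s.node_id for s in paths[0].steps] == [1, 2, 4]
        assert [s.node_id for s in paths[1].steps] == [3]

    def test_different_class_blocks_extension(self, tiny_graph):
        segs = [CoverageSegment(1, 0, 3, 1, 2.0), CoverageSegment(2, 0, 1, 2, 9.0)]
        assert len(extend_segments(tiny_graph, segs, SPEC)) == 2

    def test_unknown_node_rejected(self, tiny_graph):
        with pytest.raises(ConsistencyError):
            extend_segments(tiny_graph, [CoverageSegment(77, 0, 1, 1, 2.0)], SPEC)


class TestCoverageTrack:
    def _random_coverage(self, graph, seed):
        rng = random.Random(seed)
        return {n: np.array([float(rng.choice([0, 0, 2, 8, 40]))
                             for _ in range(len(node))])
                for n, node in graph.nodes.items()}

    def test_partition_class_purity_and_means(self):
        graph, _ = make_bubble_graph(FixtureSpec(n_bubbles=30, seed=7))
        cov = self._random_coverage(graph, 7)
        records = list(coverage_track(graph, cov, SPEC))
        seen = {}
        for rec in records:
            class_id = rec.get_tag("ci")
            offset = 0
            covered_mean = []
            for step in rec.path:
                length = len(graph.nodes[step.node_id])
                lo = max(rec.path_start, offset)
                hi = min(rec.path_end, offset + length)
                if lo < hi:
                    a, b = lo - offset, hi - offset
                    if step.is_reverse:
                        a, b = length - b, length - a
                    for base in range(a, b):
                        key = (step.node_id, base)
                        assert key not in seen, "base assigned to two paths"
                        seen[key] = class_id
                        value = cov[step.node_id][base]
                        assert SPEC.classify(np.array([value]))[0] == class_id
                        covered_mean.append(value)
                offset += length
            assert abs(rec.get_tag("cm") - np.mean(covered_mean)) < 1e-9
        expected = {(n, i) for n, arr in cov.items()
                    for i in range(len(arr)) if arr[i] >= SPEC.breakpoints[0]}
        assert set(seen) == expected

    def test_byte_identical_determinism(self):
        graph, _ = make_bubble_graph(FixtureSpec(n_bubbles=15, seed=3))
        cov = self._random_coverage(graph, 11)
        first = "".join(write_gaf_line(r) for r in coverage_track(graph, cov, SPEC))
        second = "".join(write_gaf_line(r) for r in coverage_track(graph, cov, SPEC))
        assert first == second

    def test_record_name_encodes_class_and_mean(self, tiny_graph):
        cov = {1: np.array([10.0, 10, 10]), 2: np.array([10.0]),
               3: np.zeros(4)}
        (rec,) = coverage_track(tiny_graph, cov, SPEC)
        assert rec.query_name == "cov_5-30_mean10.00"
        assert rec.get_tag("cc") == "5-30"

    def test_read_pipeline_end_to_end(self):
        spec = FixtureSpec(n_bubbles=8, seed=5, read_depth=8.0, read_len=25)
        graph, _ = make_bubble_graph(spec)
        reads = list(simulate_reads(graph, spec))
        cov = compute_coverage_from_gaf(graph, iter(reads), 1)
        records = list(coverage_track(graph, cov, SPEC))
        assert records, "expected coverage paths from depth-8 reads"
        for rec in records:
            assert rec.path_end > rec.path_start
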