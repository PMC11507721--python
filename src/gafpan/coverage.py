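"""Coarse-grained coverage tracks: bin per-base node coverage, extend greedily.

Functional-genomics coverage (e.g. ATAC-seq read depth piped from
``vg pack``) is summarized into GAF paths along which coverage is consistent:

1. per-base coverage inside every node is quantized into coverage classes
   delimited by breakpoints (default 1, 5, 30 reads, giving classes [1,5),
   [5,30), [30,inf); bases below the first breakpoint are discarded);
2. maximal same-class base runs within a node become segments ("bins");
3. segments are greedily extended across node boundaries while the adjacent
   segment has the same class, producing one path per group.

Extension only crosses a node boundary when the current segment reaches that
boundary and the neighboring segment starts at its own boundary; interior
segments of a path therefore always span their whole node.  At branches the
smallest node ID (forward orientation first) wins and every segment is
consumed exactly once, so output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import ConsistencyError, FormatError
from .gaf_io import GAFRecord
from .graph_model import OrientedStep, PangenomeGraph, neighbors

logger = logging.getLogger(__name__)

DEFAULT_BREAKPOINTS = (1.0, 5.0, 30.0)
COVERAGE_MAPQ = 60


@dataclass(frozen=True)
class CoverageBinSpec:
    """Coverage classes; class c (1-based) covers [breakpoints[c-1], breakpoints[c])
    with the last class unbounded.  Coverage below breakpoints[0] is unclassed."""

    breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if not bp or any(b <= 0 for b in bp) or list(bp) != sorted(set(bp)):
            raise ValueError(
                f"breakpoints must be strictly increasing positives, got {bp}")

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Per-base class IDs (0 = below the first breakpoint)."""
        return np.searchsorted(np.asarray(self.breakpoints), values, side="right")

    def label(self, class_id: int) -> str:
        bp = self.breakpoints
        if class_id == len(bp):
            return f"{bp[-1]:g}+"
        return f"{bp[class_id - 1]:g}-{bp[class_id]:g}"


@dataclass(frozen=True)
class CoverageSegment:
    node_id: int
    start: int
    end: int
    class_id: int
    mean_cov: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment bounds [{self.start},{self.end})")


@dataclass
class CoveragePath:
    steps: list[OrientedStep]
    segments: list[CoverageSegment]
    class_id: int

    def total_bases(self) -> int:
        return sum(s.end - s.start for s in self.segments)

    def mean_cov(self) -> float:
        total = self.total_bases()
        return sum(s.mean_cov * (s.end - s.start) for s in self.segments) / total


# ---------------------------------------------------------------------------
# coverage input


def load_pack_table(stream: Iterable[str],
                    graph: PangenomeGraph | None = None) -> dict[int, np.ndarray]:
    """Read a pack-style TSV (node_id, offset, coverage) into dense arrays.

    Offsets absent from the table get coverage 0.  When a graph is supplied
    arrays span whole nodes and offsets are validated against node lengths.
    Duplicate (node, offset) rows keep the last value (counted in a warning).
    """
    values: dict[int, dict[int, float]] = {}
    duplicates = 0
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"pack line {lineno}: expected 3 columns, got {len(fields)}")
        if lineno == 1 and not fields[0].lstrip("-").isdigit():
            continue  # header row
        try:
            node_id, offset, cov = int(fields[0]), int(fields[1]), float(fields[2])
        except ValueError:
            raise FormatError(f"pack line {lineno}: non-numeric field in {fields[:3]}") from None
        if cov < 0:
            raise FormatError(f"pack line {lineno}: negative coverage {cov}")
        if offset < 0:
            raise FormatError(f"pack line {lineno}: negative offset {offset}")
        if graph is not None and offset >= graph.node_length(node_id):
            raise ConsistencyError(
                f"pack line {lineno}: offset {offset} >= length of node {node_id}")
        per_node = values.setdefault(node_id, {})
        if offset in per_node:
            duplicates += 1
        per_node[offset] = cov
    if duplicates:
        logger.warning("pack table: %d duplicate (node, offset) rows; last value kept",
                       duplicates)
    arrays: dict[int, np.ndarray] = {}
    for node_id, per_node in values.items():
        size = graph.node_length(node_id) if graph is not None else max(per_node) + 1
        arr = np.zeros(size, dtype=float)
        for offset, cov in per_node.items():
            arr[offset] = cov
        arrays[node_id] = arr
    return arrays


def compute_coverage_from_gaf(graph: PangenomeGraph, reads: Iterable[GAFRecord],
                              min_mapq: int = 1) -> dict[int, np.ndarray]:
    """Per-base coverage from GAF alignments with mapq >= ``min_mapq``.

    Both read orientations project onto forward-strand node offsets
    (coverage is unstranded).
    """
    cov = {node_id: np.zeros(len(node), dtype=float)
           for node_id, node in graph.nodes.items()}
    for record in reads:
        if record.mapq < min_mapq or not record.path:
            continue
        offset = 0
        for step in record.path:
            try:
                length = graph.node_length(step.node_id)
            except Exception:
                raise ConsistencyError(
                    f"read {record.query_name!r} traverses unknown node "
                    f"{step.node_id}") from None
            lo = max(record.path_start, offset)
            hi = min(record.path_end, offset + length)
            if lo < hi:
                a, b = lo - offset, hi - offset  # path-orientation node offsets
                if step.is_reverse:
                    a, b = length - b, length - a
                cov[step.node_id][a:b] += 1
            offset += length
        if offset != record.path_len:
            raise ConsistencyError(
                f"read {record.query_name!r}: path_len {record.path_len} != "
                f"sum of node lengths {offset}")
    return cov


# ---------------------------------------------------------------------------
# binning


def bin_node_coverage(coverage: dict[int, np.ndarray],
                      spec: CoverageBinSpec = CoverageBinSpec()) -> list[CoverageSegment]:
    """Maximal same-class base runs per node; class-0 (no coverage) runs are dropped."""
    segments: list[CoverageSegment] = []
    for node_id in sorted(coverage):
        arr = np.asarray(coverage[node_id], dtype=float)
        if np.any(arr < 0):
            raise FormatError(f"node {node_id}: negative coverage")
        classes = spec.classify(arr)
        boundaries = np.flatnonzero(np.diff(classes)) + 1
        run_starts = np.concatenate(([0], boundaries))
        run_ends = np.concatenate((boundaries, [len(arr)]))
        for a, b in zip(run_starts, run_ends):
            class_id = int(classes[a])
            if class_id == 0:
                continue
            segments.append(CoverageSegment(
                node_id, int(a), int(b), class_id, float(arr[a:b].mean())))
    return segments


# ---------------------------------------------------------------------------
# greedy extension


def _touches_entry(seg: CoverageSegment, step: OrientedStep, node_len: int) -> bool:
    """Does ``seg`` start at the boundary through which ``step`` is entered?"""
    return seg.start == 0 if not step.is_reverse else seg.end == node_len


def _touches_exit(seg: CoverageSegment, step: OrientedStep, node_len: int) -> bool:
    """Does ``seg`` reach the boundary through which the path would leave ``step``?"""
    return seg.end == node_len if not step.is_reverse else seg.start == 0


def extend_segments(graph: PangenomeGraph, segments: list[CoverageSegment],
                    spec: CoverageBinSpec = CoverageBinSpec()) -> list[CoveragePath]:
    """Group segments into coverage paths by greedy same-class extension."""
    by_node: dict[int, list[CoverageSegment]] = {}
    for seg in segments:
        if seg.node_id not in graph.nodes:
            raise ConsistencyError(f"segment references unknown node {seg.node_id}")
        if seg.end > graph.node_length(seg.node_id):
            raise ConsistencyError(
                f"segment [{seg.start},{seg.end}) exceeds node {seg.node_id} length")
        by_node.setdefault(seg.node_id, []).append(seg)
    for segs in by_node.values():
        segs.sort(key=lambda s: s.start)
    consumed: set[int] = set()  # id() of consumed segments

    def candidate(step: OrientedStep, class_id: int,
                  entry: bool) -> CoverageSegment | None:
        node_len = graph.node_length(step.node_id)
        for seg in by_node.get(step.node_id, ()):
            if id(seg) in consumed or seg.class_id != class_id:
                continue
            touches = _touches_entry if entry else _touches_exit
            if touches(seg, step, node_len):
                return seg
        return None

    paths: list[CoveragePath] = []
    order = sorted(segments, key=lambda s: (s.node_id, s.start))
    for seed in order:
        if id(seed) in consumed:
            continue
        consumed.add(id(seed))
        seed_step = OrientedStep(seed.node_id, False)
        steps = [seed_step]
        segs = [seed]
        # rightward
        cur_step, cur_seg = seed_step, seed
        while _touches_exit(cur_seg, cur_step, graph.node_length(cur_step.node_id)):
            nxt = None
            for cand_step in neighbors(graph, cur_step, "right"):
                seg = candidate(cand_step, seed.class_id, entry=True)
                if seg is not None:
                    nxt = (cand_step, seg)
                    break
            if nxt is None:
                break
            cur_step, cur_seg = nxt
            consumed.add(id(cur_seg))
            steps.append(cur_step)
            segs.append(cur_seg)
        # leftward
        cur_step, cur_seg = seed_step, seed
        while _touches_entry(cur_seg, cur_step, graph.node_length(cur_step.node_id)):
            prv = None
            for cand_step in neighbors(graph, cur_step, "left"):
                seg = candidate(cand_step, seed.class_id, entry=False)
                if seg is not None:
                    prv = (cand_step, seg)
                    break
            if prv is None:
                break
            cur_step, cur_seg = prv
            consumed.add(id(cur_seg))
            steps.insert(0, cur_step)
            segs.insert(0, cur_seg)
        paths.append(CoveragePath(steps, segs, seed.class_id))
    return paths


def coverage_path_to_gaf(graph: PangenomeGraph, path: CoveragePath,
                         spec: CoverageBinSpec) -> GAFRecord:
    """One GAF record per coverage path, named ``cov_<class>_mean<mean>``."""
    path_len = sum(graph.node_length(s.node_id) for s in path.steps)
    first_step, first_seg = path.steps[0], path.segments[0]
    last_step, last_seg = path.steps[-1], path.segments[-1]
    first_len = graph.node_length(first_step.node_id)
    last_len = graph.node_length(last_step.node_id)
    path_start = (first_seg.start if not first_step.is_reverse
                  else first_len - first_seg.end)
    tail = (last_len - last_seg.end if not last_step.is_reverse
            else last_seg.start)
    path_end = path_len - tail
    covered = path_end - path_start
    mean = path.mean_cov()
    label = spec.label(path.class_id)
    return GAFRecord(
        query_name=f"cov_{label}_mean{mean:.2f}",
        query_len=covered, query_start=0, query_end=covered, strand="+",
        path=list(path.steps), path_len=path_len,
        path_start=path_start, path_end=path_end,
        matches=covered, block_len=covered, mapq=COVERAGE_MAPQ,
        tags=[("cc", "Z", label), ("cm", "f", mean), ("ci", "i", path.class_id)])


def coverage_track(graph: PangenomeGraph, coverage: dict[int, np.ndarray],
                   spec: CoverageBinSpec = CoverageBinSpec()) -> Iterator[GAFRecord]:
    """Full bin-and-extend pipeline: coverage arrays to GAF records."""
    segments = bin_node_coverage(coverage, spec)
    for path in extend_segments(graph, segments, spec):
        yield coverage_path_to_gaf(graph, path, spec)
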