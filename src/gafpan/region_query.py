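"""Region queries: reference-range to subgraph, GAF slices, trimming, chunking.

A biological query ("this gene on this haplotype") is translated into a node
set: the nodes whose projected base interval on the embedded path intersects
the requested range, expanded by a user-chosen number of *context* rounds of
adjacency so that non-reference bubbles in the region are included.  The
node-interval index then provides a candidate superset of GAF records, which
is filtered down to exact node membership.

Extracted records keep their full paths by default; ``trim_to_subgraph`` is
the explicit opt-in that cuts paths down to in-subgraph runs (what graph
viewers such as Bandage-NG need) and de-duplicates names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .errors import PathLookupError
from .gaf_io import GAFRecord
from .graph_model import (OrientedStep, PangenomeGraph, neighbors, write_gfa)
from . import sort_index


@dataclass
class Subgraph:
    node_ids: set[int]
    graph: PangenomeGraph

    def __post_init__(self) -> None:
        missing = {n for n in self.node_ids if n not in self.graph.nodes}
        if missing:
            raise PathLookupError(f"subgraph references unknown nodes {sorted(missing)}")


def expand_context(graph: PangenomeGraph, node_ids: set[int],
                   context_steps: int) -> set[int]:
    """Add ``context_steps`` rounds of all nodes adjacent to the current set."""
    current = set(node_ids)
    frontier = set(node_ids)
    for _ in range(context_steps):
        nxt: set[int] = set()
        for node_id in frontier:
            for direction in ("left", "right"):
                for step in neighbors(graph, OrientedStep(node_id), direction):
                    if step.node_id not in current:
                        nxt.add(step.node_id)
        if not nxt:
            break
        current |= nxt
        frontier = nxt
    return current


def subgraph_from_path_range(graph: PangenomeGraph, path_name: str,
                             start: int, end: int,
                             context_steps: int = 0) -> Subgraph:
    """Nodes whose base interval on ``path_name`` intersects [start, end),
    plus context expansion.  Coordinates follow the path's source contig
    (fragment offsets included), 0-based half-open."""
    fragments = graph.paths.get(path_name)
    if fragments is None:
        raise PathLookupError(f"unknown path {path_name!r}")
    total = graph.path_length(path_name)
    if not (0 <= start < end <= total):
        raise ValueError(
            f"range [{start},{end}) outside path {path_name!r} of length {total}")
    hits: set[int] = set()
    for fragment in fragments:
        offset = fragment.fragment_offset
        for step in fragment.steps:
            length = graph.node_length(step.node_id)
            if offset < end and offset + length > start:
                hits.add(step.node_id)
            offset += length
            if offset >= end:
                break
    if not hits:
        raise ValueError(
            f"range [{start},{end}) falls entirely in clipped-out gaps of "
            f"{path_name!r}")
    return Subgraph(expand_context(graph, hits, context_steps), graph)


def subgraph_from_nodes(graph: PangenomeGraph, node_ids: Iterable[int],
                        context_steps: int = 0) -> Subgraph:
    return Subgraph(expand_context(graph, set(node_ids), context_steps), graph)


def gaf_slice(gaf_path: str, sub: Subgraph) -> Iterator[GAFRecord]:
    """Records of an indexed GAF whose path visits >= 1 subgraph node.

    The node-interval query gives a superset (interval overlap); exact node
    membership removes the false positives.  File order is preserved.
    """
    if not sub.node_ids:
        raise ValueError("empty subgraph")
    lo, hi = min(sub.node_ids), max(sub.node_ids)
    for record in sort_index.query_interval(gaf_path, lo, hi):
        if any(step.node_id in sub.node_ids for step in record.path):
            yield record


def _dedupe_names(records: list[GAFRecord]) -> list[GAFRecord]:
    from collections import Counter
    counts = Counter(r.query_name for r in records)
    seen: dict[str, int] = {}
    for record in records:
        if counts[record.query_name] > 1:
            seen[record.query_name] = seen.get(record.query_name, 0) + 1
            record.query_name = f"{record.query_name}.{seen[record.query_name]}"
    return records


def trim_to_subgraph(records: Iterable[GAFRecord], sub: Subgraph) -> list[GAFRecord]:
    """Cut each record down to its maximal in-subgraph runs of steps.

    Path length and offsets are recomputed per run (clipped at cut
    boundaries); runs left with no annotated bases are dropped.  Names that
    would repeat in the output are suffixed ".1", ".2", …
    """
    graph = sub.graph
    out: list[GAFRecord] = []
    for record in records:
        runs: list[tuple[int, int]] = []
        i = 0
        n = len(record.path)
        while i < n:
            if record.path[i].node_id in sub.node_ids:
                j = i
                while j < n and record.path[j].node_id in sub.node_ids:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        lengths = [graph.node_length(s.node_id) for s in record.path]
        prefix = [0]
        for length in lengths:
            prefix.append(prefix[-1] + length)
        for i, j in runs:
            run_len = prefix[j] - prefix[i]
            new_start = max(record.path_start - prefix[i], 0)
            new_end = min(record.path_end - prefix[i], run_len)
            if new_end <= new_start:
                continue  # no annotated bases in this run
            covered = new_end - new_start
            out.append(GAFRecord(
                query_name=record.query_name, query_len=record.query_len,
                query_start=record.query_start, query_end=record.query_end,
                strand=record.strand, path=record.path[i:j], path_len=run_len,
                path_start=new_start, path_end=new_end,
                matches=min(record.matches, covered), block_len=covered,
                mapq=record.mapq, tags=list(record.tags)))
    return _dedupe_names(out)


@dataclass
class ChunkResult:
    subgraph: Subgraph
    records: list[GAFRecord]


def extract_subgraph_gfa(sub: Subgraph, stream: IO) -> None:
    """Write the subgraph as GFA with path lines last (viewer-friendly order)."""
    graph = sub.graph
    small = PangenomeGraph()
    for node_id in sorted(sub.node_ids):
        small.add_node(node_id, graph.nodes[node_id].sequence)
    for edge in graph.edges:
        if (edge.from_step.node_id in sub.node_ids
                and edge.to_step.node_id in sub.node_ids):
            small.add_edge(edge.from_step, edge.to_step)
    for name, fragments in graph.paths.items():
        for fragment in fragments:
            run: list[OrientedStep] = []
            part = 0
            for step in list(fragment.steps) + [None]:
                if step is not None and step.node_id in sub.node_ids:
                    run.append(step)
                    continue
                if run:
                    n_runs_name = name if part == 0 else f"{name}.{part}"
                    from .graph_model import EmbeddedPath
                    small.add_path_fragment(EmbeddedPath(
                        n_runs_name, list(run), 0,
                        is_reference=fragment.is_reference, line_type="P"))
                    part += 1
                    run = []
    write_gfa(small, stream, paths_last=True)


def chunk(graph: PangenomeGraph, gaf_paths: list[str], sub: Subgraph,
          trim: bool = True) -> ChunkResult:
    """Extract and merge GAF slices from all inputs for one subgraph."""
    merged: list[GAFRecord] = []
    for gaf_path in gaf_paths:
        merged.extend(gaf_slice(gaf_path, sub))
    if trim:
        merged = trim_to_subgraph(merged, sub)
    return ChunkResult(sub, merged)
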