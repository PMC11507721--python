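"""Pangenome graph model: nodes with sequences, oriented edges, embedded paths.

The graph is the bidirected sequence graph used by pangenome toolkits: every
node carries a DNA sequence and an integer ID, edges join node *sides*, and
haplotypes are embedded as ordered lists of oriented node visits.  Node IDs
must be positive integers because the whole sorting/indexing scheme treats
the ID space as a coordinate axis; graphs with string IDs must be renumbered
upstream (``vg ids -s`` / ``odgi sort`` style tools) before loading.

Coordinates everywhere are 0-based, half-open, as in BED and GAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, TextIO

from .errors import FormatError, GraphValidationError, PathLookupError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: A path whose ID span exceeds this multiple of its step count triggers a
#: sortedness warning (heuristic only; topological ID order is recommended,
#: not required).
DEFAULT_SORTEDNESS_RATIO = 100


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class OrientedStep:
    """One visit of a node, forward (``>``) or reverse (``<``)."""

    node_id: int
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.node_id < 1:
            raise GraphValidationError(f"node_id must be >= 1, got {self.node_id}")

    def flipped(self) -> "OrientedStep":
        return OrientedStep(self.node_id, not self.is_reverse)

    def __str__(self) -> str:
        return ("<" if self.is_reverse else ">") + str(self.node_id)


def parse_oriented_steps(text: str) -> list[OrientedStep]:
    """Parse an oriented-segment string like ``">23>24<26"``."""
    if not text:
        raise FormatError("empty oriented-path string")
    steps: list[OrientedStep] = []
    i, n = 0, len(text)
    while i < n:
        orient = text[i]
        if orient not in "<>":
            raise FormatError(f"malformed path token at {text[i:i + 12]!r}: "
                              "expected '>' or '<'")
        j = i + 1
        while j < n and text[j] not in "<>":
            j += 1
        token = text[i + 1:j]
        if not token.isdigit() or int(token) < 1:
            raise FormatError(f"malformed path token {text[i:j]!r}: "
                              "node ID must be a positive integer")
        steps.append(OrientedStep(int(token), orient == "<"))
        i = j
    return steps


def format_oriented_steps(steps: Iterable[OrientedStep]) -> str:
    return "".join(str(s) for s in steps)


@dataclass(frozen=True)
class Node:
    node_id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.node_id < 1:
            raise GraphValidationError(f"node_id must be >= 1, got {self.node_id}")
        if not self.sequence:
            raise GraphValidationError(f"node {self.node_id} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Edge:
    """An adjacency between two node sides.

    An edge and its reverse-complement pairing describe the same adjacency;
    :meth:`canonical` picks one orientation deterministically so the two
    compare (and hash) equal after canonicalisation.
    """

    from_step: OrientedStep
    to_step: OrientedStep

    def reversed_pair(self) -> "Edge":
        return Edge(self.to_step.flipped(), self.from_step.flipped())

    def canonical(self) -> "Edge":
        other = self.reversed_pair()
        a = (self.from_step.node_id, self.from_step.is_reverse,
             self.to_step.node_id, self.to_step.is_reverse)
        b = (other.from_step.node_id, other.from_step.is_reverse,
             other.to_step.node_id, other.to_step.is_reverse)
        return self if a <= b else other


@dataclass
class EmbeddedPath:
    """One fragment of a haplotype/contig path embedded in the graph.

    ``fragment_offset`` is the base offset of this fragment on its source
    contig: non-zero when pangenome construction clipped out part of the
    contig and this fragment starts mid-contig.
    """

    name: str
    steps: list[OrientedStep]
    fragment_offset: int = 0
    is_reference: bool = False
    line_type: str = "P"  # GFA line this fragment came from / serializes to


class PangenomeGraph:
    """Nodes, canonical edges, and named embedded paths (possibly fragmented)."""

    def __init__(self) -> None:
        self.nodes: dict[int, Node] = {}
        self.edges: set[Edge] = set()
        self.paths: dict[str, list[EmbeddedPath]] = {}
        self.header_lines: list[str] = []
        # adjacency: oriented step -> steps reachable rightward over one edge
        self._succ: dict[OrientedStep, list[OrientedStep]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: int, sequence: str) -> None:
        if node_id in self.nodes:
            raise GraphValidationError(f"duplicate segment ID {node_id}")
        self.nodes[node_id] = Node(node_id, sequence)

    def add_edge(self, from_step: OrientedStep, to_step: OrientedStep) -> None:
        for step in (from_step, to_step):
            if step.node_id not in self.nodes:
                raise GraphValidationError(
                    f"edge references unknown segment {step.node_id}")
        edge = Edge(from_step, to_step).canonical()
        if edge in self.edges:
            return
        self.edges.add(edge)
        f, t = edge.from_step, edge.to_step
        self._succ.setdefault(f, []).append(t)
        self._succ.setdefault(t.flipped(), []).append(f.flipped())

    def add_path_fragment(self, fragment: EmbeddedPath) -> None:
        if not fragment.steps:
            raise GraphValidationError(f"path {fragment.name!r} has no steps")
        for step in fragment.steps:
            if step.node_id not in self.nodes:
                raise GraphValidationError(
                    f"path {fragment.name!r} references unknown segment {step.node_id}")
        frags = self.paths.setdefault(fragment.name, [])
        frags.append(fragment)
        frags.sort(key=lambda f: f.fragment_offset)

    def has_edge(self, from_step: OrientedStep, to_step: OrientedStep) -> bool:
        return Edge(from_step, to_step).canonical() in self.edges

    # -- queries ----------------------------------------------------------

    def node_length(self, node_id: int) -> int:
        try:
            return len(self.nodes[node_id])
        except KeyError:
            raise PathLookupError(f"unknown node {node_id}") from None

    def fragment_length(self, fragment: EmbeddedPath) -> int:
        return sum(self.node_length(s.node_id) for s in fragment.steps)

    def path_length(self, name: str) -> int:
        """Source-coordinate extent of a named path (offset + length of its last fragment)."""
        frags = self._get_fragments(name)
        last = frags[-1]
        return last.fragment_offset + self.fragment_length(last)

    def _get_fragments(self, name: str) -> list[EmbeddedPath]:
        try:
            return self.paths[name]
        except KeyError:
            raise PathLookupError(f"unknown path {name!r}") from None

    def is_reference(self, name: str) -> bool:
        return all(f.is_reference for f in self._get_fragments(name))


# ---------------------------------------------------------------------------
# operations


def path_sequence(graph: PangenomeGraph, steps: Iterable[OrientedStep]) -> str:
    """Spell the DNA along a list of oriented steps."""
    parts = []
    for step in steps:
        if step.node_id not in graph.nodes:
            raise PathLookupError(f"unknown node {step.node_id}")
        seq = graph.nodes[step.node_id].sequence
        parts.append(reverse_complement(seq) if step.is_reverse else seq)
    return "".join(parts)


def set_reference(graph: PangenomeGraph, path_name: str) -> PangenomeGraph:
    """Flag every fragment of ``path_name`` as a reference (idempotent, in place)."""
    for fragment in graph._get_fragments(path_name):
        fragment.is_reference = True
    return graph


def neighbors(graph: PangenomeGraph, step: OrientedStep,
              direction: str = "right") -> list[OrientedStep]:
    """Oriented steps reachable over one edge leaving ``step``'s left or right side.

    Deterministic order: ascending node ID, forward orientation before reverse.
    """
    if step.node_id not in graph.nodes:
        raise PathLookupError(f"unknown node {step.node_id}")
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    if direction == "right":
        out = list(graph._succ.get(step, ()))
    else:
        out = [t.flipped() for t in graph._succ.get(step.flipped(), ())]
    out.sort(key=lambda s: (s.node_id, s.is_reverse))
    return out


def steps_covering(graph: PangenomeGraph, steps: list[OrientedStep],
                   start: int, end: int) -> tuple[list[OrientedStep], int, int]:
    """Minimal contiguous slice of ``steps`` covering base interval [start, end).

    Returns ``(slice, path_start, slice_len)`` where ``path_start`` is the
    offset of base ``start`` within the concatenated slice and ``slice_len``
    its total base length.  The first and last returned steps each contribute
    at least one base of [start, end).
    """
    if start >= end:
        raise ValueError(f"empty interval [{start}, {end})")
    total = 0
    first = last = None
    prefix = 0
    for i, step in enumerate(steps):
        length = graph.node_length(step.node_id)
        node_span = (total, total + length)
        if node_span[1] > start and node_span[0] < end:
            if first is None:
                first = i
                prefix = total
            last = i
        total += length
        if node_span[0] >= end:
            break
    if first is None or last is None:
        raise ValueError(f"interval [{start}, {end}) outside path of length {total}")
    chosen = steps[first:last + 1]
    slice_len = sum(graph.node_length(s.node_id) for s in chosen)
    return chosen, start - prefix, slice_len


# ---------------------------------------------------------------------------
# GFA I/O


def _parse_segment_id(name: str, line: str) -> int:
    if not name.isdigit() or int(name) < 1:
        raise FormatError(
            f"segment name {name!r} is not a positive integer (line: {line.rstrip()!r}); "
            "renumber the graph first, e.g. with 'vg ids -s' or 'odgi sort'")
    return int(name)


def _parse_p_steps(text: str, line: str) -> list[OrientedStep]:
    steps = []
    for token in text.split(","):
        if len(token) < 2 or token[-1] not in "+-":
            raise FormatError(f"malformed P-line step {token!r} (line: {line.rstrip()!r})")
        steps.append(OrientedStep(_parse_segment_id(token[:-1], line), token[-1] == "-"))
    return steps


def load_gfa(stream: TextIO | Iterable[str],
             sortedness_ratio: int = DEFAULT_SORTEDNESS_RATIO) -> PangenomeGraph:
    """Load a GFA 1.x graph (S/L/P/W lines; H preserved verbatim).

    Segment names must parse as positive integers.  W-line subranges become
    path fragments with ``fragment_offset`` set; P-line paths get offset 0.
    """
    graph = PangenomeGraph()
    deferred: list[str] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        kind = line[0]
        if kind == "H":
            graph.header_lines.append(line)
        elif kind == "S":
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"S line with {len(fields)} fields: {line!r}")
            node_id = _parse_segment_id(fields[1], line)
            graph.add_node(node_id, fields[2])
        elif kind in "LPW":
            deferred.append(line)
        # other record types (C, comments) are ignored
    for line in deferred:
        fields = line.split("\t")
        if fields[0] == "L":
            if len(fields) < 6:
                raise FormatError(f"L line with {len(fields)} fields: {line!r}")
            if fields[5] not in ("0M", "*"):
                raise FormatError(
                    f"only blunt-ended links are supported (overlap {fields[5]!r}): {line!r}")
            f = OrientedStep(_parse_segment_id(fields[1], line), fields[2] == "-")
            t = OrientedStep(_parse_segment_id(fields[3], line), fields[4] == "-")
            graph.add_edge(f, t)
        elif fields[0] == "P":
            if len(fields) < 3:
                raise FormatError(f"P line with {len(fields)} fields: {line!r}")
            steps = _parse_p_steps(fields[2], line)
            graph.add_path_fragment(EmbeddedPath(fields[1], steps, 0, line_type="P"))
        elif fields[0] == "W":
            if len(fields) < 7:
                raise FormatError(f"W line with {len(fields)} fields: {line!r}")
            sample, hap, seqid, start = fields[1], fields[2], fields[3], fields[4]
            name = f"{sample}#{hap}#{seqid}"
            offset = 0 if start == "*" else int(start)
            steps = parse_oriented_steps(fields[6])
            graph.add_path_fragment(
                EmbeddedPath(name, steps, offset, line_type="W"))
    _apply_reference_header(graph)
    _warn_unsorted_paths(graph, sortedness_ratio)
    return graph


def _reference_tokens(header_lines: list[str]) -> set[str]:
    tokens: set[str] = set()
    for line in header_lines:
        for field in line.split("\t")[1:]:
            if field.startswith("RS:Z:"):
                tokens.update(field[5:].split())
    return tokens


def _apply_reference_header(graph: PangenomeGraph) -> None:
    """Flag paths named by an ``RS:Z:`` header (GFA 1.1 reference-sample tag);
    a token matches a path name outright or its PanSN sample component."""
    tokens = _reference_tokens(graph.header_lines)
    if not tokens:
        return
    for name, fragments in graph.paths.items():
        if name in tokens or name.split("#")[0] in tokens:
            for fragment in fragments:
                fragment.is_reference = True


def _warn_unsorted_paths(graph: PangenomeGraph, ratio: int) -> None:
    for name, frags in graph.paths.items():
        for frag in frags:
            ids = [s.node_id for s in frag.steps]
            span = max(ids) - min(ids) + 1
            if span > ratio * len(ids):
                warnings.warn(
                    f"path {name!r} spans node IDs {min(ids)}-{max(ids)} over "
                    f"{len(ids)} steps; node IDs may not be topologically sorted, "
                    "which degrades GAF index performance", stacklevel=3)
                return


def write_gfa(graph: PangenomeGraph, stream: TextIO, paths_last: bool = True) -> None:
    """Serialize to GFA 1.x.  P/W lines go after S/L when ``paths_last``."""
    for line in graph.header_lines:
        stream.write(line + "\n")
    ref_names = sorted(
        name.split("#")[0] if name.count("#") == 2 else name
        for name, frags in graph.paths.items()
        if all(f.is_reference for f in frags))
    if ref_names and not (_reference_tokens(graph.header_lines) >= set(ref_names)):
        stream.write("H\tRS:Z:" + " ".join(ref_names) + "\n")
    path_lines: list[str] = []
    for name, frags in sorted(graph.paths.items()):
        for frag in frags:
            if frag.line_type == "W" and name.count("#") == 2:
                sample, hap, seqid = name.split("#")
                end = frag.fragment_offset + graph.fragment_length(frag)
                path_lines.append("\t".join([
                    "W", sample, hap, seqid, str(frag.fragment_offset), str(end),
                    format_oriented_steps(frag.steps)]))
            else:
                steps = ",".join(
                    f"{s.node_id}{'-' if s.is_reverse else '+'}" for s in frag.steps)
                path_lines.append(f"P\t{name}\t{steps}\t*")
    if not paths_last:
        for line in path_lines:
            stream.write(line + "\n")
    for node_id in sorted(graph.nodes):
        stream.write(f"S\t{node_id}\t{graph.nodes[node_id].sequence}\n")
    for edge in sorted(graph.edges,
                       key=lambda e: (e.from_step.node_id, e.from_step.is_reverse,
                                      e.to_step.node_id, e.to_step.is_reverse)):
        stream.write("\t".join([
            "L", str(edge.from_step.node_id), "-" if edge.from_step.is_reverse else "+",
            str(edge.to_step.node_id), "-" if edge.to_step.is_reverse else "+", "0M"]) + "\n")
    if paths_last:
        for line in path_lines:
            stream.write(line + "\n")
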