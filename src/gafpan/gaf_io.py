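"""GAF record parsing, serialization, and node-interval extraction.

GAF is the tab-delimited alignment/path format for sequence graphs: 12
mandatory columns followed by SAM-style typed tags.  Column 6 carries the
path, normally as a chain of oriented segments (``>23>24<26``).  The same
record type is used here for reads, projected annotations, coverage-track
paths, and variant paths — only the producer differs.

The node interval of a record, the (min, max) pair of traversed node IDs,
is the sort and index key of the whole toolkit: when node IDs follow the
graph topology a short path spans a small ID interval, so interval overlap
is a cheap superset test for subgraph overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .errors import ConsistencyError, FormatError
from .graph_model import (OrientedStep, PangenomeGraph, format_oriented_steps,
                          parse_oriented_steps, path_sequence)

MISSING_MAPQ = 255

TagValue = Union[int, float, str]


@dataclass(frozen=True)
class NodeInterval:
    """Closed interval [min_id, max_id] of node IDs traversed by a path."""

    min_id: int
    max_id: int

    def __post_init__(self) -> None:
        if self.min_id > self.max_id:
            raise ValueError(f"min_id {self.min_id} > max_id {self.max_id}")

    def overlaps(self, lo: int, hi: int) -> bool:
        return self.min_id <= hi and self.max_id >= lo


@dataclass
class GAFRecord:
    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    path: list[OrientedStep]
    path_len: int
    path_start: int
    path_end: int
    matches: int
    block_len: int
    mapq: int = MISSING_MAPQ
    tags: list[tuple[str, str, TagValue]] = field(default_factory=list)
    #: set instead of ``path`` when column 6 is a bare stable name
    stable_path: str | None = None

    def validate(self) -> None:
        if not (0 <= self.query_start <= self.query_end <= self.query_len):
            raise FormatError(
                f"{self.query_name!r}: query interval "
                f"[{self.query_start},{self.query_end}) outside [0,{self.query_len}]")
        if not (0 <= self.path_start <= self.path_end <= self.path_len):
            raise FormatError(
                f"{self.query_name!r}: path interval "
                f"[{self.path_start},{self.path_end}) outside [0,{self.path_len}]")
        if self.strand not in "+-":
            raise FormatError(f"{self.query_name!r}: bad strand {self.strand!r}")
        if not (0 <= self.mapq <= 255):
            raise FormatError(f"{self.query_name!r}: mapq {self.mapq} outside 0-255")

    def get_tag(self, tag: str) -> TagValue | None:
        for name, _, value in self.tags:
            if name == tag:
                return value
        return None


_NUMERIC_COLS = {1: "query_len", 2: "query_start", 3: "query_end",
                 6: "path_len", 7: "path_start", 8: "path_end",
                 9: "matches", 10: "block_len", 11: "mapq"}


def _parse_tag(token: str) -> tuple[str, str, TagValue]:
    parts = token.split(":", 2)
    if len(parts) != 3 or not parts[0] or len(parts[1]) != 1:
        raise FormatError(f"malformed tag {token!r}")
    tag, typ, raw = parts
    if typ == "i":
        try:
            return tag, typ, int(raw)
        except ValueError:
            raise FormatError(f"tag {token!r}: non-integer value") from None
    if typ == "f":
        try:
            return tag, typ, float(raw)
        except ValueError:
            raise FormatError(f"tag {token!r}: non-float value") from None
    return tag, typ, raw


def parse_gaf_line(line: str) -> GAFRecord:
    """Parse one GAF line into a record; tags are preserved in order."""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise FormatError(f"GAF line has {len(cols)} columns, expected >= 12")
    nums: dict[str, int] = {}
    for idx, name in _NUMERIC_COLS.items():
        raw = cols[idx]
        if raw == "*" and name == "mapq":
            nums[name] = MISSING_MAPQ
            continue
        try:
            nums[name] = int(raw)
        except ValueError:
            raise FormatError(
                f"column {idx + 1} ({name}) is not an integer: {raw!r}") from None
    path_text = cols[5]
    path: list[OrientedStep] = []
    stable_path = None
    if path_text and path_text[0] in "<>":
        path = parse_oriented_steps(path_text)
    elif path_text and path_text != "*":
        stable_path = path_text
    record = GAFRecord(
        query_name=cols[0], strand=cols[4], path=path, stable_path=stable_path,
        tags=[_parse_tag(t) for t in cols[12:]], **nums)
    record.validate()
    return record


def _format_tag_value(typ: str, value: TagValue) -> str:
    # str(float) is the shortest representation that round-trips exactly
    return str(value)


def write_gaf_line(record: GAFRecord) -> str:
    """Serialize a record to one LF-terminated GAF line (round-trip inverse of parse)."""
    record.validate()
    if record.stable_path is not None:
        path_text = record.stable_path
    elif record.path:
        path_text = format_oriented_steps(record.path)
    else:
        raise FormatError(
            f"{record.query_name!r}: empty path is not representable as indexable GAF")
    cols = [record.query_name, str(record.query_len), str(record.query_start),
            str(record.query_end), record.strand, path_text, str(record.path_len),
            str(record.path_start), str(record.path_end), str(record.matches),
            str(record.block_len), str(record.mapq)]
    cols.extend(f"{t}:{typ}:{_format_tag_value(typ, v)}" for t, typ, v in record.tags)
    return "\t".join(cols) + "\n"


def node_interval(record: GAFRecord) -> NodeInterval:
    """(min, max) of the node IDs traversed by the record's path."""
    if not record.path:
        raise ValueError(
            f"{record.query_name!r}: no oriented-segment path, no node interval")
    ids = [s.node_id for s in record.path]
    return NodeInterval(min(ids), max(ids))


def spelled_sequence(graph: PangenomeGraph, record: GAFRecord) -> str:
    """DNA spelled by the record: path sequence sliced to [path_start, path_end)."""
    full = path_sequence(graph, record.path)
    if len(full) != record.path_len:
        raise ConsistencyError(
            f"{record.query_name!r}: path_len {record.path_len} != "
            f"sum of node lengths {len(full)}")
    return full[record.path_start:record.path_end]
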