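"""Sort GAF files by node-ID interval, block-compress, index, and query.

The scheme mirrors how BED/VCF files are handled on a linear genome, with
the node-ID axis standing in for genomic position: records are sorted by
(min traversed ID, max traversed ID), written as BGZF so that (block offset,
within-block offset) virtual offsets give random access, and indexed with a
tabix-style hierarchical binning index plus a linear index over fixed-size
node-ID windows.  A query for the closed ID interval [lo, hi] then touches
only the file regions whose bins can contain overlapping records.

The sidecar index (``<file>.gai``) is a little-endian binary documented in
:class:`GAFIndex`; byte compatibility with ``.tbi``/``.csi`` is not a goal,
the semantics are.
"""

from __future__ import annotations

import heapq
import math
import os
import struct
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import pysam

from .errors import (FormatError, GafpanError, IndexMissingError,
                     SortOrderError)
from .gaf_io import GAFRecord, node_interval, parse_gaf_line

INDEX_SUFFIX = ".gai"
INDEX_MAGIC = b"GAFI\x01"
DEFAULT_MIN_SHIFT = 14          # linear-index window = 2^14 = 16384 node IDs
DEFAULT_MAX_NODE_ID = 2 ** 40   # binning depth is derived from this
_NO_OFFSET = 0xFFFFFFFFFFFFFFFF
_MAX_OPEN_CHUNKS = 64   # spill files merged at once (cascaded beyond this)


def depth_for_max_id(max_node_id: int, min_shift: int = DEFAULT_MIN_SHIFT) -> int:
    """Number of binning levels below the root needed to address ``max_node_id``."""
    bits = max(max_node_id, 1).bit_length()
    return max(1, math.ceil((bits - min_shift) / 3))


def reg2bin(beg: int, end: int, min_shift: int, depth: int) -> int:
    """Smallest bin fully containing the half-open interval [beg, end)."""
    end -= 1
    s = min_shift
    t = ((1 << (depth * 3)) - 1) // 7
    for level in range(depth, 0, -1):
        if beg >> s == end >> s:
            return t + (beg >> s)
        s += 3
        t -= 1 << ((level - 1) * 3)
    return 0


def reg2bins(beg: int, end: int, min_shift: int, depth: int) -> list[int]:
    """All bins that may hold records overlapping [beg, end)."""
    end -= 1
    out: list[int] = []
    for level in range(depth + 1):
        shift = min_shift + 3 * (depth - level)
        offset = ((1 << (3 * level)) - 1) // 7
        out.extend(range(offset + (beg >> shift), offset + (end >> shift) + 1))
    return out


# ---------------------------------------------------------------------------
# sorting


@dataclass
class SortReport:
    total: int = 0
    written: int = 0
    skipped_empty_path: int = 0
    skipped_stable_path: int = 0
    skipped_unparseable: int = 0
    chunks: int = 0


def _sort_key_of_line(line: str, rank: int) -> tuple[int, int, int] | None:
    """(min_id, max_id, input_rank) for an indexable line, None if skippable."""
    record = parse_gaf_line(line)
    if not record.path:
        return None
    iv = node_interval(record)
    return (iv.min_id, iv.max_id, rank)


def _iter_lines(source: Iterable[str] | IO) -> Iterator[str]:
    for raw in source:
        if isinstance(raw, bytes):
            raw = raw.decode()
        if raw.strip():
            yield raw if raw.endswith("\n") else raw + "\n"


def sort_gaf(source: Iterable[str] | IO, output_path: str,
             chunk_records: int = 100_000, on_error: str = "raise") -> SortReport:
    """External merge sort of GAF lines by (min_id, max_id, input order).

    At most ``chunk_records`` records are held in memory at once; sorted
    chunks are spilled to temporary files and merged.  The output is BGZF
    compressed.  Records without an oriented-segment path (empty or
    stable-name column 6) are not indexable and are skipped with a count;
    unparseable lines raise unless ``on_error='skip'``.
    """
    if chunk_records < 1:
        raise ValueError("chunk_records must be >= 1")
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    report = SortReport()
    chunk: list[tuple[tuple[int, int, int], str]] = []
    spill_files: list[str] = []
    tmpdir = tempfile.mkdtemp(prefix="gafpan_sort_")

    def spill() -> None:
        chunk.sort(key=lambda kv: kv[0])
        path = os.path.join(tmpdir, f"chunk{len(spill_files)}.tmp")
        with open(path, "w") as fh:
            for (mn, mx, rank), line in chunk:
                fh.write(f"{mn}\t{mx}\t{rank}\t{line}")
        spill_files.append(path)
        chunk.clear()

    try:
        for rank, line in enumerate(_iter_lines(source)):
            report.total += 1
            try:
                key = _sort_key_of_line(line, rank)
            except GafpanError:
                if on_error == "raise":
                    raise
                report.skipped_unparseable += 1
                continue
            if key is None:
                record = parse_gaf_line(line)
                if record.stable_path is not None:
                    report.skipped_stable_path += 1
                else:
                    report.skipped_empty_path += 1
                continue
            chunk.append((key, line))
            if len(chunk) >= chunk_records:
                spill()
        if chunk or not spill_files:
            spill()
        report.chunks = len(spill_files)

        def read_spill(path: str) -> Iterator[tuple[tuple[int, int, int], str]]:
            with open(path) as fh:
                for spilled in fh:
                    mn, mx, rank, line = spilled.split("\t", 3)
                    yield (int(mn), int(mx), int(rank)), line

        # cascade: never hold more than _MAX_OPEN_CHUNKS spill files open at once
        merge_round = 0
        while len(spill_files) > _MAX_OPEN_CHUNKS:
            group, spill_files = (spill_files[:_MAX_OPEN_CHUNKS],
                                  spill_files[_MAX_OPEN_CHUNKS:])
            merged_path = os.path.join(tmpdir, f"merge{merge_round}.tmp")
            merge_round += 1
            with open(merged_path, "w") as fh:
                for (mn, mx, rank), line in heapq.merge(
                        *(read_spill(p) for p in group), key=lambda kv: kv[0]):
                    fh.write(f"{mn}\t{mx}\t{rank}\t{line}")
            for path in group:
                os.unlink(path)
            spill_files.append(merged_path)

        tmp_out = output_path + ".tmp"
        out = pysam.BGZFile(tmp_out, "wb")
        try:
            for _, line in heapq.merge(*(read_spill(p) for p in spill_files),
                                       key=lambda kv: kv[0]):
                out.write(line.encode())
                report.written += 1
        finally:
            out.close()
        os.replace(tmp_out, output_path)
    finally:
        for path in spill_files:
            if os.path.exists(path):
                os.unlink(path)
        os.rmdir(tmpdir)
    return report


# ---------------------------------------------------------------------------
# index


@dataclass
class GAFIndex:
    """Binning + linear index over node-ID space for a sorted bgzipped GAF.

    Sidecar layout (little-endian)::

        magic           5 bytes  b"GAFI\\x01"
        min_shift       u8       log2 of the linear-index window size
        depth           u8       binning levels below the root bin
        n_records       u64      indexed record count
        n_bins          u32
        per bin:        u32 bin_id, u32 n_chunks, n_chunks x (u64 begin, u64 end)
        n_windows       u64
        linear          n_windows x u64  (0xFFF..F = no offset)
        max_node_id     u64      largest node ID seen
    """

    min_shift: int = DEFAULT_MIN_SHIFT
    depth: int = depth_for_max_id(DEFAULT_MAX_NODE_ID)
    bin_table: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    linear_index: list[int] = field(default_factory=list)
    n_records: int = 0
    max_node_id: int = 0

    @property
    def window_size(self) -> int:
        return 1 << self.min_shift

    def to_bytes(self) -> bytes:
        parts = [INDEX_MAGIC, struct.pack("<BBQ", self.min_shift, self.depth,
                                          self.n_records),
                 struct.pack("<I", len(self.bin_table))]
        for bin_id in sorted(self.bin_table):
            chunks = self.bin_table[bin_id]
            parts.append(struct.pack("<II", bin_id, len(chunks)))
            for begin, end in chunks:
                parts.append(struct.pack("<QQ", begin, end))
        parts.append(struct.pack("<Q", len(self.linear_index)))
        for voff in self.linear_index:
            parts.append(struct.pack("<Q", voff))
        parts.append(struct.pack("<Q", self.max_node_id))
        return b"".join(parts)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "GAFIndex":
        if blob[:5] != INDEX_MAGIC:
            raise FormatError("not a gafpan index file (bad magic)")
        off = 5
        min_shift, depth, n_records = struct.unpack_from("<BBQ", blob, off)
        off += 10
        (n_bins,) = struct.unpack_from("<I", blob, off)
        off += 4
        bin_table: dict[int, list[tuple[int, int]]] = {}
        for _ in range(n_bins):
            bin_id, n_chunks = struct.unpack_from("<II", blob, off)
            off += 8
            chunks = []
            for _ in range(n_chunks):
                begin, end = struct.unpack_from("<QQ", blob, off)
                off += 16
                chunks.append((begin, end))
            bin_table[bin_id] = chunks
        (n_windows,) = struct.unpack_from("<Q", blob, off)
        off += 8
        linear = list(struct.unpack_from(f"<{n_windows}Q", blob, off))
        off += 8 * n_windows
        (max_node_id,) = struct.unpack_from("<Q", blob, off)
        return cls(min_shift=min_shift, depth=depth, bin_table=bin_table,
                   linear_index=linear, n_records=n_records,
                   max_node_id=max_node_id)

    def save(self, path: str) -> None:
        tmp = path + ".tmp"
        with open(tmp, "wb") as fh:
            fh.write(self.to_bytes())
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str) -> "GAFIndex":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


def build_index(sorted_gaf: str, min_shift: int = DEFAULT_MIN_SHIFT,
                max_node_id: int = DEFAULT_MAX_NODE_ID) -> GAFIndex:
    """Scan a sorted bgzipped GAF, build the index, write ``<file>.gai``.

    Every record goes into the smallest bin containing its closed interval
    [min_id, max_id]; adjacent records in the same bin are merged into one
    chunk of virtual offsets.  Out-of-order or path-less records are errors.
    """
    depth = depth_for_max_id(max_node_id, min_shift)
    index = GAFIndex(min_shift=min_shift, depth=depth)
    # first virtual offset of any record spanning each window (sparse)
    window_first: dict[int, int] = {}
    prev_key: tuple[int, int] | None = None
    fh = pysam.BGZFile(sorted_gaf, "rb")
    try:
        lineno = 0
        while True:
            voff_begin = fh.tell()
            raw = fh.readline()
            if not raw:
                break
            lineno += 1
            voff_end = fh.tell()
            record = parse_gaf_line(raw.decode())
            if not record.path:
                raise GafpanError(
                    f"record {lineno} ({record.query_name!r}) has no "
                    "oriented-segment path and cannot be indexed")
            iv = node_interval(record)
            key = (iv.min_id, iv.max_id)
            if prev_key is not None and key < prev_key:
                raise SortOrderError(
                    f"file not sorted: record {lineno} ({record.query_name!r}) "
                    f"has interval {key} after {prev_key}; run 'gafpan sort' first")
            prev_key = key
            if iv.max_id >= (1 << (min_shift + 3 * depth)):
                raise GafpanError(
                    f"node ID {iv.max_id} exceeds the index's maximum "
                    f"({(1 << (min_shift + 3 * depth)) - 1}); rebuild with a "
                    "larger --max-node-id")
            bin_id = reg2bin(iv.min_id, iv.max_id + 1, min_shift, depth)
            chunks = index.bin_table.setdefault(bin_id, [])
            if chunks and chunks[-1][1] == voff_begin:
                chunks[-1] = (chunks[-1][0], voff_end)
            else:
                chunks.append((voff_begin, voff_end))
            for w in range(iv.min_id >> min_shift, (iv.max_id >> min_shift) + 1):
                window_first.setdefault(w, voff_begin)
            index.n_records += 1
            index.max_node_id = max(index.max_node_id, iv.max_id)
    finally:
        fh.close()
    # suffix-min over window firsts: linear[w] is a lower bound on the virtual
    # offset of every record spanning any window >= w, and is non-decreasing
    n_windows = (index.max_node_id >> min_shift) + 1 if index.n_records else 0
    linear = [_NO_OFFSET] * n_windows
    best = _NO_OFFSET
    for w in range(n_windows - 1, -1, -1):
        best = min(best, window_first.get(w, _NO_OFFSET))
        linear[w] = best
    index.linear_index = linear
    index.save(sorted_gaf + INDEX_SUFFIX)
    return index


# ---------------------------------------------------------------------------
# query


def _candidate_chunks(index: GAFIndex, lo: int, hi: int) -> list[tuple[int, int]]:
    min_voff = 0
    if index.linear_index:
        w = min(lo >> index.min_shift, len(index.linear_index) - 1)
        bound = index.linear_index[w]
        if bound != _NO_OFFSET:
            min_voff = bound
    chunks: list[tuple[int, int]] = []
    for bin_id in reg2bins(lo, hi + 1, index.min_shift, index.depth):
        for begin, end in index.bin_table.get(bin_id, ()):
            if end > min_voff:
                chunks.append((max(begin, min_voff), end))
    chunks.sort()
    merged: list[tuple[int, int]] = []
    for begin, end in chunks:
        if merged and begin <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((begin, end))
    return merged


def query_interval(gaf_path: str, lo: int, hi: int,
                   index: GAFIndex | None = None) -> Iterator[GAFRecord]:
    """Yield records whose closed node interval intersects [lo, hi], in file order.

    Any sequence-name part of a region string must be stripped by the caller;
    only the ID interval matters.
    """
    if lo > hi:
        raise ValueError(f"query lo {lo} > hi {hi}")
    if lo < 1:
        raise ValueError("node IDs start at 1")
    if index is None:
        sidecar = gaf_path + INDEX_SUFFIX
        if not os.path.exists(sidecar):
            raise IndexMissingError(
                f"no index found for {gaf_path}; run 'gafpan index' first")
        index = GAFIndex.load(sidecar)
    fh = pysam.BGZFile(gaf_path, "rb")
    try:
        for begin, end in _candidate_chunks(index, lo, hi):
            fh.seek(begin)
            while fh.tell() < end:
                raw = fh.readline()
                if not raw:
                    break
                record = parse_gaf_line(raw.decode())
                iv = node_interval(record)
                if iv.min_id > hi:
                    return  # sorted by min_id: nothing later can overlap
                if iv.overlaps(lo, hi):
                    yield record
    finally:
        fh.close()


def iter_gaf_lines(path: str) -> Iterator[str]:
    """Yield text lines from a GAF file (plain text, gzip, or BGZF)."""
    with open(path, "rb") as probe:
        gzipped = probe.read(2) == b"\x1f\x8b"
    if gzipped:
        fh = pysam.BGZFile(path, "rb")  # reads plain gzip as well as BGZF
        try:
            while True:
                raw = fh.readline()
                if not raw:
                    break
                yield raw.decode()
        finally:
            fh.close()
    else:
        with open(path) as text:
            yield from text


def read_gaf(path: str) -> Iterator[GAFRecord]:
    """Sequentially read a GAF file (plain, gzip, or BGZF)."""
    for line in iter_gaf_lines(path):
        if line.strip():
            yield parse_gaf_line(line)
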