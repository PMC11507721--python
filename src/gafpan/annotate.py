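"""Project BED/GFF3 annotations on a haplotype contig into GAF paths.

An annotation on contig ``C`` is lifted into the graph by tracing the
embedded path of ``C`` across the bases the annotation covers.  The contig
must be flagged as a reference in the graph first (``set_reference``).
Contigs are often stored as several path fragments because pangenome
construction clips out hard-to-align regions; an annotation crossing a clip
breakpoint is split into one GAF record per overlapped fragment, numbered
``label.part0``, ``label.part1``, … in source-coordinate order (a single
surviving part keeps the bare label).

For minus-strand features the emitted path is reversed and flipped so it
reads the feature 5'→3'; the GAF strand column stays "+" because the path
itself encodes orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import FormatError, PathLookupError, ReferenceStateError
from .gaf_io import GAFRecord
from .graph_model import PangenomeGraph, steps_covering

logger = logging.getLogger(__name__)

ANNOTATION_MAPQ = 60


@dataclass(frozen=True)
class AnnotationRecord:
    contig: str
    start: int          # 0-based
    end: int            # half-open
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"annotation {self.label!r}: end {self.end} <= start {self.start}")
        if self.strand not in "+-.":
            raise FormatError(f"annotation {self.label!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ProjectedAnnotation:
    record: GAFRecord
    part_index: int
    part_count: int


def _fallback_label(contig: str, start: int, end: int) -> str:
    return f"{contig}:{start}-{end}"


def resolve_label(fields: list[str], fmt: str) -> str:
    """Record name per format convention.

    BED: column 4 when present; GFF3: attribute ``Name``, else ``ID``.
    Fallback for both: ``contig:start-end`` (0-based half-open coordinates).
    All metadata collapses into this single string; richer metadata handling
    is deliberately out of scope.
    """
    if fmt == "bed":
        if len(fields) >= 4 and fields[3] and fields[3] != ".":
            return fields[3]
        return _fallback_label(fields[0], int(fields[1]), int(fields[2]))
    if fmt == "gff3":
        attrs = {}
        for item in fields[8].split(";"):
            if "=" in item:
                key, value = item.split("=", 1)
                attrs[key.strip()] = value.strip()
        for key in ("Name", "ID"):
            if attrs.get(key):
                return attrs[key]
        return _fallback_label(fields[0], int(fields[3]) - 1, int(fields[4]))
    raise ValueError(f"unknown annotation format {fmt!r}")


def project_annotation(graph: PangenomeGraph,
                       ann: AnnotationRecord) -> list[ProjectedAnnotation]:
    """Trace the graph path covered by one annotation, splitting at clip gaps.

    Each emitted part's path is the minimal contiguous step slice covering
    its bases, so ``spelled_sequence`` of the part equals the corresponding
    substring of the source contig (reverse-complemented for strand "-").
    An annotation falling entirely inside clipped-out gaps yields an empty
    list (logged).
    """
    if ann.contig not in graph.paths:
        raise PathLookupError(
            f"contig {ann.contig!r} has no embedded path in the graph")
    if not graph.is_reference(ann.contig):
        raise ReferenceStateError(
            f"contig {ann.contig!r} is not flagged as a reference; "
            "call set_reference (or pass --reference) before projecting")
    pieces: list[tuple[int, int, GAFRecord]] = []
    for fragment in graph.paths[ann.contig]:
        frag_start = fragment.fragment_offset
        frag_end = frag_start + graph.fragment_length(fragment)
        lo = max(ann.start, frag_start)
        hi = min(ann.end, frag_end)
        if lo >= hi:
            continue
        steps, path_start, slice_len = steps_covering(
            graph, fragment.steps, lo - frag_start, hi - frag_start)
        path_end = path_start + (hi - lo)
        if ann.strand == "-":
            steps = [s.flipped() for s in reversed(steps)]
            path_start, path_end = slice_len - path_end, slice_len - path_start
        record = GAFRecord(
            query_name=ann.label, query_len=ann.end - ann.start,
            query_start=lo - ann.start, query_end=hi - ann.start,
            strand="+", path=steps, path_len=slice_len,
            path_start=path_start, path_end=path_end,
            matches=hi - lo, block_len=hi - lo, mapq=ANNOTATION_MAPQ)
        pieces.append((lo, hi, record))
    if not pieces:
        logger.info("annotation %r [%d,%d) on %r lies entirely in clipped-out "
                    "gaps; skipped", ann.label, ann.start, ann.end, ann.contig)
        return []
    pieces.sort(key=lambda p: p[0])
    out = []
    for k, (_, _, record) in enumerate(pieces):
        if len(pieces) > 1:
            record.query_name = f"{ann.label}.part{k}"
        out.append(ProjectedAnnotation(record, k, len(pieces)))
    return out


def _parse_bed_line(fields: list[str]) -> AnnotationRecord:
    if len(fields) < 3:
        raise FormatError(f"BED line has {len(fields)} columns, expected >= 3")
    start, end = int(fields[1]), int(fields[2])
    strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
    return AnnotationRecord(fields[0], start, end, strand,
                            resolve_label(fields, "bed"))


def _parse_gff3_line(fields: list[str]) -> AnnotationRecord:
    if len(fields) != 9:
        raise FormatError(f"GFF3 line has {len(fields)} columns, expected 9")
    # GFF3 is 1-based closed; convert to 0-based half-open
    start, end = int(fields[3]) - 1, int(fields[4])
    strand = fields[6] if fields[6] in "+-" else "."
    return AnnotationRecord(fields[0], start, end, strand,
                            resolve_label(fields, "gff3"))


def parse_annotation_file(stream: Iterable[str], fmt: str,
                          on_error: str = "raise") -> Iterator[AnnotationRecord]:
    parser = {"bed": _parse_bed_line, "gff3": _parse_gff3_line}[fmt]
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.startswith(("track", "browser")):
            continue
        try:
            yield parser(line.split("\t"))
        except (FormatError, ValueError) as exc:
            if on_error == "raise":
                raise FormatError(f"{fmt} line {lineno}: {exc}") from exc
            logger.warning("skipping malformed %s line %d: %s", fmt, lineno, exc)


def project_file(graph: PangenomeGraph, stream: Iterable[str], fmt: str,
                 on_error: str = "raise") -> Iterator[GAFRecord]:
    """Project every annotation in a BED or GFF3 stream, input order preserved."""
    for lineno, ann in enumerate(parse_annotation_file(stream, fmt, on_error), 1):
        try:
            for part in project_annotation(graph, ann):
                yield part.record
        except (PathLookupError, ReferenceStateError, ValueError) as exc:
            raise type(exc)(f"{fmt} record {lineno} ({ann.label!r}): {exc}") from exc
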