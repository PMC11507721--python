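"""Match known variants against a pangenome VCF and emit allele paths as GAF.

A pangenome VCF (as produced by ``vg deconstruct``) stores, for every
variant site, the traversal of each allele through the graph in the ``AT``
INFO field (reference allele first).  Two conversions are supported:

* ``match_variant`` — look up an input variant in the pangenome VCF.  If
  the (normalized) ref/alt pair is present, the alternate allele's traversal
  is emitted; if only the site overlaps (different allele), the reference
  traversal is emitted as a fallback; otherwise the variant is skipped.
* ``vcf_at_to_gaf`` — convert a VCF that already carries AT (e.g. from
  genotyping with ``vg call``) straight to GAF, one record per alt allele.

Emitted paths are always members of the source record's AT list, never
synthesized.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterator

import pysam

from .errors import ConsistencyError, FormatError
from .gaf_io import GAFRecord
from .graph_model import OrientedStep, PangenomeGraph, parse_oriented_steps

logger = logging.getLogger(__name__)

VARIANT_MAPQ = 60
MATCH_TAG = "mt"  # Z tag: "alt" or "ref-fallback"


@dataclass(frozen=True)
class InputVariant:
    chrom: str
    pos: int            # 1-based, VCF convention
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise FormatError(f"variant at {self.chrom}:{self.pos}: empty allele")

    @property
    def name(self) -> str:
        return self.id if self.id else f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"


@dataclass(frozen=True)
class PangenomeVariant:
    chrom: str
    pos: int            # 1-based
    ref: str
    alts: tuple[str, ...]
    at_paths: tuple[tuple[OrientedStep, ...], ...]  # reference first

    def __post_init__(self) -> None:
        if len(self.at_paths) != 1 + len(self.alts):
            raise FormatError(
                f"{self.chrom}:{self.pos}: {len(self.at_paths)} AT traversals "
                f"for {1 + len(self.alts)} alleles")
        if any(not p for p in self.at_paths):
            raise FormatError(f"{self.chrom}:{self.pos}: empty AT traversal")

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference interval covered by the ref allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


def parse_at_field(value: str) -> list[list[OrientedStep]]:
    """Split a comma-separated AT value into one step list per allele."""
    if not value:
        raise FormatError("empty AT field")
    return [parse_oriented_steps(token) for token in value.split(",")]


def normalize_variant(v: InputVariant) -> InputVariant:
    """Trim shared leading/trailing allele bases, keeping at least one base each.

    Standard VCF-style normalization (without left-alignment against a
    reference sequence); idempotent.  A degenerate ref==alt record comes back
    unchanged.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    if ref == alt:
        return v
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt)


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele or allele == "*"


def _at_path_record(name: str, steps: tuple[OrientedStep, ...] | list[OrientedStep],
                    graph: PangenomeGraph, tags: list) -> GAFRecord:
    path_len = 0
    for step in steps:
        if step.node_id not in graph.nodes:
            raise ConsistencyError(
                f"{name!r}: AT path traverses node {step.node_id} "
                "absent from the graph")
        path_len += graph.node_length(step.node_id)
    return GAFRecord(
        query_name=name, query_len=path_len, query_start=0, query_end=path_len,
        strand="+", path=list(steps), path_len=path_len, path_start=0,
        path_end=path_len, matches=path_len, block_len=path_len,
        mapq=VARIANT_MAPQ, tags=tags)


class PangenomeVcf:
    """Pangenome variants indexed by chromosome and reference span."""

    def __init__(self, variants: list[PangenomeVariant]) -> None:
        self.by_chrom: dict[str, list[PangenomeVariant]] = {}
        for pv in variants:
            self.by_chrom.setdefault(pv.chrom, []).append(pv)
        self._starts: dict[str, list[int]] = {}
        self._max_ref: dict[str, int] = {}
        for chrom, pvs in self.by_chrom.items():
            pvs.sort(key=lambda p: (p.pos, -len(p.ref)))
            self._starts[chrom] = [p.span[0] for p in pvs]
            self._max_ref[chrom] = max(len(p.ref) for p in pvs)

    @classmethod
    def load(cls, path: str) -> "PangenomeVcf":
        variants = []
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                if "AT" not in rec.info:
                    raise FormatError(
                        f"{rec.chrom}:{rec.pos}: pangenome VCF record lacks AT INFO")
                at_value = rec.info["AT"]
                if isinstance(at_value, tuple):
                    at_value = ",".join(at_value)
                at = parse_at_field(at_value)
                variants.append(PangenomeVariant(
                    rec.chrom, rec.pos, rec.ref,
                    tuple(rec.alts or ()),
                    tuple(tuple(p) for p in at)))
        return cls(variants)

    def overlapping(self, chrom: str, start: int, end: int) -> list[PangenomeVariant]:
        """Pangenome variants whose ref span intersects [start, end), 0-based."""
        pvs = self.by_chrom.get(chrom)
        if not pvs:
            return []
        lo = bisect_right(self._starts[chrom], start - self._max_ref[chrom])
        out = []
        for pv in pvs[lo:]:
            s, e = pv.span
            if s >= end:
                break
            if e > start:
                out.append(pv)
        return out


def match_variant(v: InputVariant, pangenome: PangenomeVcf,
                  graph: PangenomeGraph) -> GAFRecord | None:
    """Apply the alt-match / ref-fallback / skip rule to one input variant.

    Exact match of the normalized (ref, alt) pair against a pangenome allele
    gives the alt traversal; a site overlap without an allele match gives the
    overlapping variant's reference traversal; no overlap gives ``None``.
    When several pangenome variants overlap, the smallest position (longest
    ref on ties) wins.
    """
    if _is_symbolic(v.alt) or _is_symbolic(v.ref):
        return None
    norm = normalize_variant(v)
    start, end = norm.pos - 1, norm.pos - 1 + len(norm.ref)
    candidates = pangenome.overlapping(norm.chrom, start, end)
    if not candidates:
        return None
    for pv in candidates:
        for alt_index, alt in enumerate(pv.alts):
            if _is_symbolic(alt):
                continue
            pv_norm = normalize_variant(
                InputVariant(pv.chrom, pv.pos, pv.ref, alt))
            if (pv_norm.pos, pv_norm.ref, pv_norm.alt) == (norm.pos, norm.ref, norm.alt):
                return _at_path_record(
                    v.name, pv.at_paths[1 + alt_index], graph,
                    tags=[(MATCH_TAG, "Z", "alt")])
    best = candidates[0]  # sorted by (pos, -len(ref))
    return _at_path_record(v.name, best.at_paths[0], graph,
                           tags=[(MATCH_TAG, "Z", "ref-fallback")])


def match_vcf(input_vcf: str, pangenome: PangenomeVcf,
              graph: PangenomeGraph) -> Iterator[tuple[InputVariant, GAFRecord | None]]:
    """Match every sequence-resolved allele of an input VCF; symbolic alts skipped."""
    skipped_symbolic = 0
    with pysam.VariantFile(input_vcf) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if _is_symbolic(alt) or _is_symbolic(rec.ref):
                    skipped_symbolic += 1
                    continue
                v = InputVariant(rec.chrom, rec.pos, rec.ref, alt,
                                 rec.id if rec.id not in (None, ".") else None)
                yield v, match_variant(v, pangenome, graph)
    if skipped_symbolic:
        logger.info("skipped %d symbolic alleles", skipped_symbolic)


def vcf_at_to_gaf(vcf_path: str, graph: PangenomeGraph) -> Iterator[GAFRecord]:
    """One GAF record per alt allele of an AT-bearing VCF (multi-allelics expand)."""
    with pysam.VariantFile(vcf_path) as vcf:
        for lineno, rec in enumerate(vcf, 1):
            if "AT" not in rec.info:
                raise FormatError(f"VCF record {lineno} ({rec.chrom}:{rec.pos}): "
                                  "missing AT INFO field")
            at_value = rec.info["AT"]
            if isinstance(at_value, tuple):
                at_value = ",".join(at_value)
            at = parse_at_field(at_value)
            alts = rec.alts or ()
            if len(at) != 1 + len(alts):
                raise FormatError(
                    f"VCF record {lineno} ({rec.chrom}:{rec.pos}): "
                    f"{len(at)} AT traversals for {1 + len(alts)} alleles")
            for alt_index, alt in enumerate(alts):
                name = (rec.id if rec.id not in (None, ".")
                        else f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}")
                yield _at_path_record(name, at[1 + alt_index], graph,
                                      tags=[("va", "Z", alt)])
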