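"""Synthetic pangenomes, reads, annotations, coverage, and AT-bearing VCFs.

Every generator is deterministic for a fixed spec/seed and self-validating:
the emitted GFA/GAF/VCF parse cleanly through this package's own readers,
and paths spell the sequences the ground-truth tables record.  The graphs
are backbone-plus-bubbles: a reference contig ``ref`` interrupted by
biallelic SNV or short-insertion bubbles, with topologically sorted integer
node IDs — the shape produced by pangenome constructors such as
minigraph-cactus on a pair of haplotypes.  Reads are error-free because the
toolkit under test indexes and queries alignments rather than producing
them; sequencing noise would exercise nothing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import IO, Iterator

from .errors import GafpanError
from .gaf_io import GAFRecord, spelled_sequence
from .graph_model import (EmbeddedPath, OrientedStep, PangenomeGraph,
                          format_oriented_steps, path_sequence, steps_covering)

BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    n_bubbles: int = 10
    node_len_range: tuple[int, int] = (5, 15)   # anchor node lengths, bases
    seed: int = 0
    read_depth: float = 5.0
    read_len: int = 30


@dataclass(frozen=True)
class BubbleTruth:
    """Ground truth for one biallelic bubble, in VCF terms plus traversals."""

    chrom: str
    pos: int                               # 1-based, VCF convention
    ref: str
    alt: str
    at_ref: tuple[OrientedStep, ...]
    at_alt: tuple[OrientedStep, ...]
    kind: str                              # "snv" | "ins"
    alt_offset: int                        # offset of alt allele in spelled at_alt


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def make_bubble_graph(spec: FixtureSpec) -> tuple[PangenomeGraph, list[BubbleTruth]]:
    """Backbone path ``ref`` with ``n_bubbles`` biallelic bubbles.

    Node IDs are assigned in topological order.  Two haplotypes are embedded:
    ``ref`` (all reference alleles, flagged reference) and ``alt`` (all
    alternate alleles).  The truth table holds VCF-style (pos, ref, alt) and
    both allele traversals in the style of ``vg deconstruct`` AT values,
    anchors included, reference traversal first.
    """
    rng = random.Random(spec.seed)
    graph = PangenomeGraph()
    next_id = 1

    def new_node(seq: str) -> int:
        nonlocal next_id
        graph.add_node(next_id, seq)
        next_id += 1
        return next_id - 1

    lo, hi = spec.node_len_range
    anchor = new_node(_random_seq(rng, rng.randint(lo, hi)))
    ref_steps = [OrientedStep(anchor)]
    alt_steps = [OrientedStep(anchor)]
    truths: list[BubbleTruth] = []
    ref_pos = len(graph.nodes[anchor].sequence)   # 0-based, bases on ref path so far
    for _ in range(spec.n_bubbles):
        left = ref_steps[-1].node_id
        kind = rng.choice(("snv", "ins"))
        if kind == "snv":
            ref_base = rng.choice(BASES)
            alt_base = rng.choice([b for b in BASES if b != ref_base])
            ref_node = new_node(ref_base)
            alt_node = new_node(alt_base)
            right = new_node(_random_seq(rng, rng.randint(lo, hi)))
            for a, b in ((left, ref_node), (left, alt_node),
                         (ref_node, right), (alt_node, right)):
                graph.add_edge(OrientedStep(a), OrientedStep(b))
            ref_steps.append(OrientedStep(ref_node))
            alt_steps.append(OrientedStep(alt_node))
            at_ref = (OrientedStep(left), OrientedStep(ref_node), OrientedStep(right))
            at_alt = (OrientedStep(left), OrientedStep(alt_node), OrientedStep(right))
            truths.append(BubbleTruth(
                "ref", ref_pos + 1, ref_base, alt_base, at_ref, at_alt, "snv",
                alt_offset=len(graph.nodes[left].sequence)))
            ref_pos += 1
        else:
            ins_node = new_node(_random_seq(rng, rng.randint(1, 5)))
            right = new_node(_random_seq(rng, rng.randint(lo, hi)))
            for a, b in ((left, right), (left, ins_node), (ins_node, right)):
                graph.add_edge(OrientedStep(a), OrientedStep(b))
            alt_steps.append(OrientedStep(ins_node))
            pad = graph.nodes[left].sequence[-1]
            at_ref = (OrientedStep(left), OrientedStep(right))
            at_alt = (OrientedStep(left), OrientedStep(ins_node), OrientedStep(right))
            truths.append(BubbleTruth(
                "ref", ref_pos, pad, pad + graph.nodes[ins_node].sequence,
                at_ref, at_alt, "ins",
                alt_offset=len(graph.nodes[left].sequence) - 1))
        ref_steps.append(OrientedStep(right))
        alt_steps.append(OrientedStep(right))
        ref_pos += len(graph.nodes[right].sequence)
    graph.add_path_fragment(EmbeddedPath("ref", ref_steps, 0, is_reference=True))
    if spec.n_bubbles:
        graph.add_path_fragment(EmbeddedPath("alt", alt_steps, 0))
    for truth in truths:  # self-check: alt traversal spells flank+alt+flank
        spelled = path_sequence(graph, list(truth.at_alt))
        assert spelled[truth.alt_offset:truth.alt_offset + len(truth.alt)] == truth.alt
    return graph, truths


def make_fragmented_path(graph: PangenomeGraph, name: str,
                         gaps: list[tuple[int, int]]) -> None:
    """Re-embed ``name`` as clipped fragments, dropping whole nodes inside gaps.

    Each (start, end) gap is given in source-path base coordinates; nodes
    fully inside a gap are removed from the path and the remaining runs
    become fragments with the proper ``fragment_offset``.  Used to emulate
    the clipped contigs produced by pangenome construction.
    """
    fragments = graph.paths.pop(name)
    source = fragments[0]
    runs: list[tuple[int, list[OrientedStep]]] = []
    offset = 0
    current: list[OrientedStep] = []
    current_off = 0
    for step in source.steps:
        length = graph.node_length(step.node_id)
        clipped = any(offset >= s and offset + length <= e for s, e in gaps)
        if clipped:
            if current:
                runs.append((current_off, current))
                current = []
        else:
            if not current:
                current_off = offset
            current.append(step)
        offset += length
    if current:
        runs.append((current_off, current))
    for frag_offset, steps in runs:
        graph.add_path_fragment(EmbeddedPath(
            name, steps, frag_offset, is_reference=source.is_reference,
            line_type="W" if name.count("#") == 2 else "P"))


def simulate_reads(graph: PangenomeGraph, spec: FixtureSpec,
                   path_names: list[str] | None = None) -> Iterator[GAFRecord]:
    """Error-free reads sampled uniformly along embedded haplotype paths.

    Expected per-base coverage over the sampled haplotypes is
    ``read_depth``; every record is checked against the haplotype sequence
    before being yielded.
    """
    rng = random.Random(spec.seed + 1)
    names = path_names if path_names is not None else sorted(graph.paths)
    walks = []
    for name in names:
        for fragment in graph.paths[name]:
            length = graph.fragment_length(fragment)
            if spec.read_len > length:
                raise ValueError(
                    f"read_len {spec.read_len} exceeds fragment of {name!r} "
                    f"({length} bases)")
            walks.append((name, fragment, length))
    total = sum(w[2] for w in walks)
    n_reads = round(spec.read_depth * total / spec.read_len)
    for i in range(n_reads):
        name, fragment, length = walks[rng.randrange(len(walks))]
        start = rng.randint(0, length - spec.read_len)
        steps, path_start, slice_len = steps_covering(
            graph, fragment.steps, start, start + spec.read_len)
        record = GAFRecord(
            query_name=f"read{i}", query_len=spec.read_len, query_start=0,
            query_end=spec.read_len, strand="+", path=steps,
            path_len=slice_len, path_start=path_start,
            path_end=path_start + spec.read_len, matches=spec.read_len,
            block_len=spec.read_len, mapq=60)
        expected = path_sequence(graph, fragment.steps)[start:start + spec.read_len]
        if spelled_sequence(graph, record) != expected:
            raise GafpanError("read simulator self-check failed")  # pragma: no cover
        yield record


def make_truth_vcf(truths: list[BubbleTruth], stream: IO,
                   graph: PangenomeGraph | None = None) -> None:
    """Write the deconstruct-style pangenome VCF: one biallelic record per
    bubble, AT INFO listing the reference then alternate traversal."""
    stream.write("##fileformat=VCFv4.2\n")
    stream.write('##INFO=<ID=AT,Number=R,Type=String,'
                 'Description="Allele traversal through the graph">\n')
    if graph is not None and "ref" in graph.paths:
        length = graph.path_length("ref")
        stream.write(f"##contig=<ID=ref,length={length}>\n")
    stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for i, t in enumerate(truths):
        at = (format_oriented_steps(t.at_ref) + ","
              + format_oriented_steps(t.at_alt))
        stream.write(f"{t.chrom}\t{t.pos}\tbubble{i}\t{t.ref}\t{t.alt}\t60\tPASS\t"
                     f"AT={at}\n")


def random_gaf_records(n: int, max_node_id: int, seed: int,
                       max_path_nodes: int = 5) -> list[GAFRecord]:
    """Structurally valid random GAF records (no backing graph).

    Paths are random oriented steps over [1, max_node_id]; numeric columns
    are mutually consistent.  Useful for sort/index stress tests where only
    the node-interval key matters.
    """
    rng = random.Random(seed)
    records = []
    for i in range(n):
        n_steps = rng.randint(1, max_path_nodes)
        base = rng.randint(1, max_node_id)
        ids = [min(max_node_id, max(1, base + rng.randint(-3, 3)))
               for _ in range(n_steps)]
        path = [OrientedStep(j, rng.random() < 0.3) for j in ids]
        path_len = rng.randint(n_steps, n_steps * 40)
        path_start = rng.randint(0, path_len - 1)
        path_end = rng.randint(path_start + 1, path_len)
        span = path_end - path_start
        query_len = span + rng.randint(0, 10)
        query_start = rng.randint(0, query_len - span)
        tags: list = []
        if rng.random() < 0.5:
            tags.append(("NM", "i", rng.randint(0, 5)))
        if rng.random() < 0.3:
            tags.append(("cg", "Z", f"{span}="))
        if rng.random() < 0.2:
            tags.append(("dv", "f", round(rng.random(), 4)))
        records.append(GAFRecord(
            query_name=f"r{i}", query_len=query_len, query_start=query_start,
            query_end=query_start + span, strand=rng.choice("+-"), path=path,
            path_len=path_len, path_start=path_start, path_end=path_end,
            matches=span, block_len=span, mapq=rng.choice([0, 1, 30, 60, 255]),
            tags=tags))
    return records


def random_annotations(graph: PangenomeGraph, path_name: str, n: int,
                       seed: int, min_len: int = 1,
                       max_len: int = 60) -> list[tuple[str, int, int, str, str]]:
    """Random BED-style intervals (contig, start, end, name, strand) on a path."""
    rng = random.Random(seed)
    total = graph.path_length(path_name)
    out = []
    for i in range(n):
        length = rng.randint(min_len, min(max_len, total))
        start = rng.randint(0, total - length)
        strand = rng.choice("+-")
        out.append((path_name, start, start + length, f"ann{i}", strand))
    return out


def pack_table_lines(coverage: dict[int, "object"]) -> Iterator[str]:
    """Serialize coverage arrays to pack-style TSV lines (header included)."""
    yield "node.id\toffset\tcoverage\n"
    for node_id in sorted(coverage):
        for offset, value in enumerate(coverage[node_id]):
            if value > 0:
                yield f"{node_id}\t{offset}\t{value:g}\n"
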