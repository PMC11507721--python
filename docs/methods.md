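# Methods

## The node-interval coordinate system

All of gafpan rests on one observation: in a pangenome graph whose integer
node IDs follow the graph topology (as produced by minigraph-cactus, PGGB, or
`vg construct`, or after renumbering with `vg ids -s` / `odgi sort`), a short
path visits nodes whose IDs lie in a small interval. The closed interval
`[min_id, max_id]` over the IDs traversed by a GAF path therefore plays the
role that `(chrom, start, end)` plays for BED/VCF on a linear genome: it is
the sort key, the index key, and the query key.

Interval overlap is a *superset* test for true path overlap — since
`min_id <= any traversed ID <= max_id`, a path sharing a node with a query
set always has an interval intersecting the query's ID span, but not
conversely. Region-level operations (`gaf_slice`) therefore follow every
interval query with an exact node-membership filter.

Records whose column 6 is a bare stable sequence name (the alternative GAF
path syntax) have no node interval; the sorter counts and skips them, and the
indexer refuses them outright.

## Sorting

`sort_gaf` is a bounded-memory external merge sort. Records are read in
chunks of `chunk_records` (default 100,000), each chunk is sorted by
`(min_id, max_id, input_rank)` and spilled to a temporary file, and the
spills are k-way merged with `heapq.merge`. When more than 64 spill files
exist they are merged in cascades of 64 so the final merge never exceeds the
process's open-file budget. The `input_rank` tie-breaker makes the output a
*stable* sort of the input, hence byte-identical for any chunk size — a
property the test suite asserts for chunk sizes {1, 7, 128, 10^6}.

Output is BGZF-compressed (via pysam) with the standard 28-byte EOF block,
so `(block offset << 16 | within-block offset)` virtual offsets give random
access; plain-gzip input is accepted on read.

## The binning index

The sidecar `.gai` index is a tabix/CSI-style structure re-targeted at
node-ID space; byte compatibility with `.tbi` is deliberately not attempted,
semantic compatibility is.

* Hierarchical bins with minimum shift 14 (finest bin = 2^14 IDs) and 3 bits
  per level. The depth is derived from the configurable maximum node ID
  (default 2^40, giving 9 levels below the root), so graphs with larger ID
  spaces only need a larger `--max-node-id`.
* Every record is assigned to the smallest bin containing
  `[min_id, max_id + 1)`; adjacent records in the same bin coalesce into one
  chunk of (begin, end) virtual offsets.
* The linear index over 16,384-ID windows stores, for window `w`, the
  suffix-minimum of the first virtual offset of any record spanning a window
  `>= w`. This is a correct lower bound for pruning chunks at query time
  (every record overlapping a query `[lo, hi]` spans some window at or right
  of `lo`'s window) and is non-decreasing by construction. Storing only the
  min-ID window's first offset — the more literal translation of tabix —
  would make pruning unsound for records whose min lies far left of the
  query.
* Queries treat both the record interval and the query as closed: node IDs
  are discrete labels and the index addresses whole nodes (nodes are assumed
  short enough that within-node indexing is unnecessary), so a shared
  endpoint counts as overlap. Since records are sorted by `min_id`,
  scanning stops at the first record with `min_id > hi`.

The sidecar layout (little-endian: magic, min_shift, depth, record count,
bin table, linear index, max node ID) is documented in
`gafpan.sort_index.GAFIndex`.

## Projecting annotations

`project_annotation` walks the embedded path of the annotation's contig,
accumulating node lengths until it finds the minimal contiguous slice of
steps covering `[start, end)`; `path_start`/`path_end` are the base offsets
of the annotation within that slice, so the first and last step each
contribute at least one annotated base. The contig must be flagged as a
reference first (`set_reference` or `--reference`); the flag round-trips
through GFA via the v1.1 `H RS:Z:` reference-sample header.

Contigs clipped during pangenome construction are stored as fragments with
source-coordinate offsets; an annotation crossing a clip gap produces one
GAF record per overlapped fragment, named `label.part0`, `label.part1`, …
in source order (a single surviving part keeps the bare label). Each part's
`query_start`/`query_end` record which sub-interval of the source annotation
it covers — a convention this package defines, since none is standard.

Minus-strand features are emitted with reversed, flipped steps so the path
reads the feature 5'→3'; the GAF strand column stays `+` because orientation
is carried by the path itself. `mapq` is fixed at 60 and
`matches = block_len = part length` (an annotation aligns perfectly to its
own path). GFF3 input is converted from 1-based closed to 0-based half-open
before projection, and features are projected independently (no
transcript-model stitching).

## Coverage bin-and-extend

Per-base coverage (from a pack-style TSV or recomputed from GAF alignments
with `mapq >= min_mapq`, default 1) is quantized by breakpoints
`1, 5, 30` into half-open classes `[1,5)`, `[5,30)`, `[30,∞)`; bases below
1 read are discarded. Breakpoint values themselves land in the class they
open: coverage 5 is "5–30", coverage 30 is "30+". Coverage is unstranded:
both read orientations project onto forward-strand node offsets.

Maximal same-class runs within a node become segments. Segments are then
greedily grouped into paths: seeds are consumed in ascending
`(node_id, start)` order and extended in both directions. An extension
across a node boundary requires (a) the current segment to reach that
boundary, (b) a not-yet-consumed same-class segment on the neighboring node
that starts at its own boundary, so interior segments of a path always span
whole nodes and partial interior bins never merge. At branch points the
smallest node ID wins (forward orientation before reverse); the losing
candidate seeds its own path later. Every segment belongs to exactly one
path, which gives the partition property the tests assert: the emitted
paths cover exactly the bases with coverage ≥ 1, each path is class-pure,
and the recorded mean (`cm:f` tag, full precision) equals the arithmetic
mean of its bases. Record names encode class and mean
(`cov_5-30_mean12.40`), with class label, mean, and class index also
emitted as `cc:Z`, `cm:f`, `ci:i` tags.

## Variant matching

The pangenome VCF (e.g. from `vg deconstruct`) carries each allele's graph
traversal in the `AT` INFO field, reference allele first. Input variants are
normalized by trimming shared trailing then leading allele bases (keeping at
least one base each, positions adjusted); pangenome alleles are normalized
the same way at comparison time, so padded and minimal representations
match.

* **alt match** — the normalized `(pos, ref, alt)` of the input equals a
  pangenome allele's: emit that alternate allele's traversal (`mt:Z:alt`).
* **ref fallback** — no allele matches but a pangenome variant's reference
  span `[pos, pos + len(ref))` intersects the input's normalized span: emit
  that variant's reference traversal (`mt:Z:ref-fallback`). With several
  overlapping candidates the smallest position (longest ref on ties) wins.
* **skip** — no overlap: no record. Symbolic alleles (`<DEL>`, breakends,
  `*`) are never matched.

Emitted paths are always members of the source record's AT list. GAF fields
span the full traversal (`path_start = 0`, `path_end = path_len`,
`query_len = path_len`). `vcf_at_to_gaf` skips the matching entirely and
emits one record per alternate allele, expanding multi-allelic sites.

## Region queries and chunking

A reference-range query projects `[start, end)` along the contig's
fragments onto the nodes they traverse, then expands the node set by
`context` rounds of adjacency (each round adds every node one edge away).
Context is measured in expansion rounds, not bases — a documented stand-in
where upstream tooling leaves the semantics open. Extracted records keep
full paths by default; `trim_to_subgraph` is the visualization-prep opt-in
that cuts each record to its maximal in-subgraph runs, recomputes
`path_len/path_start/path_end` with clipping at the cut boundaries, drops
runs left with no annotated bases, and suffixes repeated names `.1`, `.2`,
…  Subgraph GFA is written with S and L lines before P lines, the order
graph viewers expect.

## Synthetic data

`gafpan.fixtures` generates backbone-plus-bubbles graphs: anchor nodes of
5–15 bp separated by biallelic bubbles, either SNVs (two 1-bp branch nodes)
or insertions (a 1–5 bp insertion node that the reference skips), with node
IDs assigned in topological order and two embedded haplotypes (`ref`,
flagged reference, and `alt`). The truth table records each bubble's
VCF-style `(pos, ref, alt)` — insertions use the padding-base convention —
and both allele traversals, anchors included, exactly as `vg deconstruct`
writes `AT`. Reads are error-free uniform samples along haplotype walks at
a requested mean depth (default 5×, 30 bp; acceptance runs derive the depth
that yields 10,000 records): the toolkit indexes and queries alignments, it
does not align, so sequencing error would exercise nothing.

What the generator does *not* emulate, and what passing tests therefore do
not show: nested or multi-allelic bubbles, inversions and reverse-strand
haplotype steps, ID spaces with gaps or non-topological order, structural
variation at the scale where a path's ID interval becomes a poor proxy for
its node set, and alignment artifacts (clips, mismatches, mapq diversity
beyond the simulated constants). The closed-interval query semantics and
the membership filter are exercised directly, so these omissions affect
realism of inputs, not correctness of the indexing contract.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; VCF positions are
  1-based at the I/O boundary; GAF node intervals are closed.
* Float GAF tags serialize with `str()` (shortest round-tripping form), so
  parse∘write is the identity on records.
* `mapq` 255 means "missing" and round-trips as 255; `*` parses as 255.
* Empty GFA input yields an empty graph; an empty annotation stream yields
  an empty GAF; an annotation falling entirely in clipped-out gaps yields no
  records and a logged skip.
* Duplicate `(node, offset)` pack rows: last value wins, counted in a
  warning. Coverage means are exact (within 1e-9) by construction.
* The sortedness heuristic warns when a path's ID span exceeds 100× its step
  count; it never rejects.

## Problem sizes

The test suite and the acceptance script run on graphs of roughly 200–1,200
nodes with 4,000–10,000 GAF records, 200 random projections, 500 random
interval queries, and 50-bubble variant sets — sizes chosen so every oracle
(brute-force scans, substring checks, per-base coverage classification) can
be recomputed exhaustively on each run.
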