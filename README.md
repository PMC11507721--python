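# gafpan

Sort, index, query, and produce pangenome-graph annotations as GAF paths.

Pangenome graphs represent many genomes at once — nodes carry sequences,
edges carry adjacencies, haplotypes are embedded paths — but the annotation
ecosystem that makes a linear reference useful (BED/GFF/VCF files, sorted,
bgzipped, tabix-indexed, instantly sliceable) has no counterpart in graph
space. gafpan provides one, for anyone who works with GAF-format read
alignments or wants to carry gene models, repeats, coverage tracks, or known
variants *into* a graph: the Graph Alignment Format already describes paths
through a graph as plain tab-separated text, so the missing pieces are
sorting, compression, indexing, and the producers that turn classical
annotations into paths.

## The core idea

In a graph whose integer node IDs are topologically sorted (minigraph-cactus,
PGGB, `vg construct`, or anything renumbered with `vg ids -s`), a short path
touches node IDs spanning a small interval. For a GAF record with path
*p*, the closed interval

> [ n, N ] = [ min(ids(p)), max(ids(p)) ]

plays the role `(chrom, start, end)` plays for BED/VCF. gafpan sorts records
by (n, N), compresses with BGZF, and builds a tabix-style binning + linear
index over node-ID space, so extracting everything overlapping a region is
one seek-and-scan. Interval overlap is a superset of true path overlap, so
region queries finish with an exact node-membership filter.

On top of this core:

* `annotate` projects BED/GFF3 records on a haplotype contig into GAF paths,
  splitting where the contig was clipped during pangenome construction;
* `coverage` turns per-base read coverage into coarse coverage-track paths
  (bin into classes [1,5), [5,30), [30,∞); extend greedily across node
  boundaries while the class is constant);
* `variant-gaf` / `vcf2gaf` convert known variants into allele-traversal
  paths using the `AT` INFO field of a deconstructed pangenome VCF;
* `chunk` extracts a subgraph (by reference range, BED, or node set, with
  adjacency context) together with trimmed, name-deduplicated GAF slices
  ready for graph viewers.

## Worked example

Generate a small synthetic pangenome (5 bubbles on a reference backbone) and
push annotations through the whole pipeline:

```sh
$ gafpan fixtures --out fx --bubbles 5 --seed 7
[gafpan] wrote fixture set to fx (15 nodes, 21 reads, 5 bubbles)

$ head -3 fx/ann.bed
ref	9	30	ann0	0	-
ref	1	43	ann1	0	+
ref	8	61	ann2	0	+

$ gafpan annotate --graph fx/g.gfa --bed fx/ann.bed -o ann.gaf
[gafpan] projected 5 GAF records
$ head -2 ann.gaf
ann0	21	0	21	+	<9<7<6<4<3<1	37	7	28	21	21	60
ann1	42	0	42	+	>1>3>4>6>7>9>10>12	50	1	43	42	42	60
```

`ann0` was a minus-strand feature on bases [9,30) of contig `ref`: its path
steps are reversed and flipped (`<9<7…<1`) so the path spells the feature
5'→3', and of the 37 bases those six nodes span, bases [7,28) are the
annotation. Sort, index, and slice by node interval:

```sh
$ gafpan sort ann.gaf -o ann.sorted.gaf.gz
$ gafpan index ann.sorted.gaf.gz
[gafpan] indexed 5 records, max node ID 15 -> ann.sorted.gaf.gz.gai
$ gafpan query ann.sorted.gaf.gz 4-8
ann0	21	0	21	+	<9<7<6<4<3<1	37	7	28	21	21	60
ann1	42	0	42	+	>1>3>4>6>7>9>10>12	50	1	43	42	42	60
ann2	53	0	53	+	>1>3>4>6>7>9>10>12>13>15	61	8	61	53	53	60
ann4	59	0	59	+	>1>3>4>6>7>9>10>12>13>15	61	2	61	59	59	60
```

Only the four records whose node interval intersects [4,8] come back
(`ann3`, on nodes 10–15, does not). A coverage track from the bundled pack
table:

```sh
$ gafpan coverage --graph fx/g.gfa --pack fx/pack.tsv | head -2
cov_1-5_mean3.14	7	0	7	+	>1	10	1	8	7	7	60	cc:Z:1-5	cm:f:3.142857142857143	ci:i:1
cov_5-30_mean11.00	53	0	53	+	>1>2>3>5>6>8>9>10>12>13>15	65	8	61	53	53	60	cc:Z:5-30	cm:f:11.0	ci:i:2
```

Each record is one maximal path of consistent coverage class; the name and
tags carry the class (`1-5` reads, `5-30` reads, …) and the exact mean
coverage over the path's bases.

See `docs/methods.md` for the algorithms, parameter defaults, and design
choices, and `gafpan --help` for the full command set (`sort`, `index`,
`query`, `annotate`, `coverage`, `variant-gaf`, `vcf2gaf`, `chunk`,
`fixtures`).

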