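# Methods

## Coordinates

All internal coordinates are 0-based, half-open intervals on the plus strand
of a named sequence; strand is an attribute, never a coordinate system.
Conversions happen only at I/O: GTF (1-based inclusive) on read/write, CTSS
(1-based positions) on read, chain/BED natively half-open. Overlap means
≥ 1 shared base under half-open arithmetic, so abutting intervals do not
overlap. Clipping at 0 and, when a chromInfo-style length registry is
supplied, at sequence length is silent (logged, not an error).

## CAGE tag clusters

Tags on one (sequence, strand) are clustered by single linkage over interval
overlap. Because intervals are one-dimensional, a sorted sweep that merges a
tag whenever it starts before the running cluster end is exactly the
transitive closure of pairwise overlap; the tests verify this against
connected components of the explicit pairwise overlap graph. The sweep sorts
tags first, so the partition is invariant to input order.

Per cluster:

* **representative position** — the 5′ end with the maximal summed count;
  ties break to the 5′-most position relative to the strand (smallest
  coordinate on +, largest on −), keeping the choice deterministic.
* **tpm** — count × 10⁶ / library size. The library size defaults to the
  sum of retained tag counts (making Σ tpm = 10⁶ per library); a flag
  accepts the true mapped-tag total when tags were filtered upstream.
* **shape** — sharp/broad promoter classes are computed as the
  count-weighted interquantile width of member 5′ ends: the width between
  the positions at the 0.10 and 0.90 quantiles of the cumulative count
  distribution, sharp iff ≤ 4 bp. Both quantiles and the width cutoff are
  exposed in `Parameters`. This is the standard width-based CAGE shape
  formulation; the class is translation-invariant by construction.

Gene assignment uses the representative position, not the cluster span, in
a window *closed on both ends* ([−500, +500] around the TSS, same strand).
Span-overlap assignment was considered and rejected as the less reproducible
reading (a single broad cluster could attach to distant TSSes); the window
constant and the choice are explicit parameters of the design.

## Chains and liftover

UCSC chains are parsed fail-fast: block sums are checked against header
spans per chain and any inconsistency aborts the file, naming the chain id.
Blocks are normalized to plus-strand coordinates on both sides, with
minus-strand queries converted by `[s, e) → [q_size − e, q_size − s)` and an
`orientation` flag (`same`/`opposite`). Interval mapping is a piecewise
offset (mirror-offset when opposite) over an interval-tree index of blocks,
giving sublinear region queries. A `chainSwap`-style inversion is provided
so that mirror views can be built from a single chain file; it is property-
tested against the reverse per-base mapping for both query strands.

## Anchors

Every block overlapping the region of interest, trimmed to it, is an anchor
candidate; one chain is treated as one candidate homologous locus.
Competition is resolved per connected component of mutually overlapping
reference blocks (not globally): if more than `max_anchor_loci` (default 2)
distinct chains occur in a component, only the highest-scoring chains are
kept, with ties broken by larger aligned span in the component, then
lexicographic chain id. Within the kept set, each block is split at the
boundaries of the covering set, and every piece is classified 1-to-1
(single covering chain) or 1-to-2. Per-component competition preserves
distinct duplicate relationships along a long region, which a single global
top-2 cut would merge. Display colors default to gray (1-to-1) and blue
(1-to-2).

Self-alignment anchors drop trivial identity chains (same sequence, same
span, plus strand) and otherwise behave identically.

Bridged anchors compose two chain sets sharing assembly A on their target
side: the region in B is lifted back to A, intersected with the aligned
footprint of the A:C set in A coordinates, and each intersection is
projected into B and C. Composed orientation is the product of the two
orientations, the score the minimum of the two chain scores. Composed
pieces narrower than `min_width` (default 10 bp) are dropped as
composition confetti; per-base equivalence checks run with `min_width=1`.
The construction is inherently blind to homology private to B and C that is
not conserved in A; this is a documented property of the method, not
compensated for.

## Homology and WGD pairs

Homology pairs are unordered for deduplication; identifiers are opaque
strings (no id-history resolution). WGD candidates come from the ortholog
bridge: every A gene with k ≥ 2 distinct B orthologs contributes all
C(k, 2) unordered B-gene combinations, annotated with the bridging A gene.
The 1-to-2 classification is taken from the table itself; alignment
multiplicity (1-to-2 anchors) provides the independent evidence on the
sequence side. Ancestor-based grouping is a plain multiset count with
missing taxa pooled under "unknown".

## Views

* **Promoter**: regions are the union over transcripts of ±`promoter_flank`
  (500 bp) windows around each TSS. Shared-TSS calling maps each reference
  TC representative through the anchors and accepts a target TC within
  `shared_tss_tolerance` (100 bp) on the orientation-consistent strand.
  Pairing is greedy by smallest mapped distance, ties by higher combined
  tpm then coordinates, each TC used at most once; shared + turnover is a
  partition of each side's TC set. The tolerance has no counterpart in the
  original display (sharing there is read visually off the anchors), so it
  is an explicit, configurable constant.
* **Gene structure**: regions are transcript bounding boxes ±
  `transcript_flank` (500 bp); per-exon conservation is the fraction of
  exon bases covered by ≥ 1 anchor interval, in [0, 1] and monotone
  non-decreasing in the anchor set. An exon at 0.0 is unaligned in the
  homolog.
* **Neighborhood**: regions are `neighborhood_half_width` (1 Mb) each side
  of the gene-box midpoint — the fixed 2 Mb window is used for all
  comparisons in place of precomputed synteny blocks. Links are gene-level
  homology relations between the neighbor sets (the queried pair is always
  linked), each with a strand-agreement flag, plus a global conserved-order
  flag (target starts monotone across links, either direction). Sequence
  anchors can be overlaid but gene links are the primary content, matching
  how neighborhood conservation is actually read.

Views serialize to a schema-versioned JSON document that round-trips all
coordinates exactly (cluster member tags are summarized, not serialized),
or to a two-panel SVG that is presentation-only.

## Synthetic fixtures

The generator emulates three scenarios — speciation (two assemblies, one
chain), intra-genome duplication (one assembly, one self-chain), and
duplication bridged through an outgroup (two chain files sharing the
outgroup on their target side). An ancestral axis carries `n_genes`
(default 4) genes in 6 kb slots, alternating strand, with
`n_transcripts_per_gene` (default 2) three-exon transcripts whose TSSes are
spaced 400 bp apart. Descendant coordinates differ by random intergenic
indels (probability `indel_rate` = 0.5 per slot boundary, size 50–200 bp)
that become chain gaps; indels are intergenic by default so exon
conservation truth is exactly 1.0, with an option that deletes 100 bp of a
200 bp exon on the target side (planted fraction 0.5). One single-position
CAGE cluster is planted per TSS (CTSS tags are 1 bp wide, and abutting 1 bp
tags deliberately do not merge under half-open single linkage); each is
copied to its homologous position with probability 1 − `tss_turnover_prob`,
a lost copy being replaced by a novel cluster 250 bp downstream. The
250 bp shift and 400 bp TSS spacing were chosen from the 100 bp sharing
tolerance so that no unintended pair can fall within tolerance. Generation
is deterministic given the seed, and a self-check validates chain
arithmetic and re-maps every planted shared TSS through the emitted
alignments.

What the fixtures do **not** emulate: real CAGE tag-width distributions and
multi-mapping noise, inversions between homologous loci (minus-strand
mapping is exercised by randomized chain tests instead), tissue-resolved
expression, overlapping gene models, and lineage-specific conservation
invisible to the bridge. Passing end-to-end tests therefore demonstrates
correctness of the coordinate and selection machinery under clean
conditions, not robustness to real-data artifacts.

## Problem sizes and numerics

Oracle-backed checks run at sizes where exhaustive per-base computation is
exact and fast: 1000-tag libraries over 20 seeds for clustering, 10 kb
pseudo-genomes with 1000 random intervals for liftover, ≤ 5 random chains
per instance for anchor competition, and 50 fixture seeds for the
turnover-rate recovery (binomial check at three standard errors). All
tie-breaks in the package are total orders (documented above), so outputs
are invariant to input order; there is no hidden randomness — every
stochastic path takes an explicit seed.

## Known limitations

* Chains are consumed as given; no net-level filtering of best chains.
* Gene "center" for the neighborhood window is the bounding-box midpoint.
* Each gene-model input file is treated as an independent track; model sets
  from different sources are not merged.
* The bridge cannot recover B:C homology absent from A (see above).
* SVG output is a schematic, not a faithful reproduction of any browser
  rendering.
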