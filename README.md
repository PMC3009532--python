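# homolocus

A coordinate-only comparison engine for pairs of homologous loci — orthologs
across genomes, or paralogs retained from whole-genome duplications (WGD)
within one genome. It is aimed at people studying the evolution of gene
expression: where transcription starts, whether a promoter was kept, lost or
gained after duplication or speciation, whether the exon–intron structure is
intact, and whether the genomic neighborhood still carries the duplicated
gene order that distinguishes a whole-locus duplication from a gene-family
expansion.

The engine combines four ingredients:

* **CAGE tag clusters.** CAGE sequences capped 5′ ends of transcripts,
  giving per-base transcription-start evidence with counts. Tags on the same
  chromosome strand that overlap by ≥ 1 bp are merged into tag clusters
  (TCs) by single linkage. Each TC gets a representative position (the 5′
  end with the highest tag count), an expression level in tags per million
  (tpm = count × 10⁶ / library size), and a *sharp*/*broad* shape class from
  the count-weighted 0.10–0.90 interquantile width of its 5′-end
  distribution (sharp ≤ 4 bp). TCs whose representative position falls in
  the closed [−500, +500] window around a transcript's TSS are assigned to
  the gene; the highest-tpm TC is the gene's representative.
* **Chain-alignment anchors.** Pairwise genome alignments in UCSC chain
  format are decomposed into gap-free blocks; every block overlapping a
  region of interest is an anchor linking the two loci. A reference span
  aligning to a single locus gives 1-to-1 anchors (gray); spans where two
  or more chains overlap give 1-to-*M* anchors, of which only the two
  highest-scoring loci are kept and shown as 1-to-2 (blue) — the pattern
  expected for duplicates retained from a WGD. Self-alignments (selfChain)
  provide anchors between paralogous loci; where a genome has no
  self-alignment, two chain sets sharing an outgroup assembly A are
  composed (B ← A → C) into bridged B↔C anchors.
* **Homology tables.** Ortholog/paralog pairs with last-common-ancestor
  taxa. Candidate WGD paralogs in lineage B are derived by the ortholog
  bridge: two B genes sharing the same A ortholog (A approximating the
  pre-duplication ancestor).
* **Three comparison views.** *Promoter* (union of 1000 bp windows centered
  on each TSS, with shared/turnover TSS calls: a ref TC whose anchor-mapped
  position lands within 100 bp of a target TC on a consistent strand is
  shared; everything unmatched is turnover), *gene structure* (transcript
  spans ± 500 bp, with per-exon anchor-coverage fractions), and *genomic
  neighborhood* (2 Mb windows with gene-level homology links and
  conserved-order flags).

A synthetic fixture generator produces complete, self-consistent input
bundles (GTF, CTSS, chain, homology TSV) with planted ground truth for all
three duplication scenarios, so the whole pipeline is testable without any
downloads.

## Worked example

Generate an ortholog fixture in which each TSS has a 30% probability of
promoter turnover, then compare the first gene pair:

```sh
homolocus simulate --seed 7 --out-dir demo --turnover 0.3
homolocus view promoter \
    --gene-a GENE0_h --gene-b GENE0_m \
    --gtf-a demo/ref.gtf --gtf-b demo/target.gtf \
    --cage-a demo/ref.ctss --cage-b demo/target.ctss \
    --chains demo/pairwise.chain \
    --assembly-a hg --assembly-b mm \
    --out demo/view.json --svg demo/view.svg
```

`demo/view.json` then contains (abridged):

```json
"ref":   {"region": {"seq_id": "chrR", "start": 4500, "end": 5900}},
"annotations": {
  "promoter_centers_ref": [5000, 5400],
  "shared_tss":      [{"ref_position": 5400, "target_position": 5400}],
  "turnover_ref":    [5000],
  "turnover_target": [5250]
}
```

Read: the gene has two distinct TSSes, so the promoter view spans the union
of their ±500 bp windows ([4500, 5900)). The TSS at 5400 has a CAGE cluster
at the anchor-mapped position in both species — a shared, ancestral
promoter. The TSS at 5000 has reference-side CAGE support but nothing at its
mapped position in the target (promoter loss there), while the target locus
gained a novel cluster at 5250 with no reference counterpart. This matches
the planted truth in `demo/truth.json` exactly. The SVG shows the two locus
panels with anchor ribbons (gray 1-to-1, blue 1-to-2) and TC peaks scaled by
tpm.

The other subcommands expose the same machinery directly:
`homolocus cage cluster`, `homolocus anchors --region chrA:5000-9000
--chains …`, `homolocus homology wgd-pairs --orthologs …`. Every command
writes a JSON report envelope with the tool version, effective parameters
and input checksums next to its output.

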