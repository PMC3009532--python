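"""Comparison views for a pair of homologous loci.

A view pairs two locus track sets (region, trimmed gene models, tag
clusters) with the anchors linking them, in one of three modes:

* ``promoter`` — regions are the union of ±flank windows around every TSS;
  annotations report distinct promoter centers and shared/turnover TSSes.
* ``gene_structure`` — regions are transcript bounding boxes plus flanks;
  annotations report per-exon anchor coverage (a 0 fraction flags an exon
  with no alignment support in the homolog).
* ``neighborhood`` — regions are wide windows around each gene; links are
  gene-level homology relations between neighbors, with order/strand
  conservation flags (conserved neighbor order is the signature of
  duplications of whole loci rather than single-gene family expansion).

Views serialize to a stable JSON document (the machine-readable report) or
to a two-panel SVG (presentation only).
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .anchors import Anchor, anchors_for_region, bridge_anchors, self_anchors
from .annotation import (
    Gene,
    GenomicInterval,
    Parameters,
    Transcript,
    gene_structure_span,
    genes_in_region,
    neighborhood,
    promoter_span,
    tss_of,
)
from .cage import TagCluster
from .chains import Chain, ChainIndex

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

MODES = ("promoter", "gene_structure", "neighborhood")


class GeneNotFoundError(KeyError):
    pass


@dataclass
class LocusTrackSet:
    region: GenomicInterval
    genes: list[Gene]
    tag_clusters: list[TagCluster]
    assembly: str = ""


@dataclass
class ComparisonView:
    mode: str
    ref: LocusTrackSet
    target: LocusTrackSet
    anchors: list[Anchor]
    annotations: dict = field(default_factory=dict)


def resolve_gene(genes: Iterable[Gene], query: str) -> Gene:
    """Find a gene by id, symbol or synonym; on failure raise with near-miss
    suggestions."""
    genes = list(genes)
    for g in genes:
        if query == g.gene_id or query == g.name or query in g.synonyms:
            return g
    vocabulary = [g.gene_id for g in genes] + [g.name for g in genes if g.name]
    for g in genes:
        vocabulary.extend(g.synonyms)
    near = difflib.get_close_matches(query, vocabulary, n=5)
    raise GeneNotFoundError(
        f"gene {query!r} not found" + (f"; did you mean: {', '.join(near)}?" if near else "")
    )


# ---------------------------------------------------------------------------
# anchor plumbing


def _trim_anchor_to_target(a: Anchor, region: GenomicInterval) -> Anchor | None:
    sub_t = a.target_interval.intersection(region)
    if sub_t is None or sub_t.width == 0:
        return None
    w = sub_t.width
    if a.orientation == "same":
        r_start = a.ref_interval.start + (sub_t.start - a.target_interval.start)
    else:
        r_start = a.ref_interval.start + (a.target_interval.end - sub_t.end)
    return Anchor(
        ref_interval=GenomicInterval(a.ref_interval.seq_id, r_start, r_start + w),
        target_interval=sub_t,
        multiplicity=a.multiplicity,
        chain_id=a.chain_id,
        score=a.score,
        orientation=a.orientation,
        color=a.color,
    )


def _compute_anchors(
    region_ref: GenomicInterval,
    region_target: GenomicInterval,
    chains: Iterable[Chain] | ChainIndex,
    self_alignment: bool,
    bridge: tuple | None,
    params: Parameters,
) -> list[Anchor]:
    if bridge is not None:
        chains_a_to_ref, chains_a_to_target = bridge
        raw = bridge_anchors(
            chains_a_to_ref, chains_a_to_target, region_ref, max_loci=params.max_anchor_loci
        )
    elif self_alignment:
        raw = self_anchors(region_ref, list(chains), max_loci=params.max_anchor_loci)
    else:
        raw = anchors_for_region(region_ref, chains, max_loci=params.max_anchor_loci)
    trimmed = []
    for a in raw:
        t = _trim_anchor_to_target(a, region_target)
        if t is not None:
            trimmed.append(t)
    return trimmed


def _restrict_tcs(tcs: Iterable[TagCluster], region: GenomicInterval) -> list[TagCluster]:
    return [tc for tc in tcs if tc.interval.overlaps(region)]


def _mapped_position(a: Anchor, pos: int) -> int:
    if a.orientation == "same":
        return a.target_interval.start + (pos - a.ref_interval.start)
    return a.target_interval.end - 1 - (pos - a.ref_interval.start)


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, strand)


# ---------------------------------------------------------------------------
# view builders


def _track_set(
    gene: Gene,
    region: GenomicInterval,
    genes: Iterable[Gene] | None,
    tcs: Iterable[TagCluster],
    assembly: str,
) -> LocusTrackSet:
    pool = list(genes) if genes is not None else [gene]
    if all(g.gene_id != gene.gene_id for g in pool):
        pool.append(gene)
    return LocusTrackSet(
        region=region,
        genes=genes_in_region(pool, region),
        tag_clusters=_restrict_tcs(tcs, region),
        assembly=assembly,
    )


def build_promoter_view(
    gene_ref: Gene,
    gene_target: Gene,
    *,
    tcs_ref: Sequence[TagCluster] = (),
    tcs_target: Sequence[TagCluster] = (),
    genes_ref: Iterable[Gene] | None = None,
    genes_target: Iterable[Gene] | None = None,
    chains: Iterable[Chain] | ChainIndex = (),
    self_alignment: bool = False,
    bridge: tuple | None = None,
    params: Parameters | None = None,
    assembly_ref: str = "ref",
    assembly_target: str = "target",
    lengths_ref: Mapping[str, int] | None = None,
    lengths_target: Mapping[str, int] | None = None,
) -> ComparisonView:
    """Promoter view: both regions are the union of ±flank TSS windows;
    annotations carry distinct promoter centers and shared/turnover TSSes."""
    params = params or Parameters()
    region_ref = promoter_span(gene_ref, params.promoter_flank, lengths_ref)
    region_target = promoter_span(gene_target, params.promoter_flank, lengths_target)
    anchors = _compute_anchors(region_ref, region_target, chains, self_alignment, bridge, params)
    view = ComparisonView(
        mode="promoter",
        ref=_track_set(gene_ref, region_ref, genes_ref, tcs_ref, assembly_ref),
        target=_track_set(gene_target, region_target, genes_target, tcs_target, assembly_target),
        anchors=anchors,
    )
    shared, turn_ref, turn_target = shared_tss_pairs(view, params.shared_tss_tolerance)
    view.annotations = {
        "promoter_centers_ref": sorted({tss_of(t) for t in gene_ref.transcripts}),
        "promoter_centers_target": sorted({tss_of(t) for t in gene_target.transcripts}),
        "shared_tss": [
            {
                "ref_position": a.representative_position,
                "target_position": b.representative_position,
            }
            for a, b in shared
        ],
        "turnover_ref": sorted(tc.representative_position for tc in turn_ref),
        "turnover_target": sorted(tc.representative_position for tc in turn_target),
    }
    return view


def shared_tss_pairs(
    view: ComparisonView, tolerance: int = 100
) -> tuple[list[tuple[TagCluster, TagCluster]], list[TagCluster], list[TagCluster]]:
    """Pair tag clusters across the two loci through the anchors.

    A ref TC and a target TC are shared iff the ref representative position
    lies inside some anchor, its image is within ``tolerance`` bp of the
    target representative position, and the strands are consistent with the
    anchor orientation. Pairing is greedy by smallest mapped distance
    (ties: higher combined tpm, then coordinates), each TC used at most
    once; everything unmatched is listed as turnover on its own side.
    shared + turnover partitions each side's TC set.
    """
    candidates = []
    for tr in view.ref.tag_clusters:
        pos = tr.representative_position
        for a in view.anchors:
            if a.ref_interval.seq_id != tr.seq_id or not a.ref_interval.contains(pos):
                continue
            mapped = _mapped_position(a, pos)
            want_strand = tr.strand if a.orientation == "same" else _flip(tr.strand)
            for tt in view.target.tag_clusters:
                if tt.seq_id != a.target_interval.seq_id or tt.strand != want_strand:
                    continue
                d = abs(tt.representative_position - mapped)
                if d <= tolerance:
                    candidates.append(
                        (
                            d,
                            -(tr.tpm + tt.tpm),
                            tr.representative_position,
                            tt.representative_position,
                            tr,
                            tt,
                        )
                    )
    candidates.sort(key=lambda c: c[:4])
    used_ref: set[int] = set()
    used_target: set[int] = set()
    shared: list[tuple[TagCluster, TagCluster]] = []
    for d, _, _, _, tr, tt in candidates:
        if id(tr) in used_ref or id(tt) in used_target:
            continue
        used_ref.add(id(tr))
        used_target.add(id(tt))
        shared.append((tr, tt))
    turnover_ref = [tc for tc in view.ref.tag_clusters if id(tc) not in used_ref]
    turnover_target = [tc for tc in view.target.tag_clusters if id(tc) not in used_target]
    return shared, turnover_ref, turnover_target


def exon_conservation(
    transcript: Transcript, anchors: Sequence[Anchor], side: str = "ref"
) -> list[tuple[int, float]]:
    """Fraction of each exon covered by >=1 anchor interval, in [0, 1].

    Monotone non-decreasing as anchors are added; 0.0 everywhere when no
    anchors exist.
    """
    ivs = sorted(
        (a.ref_interval if side == "ref" else a.target_interval)
        for a in anchors
        if (a.ref_interval if side == "ref" else a.target_interval).seq_id
        == transcript.seq_id
    )
    merged: list[list[int]] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    out = []
    for i, exon in enumerate(transcript.exons):
        covered = 0
        for s, e in merged:
            covered += max(0, min(e, exon.end) - max(s, exon.start))
        out.append((i, covered / exon.width if exon.width else 0.0))
    return out


def build_gene_structure_view(
    gene_ref: Gene,
    gene_target: Gene,
    *,
    tcs_ref: Sequence[TagCluster] = (),
    tcs_target: Sequence[TagCluster] = (),
    genes_ref: Iterable[Gene] | None = None,
    genes_target: Iterable[Gene] | None = None,
    chains: Iterable[Chain] | ChainIndex = (),
    self_alignment: bool = False,
    bridge: tuple | None = None,
    params: Parameters | None = None,
    assembly_ref: str = "ref",
    assembly_target: str = "target",
    lengths_ref: Mapping[str, int] | None = None,
    lengths_target: Mapping[str, int] | None = None,
) -> ComparisonView:
    """Gene-structure view: transcript spans plus flanks, with per-exon
    anchor-coverage annotations on both sides."""
    params = params or Parameters()
    region_ref = gene_structure_span(gene_ref, params.transcript_flank, lengths_ref)
    region_target = gene_structure_span(gene_target, params.transcript_flank, lengths_target)
    anchors = _compute_anchors(region_ref, region_target, chains, self_alignment, bridge, params)
    view = ComparisonView(
        mode="gene_structure",
        ref=_track_set(gene_ref, region_ref, genes_ref, tcs_ref, assembly_ref),
        target=_track_set(gene_target, region_target, genes_target, tcs_target, assembly_target),
        anchors=anchors,
    )
    view.annotations = {
        "exon_conservation_ref": {
            t.transcript_id: [
                {"exon_index": i, "covered_fraction": f}
                for i, f in exon_conservation(t, anchors, side="ref")
            ]
            for t in gene_ref.transcripts
        },
        "exon_conservation_target": {
            t.transcript_id: [
                {"exon_index": i, "covered_fraction": f}
                for i, f in exon_conservation(t, anchors, side="target")
            ]
            for t in gene_target.transcripts
        },
    }
    return view


def build_neighborhood_view(
    gene_ref: Gene,
    gene_target: Gene,
    *,
    genes_ref: Iterable[Gene],
    genes_target: Iterable[Gene],
    homology_pairs: Sequence = (),
    tcs_ref: Sequence[TagCluster] = (),
    tcs_target: Sequence[TagCluster] = (),
    params: Parameters | None = None,
    assembly_ref: str = "ref",
    assembly_target: str = "target",
    lengths_ref: Mapping[str, int] | None = None,
    lengths_target: Mapping[str, int] | None = None,
) -> ComparisonView:
    """Neighborhood view: wide windows around each gene with gene-level
    homology links between neighbors.

    Links are annotated per-pair with strand agreement; a global
    conserved-order flag reports whether linked neighbors appear in the same
    (or fully mirrored) order on both sides.
    """
    params = params or Parameters()
    region_ref = neighborhood(gene_ref, params.neighborhood_half_width, lengths_ref)
    region_target = neighborhood(gene_target, params.neighborhood_half_width, lengths_target)
    ref_ts = _track_set(gene_ref, region_ref, genes_ref, tcs_ref, assembly_ref)
    target_ts = _track_set(gene_target, region_target, genes_target, tcs_target, assembly_target)

    related: dict[frozenset, str] = {}
    for p in homology_pairs:
        related[frozenset((p.gene_a, p.gene_b))] = p.relation

    links = []
    for g1 in ref_ts.genes:
        for g2 in target_ts.genes:
            key = frozenset((g1.gene_id, g2.gene_id))
            is_query = g1.gene_id == gene_ref.gene_id and g2.gene_id == gene_target.gene_id
            if key in related or is_query:
                links.append(
                    {
                        "ref_gene": g1.gene_id,
                        "target_gene": g2.gene_id,
                        "relation": related.get(key, "query"),
                        "strand_match": g1.strand == g2.strand,
                        "_ref_start": g1.span.start,
                        "_target_start": g2.span.start,
                    }
                )
    links.sort(key=lambda l: (l["_ref_start"], l["_target_start"]))
    target_order = [l["_target_start"] for l in links]
    increasing = all(a < b for a, b in zip(target_order, target_order[1:]))
    decreasing = all(a > b for a, b in zip(target_order, target_order[1:]))
    conserved_order = len(links) > 0 and (increasing or decreasing)
    for l in links:
        del l["_ref_start"], l["_target_start"]

    view = ComparisonView(
        mode="neighborhood",
        ref=ref_ts,
        target=target_ts,
        anchors=[],
        annotations={"homology_links": links, "conserved_order": conserved_order},
    )
    return view


# ---------------------------------------------------------------------------
# serialization


def _iv_to_dict(iv: GenomicInterval) -> dict:
    return {"seq_id": iv.seq_id, "start": iv.start, "end": iv.end, "strand": iv.strand}


def _iv_from_dict(d: dict) -> GenomicInterval:
    return GenomicInterval(d["seq_id"], d["start"], d["end"], d["strand"])


def _gene_to_dict(g: Gene) -> dict:
    return {
        "gene_id": g.gene_id,
        "name": g.name,
        "synonyms": list(g.synonyms),
        "transcripts": [
            {
                "transcript_id": t.transcript_id,
                "strand": t.strand,
                "exons": [[e.seq_id, e.start, e.end] for e in t.exons],
            }
            for t in g.transcripts
        ],
    }


def _gene_from_dict(d: dict) -> Gene:
    txs = []
    for td in d["transcripts"]:
        exons = tuple(
            GenomicInterval(seq, s, e, td["strand"]) for seq, s, e in td["exons"]
        )
        txs.append(Transcript(td["transcript_id"], d["gene_id"], exons, td["strand"]))
    return Gene(d["gene_id"], tuple(txs), name=d["name"], synonyms=tuple(d["synonyms"]))


def _tc_to_dict(tc: TagCluster) -> dict:
    return {
        "interval": _iv_to_dict(tc.interval),
        "strand": tc.strand,
        "total_count": tc.total_count,
        "tpm": tc.tpm,
        "representative_position": tc.representative_position,
        "shape": tc.shape,
    }


def _tc_from_dict(d: dict) -> TagCluster:
    return TagCluster(
        interval=_iv_from_dict(d["interval"]),
        strand=d["strand"],
        member_tags=(),
        total_count=d["total_count"],
        tpm=d["tpm"],
        representative_position=d["representative_position"],
        shape=d["shape"],
    )


def _track_to_dict(ts: LocusTrackSet) -> dict:
    return {
        "assembly": ts.assembly,
        "region": _iv_to_dict(ts.region),
        "genes": [_gene_to_dict(g) for g in ts.genes],
        "tag_clusters": [_tc_to_dict(tc) for tc in ts.tag_clusters],
    }


def _track_from_dict(d: dict) -> LocusTrackSet:
    return LocusTrackSet(
        region=_iv_from_dict(d["region"]),
        genes=[_gene_from_dict(g) for g in d["genes"]],
        tag_clusters=[_tc_from_dict(tc) for tc in d["tag_clusters"]],
        assembly=d["assembly"],
    )


def _anchor_to_dict(a: Anchor) -> dict:
    return {
        "ref_interval": _iv_to_dict(a.ref_interval),
        "target_interval": _iv_to_dict(a.target_interval),
        "multiplicity": a.multiplicity,
        "chain_id": a.chain_id,
        "score": a.score,
        "orientation": a.orientation,
        "color": a.color,
    }


def _anchor_from_dict(d: dict) -> Anchor:
    return Anchor(
        ref_interval=_iv_from_dict(d["ref_interval"]),
        target_interval=_iv_from_dict(d["target_interval"]),
        multiplicity=d["multiplicity"],
        chain_id=d["chain_id"],
        score=d["score"],
        orientation=d["orientation"],
        color=d["color"],
    )


def view_to_dict(view: ComparisonView) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "mode": view.mode,
        "ref": _track_to_dict(view.ref),
        "target": _track_to_dict(view.target),
        "anchors": [_anchor_to_dict(a) for a in view.anchors],
        "annotations": view.annotations,
    }


def view_from_dict(d: dict) -> ComparisonView:
    return ComparisonView(
        mode=d["mode"],
        ref=_track_from_dict(d["ref"]),
        target=_track_from_dict(d["target"]),
        anchors=[_anchor_from_dict(a) for a in d["anchors"]],
        annotations=d["annotations"],
    )


def view_from_json(text: str) -> ComparisonView:
    return view_from_dict(json.loads(text))


def serialize_view(view: ComparisonView, format: str = "json") -> str:
    """Serialize a view to the stable JSON schema or a two-panel SVG."""
    if format == "json":
        return json.dumps(view_to_dict(view), indent=2, sort_keys=True)
    if format == "svg":
        return _render_svg(view)
    raise ValueError(f"unknown serialization format {format!r}")


# ---------------------------------------------------------------------------
# SVG (presentation only)

_PANEL_W = 1000
_PANEL_H = 130
_MARGIN = 20


def _render_svg(view: ComparisonView) -> str:
    height = 2 * _PANEL_H + 3 * _MARGIN

    def scale(ts: LocusTrackSet):
        w = max(1, ts.region.width)
        return lambda pos: _MARGIN + (_PANEL_W - 2 * _MARGIN) * (pos - ts.region.start) / w

    x_ref = scale(view.ref)
    x_target = scale(view.target)
    y_ref = _MARGIN
    y_target = _MARGIN * 2 + _PANEL_H

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_PANEL_W}" height="{height}" '
        f'viewBox="0 0 {_PANEL_W} {height}">',
        f'<title>{view.mode} view</title>',
    ]

    # anchor ribbons between panels, colored by multiplicity
    for a in view.anchors:
        x1a, x1b = x_ref(a.ref_interval.start), x_ref(a.ref_interval.end)
        x2a, x2b = x_target(a.target_interval.start), x_target(a.target_interval.end)
        if a.orientation == "opposite":
            x2a, x2b = x2b, x2a
        parts.append(
            f'<polygon points="{x1a:.1f},{y_ref + 90} {x1b:.1f},{y_ref + 90} '
            f'{x2b:.1f},{y_target + 40} {x2a:.1f},{y_target + 40}" '
            f'fill="{a.color}" fill-opacity="0.4" stroke="none"/>'
        )

    for ts, x, y in ((view.ref, x_ref, y_ref), (view.target, x_target, y_target)):
        parts.append(
            f'<line x1="{_MARGIN}" y1="{y + 70}" x2="{_PANEL_W - _MARGIN}" y2="{y + 70}" '
            f'stroke="black" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{_MARGIN}" y="{y + 12}" font-size="11">{ts.assembly} '
            f'{ts.region.seq_id}:{ts.region.start}-{ts.region.end}</text>'
        )
        for g in ts.genes:
            for t in g.transcripts:
                for e in t.exons:
                    xs = x(max(e.start, ts.region.start))
                    xe = x(min(e.end, ts.region.end))
                    parts.append(
                        f'<rect x="{xs:.1f}" y="{y + 62}" width="{max(1.0, xe - xs):.1f}" '
                        f'height="16" fill="darkgreen"/>'
                    )
        max_tpm = max((tc.tpm for tc in ts.tag_clusters), default=0.0)
        for tc in ts.tag_clusters:
            xp = x(tc.representative_position)
            h = 6 + (40 * tc.tpm / max_tpm if max_tpm > 0 else 0)
            parts.append(
                f'<line x1="{xp:.1f}" y1="{y + 58}" x2="{xp:.1f}" y2="{y + 58 - h:.1f}" '
                f'stroke="crimson" stroke-width="2"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts)
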