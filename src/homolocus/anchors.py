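"""Anchors: classified alignment links between a reference region and
homologous target loci.

Every gap-free chain block overlapping a region of interest is an anchor
candidate. A reference base covered by blocks of exactly one chain yields
1-to-1 anchors; where blocks of two or more distinct chains overlap on the
reference, the overlapping sub-intervals become 1-to-2 anchors from each
chain. When more than ``max_loci`` (default 2) chains compete within a
cluster of mutually overlapping reference blocks, only the highest-scoring
chains are kept — each chain being treated as one candidate homologous
locus. By display convention 1-to-1 anchors are gray and 1-to-2 blue.

Two special constructions:

* ``self_anchors`` uses a self-alignment of one assembly against itself to
  link paralogous loci, after discarding the trivial identity chains.
* ``bridge_anchors`` composes A:B with A:C alignments through the shared
  assembly A, aligning B with C when no direct B:C alignment exists (e.g.
  duplicate loci in a genome with no self-chain, bridged through an
  outgroup genome). The construction cannot see homology private to B and C
  that is absent from A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import GenomicInterval
from .chains import (
    AlignedBlock,
    Chain,
    ChainIndex,
    blocks_of,
    map_interval,
    project_through_block,
)

logger = logging.getLogger(__name__)

DEFAULT_COLORS = {"one_to_one": "gray", "one_to_two": "blue"}


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class Anchor:
    ref_interval: GenomicInterval
    target_interval: GenomicInterval
    multiplicity: str  # "one_to_one" | "one_to_two"
    chain_id: str
    score: float
    orientation: str  # "same" | "opposite"
    color: str

    def __post_init__(self) -> None:
        if self.ref_interval.width != self.target_interval.width:
            raise AnchorError("anchor sides differ in width")
        if self.ref_interval.width == 0:
            raise AnchorError("empty anchor")


@dataclass(frozen=True)
class _Seg:
    """A trimmed, oriented ref<->target alignment piece awaiting classification."""

    ref: GenomicInterval
    target: GenomicInterval
    orientation: str
    chain_id: str
    locus_key: str  # identity of the candidate homologous locus
    score: float


def _project_piece(seg: _Seg, start: int, end: int) -> GenomicInterval:
    w = end - start
    if seg.orientation == "same":
        t_start = seg.target.start + (start - seg.ref.start)
    else:
        t_start = seg.target.end - (end - seg.ref.start)
    return GenomicInterval(seg.target.seq_id, t_start, t_start + w)


def _components(segs: list[_Seg]) -> list[list[_Seg]]:
    """Connected components of ref-overlapping segments (per sequence)."""
    segs = sorted(segs, key=lambda s: (s.ref.seq_id, s.ref.start, s.ref.end))
    comps: list[list[_Seg]] = []
    cur: list[_Seg] = []
    cur_seq, cur_end = None, -1
    for s in segs:
        if cur and s.ref.seq_id == cur_seq and s.ref.start < cur_end:
            cur.append(s)
            cur_end = max(cur_end, s.ref.end)
        else:
            if cur:
                comps.append(cur)
            cur = [s]
            cur_seq, cur_end = s.ref.seq_id, s.ref.end
    if cur:
        comps.append(cur)
    return comps


def _emit_anchors(
    segs: list[_Seg],
    max_loci: int,
    colors: dict[str, str] | None,
    min_width: int,
) -> list[Anchor]:
    colors = {**DEFAULT_COLORS, **(colors or {})}
    anchors: list[Anchor] = []
    dropped = 0
    for comp in _components(segs):
        # rank candidate loci: score desc, aligned span desc, key asc
        stats: dict[str, list[float]] = {}
        for s in comp:
            st = stats.setdefault(s.locus_key, [0.0, 0])
            st[0] = max(st[0], s.score)
            st[1] += s.ref.width
        ranked = sorted(stats, key=lambda k: (-stats[k][0], -stats[k][1], k))
        keep = set(ranked[:max_loci])
        kept = [s for s in comp if s.locus_key in keep]
        bounds = sorted({s.ref.start for s in kept} | {s.ref.end for s in kept})
        atoms = list(zip(bounds, bounds[1:]))
        cover = {
            (a, b): len(
                {s.locus_key for s in kept if s.ref.start <= a and s.ref.end >= b}
            )
            for a, b in atoms
        }
        for s in kept:
            pieces: list[tuple[int, int, str]] = []
            for a, b in atoms:
                if a >= s.ref.start and b <= s.ref.end and cover[(a, b)] > 0:
                    mult = "one_to_one" if cover[(a, b)] == 1 else "one_to_two"
                    if pieces and pieces[-1][1] == a and pieces[-1][2] == mult:
                        pieces[-1] = (pieces[-1][0], b, mult)
                    else:
                        pieces.append((a, b, mult))
            for a, b, mult in pieces:
                if b - a < min_width:
                    dropped += 1
                    continue
                anchors.append(
                    Anchor(
                        ref_interval=GenomicInterval(s.ref.seq_id, a, b),
                        target_interval=_project_piece(s, a, b),
                        multiplicity=mult,
                        chain_id=s.chain_id,
                        score=s.score,
                        orientation=s.orientation,
                        color=colors[mult],
                    )
                )
    if dropped:
        logger.info("discarded %d anchor piece(s) below min width %d", dropped, min_width)
    return sorted(
        anchors, key=lambda a: (a.ref_interval.start, a.ref_interval.end, a.chain_id)
    )


def _trim_block(b: AlignedBlock, region: GenomicInterval) -> _Seg | None:
    sub = b.t_interval.intersection(region)
    if sub is None or sub.width == 0:
        return None
    target = project_through_block(b, sub, source="t")
    return _Seg(sub, target, b.orientation, b.chain_id, b.chain_id, b.score)


def anchors_for_region(
    region: GenomicInterval,
    chains: Iterable[Chain] | ChainIndex,
    max_loci: int = 2,
    colors: dict[str, str] | None = None,
    min_width: int = 1,
) -> list[Anchor]:
    """Classified anchors for all chain blocks overlapping a reference region.

    Blocks are trimmed to the region; competition between more than
    ``max_loci`` chains is resolved per cluster of mutually overlapping
    reference blocks (score desc, aligned span desc, chain id asc). The
    output is invariant to chain input order, and no reference base carries
    more than ``max_loci`` distinct chain ids.
    """
    if max_loci < 1:
        raise AnchorError("max_loci must be >= 1")
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    segs = []
    for b in index.blocks_overlapping(region, side="t"):
        seg = _trim_block(b, region)
        if seg is not None:
            segs.append(seg)
    return _emit_anchors(segs, max_loci, colors, min_width)


def is_trivial_self_chain(c: Chain) -> bool:
    """An identity self-alignment: same sequence, same span, same orientation."""
    return (
        c.t_name == c.q_name
        and c.q_strand == "+"
        and c.t_start == c.q_start
        and c.t_end == c.q_end
    )


def self_anchors(
    region: GenomicInterval,
    self_chains: Iterable[Chain],
    max_loci: int = 2,
    colors: dict[str, str] | None = None,
    min_width: int = 1,
) -> list[Anchor]:
    """Anchors between paralogous loci from a self-alignment of one assembly,
    with trivial identity chains discarded."""
    kept = [c for c in self_chains if not is_trivial_self_chain(c)]
    return anchors_for_region(region, kept, max_loci=max_loci, colors=colors, min_width=min_width)


def bridge_anchors(
    chains_a_to_b: Iterable[Chain] | ChainIndex,
    chains_a_to_c: Iterable[Chain] | ChainIndex,
    region_in_b: GenomicInterval,
    max_loci: int = 2,
    min_width: int = 10,
    colors: dict[str, str] | None = None,
) -> list[Anchor]:
    """Compose two chain sets sharing assembly A on their target side into
    B<->C anchors for a region in B.

    The region is mapped back to A, intersected in A coordinates with the
    aligned footprint of the second set, and each intersection is projected
    into B and C. Composed orientation is the product of the two
    orientations; the score is the min of the two chain scores. Pieces
    narrower than ``min_width`` (default 10 bp) are discarded to avoid
    composition confetti.
    """
    idx_ab = chains_a_to_b if isinstance(chains_a_to_b, ChainIndex) else ChainIndex(chains_a_to_b)
    idx_ac = chains_a_to_c if isinstance(chains_a_to_c, ChainIndex) else ChainIndex(chains_a_to_c)

    # consistency: shared A-side sequences must agree on declared lengths
    sizes_ab = {c.t_name: c.t_size for c in idx_ab.chains}
    for c in idx_ac.chains:
        if c.t_name in sizes_ab and sizes_ab[c.t_name] != c.t_size:
            raise AnchorError(
                f"bridge chain sets disagree on size of shared sequence {c.t_name}: "
                f"{sizes_ab[c.t_name]} vs {c.t_size}"
            )

    segs: list[_Seg] = []
    for m1 in map_interval(idx_ab, region_in_b, "q2t"):
        # m1.source in B, m1.mapped in A
        for m2 in map_interval(idx_ac, m1.mapped, "t2q"):
            # m2.source in A (inside m1.mapped), m2.mapped in C
            w = m2.source.width
            if m1.orientation == "same":
                b_start = m1.source.start + (m2.source.start - m1.mapped.start)
            else:
                b_start = m1.source.start + (m1.mapped.end - m2.source.end)
            b_iv = GenomicInterval(region_in_b.seq_id, b_start, b_start + w)
            orientation = "same" if m1.orientation == m2.orientation else "opposite"
            segs.append(
                _Seg(
                    ref=b_iv,
                    target=m2.mapped,
                    orientation=orientation,
                    chain_id=f"{m1.chain_id}|{m2.chain_id}",
                    locus_key=m2.chain_id,
                    score=min(m1.score, m2.score),
                )
            )
    return _emit_anchors(segs, max_loci, colors, min_width)
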