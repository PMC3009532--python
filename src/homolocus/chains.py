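"""UCSC chain alignments: parsing, block decomposition, interval mapping.

A chain is a colinear list of gap-free aligned blocks between a *target*
assembly (always given on the plus strand) and a *query* assembly (possibly
on the minus strand). Every emitted coordinate here is normalized to the
plus strand; inversion is carried as an ``orientation`` flag, so the mirror
arithmetic is testable with plain offsets.

Chain text format, per header::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
    size dt dq
    ...
    size

where ``dt``/``dq`` are the unaligned gaps after each block on the target and
query side. Block arithmetic is validated on load and a malformed chain
aborts the file (fail-fast), naming the chain id.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .annotation import GenomicInterval

logger = logging.getLogger(__name__)


class ChainError(ValueError):
    """Malformed chain input."""


@dataclass(frozen=True)
class Chain:
    chain_id: str
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[tuple[int, int, int], ...]  # (size, dt, dq); last has dt=dq=0

    def validate(self) -> None:
        if self.q_strand not in ("+", "-"):
            raise ChainError(f"chain {self.chain_id}: q_strand must be + or -")
        if not self.blocks:
            raise ChainError(f"chain {self.chain_id}: no alignment blocks")
        t_sum = sum(size + dt for size, dt, _ in self.blocks)
        q_sum = sum(size + dq for size, _, dq in self.blocks)
        for size, dt, dq in self.blocks:
            if size <= 0:
                raise ChainError(f"chain {self.chain_id}: block size must be > 0")
            if dt < 0 or dq < 0:
                raise ChainError(f"chain {self.chain_id}: negative gap")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ChainError(f"chain {self.chain_id}: last block must close the chain")
        if t_sum != self.t_end - self.t_start:
            raise ChainError(
                f"chain {self.chain_id}: target blocks sum to {t_sum}, header span "
                f"{self.t_end - self.t_start}"
            )
        if q_sum != self.q_end - self.q_start:
            raise ChainError(
                f"chain {self.chain_id}: query blocks sum to {q_sum}, header span "
                f"{self.q_end - self.q_start}"
            )
        if not (0 <= self.t_start <= self.t_end <= self.t_size):
            raise ChainError(f"chain {self.chain_id}: target span outside sequence")
        if not (0 <= self.q_start <= self.q_end <= self.q_size):
            raise ChainError(f"chain {self.chain_id}: query span outside sequence")


@dataclass(frozen=True)
class AlignedBlock:
    """One gap-free block, both sides on the plus strand."""

    t_interval: GenomicInterval
    q_interval: GenomicInterval
    orientation: str  # "same" | "opposite"
    chain_id: str
    score: float

    def __post_init__(self) -> None:
        if self.t_interval.width != self.q_interval.width:
            raise ChainError("aligned block sides differ in width")


@dataclass(frozen=True)
class MappedSegment:
    """Result of mapping an interval through one block."""

    source: GenomicInterval
    mapped: GenomicInterval
    chain_id: str
    orientation: str
    score: float


def read_chains(path: str | Path) -> list[Chain]:
    """Parse a UCSC chain file (plain or gzip), validating block arithmetic."""
    opener = gzip.open if str(path).endswith(".gz") else open
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def finalize() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ChainError(f"{path}: chain {header[-1]} has no block lines")
        c = Chain(
            chain_id=header[12] if len(header) > 12 else "",
            score=float(header[1]),
            t_name=header[2],
            t_size=int(header[3]),
            t_start=int(header[5]),
            t_end=int(header[6]),
            q_name=header[7],
            q_size=int(header[8]),
            q_strand=header[9],
            q_start=int(header[10]),
            q_end=int(header[11]),
            blocks=tuple(blocks),
        )
        if header[4] != "+":
            raise ChainError(f"chain {c.chain_id}: target strand must be +")
        c.validate()
        chains.append(c)
        header, blocks = None, []

    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if not stripped:
                finalize()
                continue
            fields = stripped.split()
            if fields[0] == "chain":
                finalize()
                if len(fields) < 12:
                    raise ChainError(f"{path}: line {lineno}: short chain header")
                header = fields
            else:
                if header is None:
                    raise ChainError(f"{path}: line {lineno}: block line outside a chain")
                try:
                    nums = [int(x) for x in fields]
                except ValueError as exc:
                    raise ChainError(f"{path}: line {lineno}: non-integer block line") from exc
                if len(nums) == 3:
                    blocks.append((nums[0], nums[1], nums[2]))
                elif len(nums) == 1:
                    blocks.append((nums[0], 0, 0))
                else:
                    raise ChainError(f"{path}: line {lineno}: block line needs 1 or 3 numbers")
    finalize()
    return chains


def write_chains(chains: Iterable[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


def blocks_of(c: Chain) -> list[AlignedBlock]:
    """Cursor walk of a chain into plus-strand blocks, sorted by t_start.

    On a minus-strand query, a block ``[s, e)`` in minus coordinates converts
    to plus strand as ``[q_size - e, q_size - s)`` with opposite orientation.
    """
    out: list[AlignedBlock] = []
    t, q = c.t_start, c.q_start
    for size, dt, dq in c.blocks:
        t_iv = GenomicInterval(c.t_name, t, t + size)
        if c.q_strand == "+":
            q_iv = GenomicInterval(c.q_name, q, q + size)
            orientation = "same"
        else:
            q_iv = GenomicInterval(c.q_name, c.q_size - (q + size), c.q_size - q)
            orientation = "opposite"
        out.append(AlignedBlock(t_iv, q_iv, orientation, c.chain_id, c.score))
        t += size + dt
        q += size + dq
    return out


def project_through_block(
    block: AlignedBlock, sub: GenomicInterval, source: str = "t"
) -> GenomicInterval:
    """Offset-map a sub-interval of one side of a block onto the other side.

    Mirror-offset when orientation is opposite (anti-monotone per base).
    """
    src = block.t_interval if source == "t" else block.q_interval
    dst = block.q_interval if source == "t" else block.t_interval
    if not (src.start <= sub.start and sub.end <= src.end):
        raise ValueError("sub-interval not contained in block side")
    w = sub.width
    if block.orientation == "same":
        start = dst.start + (sub.start - src.start)
    else:
        start = dst.end - (sub.end - src.start)
    return GenomicInterval(dst.seq_id, start, start + w)


class ChainIndex:
    """Interval-tree index over the blocks of many chains, both sides."""

    def __init__(self, chains: Iterable[Chain]):
        self.chains = list(chains)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for c in self.chains:
            for b in blocks_of(c):
                for side, iv in (("t", b.t_interval), ("q", b.q_interval)):
                    if iv.width == 0:
                        continue
                    tree = self._trees.setdefault((side, iv.seq_id), IntervalTree())
                    tree.addi(iv.start, iv.end, b)

    def blocks_overlapping(self, iv: GenomicInterval, side: str = "t") -> list[AlignedBlock]:
        tree = self._trees.get((side, iv.seq_id))
        if tree is None or iv.width == 0:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        key_iv = (lambda b: b.t_interval) if side == "t" else (lambda b: b.q_interval)
        return sorted(hits, key=lambda b: (key_iv(b).start, b.chain_id))


def map_interval(
    chains: Iterable[Chain] | ChainIndex,
    iv: GenomicInterval,
    direction: str = "t2q",
) -> list[MappedSegment]:
    """Piecewise liftover of an interval through every overlapping block.

    Returns one segment per (block x overlap): the overlapping sub-interval
    on the source side and its width-equal image on the other side, sorted by
    sub-interval start. An interval falling entirely in chain gaps maps to
    nothing.
    """
    if direction not in ("t2q", "q2t"):
        raise ValueError(f"direction must be 't2q' or 'q2t', got {direction!r}")
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    side = "t" if direction == "t2q" else "q"
    out: list[MappedSegment] = []
    for b in index.blocks_overlapping(iv, side):
        src = b.t_interval if side == "t" else b.q_interval
        sub = src.intersection(GenomicInterval(iv.seq_id, iv.start, iv.end))
        if sub is None or sub.width == 0:
            continue
        mapped = project_through_block(b, sub, source=side)
        out.append(MappedSegment(sub, mapped, b.chain_id, b.orientation, b.score))
    return sorted(out, key=lambda m: (m.source.start, m.chain_id, m.mapped.start))


def invert(c: Chain) -> Chain:
    """Swap target and query sides (the chainSwap transform).

    For a plus-strand query this swaps the two sides and the gap columns.
    For a minus-strand query the block order reverses and both spans are
    re-expressed on the opposite strand of their own sequence, preserving
    the per-base correspondence (verified against q->t mapping in tests).
    """
    if c.q_strand == "+":
        blocks = tuple((size, dq, dt) for size, dt, dq in c.blocks)
        inv = Chain(
            chain_id=c.chain_id,
            score=c.score,
            t_name=c.q_name,
            t_size=c.q_size,
            t_start=c.q_start,
            t_end=c.q_end,
            q_name=c.t_name,
            q_size=c.t_size,
            q_strand="+",
            q_start=c.t_start,
            q_end=c.t_end,
            blocks=blocks,
        )
    else:
        sizes = [b[0] for b in c.blocks]
        gaps = [(b[1], b[2]) for b in c.blocks[:-1]]
        rev_sizes = sizes[::-1]
        rev_gaps = gaps[::-1]
        new_blocks = []
        for i, size in enumerate(rev_sizes):
            if i < len(rev_gaps):
                dt_old, dq_old = rev_gaps[i]
                new_blocks.append((size, dq_old, dt_old))
            else:
                new_blocks.append((size, 0, 0))
        inv = Chain(
            chain_id=c.chain_id,
            score=c.score,
            t_name=c.q_name,
            t_size=c.q_size,
            t_start=c.q_size - c.q_end,
            t_end=c.q_size - c.q_start,
            q_name=c.t_name,
            q_size=c.t_size,
            q_strand="-",
            q_start=c.t_size - c.t_end,
            q_end=c.t_size - c.t_start,
            blocks=tuple(new_blocks),
        )
    inv.validate()
    return inv
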