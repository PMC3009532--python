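"""CAGE tag clustering and promoter-level summaries.

CAGE (cap analysis of gene expression) sequences capped 5' ends, giving
single-base evidence of transcription starts with tag counts. Tags mapping to
the same chromosome strand and overlapping by at least 1 bp are merged into
tag clusters (TCs) by single linkage. Each TC carries:

* a representative position — the 5' end supported by the most tags;
* an expression level in tags per million (tpm), count x 1e6 / library size;
* a shape class, sharp or broad, from the count-weighted interquantile width
  of the 5'-end distribution (defaults: 0.10-0.90 quantiles, sharp <= 4 bp).

TCs are assigned to genes when their representative position falls in a
closed window (default [-500, +500]) around a transcript's TSS on the same
strand; the highest-tpm TC becomes the representative TC for the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import Gene, GenomicInterval, Parameters, Transcript, tss_of

logger = logging.getLogger(__name__)


class CageError(ValueError):
    """Malformed CAGE input."""


@dataclass(frozen=True)
class CageTag:
    """A (collapsed) mapped CAGE tag with a strand-aware 5' end."""

    interval: GenomicInterval
    five_prime: int
    count: int

    def __post_init__(self) -> None:
        if not self.interval.contains(self.five_prime):
            raise CageError(
                f"five_prime {self.five_prime} outside tag interval "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.count < 1:
            raise CageError(f"tag count must be >= 1, got {self.count}")


@dataclass
class TagCluster:
    """A strand-specific single-linkage cluster of CAGE tags."""

    interval: GenomicInterval
    strand: str
    member_tags: tuple[CageTag, ...]
    total_count: int
    tpm: float
    representative_position: int
    shape: str

    @property
    def seq_id(self) -> str:
        return self.interval.seq_id


@dataclass
class CageLibrary:
    tags: list[CageTag]
    library_size: int

    def __post_init__(self) -> None:
        total = sum(t.count for t in self.tags)
        if self.library_size < total:
            raise CageError(
                f"library_size {self.library_size} smaller than retained tag total {total}"
            )


# ---------------------------------------------------------------------------
# input


def read_cage(
    path: str | Path, format: str = "ctss", library_size: int | None = None
) -> CageLibrary:
    """Read CAGE tags from CTSS text or BED6 (score column = tag count).

    CTSS columns are whitespace separated: sequence, 1-based position, strand,
    count; tags are 1 bp wide. The library size defaults to the sum of counts
    unless an externally known mapped-tag total is supplied.
    """
    tags: list[CageTag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split()
            try:
                if format == "ctss":
                    if len(fields) < 4:
                        raise CageError("expected 4 columns (seq, pos, strand, count)")
                    seq, pos1, strand, count = fields[0], int(fields[1]), fields[2], int(fields[3])
                    start = pos1 - 1
                    iv = GenomicInterval(seq, start, start + 1, strand)
                    five = start
                elif format == "bed6":
                    if len(fields) < 6:
                        raise CageError("expected 6 BED columns")
                    seq, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
                    count = int(fields[4])
                    iv = GenomicInterval(seq, start, end, strand)
                    five = start if strand == "+" else end - 1
                else:
                    raise ValueError(f"unknown CAGE format {format!r}")
                if strand not in ("+", "-"):
                    raise CageError(f"unknown strand symbol {strand!r}")
                if count <= 0:
                    raise CageError(f"non-positive tag count {count}")
            except (ValueError, CageError) as exc:
                raise CageError(f"{path}: line {lineno}: {exc}") from exc
            tags.append(CageTag(iv, five, count))
    total = sum(t.count for t in tags)
    return CageLibrary(tags, library_size if library_size is not None else total)


def write_tc_bed(tcs: Iterable[TagCluster], path: str | Path) -> None:
    """BED6+3 track: chrom, start, end, name, count, strand, tpm,
    representative_position, shape."""
    with open(path, "w") as fh:
        for i, tc in enumerate(tcs):
            fh.write(
                f"{tc.seq_id}\t{tc.interval.start}\t{tc.interval.end}\tTC{i}\t"
                f"{tc.total_count}\t{tc.strand}\t{tc.tpm:.6g}\t"
                f"{tc.representative_position}\t{tc.shape}\n"
            )


# ---------------------------------------------------------------------------
# clustering and summaries


def _rep_position(tags: Sequence[CageTag], strand: str) -> int:
    counts: dict[int, int] = {}
    for t in tags:
        counts[t.five_prime] = counts.get(t.five_prime, 0) + t.count
    best = max(counts.values())
    tied = [p for p, c in counts.items() if c == best]
    # tie -> 5'-most relative to strand
    return min(tied) if strand == "+" else max(tied)


def representative_position(tc: TagCluster) -> int:
    """The 5' end with the highest summed tag count (ties: 5'-most)."""
    return _rep_position(tc.member_tags, tc.strand)


def compute_tpm(tc: TagCluster, library_size: int) -> float:
    """Tags per million: total_count x 1e6 / library_size."""
    if library_size <= 0:
        raise CageError("library_size must be positive for tpm")
    return tc.total_count * 1e6 / library_size


def _shape_width(
    tags: Sequence[CageTag], quantiles: tuple[float, float]
) -> int:
    counts: dict[int, int] = {}
    for t in tags:
        counts[t.five_prime] = counts.get(t.five_prime, 0) + t.count
    positions = np.array(sorted(counts), dtype=np.int64)
    weights = np.array([counts[p] for p in positions], dtype=np.int64)
    cum = np.cumsum(weights)
    total = int(cum[-1])

    def pos_at(q: float) -> int:
        idx = int(np.searchsorted(cum, q * total, side="left"))
        return int(positions[min(idx, len(positions) - 1)])

    lo, hi = quantiles
    return pos_at(hi) - pos_at(lo)


def classify_shape(
    tc: TagCluster,
    quantiles: tuple[float, float] = (0.10, 0.90),
    sharp_width_max: int = 4,
) -> str:
    """Sharp iff the count-weighted interquantile width of 5' ends is small.

    Invariant under uniform coordinate translation by construction.
    """
    width = _shape_width(tc.member_tags, quantiles)
    return "sharp" if width <= sharp_width_max else "broad"


def cluster_tags(
    lib: CageLibrary,
    params: Parameters | None = None,
    library_size: int | None = None,
) -> list[TagCluster]:
    """Single-linkage clustering of tags per (sequence, strand).

    Two tags belong to one cluster iff they are connected by a chain of
    pairwise interval overlaps of >= 1 bp (half-open: abutting tags do not
    merge). The output is a partition of the input tags, sorted by
    (seq_id, strand, start), with clusters on one strand pairwise
    non-overlapping. Deterministic under permutation of the input.
    """
    params = params or Parameters()
    lib_size = library_size if library_size is not None else lib.library_size
    groups: dict[tuple[str, str], list[CageTag]] = {}
    for tag in lib.tags:
        groups.setdefault((tag.interval.seq_id, tag.interval.strand), []).append(tag)

    clusters: list[TagCluster] = []
    for (seq, strand) in sorted(groups):
        tags = sorted(
            groups[(seq, strand)],
            key=lambda t: (t.interval.start, t.interval.end, t.five_prime, t.count),
        )
        current: list[CageTag] = []
        cur_end = -1
        for tag in tags:
            if current and tag.interval.start < cur_end:
                current.append(tag)
                cur_end = max(cur_end, tag.interval.end)
            else:
                if current:
                    clusters.append(_make_cluster(seq, strand, current, lib_size, params))
                current = [tag]
                cur_end = tag.interval.end
        if current:
            clusters.append(_make_cluster(seq, strand, current, lib_size, params))
    return clusters


def _make_cluster(
    seq: str,
    strand: str,
    tags: list[CageTag],
    library_size: int,
    params: Parameters,
) -> TagCluster:
    total = sum(t.count for t in tags)
    interval = GenomicInterval(
        seq, min(t.interval.start for t in tags), max(t.interval.end for t in tags), strand
    )
    tc = TagCluster(
        interval=interval,
        strand=strand,
        member_tags=tuple(tags),
        total_count=total,
        tpm=0.0,
        representative_position=_rep_position(tags, strand),
        shape="sharp",
    )
    tc.shape = classify_shape(tc, params.shape_quantiles, params.sharp_width_max)
    if library_size > 0:
        tc.tpm = compute_tpm(tc, library_size)
    return tc


# ---------------------------------------------------------------------------
# gene assignment


def _tc_sort_key(tc: TagCluster) -> tuple:
    # higher tpm, then higher count, then 5'-most representative position
    five_most = tc.representative_position if tc.strand == "+" else -tc.representative_position
    return (-tc.tpm, -tc.total_count, five_most)


def assign_representative_tc(
    g: Gene,
    tcs: Sequence[TagCluster],
    window: int = 500,
) -> tuple[dict[str, TagCluster | None], TagCluster | None]:
    """Map TCs to the gene's transcripts and pick representatives.

    A TC is a candidate for a transcript iff it lies on the same sequence and
    strand and its representative position falls in the closed window
    ``[tss - window, tss + window]``. Per transcript the max-tpm TC wins;
    the gene-level representative is the best TC over all transcripts.
    Ties break by higher total count, then 5'-most representative position,
    making the result invariant to TC input order.
    """
    per_tx: dict[str, TagCluster | None] = {}
    gene_candidates: list[TagCluster] = []
    for t in g.transcripts:
        tss = tss_of(t)
        cands = [
            tc
            for tc in tcs
            if tc.seq_id == t.seq_id
            and tc.strand == t.strand
            and tss - window <= tc.representative_position <= tss + window
        ]
        if cands:
            best = min(cands, key=_tc_sort_key)
            per_tx[t.transcript_id] = best
            gene_candidates.extend(cands)
        else:
            per_tx[t.transcript_id] = None
    gene_rep = min(gene_candidates, key=_tc_sort_key) if gene_candidates else None
    return per_tx, gene_rep
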