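"""Gene models and the strand-aware regions behind the three comparison views.

All coordinates inside the package are 0-based, half-open, expressed on the
plus strand of a named sequence. GTF's 1-based inclusive convention is
converted at I/O only; BED-family inputs are already native.

The three view regions computed here mirror how comparative promoter browsers
frame a locus:

* promoter view — a fixed-width window (default 1000 bp, i.e. ±500) around
  each transcription start site, unioned over a gene's transcripts;
* gene structure view — the transcript bounding box plus a flat flank
  (default 500 bp) on both sides;
* genomic neighborhood view — a wide window (default 2 Mb) centered on the
  gene, for macro-synteny inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GeneModelError(ValueError):
    """Malformed gene-model input (bad line, bad coordinates, empty transcript)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded span ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 shared base under half-open arithmetic; strand-blind."""
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.seq_id,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    """An exon chain on one sequence and strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneModelError(f"transcript {self.transcript_id} has zero exons")
        if self.strand not in ("+", "-"):
            raise GeneModelError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        seqs = {e.seq_id for e in self.exons}
        if len(seqs) > 1:
            raise GeneModelError(
                f"transcript {self.transcript_id} spans sequences {sorted(seqs)}"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise GeneModelError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = e.end

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    transcripts: tuple[Transcript, ...]
    name: str = ""
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise GeneModelError(f"gene {self.gene_id} has no transcripts")
        seqs = {t.seq_id for t in self.transcripts}
        if len(seqs) > 1:
            raise GeneModelError(
                f"gene {self.gene_id} spans sequences {sorted(seqs)}"
            )

    @property
    def seq_id(self) -> str:
        return self.transcripts[0].seq_id

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Bounding box of all transcripts."""
        return GenomicInterval(
            self.seq_id,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )


@dataclass(frozen=True)
class Parameters:
    """Tunable distances and selection constants, in bp unless noted.

    Defaults: ±500 bp promoter flank (1000 bp promoter window), 500 bp
    transcript flank, a closed ±500 bp TSS window for assigning tag clusters
    to genes, a 1 Mb neighborhood half-width (2 Mb window), 100 bp shared-TSS
    tolerance, 0.10/0.90 shape quantiles with a 4 bp sharp-promoter maximum
    width, and at most 2 homologous loci kept per anchor cluster.
    """

    promoter_flank: int = 500
    transcript_flank: int = 500
    tc_gene_window: int = 500
    neighborhood_half_width: int = 1_000_000
    shared_tss_tolerance: int = 100
    shape_quantiles: tuple[float, float] = (0.10, 0.90)
    sharp_width_max: int = 4
    max_anchor_loci: int = 2

    def __post_init__(self) -> None:
        for name in (
            "promoter_flank",
            "transcript_flank",
            "tc_gene_window",
            "neighborhood_half_width",
            "shared_tss_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.shape_quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("shape_quantiles must satisfy 0 < lo < hi < 1")
        if self.max_anchor_loci < 1:
            raise ValueError("max_anchor_loci must be >= 1")


# ---------------------------------------------------------------------------
# sequence-length registry and clipping


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (seq_id, length), chromInfo-shaped."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GeneModelError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def clip_interval(
    iv: GenomicInterval, lengths: Mapping[str, int] | None = None
) -> GenomicInterval:
    """Clip silently at 0 and, when a registry is given, at sequence length."""
    start = max(0, iv.start)
    end = iv.end
    if lengths is not None and iv.seq_id in lengths:
        end = min(end, lengths[iv.seq_id])
    end = max(start, end)
    if (start, end) != (iv.start, iv.end):
        logger.debug("clipped %s:[%d,%d) to [%d,%d)", iv.seq_id, iv.start, iv.end, start, end)
    return GenomicInterval(iv.seq_id, start, end, iv.strand)


# ---------------------------------------------------------------------------
# readers / writer


def read_gene_models(path: str | Path, format: str = "gtf") -> list[Gene]:
    """Read gene models from GTF or BED12 into 0-based half-open Genes.

    Output is deterministically ordered by (seq_id, start, gene_id).
    Transcripts with zero exons are rejected with a logged report.
    """
    if format == "gtf":
        genes = _read_gtf(Path(path))
    elif format == "bed12":
        genes = _read_bed12(Path(path))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return sorted(genes, key=lambda g: (g.seq_id, g.span.start, g.gene_id))


def _prescan_gtf(path: Path) -> bool:
    """Validate line shape up front so parse errors can name the line. Returns
    True when the file contains at least one feature line."""
    any_feature = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GeneModelError(
                    f"{path}: line {lineno}: expected >=9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GeneModelError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GeneModelError(
                    f"{path}: line {lineno}: bad coordinate range {start}..{end}"
                )
            if fields[6] not in ("+", "-"):
                raise GeneModelError(
                    f"{path}: line {lineno}: strand must be + or -, got {fields[6]!r}"
                )
            any_feature = True
    return any_feature


def _read_gtf(path: Path) -> list[Gene]:
    if not _prescan_gtf(path):
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, strand)
    gene_names: dict[str, str] = {}
    gene_syns: dict[str, tuple[str, ...]] = {}
    declared_tx: set[str] = set()

    for f in db.all_features():
        attrs = f.attributes
        gid = attrs.get("gene_id", [None])[0]
        if gid and "gene_name" in attrs:
            gene_names.setdefault(gid, attrs["gene_name"][0])
        if gid and "gene_synonym" in attrs:
            gene_syns.setdefault(
                gid, tuple(s for v in attrs["gene_synonym"] for s in v.split(","))
            )
        if f.featuretype == "transcript":
            tid = attrs.get("transcript_id", [None])[0]
            if tid:
                declared_tx.add(tid)
                tx_meta.setdefault(tid, (gid or tid, f.strand))
        if f.featuretype != "exon":
            continue
        tid = attrs.get("transcript_id", [None])[0]
        if tid is None or gid is None:
            raise GeneModelError(
                f"{path}: exon at {f.seqid}:{f.start}-{f.end} lacks gene_id/transcript_id"
            )
        # GTF is 1-based inclusive -> 0-based half-open
        exons_by_tx.setdefault(tid, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        )
        tx_meta[tid] = (gid, f.strand)

    empty = declared_tx - set(exons_by_tx)
    if empty:
        logger.warning(
            "%s: rejected %d transcript(s) with zero exons: %s",
            path,
            len(empty),
            ", ".join(sorted(empty)),
        )

    by_gene: dict[str, list[Transcript]] = {}
    for tid, exons in exons_by_tx.items():
        gid, strand = tx_meta[tid]
        exons = sorted(exons, key=lambda e: e.start)
        by_gene.setdefault(gid, []).append(
            Transcript(tid, gid, tuple(exons), strand)
        )
    return [
        Gene(
            gid,
            tuple(sorted(txs, key=lambda t: (t.start, t.transcript_id))),
            name=gene_names.get(gid, gid),
            synonyms=gene_syns.get(gid, ()),
        )
        for gid, txs in by_gene.items()
    ]


def _read_bed12(path: Path) -> list[Gene]:
    by_gene: dict[str, list[Transcript]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 12:
                raise GeneModelError(
                    f"{path}: line {lineno}: BED12 needs 12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise GeneModelError(f"{path}: line {lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise GeneModelError(f"{path}: line {lineno}: bad strand {strand!r}")
            if not (len(sizes) == len(starts) == block_count):
                raise GeneModelError(
                    f"{path}: line {lineno}: blockCount inconsistent with block lists"
                )
            if block_count == 0:
                logger.warning("%s: line %d: rejected zero-exon record %s", path, lineno, name)
                continue
            if "|" in name:
                gid, tid = name.split("|", 1)
            else:
                gid = tid = name
            exons = tuple(
                GenomicInterval(chrom, chrom_start + bs, chrom_start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            )
            by_gene.setdefault(gid, []).append(Transcript(tid, gid, exons, strand))
            names.setdefault(gid, gid)
    return [
        Gene(gid, tuple(sorted(txs, key=lambda t: (t.start, t.transcript_id))), name=names[gid])
        for gid, txs in by_gene.items()
    ]


def write_gtf(genes: Iterable[Gene], path: str | Path, source: str = "homolocus") -> None:
    """Emit exon records (1-based inclusive), inverse of the GTF reader."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                    )
                    if g.name and g.name != g.gene_id:
                        attrs += f' gene_name "{g.name}";'
                    fh.write(
                        f"{e.seq_id}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# region operations


def tss_of(t: Transcript) -> int:
    """Strand-aware transcription start: first base of the first exon (+) or
    last base of the last exon (−), 0-based."""
    return t.start if t.strand == "+" else t.end - 1


def promoter_region(
    t: Transcript, flank: int, lengths: Mapping[str, int] | None = None
) -> GenomicInterval:
    """The ``2*flank`` window centered on the TSS, clipped at sequence bounds."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    tss = tss_of(t)
    return clip_interval(
        GenomicInterval(t.seq_id, max(0, tss - flank), tss + flank, t.strand), lengths
    )


def promoter_span(
    g: Gene, flank: int, lengths: Mapping[str, int] | None = None
) -> GenomicInterval:
    """Smallest interval containing every transcript's promoter region."""
    regions = [promoter_region(t, flank, lengths) for t in g.transcripts]
    return GenomicInterval(
        g.seq_id,
        min(r.start for r in regions),
        max(r.end for r in regions),
        g.strand,
    )


def gene_structure_span(
    g: Gene, flank: int, lengths: Mapping[str, int] | None = None
) -> GenomicInterval:
    """Smallest interval containing every transcript span plus flat flanks."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return clip_interval(
        GenomicInterval(
            g.seq_id,
            max(0, min(t.start for t in g.transcripts) - flank),
            max(t.end for t in g.transcripts) + flank,
            g.strand,
        ),
        lengths,
    )


def neighborhood(
    g: Gene, half_width: int, lengths: Mapping[str, int] | None = None
) -> GenomicInterval:
    """Window of ``2*half_width`` centered on the midpoint of the gene box."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    box = g.span
    mid = (box.start + box.end) // 2
    return clip_interval(
        GenomicInterval(g.seq_id, max(0, mid - half_width), mid + half_width, g.strand),
        lengths,
    )


def genes_in_region(genes: Iterable[Gene], region: GenomicInterval) -> list[Gene]:
    """Genes whose bounding box overlaps the region by >=1 bp, sorted by start."""
    hits = [g for g in genes if g.span.overlaps(region)]
    return sorted(hits, key=lambda g: (g.span.start, g.gene_id))
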