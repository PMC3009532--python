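"""Self-consistent toy datasets with known ground truth.

The generator lays out an "ancestral" locus (genes with multi-exon
transcripts in fixed slots on one pseudo-chromosome) and derives two
descendant loci from it by coordinate offsetting plus random indels, which
become the gap structure of an alignment chain. CAGE tag clusters are
planted at every transcription start site; each TSS is copied to its
homologous position in the second locus with probability
``1 - tss_turnover_prob``, a lost copy being replaced by a novel cluster
250 bp downstream (genuine promoter turnover on both sides of the
comparison). Three duplication scenarios are emulated:

* ``ortholog`` — two assemblies linked by one pairwise chain (speciation);
* ``self_paralog`` — one assembly holding both loci, linked by a
  self-alignment chain (intra-genome duplication);
* ``bridged_paralog`` — duplicate loci in one assembly, each aligned to a
  shared outgroup assembly; the two chain files share the outgroup on their
  target side so the loci can only be compared through bridge composition.

Everything is deterministic given the seed, and a self-check pass validates
chain arithmetic and re-maps every planted shared TSS through the emitted
alignments at generation time.

Coordinates only; no sequence is simulated. Indels are placed between genes
by default so exon-conservation truth is exactly 1.0; an optional exonic
deletion plants a known fractional value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable

import numpy as np

from .annotation import Gene, GenomicInterval, Transcript
from .chains import Chain, blocks_of, map_interval

logger = logging.getLogger(__name__)

MODES = ("ortholog", "self_paralog", "bridged_paralog")

_SLOT = 6000
_MARGIN = 5000
_TSS_SPACING = 400
_NOVEL_SHIFT = 250  # > shared-TSS tolerance; < promoter flank


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureParams:
    n_genes: int = 4
    n_transcripts_per_gene: int = 2
    dup_mode: str = "ortholog"
    tss_turnover_prob: float = 0.0
    indel_rate: float = 0.5
    indel_size: tuple[int, int] = (50, 200)
    exonic_deletion: bool = False

    def validate(self) -> None:
        if self.dup_mode not in MODES:
            raise FixtureError(f"unknown dup_mode {self.dup_mode!r}")
        if not 1 <= self.n_genes <= 50:
            raise FixtureError("n_genes must be in 1..50")
        if not 1 <= self.n_transcripts_per_gene <= 4:
            raise FixtureError("n_transcripts_per_gene must be in 1..4")
        if not 0.0 <= self.tss_turnover_prob <= 1.0:
            raise FixtureError("tss_turnover_prob must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise FixtureError("indel_rate must be in [0, 1]")
        if self.exonic_deletion and self.dup_mode == "bridged_paralog":
            raise FixtureError("exonic_deletion is not supported in bridged mode")


@dataclass
class FixtureTruth:
    """Planted ground truth, keyed by reference-side gene id."""

    mode: str
    gene_pairs: list[tuple[str, str]]
    shared_tss: dict[str, list[tuple[int, int]]]
    turnover_ref: dict[str, list[int]]
    turnover_target: dict[str, list[int]]
    exon_conservation: dict[str, list[float]]
    wgd_pairs: list[tuple[str, str]]
    anchor_segments: list[tuple[list, list]]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "gene_pairs": [list(p) for p in self.gene_pairs],
            "shared_tss": {k: [list(x) for x in v] for k, v in self.shared_tss.items()},
            "turnover_ref": self.turnover_ref,
            "turnover_target": self.turnover_target,
            "exon_conservation": self.exon_conservation,
            "wgd_pairs": [list(p) for p in self.wgd_pairs],
            "anchor_segments": [[list(a), list(b)] for a, b in self.anchor_segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureTruth":
        return cls(
            mode=d["mode"],
            gene_pairs=[tuple(p) for p in d["gene_pairs"]],
            shared_tss={k: [tuple(x) for x in v] for k, v in d["shared_tss"].items()},
            turnover_ref=d["turnover_ref"],
            turnover_target=d["turnover_target"],
            exon_conservation=d["exon_conservation"],
            wgd_pairs=[tuple(p) for p in d["wgd_pairs"]],
            anchor_segments=[(tuple(a), tuple(b)) for a, b in d["anchor_segments"]],
        )


@dataclass
class FixtureBundle:
    seed: int
    params: FixtureParams
    files: dict[str, str]  # filename -> text content
    roles: dict[str, str]  # semantic role -> filename
    truth: FixtureTruth
    chain_objects: dict[str, list[Chain]]  # role -> parsed chains

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, text in sorted(self.files.items()):
            p = out / name
            p.write_text(text)
            paths[name] = p
        return paths

    def path_for(self, role: str, out_dir: str | Path) -> Path:
        return Path(out_dir) / self.roles[role]


# ---------------------------------------------------------------------------
# ancestral layout


def _ancestral_genes(params: FixtureParams, suffix: str) -> list[dict]:
    """Gene dicts in ancestral coordinates: id, strand, per-transcript exon
    triples and TSS."""
    genes = []
    for i in range(params.n_genes):
        base = _MARGIN + i * _SLOT
        strand = "+" if i % 2 == 0 else "-"
        txs = []
        for j in range(params.n_transcripts_per_gene):
            if strand == "+":
                tss = base + _TSS_SPACING * j
                exons = [
                    (tss, tss + 200),
                    (tss + 900, tss + 1100),
                    (tss + 1700, tss + 2000),
                ]
            else:
                right = base + 2400 + _TSS_SPACING * j
                exons = [
                    (right - 2000, right - 1700),
                    (right - 1100, right - 900),
                    (right - 300, right),
                ]
                tss = right - 1
            txs.append({"tid": f"T{i}.{j}{suffix}", "tss": tss, "exons": exons})
        genes.append({"gid": f"GENE{i}{suffix}", "strand": strand, "transcripts": txs})
    return genes


def _ancestral_length(params: FixtureParams) -> int:
    return 2 * _MARGIN + params.n_genes * _SLOT


# ---------------------------------------------------------------------------
# indel events and coordinate maps

# event kinds: "ins_ref" (extra ref bases), "ins_target" (extra target bases),
# "del_target" (ancestral bases present in ref, absent in target)


def _draw_events(
    rng: np.random.Generator,
    params: FixtureParams,
    kinds: tuple[str, ...],
) -> list[tuple[int, str, int]]:
    events = []
    lo, hi = params.indel_size
    for i in range(1, params.n_genes):
        cand = _MARGIN + i * _SLOT - 1000
        if rng.random() < params.indel_rate:
            kind = kinds[int(rng.integers(len(kinds)))]
            size = int(rng.integers(lo, hi + 1))
            events.append((cand, kind, size))
    if params.exonic_deletion and params.n_genes >= 1:
        # middle exon of transcript 0 of (plus-strand) gene 0: delete 100 of
        # 200 bases on the target side -> planted covered fraction 0.5
        exon_start = _MARGIN + 900
        events.append((exon_start + 50, "del_target", 100))
    return sorted(events)


class _CoordMap:
    """Monotone ancestral -> descendant coordinate map from indel events."""

    def __init__(self, events: Iterable[tuple[int, str, int]], side: str, offset: int = 0):
        self.breaks: list[tuple[int, int]] = []  # (ancestral pos, cumulative delta)
        delta = 0
        for pos, kind, size in sorted(events):
            if side == "ref" and kind == "ins_ref":
                delta += size
                self.breaks.append((pos, delta))
            elif side == "target" and kind == "ins_target":
                delta += size
                self.breaks.append((pos, delta))
            elif side == "target" and kind == "del_target":
                delta -= size
                self.breaks.append((pos + size, delta))
        self.offset = offset

    def __call__(self, x: int) -> int:
        delta = 0
        for pos, d in self.breaks:
            if pos <= x:
                delta = d
            else:
                break
        return x + delta + self.offset


def _chain_blocks(events: list[tuple[int, str, int]], length: int) -> list[tuple[int, int, int]]:
    """Walk the ancestral axis into (size, dt, dq) chain blocks."""
    blocks: list[tuple[int, int, int]] = []
    prev = 0
    for pos, kind, size in events:
        block = pos - prev
        if block <= 0:
            raise FixtureError("indel events too close; cannot form chain blocks")
        if kind == "ins_ref":
            blocks.append((block, size, 0))
            prev = pos
        elif kind == "ins_target":
            blocks.append((block, 0, size))
            prev = pos
        elif kind == "del_target":
            blocks.append((block, size, 0))
            prev = pos + size
        else:  # pragma: no cover
            raise FixtureError(f"unknown event kind {kind}")
    blocks.append((length - prev, 0, 0))
    return blocks


# ---------------------------------------------------------------------------
# emission helpers


def _gtf_text(genes: list[dict], seq: str, mapper: _CoordMap, source: str) -> str:
    buf = StringIO()
    for g in genes:
        for t in g["transcripts"]:
            for s, e in t["exons"]:
                buf.write(
                    f"{seq}\t{source}\texon\t{mapper(s) + 1}\t{mapper(e - 1) + 1}\t.\t"
                    f"{g['strand']}\t.\t"
                    f'gene_id "{g["gid"]}"; transcript_id "{t["tid"]}";\n'
                )
    return buf.getvalue()


def _chain_text(c: Chain) -> str:
    buf = StringIO()
    buf.write(
        f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
        f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
    )
    for i, (size, dt, dq) in enumerate(c.blocks):
        buf.write(f"{size}\n" if i == len(c.blocks) - 1 else f"{size} {dt} {dq}\n")
    buf.write("\n")
    return buf.getvalue()


def _exon_truth(
    genes: list[dict], events: list[tuple[int, str, int]]
) -> dict[str, list[float]]:
    """Per reference transcript, the aligned fraction of each exon."""
    out: dict[str, list[float]] = {}
    for g in genes:
        for t in g["transcripts"]:
            fracs = []
            for s, e in t["exons"]:
                ref_width = e - s
                uncovered = 0
                for pos, kind, size in events:
                    if kind == "ins_ref" and s < pos < e:
                        ref_width += size
                        uncovered += size
                    elif kind == "del_target":
                        uncovered += max(0, min(e, pos + size) - max(s, pos))
                fracs.append(1.0 - uncovered / ref_width)
            out[t["tid"]] = fracs
    return out


# ---------------------------------------------------------------------------
# the generator


def simulate_homologous_loci(
    seed: int,
    params: FixtureParams | None = None,
    verify: bool = True,
    **overrides,
) -> FixtureBundle:
    """Generate a fixture bundle (gene models, CAGE, chains, homology table,
    truth) for one duplication scenario. Byte-identical for a given seed."""
    params = replace(params or FixtureParams(), **overrides)
    params.validate()
    rng = np.random.default_rng(seed)
    G = _ancestral_length(params)

    if params.dup_mode == "ortholog":
        bundle = _simulate_pairwise(seed, params, rng, G, self_mode=False)
    elif params.dup_mode == "self_paralog":
        bundle = _simulate_pairwise(seed, params, rng, G, self_mode=True)
    else:
        bundle = _simulate_bridged(seed, params, rng, G)
    if verify:
        _self_check(bundle)
    return bundle


def _plant_cage(
    rng: np.random.Generator,
    genes_ref: list[dict],
    genes_target: list[dict],
    map_ref: _CoordMap,
    map_target: _CoordMap,
    seq_ref: str,
    seq_target: str,
    prob: float,
) -> tuple[list[tuple], list[tuple], FixtureTruth]:
    """Plant one single-position tag cluster per TSS; copy to the homologous
    position with probability 1-prob, else replace by a novel downstream TC."""
    ctss_ref: list[tuple] = []  # (seq, pos0, strand, count)
    ctss_target: list[tuple] = []
    shared: dict[str, list[tuple[int, int]]] = {}
    turn_ref: dict[str, list[int]] = {}
    turn_target: dict[str, list[int]] = {}
    gene_pairs = []
    for g_ref, g_tgt in zip(genes_ref, genes_target):
        gid = g_ref["gid"]
        gene_pairs.append((gid, g_tgt["gid"]))
        shared[gid] = []
        turn_ref[gid] = []
        turn_target[gid] = []
        for j, t in enumerate(g_ref["transcripts"]):
            anc_tss = t["tss"]
            ref_pos = map_ref(anc_tss)
            tgt_pos = map_target(anc_tss)
            ctss_ref.append((seq_ref, ref_pos, g_ref["strand"], 10 + 2 * j))
            if rng.random() < prob:
                turn_ref[gid].append(ref_pos)
                novel = tgt_pos + _NOVEL_SHIFT
                ctss_target.append((seq_target, novel, g_tgt["strand"], 5))
                turn_target[gid].append(novel)
            else:
                ctss_target.append((seq_target, tgt_pos, g_tgt["strand"], 8 + 2 * j))
                shared[gid].append((ref_pos, tgt_pos))
    truth = FixtureTruth(
        mode="",
        gene_pairs=gene_pairs,
        shared_tss=shared,
        turnover_ref=turn_ref,
        turnover_target=turn_target,
        exon_conservation={},
        wgd_pairs=[],
        anchor_segments=[],
    )
    return ctss_ref, ctss_target, truth


def _ctss_text(rows: list[tuple]) -> str:
    return "".join(f"{seq}\t{pos + 1}\t{strand}\t{count}\n" for seq, pos, strand, count in rows)


def _simulate_pairwise(
    seed: int,
    params: FixtureParams,
    rng: np.random.Generator,
    G: int,
    self_mode: bool,
) -> FixtureBundle:
    kinds = ("ins_ref", "ins_target")
    events = _draw_events(rng, params, kinds)
    map_ref = _CoordMap(events, "ref")
    ref_len = map_ref(G)
    if self_mode:
        locus_b_offset = ref_len + 10_000
        seq_ref = seq_target = "chrS"
        assembly_ref = assembly_target = "hg"
        map_target = _CoordMap(events, "target", offset=locus_b_offset)
    else:
        locus_b_offset = 0
        seq_ref, seq_target = "chrR", "chrQ"
        assembly_ref, assembly_target = "hg", "mm"
        map_target = _CoordMap(events, "target")
    target_end = map_target(G)

    suffix_ref = "_a" if self_mode else "_h"
    suffix_target = "_b" if self_mode else "_m"
    genes_ref = _ancestral_genes(params, suffix_ref)
    genes_target = _ancestral_genes(params, suffix_target)

    t_size = ref_len + 1000
    q_size = target_end + 1000
    if self_mode:
        t_size = q_size = target_end + 1000
    chain = Chain(
        chain_id="1",
        score=9900,
        t_name=seq_ref,
        t_size=t_size,
        t_start=map_ref(0),
        t_end=ref_len,
        q_name=seq_target,
        q_size=q_size,
        q_strand="+",
        q_start=map_target(0),
        q_end=target_end,
        blocks=tuple(_chain_blocks(events, G)),
    )
    chain.validate()

    ctss_ref, ctss_target, truth = _plant_cage(
        rng, genes_ref, genes_target, map_ref, map_target, seq_ref, seq_target,
        params.tss_turnover_prob,
    )
    truth.mode = params.dup_mode
    truth.exon_conservation = _exon_truth(genes_ref, events)
    truth.anchor_segments = [
        (
            [b.t_interval.seq_id, b.t_interval.start, b.t_interval.end],
            [b.q_interval.seq_id, b.q_interval.start, b.q_interval.end],
        )
        for b in blocks_of(chain)
    ]

    species_ref = "human"
    species_target = "human" if self_mode else "mouse"
    relation = "paralog" if self_mode else "ortholog"
    ancestor = "Euteleostomi" if self_mode else "Euarchontoglires"
    hom_rows = ["gene_a\tspecies_a\tgene_b\tspecies_b\trelation\tancestor_taxon"]
    for ga, gb in truth.gene_pairs:
        hom_rows.append(f"{ga}\t{species_ref}\t{gb}\t{species_target}\t{relation}\t{ancestor}")

    gtf_ref = _gtf_text(genes_ref, seq_ref, map_ref, "fixture")
    gtf_target = _gtf_text(genes_target, seq_target, map_target, "fixture")
    if self_mode:
        files = {
            "genes.gtf": gtf_ref + gtf_target,
            "cage.ctss": _ctss_text(sorted(ctss_ref + ctss_target)),
            "self.chain": _chain_text(chain),
            "homology.tsv": "\n".join(hom_rows) + "\n",
        }
        roles = {
            "gtf_ref": "genes.gtf",
            "gtf_target": "genes.gtf",
            "ctss_ref": "cage.ctss",
            "ctss_target": "cage.ctss",
            "chain": "self.chain",
            "homology": "homology.tsv",
            "truth": "truth.json",
        }
    else:
        files = {
            "ref.gtf": gtf_ref,
            "target.gtf": gtf_target,
            "ref.ctss": _ctss_text(sorted(ctss_ref)),
            "target.ctss": _ctss_text(sorted(ctss_target)),
            "pairwise.chain": _chain_text(chain),
            "homology.tsv": "\n".join(hom_rows) + "\n",
        }
        roles = {
            "gtf_ref": "ref.gtf",
            "gtf_target": "target.gtf",
            "ctss_ref": "ref.ctss",
            "ctss_target": "target.ctss",
            "chain": "pairwise.chain",
            "homology": "homology.tsv",
            "truth": "truth.json",
        }
    files["truth.json"] = json.dumps(truth.to_dict(), indent=2, sort_keys=True)
    return FixtureBundle(
        seed=seed,
        params=params,
        files=files,
        roles=roles,
        truth=truth,
        chain_objects={"chain": [chain]},
    )


def _simulate_bridged(
    seed: int, params: FixtureParams, rng: np.random.Generator, G: int
) -> FixtureBundle:
    # outgroup assembly A is the unchanged ancestral axis; the two duplicate
    # loci each accumulate their own target-side indels
    events_a = _draw_events(rng, params, ("ins_target", "del_target"))
    events_b = _draw_events(rng, params, ("ins_target", "del_target"))
    map_a = _CoordMap(events_a, "target")
    map_b = _CoordMap(events_b, "target")
    identity = _CoordMap([], "ref")
    len_a, len_b = map_a(G), map_b(G)

    genes_h = _ancestral_genes(params, "_h")
    genes_a = _ancestral_genes(params, "_a")
    genes_b = _ancestral_genes(params, "_b")

    chain_a = Chain(
        chain_id="1",
        score=9900,
        t_name="chrA",
        t_size=G + 1000,
        t_start=0,
        t_end=G,
        q_name="chrZ1",
        q_size=len_a + 1000,
        q_strand="+",
        q_start=0,
        q_end=len_a,
        blocks=tuple(_chain_blocks(events_a, G)),
    )
    chain_b = Chain(
        chain_id="2",
        score=9800,
        t_name="chrA",
        t_size=G + 1000,
        t_start=0,
        t_end=G,
        q_name="chrZ2",
        q_size=len_b + 1000,
        q_strand="+",
        q_start=0,
        q_end=len_b,
        blocks=tuple(_chain_blocks(events_b, G)),
    )
    chain_a.validate()
    chain_b.validate()

    ctss_a, ctss_b, truth = _plant_cage(
        rng, genes_a, genes_b, map_a, map_b, "chrZ1", "chrZ2", params.tss_turnover_prob
    )
    truth.mode = params.dup_mode
    truth.exon_conservation = _exon_truth(genes_a, [])
    truth.wgd_pairs = sorted(
        (f"GENE{i}_a", f"GENE{i}_b") for i in range(params.n_genes)
    )
    truth.anchor_segments = []

    hom_rows = ["gene_a\tspecies_a\tgene_b\tspecies_b\trelation\tancestor_taxon"]
    for i in range(params.n_genes):
        hom_rows.append(f"GENE{i}_h\thuman\tGENE{i}_a\tzebrafish\tortholog\tEuteleostomi")
        hom_rows.append(f"GENE{i}_h\thuman\tGENE{i}_b\tzebrafish\tortholog\tEuteleostomi")

    files = {
        "outgroup.gtf": _gtf_text(genes_h, "chrA", identity, "fixture"),
        "genes.gtf": _gtf_text(genes_a, "chrZ1", map_a, "fixture")
        + _gtf_text(genes_b, "chrZ2", map_b, "fixture"),
        "cage.ctss": _ctss_text(sorted(ctss_a + ctss_b)),
        "bridge_a.chain": _chain_text(chain_a),
        "bridge_b.chain": _chain_text(chain_b),
        "combined.chain": _chain_text(chain_a) + _chain_text(chain_b),
        "homology.tsv": "\n".join(hom_rows) + "\n",
        "truth.json": json.dumps(truth.to_dict(), indent=2, sort_keys=True),
    }
    roles = {
        "gtf_ref": "genes.gtf",
        "gtf_target": "genes.gtf",
        "gtf_outgroup": "outgroup.gtf",
        "ctss_ref": "cage.ctss",
        "ctss_target": "cage.ctss",
        "chain_bridge_ref": "bridge_a.chain",
        "chain_bridge_target": "bridge_b.chain",
        "chain_combined": "combined.chain",
        "homology": "homology.tsv",
        "truth": "truth.json",
    }
    return FixtureBundle(
        seed=seed,
        params=params,
        files=files,
        roles=roles,
        truth=truth,
        chain_objects={
            "chain_bridge_ref": [chain_a],
            "chain_bridge_target": [chain_b],
        },
    )


def _self_check(bundle: FixtureBundle) -> None:
    """Validate chain arithmetic and re-map every planted shared TSS."""
    for chains in bundle.chain_objects.values():
        for c in chains:
            c.validate()
    truth = bundle.truth
    for gid, pairs in truth.shared_tss.items():
        for ref_pos, tgt_pos in pairs:
            if bundle.params.dup_mode == "bridged_paralog":
                ca = bundle.chain_objects["chain_bridge_ref"]
                cb = bundle.chain_objects["chain_bridge_target"]
                seq = ca[0].q_name
                back = map_interval(ca, GenomicInterval(seq, ref_pos, ref_pos + 1), "q2t")
                assert len(back) == 1, f"{gid}: TSS {ref_pos} not bridgeable"
                fwd = map_interval(cb, back[0].mapped, "t2q")
                assert fwd and fwd[0].mapped.start == tgt_pos, (
                    f"{gid}: bridged TSS {ref_pos} maps to {fwd}, expected {tgt_pos}"
                )
            else:
                chains = bundle.chain_objects["chain"]
                seq = chains[0].t_name
                fwd = map_interval(chains, GenomicInterval(seq, ref_pos, ref_pos + 1), "t2q")
                assert fwd and fwd[0].mapped.start == tgt_pos, (
                    f"{gid}: TSS {ref_pos} maps to {fwd}, expected {tgt_pos}"
                )


# ---------------------------------------------------------------------------
# random instances for oracle-style checks


def random_tags(
    rng: np.random.Generator,
    n: int,
    n_seqs: int = 2,
    seq_len: int = 5000,
    max_width: int = 30,
    max_count: int = 5,
):
    """A random CAGE library for clustering equivalence checks."""
    from .cage import CageLibrary, CageTag

    tags = []
    for _ in range(n):
        seq = f"chr{int(rng.integers(1, n_seqs + 1))}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, seq_len))
        width = int(rng.integers(1, max_width + 1))
        iv = GenomicInterval(seq, start, start + width, strand)
        five = start if strand == "+" else start + width - 1
        tags.append(CageTag(iv, five, int(rng.integers(1, max_count + 1))))
    return CageLibrary(tags, sum(t.count for t in tags))


def random_chain(
    rng: np.random.Generator,
    chain_id: str,
    t_name: str = "chrT",
    q_name: str = "chrQ",
    t_size: int = 2000,
    q_size: int = 2000,
    max_blocks: int = 5,
    minus_prob: float = 0.4,
    scores: tuple = (700, 800, 900, 1000),
) -> Chain:
    """A random valid chain (possibly minus-strand query)."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(5, 61))
        if i == n_blocks - 1:
            blocks.append((size, 0, 0))
        else:
            blocks.append((size, int(rng.integers(0, 41)), int(rng.integers(0, 41))))
    t_span = sum(s + dt for s, dt, _ in blocks)
    q_span = sum(s + dq for s, _, dq in blocks)
    t_start = int(rng.integers(0, max(1, t_size - t_span)))
    q_start = int(rng.integers(0, max(1, q_size - q_span)))
    q_strand = "-" if rng.random() < minus_prob else "+"
    c = Chain(
        chain_id=chain_id,
        score=float(scores[int(rng.integers(len(scores)))]),
        t_name=t_name,
        t_size=t_size,
        t_start=t_start,
        t_end=t_start + t_span,
        q_name=q_name,
        q_size=q_size,
        q_strand=q_strand,
        q_start=q_start,
        q_end=q_start + q_span,
        blocks=tuple(blocks),
    )
    c.validate()
    return c


def random_chains(rng: np.random.Generator, n: int, **kw) -> list[Chain]:
    return [random_chain(rng, chain_id=str(i + 1), **kw) for i in range(n)]


# ---------------------------------------------------------------------------
# end-to-end evaluation of a bundle


def evaluate_fixture(bundle: FixtureBundle, out_dir: str | Path | None = None) -> dict:
    """Run the full promoter-comparison pipeline on a bundle and summarise
    shared/turnover recovery per gene pair.

    Used by the generator's consumers (tests, reports) as the standard
    end-to-end harness; writes the bundle to ``out_dir`` (or a temporary
    directory) and goes through the on-disk formats like a real run.
    """
    import tempfile

    from .annotation import read_gene_models
    from .cage import cluster_tags, read_cage
    from .chains import read_chains
    from .views import build_promoter_view

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(out_dir) if out_dir is not None else Path(tmp)
        bundle.write(base)
        genes_ref = {
            g.gene_id: g for g in read_gene_models(bundle.path_for("gtf_ref", base))
        }
        genes_target = {
            g.gene_id: g for g in read_gene_models(bundle.path_for("gtf_target", base))
        }
        tcs_ref = cluster_tags(read_cage(bundle.path_for("ctss_ref", base)))
        tcs_target = cluster_tags(read_cage(bundle.path_for("ctss_target", base)))

        kwargs: dict = {}
        if bundle.params.dup_mode == "bridged_paralog":
            kwargs["bridge"] = (
                read_chains(bundle.path_for("chain_bridge_ref", base)),
                read_chains(bundle.path_for("chain_bridge_target", base)),
            )
            kwargs["chains"] = ()
        else:
            kwargs["chains"] = read_chains(bundle.path_for("chain", base))
            kwargs["self_alignment"] = bundle.params.dup_mode == "self_paralog"

        per_gene = {}
        n_tss = 0
        n_turnover = 0
        for gid_ref, gid_target in bundle.truth.gene_pairs:
            view = build_promoter_view(
                genes_ref[gid_ref],
                genes_target[gid_target],
                tcs_ref=tcs_ref,
                tcs_target=tcs_target,
                **kwargs,
            )
            ann = view.annotations
            shared = sorted(
                (p["ref_position"], p["target_position"]) for p in ann["shared_tss"]
            )
            per_gene[gid_ref] = {
                "shared": shared,
                "turnover_ref": list(ann["turnover_ref"]),
                "turnover_target": list(ann["turnover_target"]),
            }
            n_tss += len(shared) + len(ann["turnover_ref"])
            n_turnover += len(ann["turnover_ref"])
        return {
            "per_gene": per_gene,
            "n_tss": n_tss,
            "n_turnover_ref": n_turnover,
            "turnover_fraction": n_turnover / n_tss if n_tss else 0.0,
        }
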