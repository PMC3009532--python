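"""Ortholog/paralog tables and WGD-candidate pair derivation.

Homology pairs are unordered: ``(a, b)`` and ``(b, a)`` are the same pair for
deduplication. Each pair carries a relation (ortholog — separated by
speciation — or paralog — separated by duplication) and the taxon label of
the last common ancestor at the split.

Duplicate pairs retained from a whole-genome duplication in lineage B are
approximated through an ortholog bridge: two B genes sharing the same
ortholog in an outgroup species A (which approximates the pre-duplication
ancestral genome) are emitted as candidate WGD paralogs. Tandem duplicates
private to B are not distinguished here — that would need a gene tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RELATIONS = ("ortholog", "paralog")

REQUIRED_COLUMNS = ["gene_a", "species_a", "gene_b", "species_b", "relation", "ancestor_taxon"]


class HomologyError(ValueError):
    pass


@dataclass(frozen=True)
class HomologyPair:
    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    relation: str
    ancestor_taxon: str = ""
    confidence: str | None = None
    bridge_gene: str | None = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise HomologyError(f"unknown relation {self.relation!r}")
        if self.species_a == self.species_b and self.gene_a == self.gene_b:
            raise HomologyError(f"self-pair {self.gene_a} in {self.species_a}")

    @property
    def key(self) -> tuple:
        """Unordered identity of the pair."""
        return tuple(sorted([(self.species_a, self.gene_a), (self.species_b, self.gene_b)]))


def read_homology_table(path: str | Path) -> list[HomologyPair]:
    """TSV with header gene_a, species_a, gene_b, species_b, relation,
    ancestor_taxon[, confidence]; BioMart-export shaped.

    Unordered duplicates are removed (first occurrence wins); self-pairs in
    one species are rejected with a logged report; an unknown relation token
    aborts the load. Output is stably sorted by pair key.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise HomologyError(f"{path}: missing column(s) {missing}")
    pairs: list[HomologyPair] = []
    rejected = 0
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        relation = row.relation
        if relation not in RELATIONS:
            raise HomologyError(f"{path}: unknown relation token {relation!r}")
        if row.species_a == row.species_b and row.gene_a == row.gene_b:
            rejected += 1
            continue
        p = HomologyPair(
            gene_a=row.gene_a,
            species_a=row.species_a,
            gene_b=row.gene_b,
            species_b=row.species_b,
            relation=relation,
            ancestor_taxon=getattr(row, "ancestor_taxon", ""),
            confidence=getattr(row, "confidence", None),
        )
        if p.key in seen:
            continue
        seen.add(p.key)
        pairs.append(p)
    if rejected:
        logger.warning("%s: rejected %d same-species self-pair row(s)", path, rejected)
    return sorted(pairs, key=lambda p: p.key)


def write_homology_table(pairs: Iterable[HomologyPair], path: str | Path) -> None:
    rows = [
        {
            "gene_a": p.gene_a,
            "species_a": p.species_a,
            "gene_b": p.gene_b,
            "species_b": p.species_b,
            "relation": p.relation,
            "ancestor_taxon": p.ancestor_taxon,
            "confidence": p.confidence or "",
            "bridge_gene": p.bridge_gene or "",
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS + ["confidence", "bridge_gene"]).to_csv(
        path, sep="\t", index=False
    )


def wgd_pairs_via_bridge(
    orthologs: Sequence[HomologyPair], bridge_species: str | None = None
) -> list[HomologyPair]:
    """Candidate WGD paralog pairs in species B via shared orthologs in A.

    For every A gene with >= 2 distinct B orthologs, all unordered
    combinations of those B genes are emitted as paralog pairs annotated
    with the bridging A gene; the output size is the sum of C(k, 2) over
    bridge genes and is independent of input row order.
    """
    for p in orthologs:
        if p.relation != "ortholog":
            raise HomologyError("wgd_pairs_via_bridge expects ortholog pairs only")
    if not orthologs:
        return []
    if bridge_species is None:
        bridge_species = orthologs[0].species_a
    partners: dict[str, dict[str, str]] = {}  # A gene -> {B gene: ancestor}
    for p in orthologs:
        if p.species_a == bridge_species and p.species_b != bridge_species:
            a, b = p.gene_a, p.gene_b
        elif p.species_b == bridge_species and p.species_a != bridge_species:
            a, b = p.gene_b, p.gene_a
        else:
            raise HomologyError(
                f"pair ({p.gene_a},{p.gene_b}) does not cross bridge species "
                f"{bridge_species!r}"
            )
        partners.setdefault(a, {})[b] = p.ancestor_taxon
    other_species = {
        (p.species_b if p.species_a == bridge_species else p.species_a) for p in orthologs
    }
    species_b = sorted(other_species)[0]
    out: list[HomologyPair] = []
    seen: set[tuple] = set()
    for a_gene in sorted(partners):
        b_genes = sorted(partners[a_gene])
        if len(b_genes) < 2:
            continue
        for g1, g2 in combinations(b_genes, 2):
            anc1, anc2 = partners[a_gene][g1], partners[a_gene][g2]
            pair = HomologyPair(
                gene_a=g1,
                species_a=species_b,
                gene_b=g2,
                species_b=species_b,
                relation="paralog",
                ancestor_taxon=anc1 if anc1 == anc2 else "",
                bridge_gene=a_gene,
            )
            if pair.key in seen:
                continue
            seen.add(pair.key)
            out.append(pair)
    return sorted(out, key=lambda p: p.key)


def paralog_counts_by_ancestor(pairs: Iterable[HomologyPair]) -> dict[str, int]:
    """Group pairs by last-common-ancestor taxon; missing labels count as
    "unknown". Useful for locating the duplication burst consistent with the
    early-vertebrate (1R/2R) or teleost (3R) whole-genome duplications."""
    counts: dict[str, int] = {}
    for p in pairs:
        taxon = p.ancestor_taxon or "unknown"
        counts[taxon] = counts.get(taxon, 0) + 1
    return counts
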