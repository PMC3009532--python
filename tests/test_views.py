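"""Comparison views: regions, shared/turnover TSSes, exon conservation,
neighborhood links, serialization."""

import json
import xml.etree.ElementTree as ET

import pytest

from homolocus.anchors import Anchor
from homolocus.annotation import GenomicInterval, Parameters
from homolocus.cage import TagCluster
from homolocus.chains import Chain, invert
from homolocus.homology import HomologyPair
from homolocus.views import (
    GeneNotFoundError,
    build_gene_structure_view,
    build_neighborhood_view,
    build_promoter_view,
    exon_conservation,
    resolve_gene,
    serialize_view,
    shared_tss_pairs,
    view_from_json,
    view_to_dict,
)

from conftest import make_gene, make_transcript


def tc(seq, pos, strand="+", tpm=10.0, count=10):
    return TagCluster(
        interval=GenomicInterval(seq, pos, pos + 1, strand),
        strand=strand,
        member_tags=(),
        total_count=count,
        tpm=tpm,
        representative_position=pos,
        shape="sharp",
    )


def anchor(ref, target, orientation="same", mult="one_to_one", cid="1", score=900.0):
    return Anchor(
        ref_interval=GenomicInterval(*ref),
        target_interval=GenomicInterval(*target),
        multiplicity=mult,
        chain_id=cid,
        score=score,
        orientation=orientation,
        color="gray",
    )


def whole_chain(t_name, q_name, length=20000, score=9000.0, cid="1"):
    c = Chain(cid, score, t_name, length, 0, length, q_name, length, "+", 0, length,
              ((length, 0, 0),))
    c.validate()
    return c


def gene_pair():
    g_ref = make_gene(
        "GR",
        (
            make_transcript("TR1", "GR", ((1000, 1500),), "chrR", "+"),
            make_transcript("TR2", "GR", ((5000, 5500),), "chrR", "+"),
        ),
    )
    g_target = make_gene(
        "GT",
        (
            make_transcript("TT1", "GT", ((1000, 1500),), "chrQ", "+"),
            make_transcript("TT2", "GT", ((5000, 5500),), "chrQ", "+"),
        ),
    )
    return g_ref, g_target


class TestPromoterView:
    def test_region_is_union_of_tss_windows(self):
        g_ref, g_target = gene_pair()
        view = build_promoter_view(g_ref, g_target, chains=[whole_chain("chrR", "chrQ")])
        assert (view.ref.region.start, view.ref.region.end) == (500, 5500)

    def test_no_chains_gives_empty_anchor_view(self):
        g_ref, g_target = gene_pair()
        view = build_promoter_view(g_ref, g_target)
        assert view.anchors == []
        assert view.annotations["shared_tss"] == []

    def test_distinct_promoter_centers_reported(self):
        # 6 isoforms at 4 distinct TSSes
        tsses = [1000, 1000, 2000, 3000, 3000, 4000]
        txs = tuple(
            make_transcript(f"T{i}", "G6", ((t, t + 300),), "chrR", "+")
            for i, t in enumerate(tsses)
        )
        g = make_gene("G6", txs)
        _, g_target = gene_pair()
        view = build_promoter_view(g, g_target, chains=[whole_chain("chrR", "chrQ")])
        assert view.annotations["promoter_centers_ref"] == [1000, 2000, 3000, 4000]

    def test_gene_resolution_suggests_near_misses(self):
        g_ref, _ = gene_pair()
        with pytest.raises(GeneNotFoundError, match="GR"):
            resolve_gene([g_ref], "GRX")


class TestSharedTss:
    def _view(self, anchors, tcs_ref, tcs_target):
        g_ref, g_target = gene_pair()
        view = build_promoter_view(g_ref, g_target)
        view.anchors = anchors
        view.ref.tag_clusters = tcs_ref
        view.target.tag_clusters = tcs_target
        return view

    def test_mapped_within_tolerance_is_shared(self):
        view = self._view(
            [anchor(("chrR", 900, 1100), ("chrQ", 4900, 5100))],
            [tc("chrR", 1000)],
            [tc("chrQ", 5040)],
        )
        shared, t_ref, t_target = shared_tss_pairs(view, 100)
        assert len(shared) == 1 and not t_ref and not t_target

    def test_ref_tc_outside_anchors_is_turnover(self):
        view = self._view(
            [anchor(("chrR", 2000, 2100), ("chrQ", 2000, 2100))],
            [tc("chrR", 1000)],
            [tc("chrQ", 1000)],
        )
        shared, t_ref, t_target = shared_tss_pairs(view, 100)
        assert not shared and len(t_ref) == 1 and len(t_target) == 1

    def test_strand_consistency_with_opposite_orientation(self):
        view = self._view(
            [anchor(("chrR", 900, 1100), ("chrQ", 900, 1100), orientation="opposite")],
            [tc("chrR", 1000, strand="+")],
            [tc("chrQ", 1000, strand="-")],
        )
        shared, *_ = shared_tss_pairs(view, 100)
        assert len(shared) == 1  # mapped = 900+1100-1-1000 = 999, distance 1

    def test_each_tc_used_once_greedy_by_distance(self):
        view = self._view(
            [anchor(("chrR", 900, 1100), ("chrQ", 900, 1100))],
            [tc("chrR", 1000), tc("chrR", 1010)],
            [tc("chrQ", 1005)],
        )
        shared, t_ref, t_target = shared_tss_pairs(view, 100)
        assert len(shared) == 1 and not t_target
        assert shared[0][0].representative_position == 1000  # distance 5 < 5? both 5 -> tpm tie -> coordinates
        assert len(t_ref) == 1

    def test_partition_property(self):
        view = self._view(
            [anchor(("chrR", 500, 5500), ("chrQ", 500, 5500))],
            [tc("chrR", 1000), tc("chrR", 3000)],
            [tc("chrQ", 1010), tc("chrQ", 4900)],
        )
        shared, t_ref, t_target = shared_tss_pairs(view, 100)
        assert len(shared) * 2 + len(t_ref) + len(t_target) == 4
        for a, b in shared:
            assert abs(a.representative_position - b.representative_position) <= 100


class TestExonConservation:
    def test_fully_covered_exon(self):
        t = make_transcript("T", "G", ((0, 100),), "chrR")
        assert exon_conservation(t, [anchor(("chrR", 0, 100), ("chrQ", 0, 100))]) == [(0, 1.0)]

    def test_half_covered_exon(self):
        t = make_transcript("T", "G", ((0, 100),), "chrR")
        assert exon_conservation(t, [anchor(("chrR", 0, 50), ("chrQ", 0, 50))]) == [(0, 0.5)]

    def test_no_anchors_means_zero_everywhere(self):
        t = make_transcript("T", "G", ((0, 100), (200, 300)), "chrR")
        assert exon_conservation(t, []) == [(0, 0.0), (1, 0.0)]

    def test_monotone_in_anchor_set(self):
        t = make_transcript("T", "G", ((0, 100),), "chrR")
        a1 = [anchor(("chrR", 0, 30), ("chrQ", 0, 30))]
        a2 = a1 + [anchor(("chrR", 50, 90), ("chrQ", 50, 90), cid="2")]
        f1 = exon_conservation(t, a1)[0][1]
        f2 = exon_conservation(t, a2)[0][1]
        assert 0.0 <= f1 <= f2 <= 1.0


class TestGeneStructureView:
    def test_region_is_span_plus_flanks(self):
        g_ref, g_target = gene_pair()
        view = build_gene_structure_view(g_ref, g_target, chains=[whole_chain("chrR", "chrQ")])
        assert (view.ref.region.start, view.ref.region.end) == (500, 6000)
        assert "exon_conservation_ref" in view.annotations

    def test_pairwise_api_for_co_orthologs(self):
        g_ref, g_target = gene_pair()
        other = make_gene("GT2", (make_transcript("TT3", "GT2", ((8000, 8600),), "chrQ", "+"),))
        chains = [whole_chain("chrR", "chrQ")]
        v1 = build_gene_structure_view(g_ref, g_target, chains=chains)
        v2 = build_gene_structure_view(g_ref, other, chains=chains)
        assert v1.target.region != v2.target.region


class TestNeighborhoodView:
    def _genes(self, seq, ids, start=10000, spacing=3000, strands=None):
        out = []
        for i, gid in enumerate(ids):
            s = start + i * spacing
            strand = (strands or ["+"] * len(ids))[i]
            out.append(make_gene(gid, (make_transcript(f"t{gid}", gid, ((s, s + 1000),), seq, strand),)))
        return out

    def test_planted_neighbor_pairs_linked_in_order(self):
        ref_genes = self._genes("chrR", ["SP3", "RAPGEF4", "CDCA7", "SP9"])
        target_genes = self._genes("chrQ", ["SP4", "RAPGEF5", "CDCA7L", "SP8"])
        pairs = [
            HomologyPair("SP3", "human", "SP4", "human", "paralog", "Euteleostomi"),
            HomologyPair("RAPGEF4", "human", "RAPGEF5", "human", "paralog", "Euteleostomi"),
            HomologyPair("CDCA7", "human", "CDCA7L", "human", "paralog", "Euteleostomi"),
            HomologyPair("SP9", "human", "SP8", "human", "paralog", "Euteleostomi"),
        ]
        view = build_neighborhood_view(
            ref_genes[0], target_genes[0],
            genes_ref=ref_genes, genes_target=target_genes, homology_pairs=pairs,
        )
        links = view.annotations["homology_links"]
        assert len(links) == 4
        assert view.annotations["conserved_order"] is True
        assert all(l["strand_match"] for l in links)

    def test_no_homologs_links_only_query_pair(self):
        ref_genes = self._genes("chrR", ["A", "B"])
        target_genes = self._genes("chrQ", ["X", "Y"])
        view = build_neighborhood_view(
            ref_genes[0], target_genes[0],
            genes_ref=ref_genes, genes_target=target_genes, homology_pairs=[],
        )
        links = view.annotations["homology_links"]
        assert [(l["ref_gene"], l["target_gene"], l["relation"]) for l in links] == [("A", "X", "query")]

    def test_scrambled_order_clears_conserved_flag(self):
        ref_genes = self._genes("chrR", ["A", "B", "C"])
        target_genes = self._genes("chrQ", ["Z", "X", "Y"])  # order scrambled vs homology
        pairs = [
            HomologyPair("A", "h", "X", "h", "paralog", ""),
            HomologyPair("B", "h", "Y", "h", "paralog", ""),
            HomologyPair("C", "h", "Z", "h", "paralog", ""),
        ]
        view = build_neighborhood_view(
            ref_genes[0], target_genes[1],
            genes_ref=ref_genes, genes_target=target_genes, homology_pairs=pairs,
        )
        assert view.annotations["conserved_order"] is False


class TestSerialization:
    def _view(self):
        g_ref, g_target = gene_pair()
        return build_promoter_view(
            g_ref, g_target,
            tcs_ref=[tc("chrR", 1000)], tcs_target=[tc("chrQ", 1000)],
            chains=[whole_chain("chrR", "chrQ")],
        )

    def test_json_round_trip_is_lossless(self):
        view = self._view()
        text = serialize_view(view, "json")
        back = view_from_json(text)
        assert view_to_dict(back) == view_to_dict(view)
        assert serialize_view(back, "json") == text

    def test_empty_anchor_view_serializes(self):
        g_ref, g_target = gene_pair()
        view = build_promoter_view(g_ref, g_target)
        doc = json.loads(serialize_view(view, "json"))
        assert doc["anchors"] == [] and doc["schema_version"] == "1"

    def test_svg_is_well_formed(self):
        root = ET.fromstring(serialize_view(self._view(), "svg"))
        assert root.tag.endswith("svg")

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            serialize_view(self._view(), "pdf")

    def test_mirror_views_share_unordered_pairs(self):
        g_ref, g_target = gene_pair()
        chain = whole_chain("chrR", "chrQ")
        fwd = build_promoter_view(
            g_ref, g_target, tcs_ref=[tc("chrR", 1000)], tcs_target=[tc("chrQ", 1020)],
            chains=[chain],
        )
        rev = build_promoter_view(
            g_target, g_ref, tcs_ref=[tc("chrQ", 1020)], tcs_target=[tc("chrR", 1000)],
            chains=[invert(chain)],
        )
        f = {(p["ref_position"], p["target_position"]) for p in fwd.annotations["shared_tss"]}
        r = {(p["target_position"], p["ref_position"]) for p in rev.annotations["shared_tss"]}
        assert f == r and f
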