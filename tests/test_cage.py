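"""CAGE tag clustering, representative positions, tpm and shape classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homolocus.annotation import GenomicInterval
from homolocus.cage import (
    CageError,
    CageLibrary,
    CageTag,
    assign_representative_tc,
    classify_shape,
    cluster_tags,
    compute_tpm,
    read_cage,
    representative_position,
)
from homolocus.synthetic_fixtures import random_tags

from conftest import make_gene, make_transcript


def tag(seq="chr1", start=100, end=120, strand="+", count=1, five=None):
    if five is None:
        five = start if strand == "+" else end - 1
    return CageTag(GenomicInterval(seq, start, end, strand), five, count)


def lib(*tags):
    return CageLibrary(list(tags), sum(t.count for t in tags))


class TestReadCage:
    def test_ctss_one_based_conversion(self, tmp_path):
        p = tmp_path / "a.ctss"
        p.write_text("chr1\t101\t+\t7\n")
        (t,) = read_cage(p, "ctss").tags
        assert (t.five_prime, t.count, t.interval.start, t.interval.end) == (100, 7, 100, 101)

    def test_bed6_minus_strand_five_prime(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t120\ttag\t3\t-\n")
        (t,) = read_cage(p, "bed6").tags
        assert (t.five_prime, t.count) == (119, 3)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.ctss"
        p.write_text("")
        out = read_cage(p, "ctss")
        assert out.tags == [] and out.library_size == 0

    @pytest.mark.parametrize("line", ["chr1\t101\t+\t0", "chr1\t101\t*\t5"])
    def test_bad_count_or_strand_raises(self, tmp_path, line):
        p = tmp_path / "bad.ctss"
        p.write_text(line + "\n")
        with pytest.raises(CageError):
            read_cage(p, "ctss")


class TestClustering:
    def test_overlap_by_one_base_merges(self):
        tcs = cluster_tags(lib(tag(start=100, end=120), tag(start=119, end=140)))
        assert len(tcs) == 1
        assert (tcs[0].interval.start, tcs[0].interval.end) == (100, 140)

    def test_abutting_tags_stay_separate(self):
        tcs = cluster_tags(lib(tag(start=100, end=120), tag(start=120, end=140)))
        assert len(tcs) == 2

    def test_strands_never_merge(self):
        tcs = cluster_tags(lib(tag(start=100, end=120, strand="+"), tag(start=100, end=120, strand="-")))
        assert len(tcs) == 2

    def test_matches_pairwise_connected_components(self):
        """Sweep clustering equals brute-force components of the pairwise
        overlap graph (independent scipy route)."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        rng = np.random.default_rng(3)
        library = random_tags(rng, 200)
        tcs = cluster_tags(library)
        # brute force per (seq, strand)
        n_expected = 0
        for seq in {t.interval.seq_id for t in library.tags}:
            for strand in "+-":
                group = [t for t in library.tags if t.interval.seq_id == seq and t.interval.strand == strand]
                if not group:
                    continue
                n = len(group)
                starts = np.array([t.interval.start for t in group])
                ends = np.array([t.interval.end for t in group])
                adj = (starts[:, None] < ends[None, :]) & (starts[None, :] < ends[:, None])
                n_comp, labels = connected_components(csr_matrix(adj), directed=False)
                n_expected += n_comp
        assert len(tcs) == n_expected

    def test_partition_and_count_conservation(self):
        rng = np.random.default_rng(4)
        library = random_tags(rng, 300)
        tcs = cluster_tags(library)
        assert sum(len(tc.member_tags) for tc in tcs) == len(library.tags)
        assert sum(tc.total_count for tc in tcs) == sum(t.count for t in library.tags)
        # same-strand clusters pairwise non-overlapping
        by_key = {}
        for tc in tcs:
            by_key.setdefault((tc.seq_id, tc.strand), []).append(tc.interval)
        for ivs in by_key.values():
            ivs = sorted(ivs, key=lambda i: i.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        library = random_tags(rng, 100)
        shuffled = list(library.tags)
        rng.shuffle(shuffled)
        a = cluster_tags(library)
        b = cluster_tags(CageLibrary(shuffled, library.library_size))
        key = lambda tcs: [
            (tc.seq_id, tc.strand, tc.interval.start, tc.interval.end, tc.total_count, tc.representative_position)
            for tc in tcs
        ]
        assert key(a) == key(b)


class TestRepresentativeAndTpm:
    def test_argmax_of_summed_counts(self):
        tcs = cluster_tags(
            lib(
                tag(start=100, end=112, count=3, five=100),
                tag(start=105, end=112, count=7, five=105),
                tag(start=110, end=112, count=2, five=110),
            )
        )
        assert representative_position(tcs[0]) == 105

    def test_tie_breaks_five_prime_most(self):
        plus = cluster_tags(lib(tag(start=100, end=111, count=5, five=100), tag(start=110, end=120, count=5, five=110)))
        assert plus[0].representative_position == 100
        minus = cluster_tags(
            lib(
                tag(start=100, end=111, strand="-", count=5, five=110),
                tag(start=95, end=101, strand="-", count=5, five=100),
            )
        )
        assert minus[0].representative_position == 110

    def test_single_tag(self):
        tcs = cluster_tags(lib(tag(start=42, end=63)))
        assert tcs[0].representative_position == 42

    def test_tpm_definition_and_errors(self):
        tc = cluster_tags(lib(tag(count=50)))[0]
        assert compute_tpm(tc, 10**6) == 50.0
        tc1 = cluster_tags(lib(tag(count=1)))[0]
        assert compute_tpm(tc1, 2 * 10**6) == 0.5
        with pytest.raises(CageError):
            compute_tpm(tc, 0)

    def test_tpm_normalization_identity(self):
        rng = np.random.default_rng(6)
        library = random_tags(rng, 150)
        tcs = cluster_tags(library)
        assert sum(tc.tpm for tc in tcs) == pytest.approx(1e6)


class TestShape:
    def test_single_position_is_sharp(self):
        tc = cluster_tags(lib(tag(count=9)))[0]
        assert classify_shape(tc) == "sharp"

    def test_uniform_wide_distribution_is_broad(self):
        tags = [tag(start=100 + i, end=160 + i, count=1, five=100 + i) for i in range(50)]
        tc = cluster_tags(lib(*tags))[0]
        assert classify_shape(tc, (0.1, 0.9), 4) == "broad"

    def test_two_close_positions_are_sharp(self):
        tc = cluster_tags(lib(tag(start=100, end=110, count=5, five=100), tag(start=103, end=110, count=5, five=103)))[0]
        assert classify_shape(tc, (0.1, 0.9), 4) == "sharp"

    def test_translation_invariance(self):
        def shape_at(shift):
            tags = [
                tag(start=100 + shift + 2 * i, end=140 + shift + 2 * i, count=i + 1, five=100 + shift + 2 * i)
                for i in range(10)
            ]
            return classify_shape(cluster_tags(lib(*tags))[0])

        assert shape_at(0) == shape_at(1000) == shape_at(54321)


class TestAssignment:
    def _gene(self):
        return make_gene("G", (make_transcript("T", "G", ((1000, 2000),), "chr1", "+"),))

    def _tc(self, pos, tpm, count=10, strand="+"):
        tcs = cluster_tags(lib(tag(start=pos, end=pos + 10, strand=strand, count=count,
                                   five=pos if strand == "+" else pos + 9)))
        tcs[0].tpm = tpm
        return tcs[0]

    def test_highest_tpm_wins(self):
        a, b = self._tc(900, 10.0), self._tc(1100, 25.0)
        per_tx, rep = assign_representative_tc(self._gene(), [a, b], 500)
        assert rep is b and per_tx["T"] is b

    def test_window_boundary_is_closed(self):
        inside = self._tc(1500, 5.0)  # rep position == tss + 500
        outside = self._tc(1501, 50.0)
        per_tx, rep = assign_representative_tc(self._gene(), [inside, outside], 500)
        assert rep is inside

    def test_opposite_strand_never_assigned(self):
        tc = self._tc(995, 99.0, strand="-")
        per_tx, rep = assign_representative_tc(self._gene(), [tc], 500)
        assert rep is None and per_tx["T"] is None

    def test_result_invariant_to_input_order(self):
        tcs = [self._tc(900, 10.0), self._tc(1100, 10.0), self._tc(1200, 5.0)]
        _, rep1 = assign_representative_tc(self._gene(), tcs, 500)
        _, rep2 = assign_representative_tc(self._gene(), tcs[::-1], 500)
        assert rep1.representative_position == rep2.representative_position


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 300), st.integers(1, 30), st.integers(1, 5)),
        min_size=1,
        max_size=40,
    )
)
def test_clustering_partition_property(raw):
    """Every tag lands in exactly one cluster and counts are conserved."""
    tags = [tag(start=s, end=s + w, count=c) for s, w, c in raw]
    tcs = cluster_tags(CageLibrary(tags, sum(t.count for t in tags)))
    assert sum(len(tc.member_tags) for tc in tcs) == len(tags)
    assert sum(tc.total_count for tc in tcs) == sum(t.count for t in tags)
    for tc in tcs:
        assert tc.interval.start <= tc.representative_position < tc.interval.end
        assert tc.interval.start == min(t.interval.start for t in tc.member_tags)
        assert tc.interval.end == max(t.interval.end for t in tc.member_tags)
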