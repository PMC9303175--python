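"""p-distances, ambiguity policies, partitions and the barcode gap."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ribogap.distance import (
    AmbiguityPolicy,
    DistancePolicy,
    UndefinedDistanceError,
    aligned_pair_distance,
    barcode_gap_report,
    distance_histogram,
    distance_matrix,
    intra_inter_partition,
    pairwise_distance,
    similarity_filter,
    write_phylip,
)
from ribogap.seqio import Alignment, SeqRecord

STRICT = DistancePolicy(AmbiguityPolicy.STRICT)
OVERLAP = DistancePolicy(AmbiguityPolicy.SET_OVERLAP)


def rec(rid, seq, taxon=""):
    return SeqRecord(id=rid, residues=seq, taxon=taxon)


class TestPairwiseDistance:
    @pytest.mark.parametrize(
        "a,b,diff,sites",
        [
            ("ACGT", "ACGT", 0, 4),
            ("AAAA", "AAAT", 1, 4),
            ("AC-T", "ACGT", 0, 3),     # pairwise deletion
            ("ANGT", "ACGT", 0, 3),     # N excluded by default
        ],
    )
    def test_strict_counts(self, a, b, diff, sites):
        pd = pairwise_distance(rec("a", a), rec("b", b), STRICT)
        assert (pd.differences, pd.compared_sites) == (diff, sites)
        assert pd.percent == pytest.approx(100 * diff / sites)

    def test_ambiguity_policies_disagree_on_compatible_codes(self):
        a, b = rec("a", "AR"), rec("b", "AA")
        assert pairwise_distance(a, b, STRICT).differences == 1
        assert pairwise_distance(a, b, OVERLAP).differences == 0

    def test_n_compared_when_toggled(self):
        policy = DistancePolicy(AmbiguityPolicy.SET_OVERLAP, exclude_n=False)
        pd = pairwise_distance(rec("a", "AN"), rec("b", "AC"), policy)
        assert pd.compared_sites == 2 and pd.differences == 0  # N overlaps C

    def test_all_gap_pair_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance(rec("a", "--"), rec("b", "AC"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_distance(rec("a", "ACG"), rec("b", "AC"))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGTRYN-"), st.sampled_from("ACGTRYN-")
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_strict_at_least_set_overlap(self, pairs):
        a = "".join(p[0] for p in pairs)
        b = "".join(p[1] for p in pairs)
        try:
            d_strict = pairwise_distance(rec("a", a), rec("b", b), STRICT)
            d_over = pairwise_distance(rec("a", a), rec("b", b), OVERLAP)
        except UndefinedDistanceError:
            return
        assert d_strict.differences >= d_over.differences
        assert d_strict.percent >= d_over.percent


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        aln = Alignment(records=[rec(f"s{i}", "ACGTACGT") for i in range(3)])
        dm = distance_matrix(aln)
        assert np.all(dm.percent == 0)

    def test_small_example(self):
        aln = Alignment(records=[rec("a", "AAAA"), rec("b", "AAAT"), rec("c", "AATT")])
        dm = distance_matrix(aln)
        assert dm.value("a", "b") == 25
        assert dm.value("a", "c") == 50
        assert dm.value("b", "c") == 25

    def test_agrees_with_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        rows = [
            rec(f"s{i}", "".join(rng.choice(list("ACGT-"), size=40)))
            for i in range(20)
        ]
        aln = Alignment(records=rows)
        dm = distance_matrix(aln)
        for i, j in itertools.combinations(range(20), 2):
            diff = comp = 0
            for x, y in zip(rows[i].residues, rows[j].residues):
                if x == "-" or y == "-":
                    continue
                comp += 1
                diff += x != y
            assert dm.differences[i, j] == diff
            assert dm.compared_sites[i, j] == comp

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        rows = [
            rec(f"s{i}", "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(6)
        ]
        dm = distance_matrix(Alignment(records=rows))
        assert np.allclose(dm.percent, dm.percent.T)
        assert np.all(np.diag(dm.percent) == 0)

    def test_phylip_writer_round_trips_values(self, tmp_path):
        rows = [rec("a", "AAAA"), rec("b", "AAAT"), rec("c", "AATT")]
        dm = distance_matrix(Alignment(records=rows))
        out = tmp_path / "m.phy"
        write_phylip(dm, out)
        lines = out.read_text().splitlines()
        assert lines[0].strip() == "3"
        vals = [float(x) for x in lines[1].split()[1:]]
        assert vals == pytest.approx([0.0, 25.0, 50.0])


class TestPartitionAndGap:
    def _dm(self, seqs, taxa):
        rows = [rec(f"s{i}", s, t) for i, (s, t) in enumerate(zip(seqs, taxa))]
        dm = distance_matrix(Alignment(records=rows))
        tmap = {r.id: r.taxon for r in rows}
        return dm, tmap

    def test_counting_two_by_two(self):
        dm, tmap = self._dm(
            ["AAAAAAAA", "AAAAAAAT", "TTTTAAAA", "TTTTAAAT"],
            ["X", "X", "Y", "Y"],
        )
        part = intra_inter_partition(dm, tmap)
        assert sorted(len(v) for v in part.intra.values()) == [1, 1]
        assert len(part.inter[("X", "Y")]) == 4

    def test_single_taxon_no_inter(self):
        dm, tmap = self._dm(["AAAA", "AAAT"], ["X", "X"])
        part = intra_inter_partition(dm, tmap)
        assert part.inter == {}

    def test_unmapped_label_raises(self):
        dm, _ = self._dm(["AAAA", "AAAT"], ["X", "X"])
        with pytest.raises(KeyError):
            intra_inter_partition(dm, {"s0": "X"})

    def test_partition_matches_exhaustive_scan_on_simulation(
        self, birth_death_dataset
    ):
        ds = birth_death_dataset
        aln = ds.clone_alignment(include_reference=False)
        dm = distance_matrix(aln)
        part = intra_inter_partition(dm, ds.taxon_map)
        # brute-force scan
        for taxon in part.intra:
            members = [l for l in dm.labels if ds.taxon_map[l] == taxon]
            expected = max(
                dm.value(a, b) for a, b in itertools.combinations(members, 2)
            )
            assert part.max_intra(taxon) == pytest.approx(expected)
        for (ta, tb) in part.inter:
            a_members = [l for l in dm.labels if ds.taxon_map[l] == ta]
            b_members = [l for l in dm.labels if ds.taxon_map[l] == tb]
            expected = min(
                dm.value(a, b) for a in a_members for b in b_members
            )
            assert part.min_inter(ta, tb) == pytest.approx(expected)

    def test_gap_arithmetic(self):
        # intra maxima {1 diff /8 = 12.5%, 2 diffs /8 = 25%};
        # min inter 5 diffs /8 = 62.5% -> gap = 62.5 - 25 = 37.5
        dm, tmap = self._dm(
            ["AAAAAAAA", "AAAAAAAT", "TTTTTAAA", "TTTTTATT"],
            ["X", "X", "Y", "Y"],
        )
        report = barcode_gap_report(dm, tmap)
        p = report.pair("X", "Y")
        assert p.max_intra_a == pytest.approx(12.5)
        assert p.max_intra_b == pytest.approx(25.0)
        assert p.min_inter == pytest.approx(62.5)
        assert p.gap == pytest.approx(37.5)
        assert p.gap_present

    def test_negative_gap_not_present(self):
        dm, tmap = self._dm(
            ["AAAAAAAA", "TTTTTAAA", "AAAAAAAT", "AAAAATAT"],
            ["X", "X", "Y", "Y"],
        )
        report = barcode_gap_report(dm, tmap)
        assert not report.pair("X", "Y").gap_present

    def test_singleton_taxon_flagged_not_dropped(self):
        dm, tmap = self._dm(
            ["AAAAAAAA", "AAAAAAAT", "TTTTAAAA"], ["X", "X", "Y"]
        )
        report = barcode_gap_report(dm, tmap)
        p = report.pair("X", "Y")
        assert p.singleton and p.gap is None and p.gap_present is None


class TestSimilarityFilter:
    def test_threshold_zero_keeps_exact_matches(self):
        q = rec("q", "ACGTACGTACGTACGTACGT")
        near = rec("n", "ACGTACGTACGTACGTACGT")
        far = rec("f", "ACGTTCGTACGAACGTACTT")
        assert similarity_filter(q, [near, far], 0) == [near]

    def test_five_percent_screen(self):
        rng = np.random.default_rng(23)
        base = "".join(rng.choice(list("ACGT"), size=200))
        q = rec("q", base)
        candidates = []
        for k in range(1, 11):  # 1%..10% divergence in 1% steps
            seq = list(base)
            for pos in rng.choice(200, size=2 * k, replace=False):
                seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            candidates.append(rec(f"d{k}", "".join(seq)))
        kept = similarity_filter(q, candidates, 5.0)
        assert [c.id for c in kept] == ["d1", "d2", "d3", "d4", "d5"]

    def test_alignment_based_distance_handles_indels(self):
        q = rec("q", "ACGTACGTACGTACGTAC")
        cand = rec("c", "ACGTACGTCGTACGTAC")  # one deletion
        d = aligned_pair_distance(q, cand)
        assert d.differences == 0  # gap column excluded, rest identical


class TestHistogram:
    def test_example_bins(self):
        bins = distance_histogram([0, 1, 1, 2], 1.0)
        assert bins == [(0.0, 1.0, 1), (1.0, 2.0, 2), (2.0, 3.0, 1)]

    def test_empty(self):
        assert distance_histogram([], 1.0) == []

    def test_nonpositive_width(self):
        with pytest.raises(ValueError):
            distance_histogram([1.0], 0)

    @given(
        st.lists(st.floats(min_value=0, max_value=60), min_size=1, max_size=100),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_counts_conserve_total(self, values, width):
        bins = distance_histogram(values, width)
        assert sum(c for _, _, c in bins) == len(values)
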