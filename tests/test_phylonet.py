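"""Neighbour joining, neighbour-net and treelikeness statistics."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest

from conftest import box_metric, random_binary_tree
from ribogap.distance import DistanceMatrix
from ribogap.phylonet import (
    Split,
    all_circular_splits,
    circular_ordering,
    delta_score,
    estimate_split_weights,
    neighbour_net,
    nj,
    write_nexus_splits,
)


def tree_split_weights(tree, labels):
    out = {}
    for side, w in tree.splits():
        sp = Split.make(side, labels)
        out[sp] = out.get(sp, 0.0) + w
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        dm = DistanceMatrix.from_square(["a", "b", "c"], D)
        tree = nj(dm)
        lengths = {
            tree.leaf_labels[leaf]: w
            for leaf in tree.leaf_labels
            for _, w in tree.adjacency[leaf]
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_four_taxon_additive_recovered_exactly(self):
        rng = np.random.default_rng(2)
        true = random_binary_tree(4, rng)
        dm = true.leaf_distances()
        est = nj(dm)
        assert tree_split_weights(est, dm.labels) == pytest.approx(
            tree_split_weights(true, dm.labels)
        )

    def test_additive_matrices_regenerated(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            true = random_binary_tree(8, rng)
            dm = true.leaf_distances()
            est = nj(dm)
            d2 = est.leaf_distances()
            perm = [d2.labels.index(l) for l in dm.labels]
            assert np.abs(
                dm.percent - d2.percent[np.ix_(perm, perm)]
            ).max() < 1e-9

    def test_tie_break_deterministic(self):
        # ultrametric with symmetric tie: joins must pick the lexicographically
        # first minimal pair, and repeated runs agree
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            float,
        )
        dm = DistanceMatrix.from_square(list("abcd"), D)
        n1 = nj(dm).newick()
        n2 = nj(dm).newick()
        assert n1 == n2
        # both resolutions fit the matrix equally; the produced tree must
        # still reproduce it exactly
        d2 = nj(dm).leaf_distances()
        perm = [d2.labels.index(l) for l in dm.labels]
        assert np.abs(dm.percent - d2.percent[np.ix_(perm, perm)]).max() < 1e-9

    def test_negative_lengths_clamped(self):
        D = np.array(
            [[0, 1, 1, 10], [1, 0, 1, 10], [1, 1, 0, 1], [10, 10, 1, 0]], float
        )
        dm = DistanceMatrix.from_square(list("abcd"), D)
        tree = nj(dm)
        for nbrs in tree.adjacency.values():
            for _, w in nbrs:
                assert w >= 0

    def test_too_few_taxa(self):
        dm = DistanceMatrix.from_square(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            nj(dm)

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(4)
        tree = nj(random_binary_tree(6, rng).leaf_distances())
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 6

    def test_against_skbio_oracle(self):
        """Independent NJ implementation (scikit-bio) joins the same
        topology on a noisy matrix (branch-length clamping policies differ,
        so the comparison is on splits)."""
        import skbio

        rng = np.random.default_rng(9)
        # generic matrix: additive plus mild symmetric noise
        true = random_binary_tree(6, rng)
        dm = true.leaf_distances()
        noise = rng.uniform(0, 0.05, size=dm.percent.shape)
        noisy = dm.percent + noise + noise.T
        noisy = (noisy + noisy.T) / 2  # exact float symmetry
        np.fill_diagonal(noisy, 0)
        dmx = DistanceMatrix.from_square(dm.labels, noisy)
        mine = nj(dmx)
        all_taxa = set(dm.labels)
        my_splits = {
            frozenset(side)
            for side, _ in mine.splits()
            if 1 < len(side) < len(all_taxa) - 1
        }
        theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
        their_splits = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_taxa) - 1:
                if min(side) != min(all_taxa):
                    their_splits.add(side)
                else:
                    their_splits.add(frozenset(all_taxa - side))
        assert my_splits == their_splits


class TestNeighbourNet:
    def test_additive_input_returns_tree_splits(self):
        rng = np.random.default_rng(21)
        for n in (5, 7):
            true = random_binary_tree(n, rng)
            dm = true.leaf_distances()
            ss = neighbour_net(dm)
            expected = tree_split_weights(true, dm.labels)
            got = {s: w for s, w in zip(ss.splits, ss.weights) if w > 1e-6}
            assert set(got) == set(expected)
            for sp, w in expected.items():
                assert got[sp] == pytest.approx(w, abs=1e-6)
            assert ss.residual_norm < 1e-6

    def test_box_metric_recovers_both_incompatible_splits(self):
        dm = box_metric(2.0, 3.0, trivial={0: 1.0, 1: 1.2, 2: 0.8, 3: 1.5})
        ss = neighbour_net(dm)
        assert ss.weight_of(["a", "b"]) == pytest.approx(2.0, abs=1e-6)
        assert ss.weight_of(["a", "d"]) == pytest.approx(3.0, abs=1e-6)
        assert ss.weight_of(["a"]) == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        A = rng.uniform(0.5, 3, size=(6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(6)]
        ss1 = neighbour_net(DistanceMatrix.from_square(labels, D))
        perm = rng.permutation(6)
        ss2 = neighbour_net(
            DistanceMatrix.from_square(
                [labels[i] for i in perm], D[np.ix_(perm, perm)]
            )
        )
        w1 = {s.side: round(float(w), 8) for s, w in zip(ss1.splits, ss1.weights)}
        w2 = {s.side: round(float(w), 8) for s, w in zip(ss2.splits, ss2.weights)}
        assert w1 == w2

    def test_circular_ordering_contains_all_taxa_once(self):
        rng = np.random.default_rng(41)
        true = random_binary_tree(9, rng)
        dm = true.leaf_distances()
        ordering = circular_ordering(dm)
        assert sorted(ordering) == sorted(dm.labels)

    def test_small_n_falls_back_to_nj(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        dm = DistanceMatrix.from_square(["a", "b", "c"], D)
        ss = neighbour_net(dm)
        assert ss.metadata["method"] == "nj-fallback"
        assert ss.weight_of(["c"]) == pytest.approx(3.0)

    @pytest.mark.skipif(
        shutil.which("Rscript") is None, reason="Rscript unavailable"
    )
    def test_against_phangorn_oracle(self, tmp_path):
        """Split weights match the independent R implementation."""
        rng = np.random.default_rng(7)
        n = 7
        A = rng.uniform(0.5, 3, size=(n, n))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix.from_square(labels, D)
        ss = neighbour_net(dm)
        mine = {
            tuple(sorted(s.side)): round(float(w), 5)
            for s, w in zip(ss.splits, ss.weights)
        }
        mat = tmp_path / "dm.txt"
        np.savetxt(mat, D)
        script = f'''
suppressMessages(library(phangorn))
D <- as.matrix(read.table("{mat}"))
labs <- paste0("t", 0:(nrow(D)-1))
rownames(D) <- colnames(D) <- labs
nn <- phangorn:::neighborNet(D)
spl <- nn$splits
w <- attr(spl, "weights")
tl <- nn$tip.label
for (i in seq_along(spl)) cat(paste(sort(tl[spl[[i]]]), collapse=","), w[i], "\\n")
'''
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        theirs = {}
        all_taxa = frozenset(labels)
        for line in res.stdout.strip().splitlines():
            side_str, w = line.split()
            side = frozenset(side_str.split(","))
            if "t0" in side:
                side = all_taxa - side
            if float(w) > 1e-9:
                theirs[tuple(sorted(side))] = round(float(w), 5)
        assert set(mine) == set(theirs)
        for k in mine:
            assert mine[k] == pytest.approx(theirs[k], abs=1e-4)


class TestSplitWeights:
    def test_exact_recovery_from_constructed_sum(self):
        rng = np.random.default_rng(55)
        labels = [f"t{i}" for i in range(6)]
        ordering = list(labels)
        splits = all_circular_splits(ordering)
        true_w = rng.uniform(0, 2, size=len(splits))
        true_w[rng.random(len(splits)) < 0.5] = 0.0
        D = np.zeros((6, 6))
        for s, w in zip(splits, true_w):
            for i, j in itertools.combinations(range(6), 2):
                if s.separates(labels[i], labels[j]):
                    D[i, j] += w
                    D[j, i] += w
        dm = DistanceMatrix.from_square(labels, D)
        est, rnorm = estimate_split_weights(dm, splits)
        assert rnorm < 1e-8
        assert est == pytest.approx(true_w, abs=1e-8)

    def test_noise_gives_positive_residual_nonnegative_weights(self):
        rng = np.random.default_rng(66)
        A = rng.uniform(0.5, 2, size=(5, 5))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(5)]
        dm = DistanceMatrix.from_square(labels, D)
        splits = all_circular_splits(labels)
        w, rnorm = estimate_split_weights(dm, splits)
        assert rnorm > 0
        assert np.all(w >= 0)

    def test_duplicate_splits_rejected(self):
        labels = ["a", "b", "c", "d"]
        s = Split.make(["a", "b"], labels)
        dm = box_metric(1, 1)
        with pytest.raises(ValueError):
            estimate_split_weights(dm, [s, s])

    def test_single_split_weight_one(self):
        labels = ["a", "b", "c", "d"]
        D = np.zeros((4, 4))
        for i, j in itertools.combinations(range(4), 2):
            if (i < 2) != (j < 2):
                D[i, j] = D[j, i] = 1.0
        dm = DistanceMatrix.from_square(labels, D)
        w, rnorm = estimate_split_weights(dm, [Split.make(["a", "b"], labels)])
        assert w == pytest.approx([1.0])
        assert rnorm < 1e-12


class TestDeltaScore:
    def test_zero_on_additive(self):
        rng = np.random.default_rng(12)
        dm = random_binary_tree(7, rng).leaf_distances()
        stats = delta_score(dm)
        assert stats.mean_delta == pytest.approx(0.0, abs=1e-12)
        assert stats.q_residual == pytest.approx(0.0, abs=1e-12)

    def test_one_on_equal_box_quartet(self):
        dm = box_metric(1.0, 1.0)
        stats = delta_score(dm)
        assert stats.mean_delta == pytest.approx(1.0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(19)
        A = rng.uniform(0.5, 3, size=(8, 8))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix.from_square([f"t{i}" for i in range(8)], D)
        stats = delta_score(dm)
        assert 0 <= stats.mean_delta <= 1
        for v in stats.per_taxon_delta.values():
            assert 0 <= v <= 1

    def test_needs_four_taxa(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        with pytest.raises(ValueError):
            delta_score(DistanceMatrix.from_square(["a", "b", "c"], D))


def test_nexus_splits_export(tmp_path):
    dm = box_metric(2.0, 3.0, trivial={0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0})
    ss = neighbour_net(dm)
    out = tmp_path / "splits.nex"
    write_nexus_splits(ss, out)
    text = out.read_text()
    assert text.startswith("#NEXUS")
    assert "BEGIN Splits;" in text
    assert f"nsplits={len(ss.splits)}" in text
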