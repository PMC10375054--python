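"""Distance matrices, AMOVA, pairwise Phi_ST, d_xy and NJ trees."""

import itertools

import numpy as np
import pytest

import mitopop as mp
from mitopop.errors import InputError, UndefinedStatisticError
from mitopop.structure import (
    PairwiseDistanceMatrix,
    pairwise_diff_comparable,
)
from mitopop.simulate import (
    mutation_counts,
    pairwise_differences_from_genealogy,
    simulate_genealogy,
)

from conftest import random_alignment


class TestPairwiseDifferences:
    def test_identical_and_simple_pairs(self):
        aln = mp.SequenceAlignment(
            ("a", "b", "c"), ("P",) * 3, ("AAAA", "AAAA", "AATT")
        )
        d = mp.pairwise_difference_matrix(aln)
        assert d.matrix[0, 1] == 0
        assert d.matrix[0, 2] == 2

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(42)
        aln = random_alignment(rng, n=8, L=20, missing_rate=0.1)
        d = mp.pairwise_difference_matrix(aln).matrix
        for i, j in itertools.combinations(range(8), 2):
            expected = sum(
                1
                for x, y in zip(aln.sequences[i], aln.sequences[j])
                if x in "ACGT" and y in "ACGT" and x != y
            )
            assert d[i, j] == expected == d[j, i]

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            PairwiseDistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(InputError):
            PairwiseDistanceMatrix(("a", "b"), np.array([[1.0, 0.0], [0.0, 0.0]]))


def amova_oracle(d, groups):
    """Explicit-loop sums of squares, independent of the package's vectorised path."""
    n = d.shape[0]
    p = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        ss_within += sum(
            d[i, j] ** 2 for i, j in itertools.combinations(g, 2)
        ) / len(g)
    ss_among = ss_total - ss_within
    vb = ss_within / (n - p)
    nbar = (n - sum(len(g) ** 2 for g in groups) / n) / (p - 1)
    va = (ss_among / (p - 1) - vb) / nbar
    return va, vb, ss_among, ss_within


class TestAmova:
    def test_fixed_difference_gives_phi_one(self):
        aln = mp.SequenceAlignment(
            ("a", "b", "c", "d"),
            ("P1", "P1", "P2", "P2"),
            ("AAAA", "AAAA", "AAAT", "AAAT"),
        )
        res = mp.amova(
            mp.pairwise_difference_matrix(aln), aln.populations, n_perm=0
        )
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.df_among == 1 and res.df_within == 2

    def test_components_match_explicit_loop_oracle(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, n=9, L=25)
        pops = ["A"] * 3 + ["B"] * 2 + ["C"] * 4
        dist = mp.pairwise_difference_matrix(aln)
        res = mp.amova(dist, pops, n_perm=0)
        groups = [[0, 1, 2], [3, 4], [5, 6, 7, 8]]
        va, vb, ss_a, ss_w = amova_oracle(dist.matrix, groups)
        assert res.va == pytest.approx(va, rel=1e-12)
        assert res.vb == pytest.approx(vb, rel=1e-12)
        assert res.ss_among == pytest.approx(ss_a, rel=1e-12)
        assert res.ss_within == pytest.approx(ss_w, rel=1e-12)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=0.01)
        assert res.phi_st == pytest.approx(va / (va + vb), rel=1e-12)

    def test_permutation_pvalue_reproducible(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, n=12, L=30, n_pops=2)
        dist = mp.pairwise_difference_matrix(aln)
        r1 = mp.amova(dist, aln.populations, n_perm=200, seed=11)
        r2 = mp.amova(dist, aln.populations, n_perm=200, seed=11)
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_all_zero_distances_give_nan(self):
        aln = mp.SequenceAlignment(
            ("a", "b", "c", "d"), ("P", "P", "Q", "Q"), ("AAAA",) * 4
        )
        with pytest.warns(UserWarning):
            res = mp.amova(
                mp.pairwise_difference_matrix(aln), aln.populations, n_perm=100
            )
        assert np.isnan(res.phi_st) and np.isnan(res.p_value)

    def test_random_labels_of_one_pool_center_on_zero(self):
        rng = np.random.default_rng(21)
        phis = []
        for _ in range(300):
            gen = simulate_genealogy(20, rng)
            muts = mutation_counts(gen, 5.0, rng)
            d = pairwise_differences_from_genealogy(gen, muts)
            if d.max() == 0:
                continue
            labels = np.array(["A"] * 10 + ["B"] * 10)
            rng.shuffle(labels)
            dist = PairwiseDistanceMatrix(tuple(map(str, range(20))), d)
            phis.append(mp.amova(dist, labels, n_perm=0).phi_st)
        assert abs(np.mean(phis)) < 0.03


class TestPairwisePhist:
    def test_fixed_difference_pair(self):
        aln = mp.SequenceAlignment(
            ("a", "b", "c", "d"),
            ("P1", "P1", "P2", "P2"),
            ("AAAA", "AAAA", "TTAA", "TTAA"),
        )
        phi, p = mp.pairwise_phist(
            mp.pairwise_difference_matrix(aln), aln.populations, n_perm=50, seed=0
        )
        assert phi.loc["P1", "P2"] == pytest.approx(1.0)

    def test_identical_composition_near_zero(self):
        aln = mp.SequenceAlignment(
            tuple(f"s{i}" for i in range(8)),
            ("P1",) * 4 + ("P2",) * 4,
            ("AAAA", "AAAT", "AAAA", "AAAT") * 2,
        )
        phi, p = mp.pairwise_phist(
            mp.pairwise_difference_matrix(aln), aln.populations, n_perm=200, seed=5
        )
        assert phi.loc["P1", "P2"] <= 0.0  # no among-population signal
        assert p.loc["P1", "P2"] > 0.2


class TestDxy:
    def test_identical_monomorphic_pops(self):
        aln = mp.SequenceAlignment(
            ("a", "b"), ("P", "Q"), ("AAAAAAAAAA", "AAAAAAAAAA")
        )
        assert mp.dxy(aln, "P", "Q") == 0.0

    def test_single_fixed_difference(self):
        aln = mp.SequenceAlignment(
            ("a", "b"), ("P", "Q"), ("AAAAAAAAAA", "AAAAAAAAAT")
        )
        assert mp.dxy(aln, "P", "Q") == pytest.approx(0.1)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, n=7, L=12, n_pops=2, missing_rate=0.1)
        pops = set(aln.populations)
        if len(pops) < 2:
            pytest.skip("need two populations in draw")
        a, b = sorted(pops)
        fracs = []
        for i, j in itertools.product(range(7), range(7)):
            if aln.populations[i] != a or aln.populations[j] != b:
                continue
            si, sj = aln.sequences[i], aln.sequences[j]
            comp = sum(1 for x, y in zip(si, sj) if x in "ACGT" and y in "ACGT")
            d = sum(
                1 for x, y in zip(si, sj) if x in "ACGT" and y in "ACGT" and x != y
            )
            if comp:
                fracs.append(d / comp)
        assert mp.dxy(aln, a, b) == pytest.approx(np.mean(fracs), abs=1e-12)


class TestNJ:
    def test_two_taxa_single_edge(self):
        t = mp.nj_tree(
            PairwiseDistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        )
        assert t.path_length_matrix().loc["A", "B"] == 3.0

    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        t = mp.nj_tree(PairwiseDistanceMatrix(("A", "B", "C", "D"), D))
        plm = t.path_length_matrix().to_numpy()
        assert np.abs(plm - D).max() < 1e-9
        assert t.splits() == {frozenset({"C", "D"})}

    def test_agrees_with_biopython_on_random_additive_matrix(self):
        # independent oracle: Biopython's NJ on the same matrix
        from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

        rng = np.random.default_rng(2)
        # random additive matrix from a random 6-taxon tree built by
        # attaching taxa with random positive branch lengths
        names = ["t1", "t2", "t3", "t4", "t5", "t6"]
        import networkx as nx

        g = nx.Graph()
        g.add_edge("t1", "x1", length=rng.uniform(0.5, 2))
        g.add_edge("t2", "x1", length=rng.uniform(0.5, 2))
        g.add_edge("x1", "x2", length=rng.uniform(0.5, 2))
        g.add_edge("t3", "x2", length=rng.uniform(0.5, 2))
        g.add_edge("x2", "x3", length=rng.uniform(0.5, 2))
        g.add_edge("t4", "x3", length=rng.uniform(0.5, 2))
        g.add_edge("x3", "x4", length=rng.uniform(0.5, 2))
        g.add_edge("t5", "x4", length=rng.uniform(0.5, 2))
        g.add_edge("t6", "x4", length=rng.uniform(0.5, 2))
        D = np.zeros((6, 6))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    D[i, j] = D[j, i] = nx.shortest_path_length(
                        g, a, b, weight="length"
                    )
        ours = mp.nj_tree(PairwiseDistanceMatrix(tuple(names), D))
        assert np.abs(ours.path_length_matrix().to_numpy() - D).max() < 1e-9
        bio_dm = DistanceMatrix(
            names, [[float(D[i, j]) for j in range(i + 1)] for i in range(6)]
        )
        bio_tree = DistanceTreeConstructor().nj(bio_dm)
        # compare leaf-to-leaf path lengths
        for a, b in itertools.combinations(names, 2):
            assert bio_tree.distance(a, b) == pytest.approx(
                ours.path_length_matrix().loc[a, b], abs=1e-9
            )

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            aln = random_alignment(rng, n=6, L=15)
            t = mp.nj_tree(mp.pairwise_difference_matrix(aln))
            assert all(d["length"] >= 0 for _, _, d in t.graph.edges(data=True))

    def test_star_like_haplotypes_give_shallow_tree(self):
        # one centre, five 1-step satellites: all internal branches ~ 0
        centre = "A" * 20
        seqs = [centre] + [centre[:i] + "T" + centre[i + 1 :] for i in range(5)]
        aln = mp.SequenceAlignment(
            tuple(f"h{i}" for i in range(6)), ("P",) * 6, tuple(seqs)
        )
        t = mp.nj_tree(mp.pairwise_difference_matrix(aln))
        internal = [
            d["length"]
            for u, v, d in t.graph.edges(data=True)
            if not (str(u).startswith("h") or str(v).startswith("h"))
        ]
        assert max(internal, default=0.0) < 1e-9

    def test_newick_parses(self):
        from io import StringIO

        from Bio import Phylo

        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        t = mp.nj_tree(PairwiseDistanceMatrix(("A", "B", "C", "D"), D))
        tree = Phylo.read(StringIO(t.newick()), "newick")
        assert sorted(l.name for l in tree.get_terminals()) == ["A", "B", "C", "D"]


class TestBootstrap:
    def test_clear_split_gets_high_support(self):
        # two 3-haplotype clusters separated by 10 fixed differences
        base = "A" * 40
        far = "T" * 10 + "A" * 30
        cluster1 = [base, base[:20] + "C" + base[21:], base[:25] + "G" + base[26:]]
        cluster2 = [far, far[:30] + "C" + far[31:], far[:35] + "G" + far[36:]]
        aln = mp.SequenceAlignment(
            tuple(f"h{i}" for i in range(6)),
            ("P",) * 6,
            tuple(cluster1 + cluster2),
        )
        tree, support = mp.bootstrap_support(aln, n_reps=100, seed=4)
        split = frozenset({"h3", "h4", "h5"})
        assert split in support
        assert support[split] >= 95.0

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(6)
        aln = random_alignment(rng, n=6, L=30)
        _, support = mp.bootstrap_support(aln, n_reps=1, seed=0)
        assert set(support.values()) <= {0.0, 100.0}

    def test_support_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        aln = random_alignment(rng, n=6, L=30)
        _, s1 = mp.bootstrap_support(aln, n_reps=50, seed=3)
        _, s2 = mp.bootstrap_support(aln, n_reps=50, seed=3)
        assert s1 == s2


def test_pairwise_structure_bundle(table1_aln):
    # small permutation count: exercises the full Table-4-style bundle
    res = mp.pairwise_structure(table1_aln, n_perm=20, seed=1)
    assert res.phi_st.shape == (6, 6)
    assert np.allclose(res.phi_st, res.phi_st.T)
    iu = np.triu_indices(6, k=1)
    assert ((res.p_values.to_numpy()[iu] > 0) & (res.p_values.to_numpy()[iu] <= 1)).all()
    # Holm adjustment never decreases a p-value
    assert (
        res.p_values_holm.to_numpy()[iu] >= res.p_values.to_numpy()[iu] - 1e-12
    ).all()
    assert (res.d_xy.to_numpy() >= 0).all()
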