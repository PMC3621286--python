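"""Tree engine: NJ, K80 pruning likelihood, NNI search, bootstrap, monophyly."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from wildmeat.phylo import (
    MLConfig,
    Tree,
    bootstrap,
    collapse_low_support,
    estimate_kappa,
    from_newick,
    k80_transition_matrix,
    loglik,
    ml_tree,
    monophyly,
    nj,
    nj_from_alignment,
    nni_neighbors,
    nni_search,
    optimize_branch_lengths,
    to_newick,
)
from wildmeat.seq_io import Alignment, Sequence
from wildmeat.synthetic_data import evolve


def leaf_distances(tree: Tree) -> dict[tuple[str, str], float]:
    """Path lengths between all tip pairs (independent of topology encoding)."""
    tips = tree.tips()
    out = {}
    for a, b in itertools.combinations(sorted(tips), 2):
        # BFS path length
        start, goal = tips[a], tips[b]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, l in tree.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        out[(a, b)] = dist[goal]
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj(["A", "B", "C"], D)
        d = leaf_distances(t)
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        assert d[("A", "B")] == pytest.approx(3)
        assert d[("A", "C")] == pytest.approx(4)
        assert d[("B", "C")] == pytest.approx(5)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) -> additive matrix
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], float)
        t = nj(["A", "B", "C", "D"], D)
        # brute force: each of the 3 topologies has 5 branch lengths with a
        # closed least-squares fit; the additive one fits exactly
        best = _best_lsq_quartet(["A", "B", "C", "D"], D)
        assert t.splits() == {best}
        d = leaf_distances(t)
        for (a, b), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert d[(a, b)] == pytest.approx(expected)

    def test_additive_matrix_from_random_tree_recovers_splits(self):
        rng = np.random.default_rng(4)
        # random 6-taxon additive matrix built from a known tree
        true = from_newick(
            "((A:0.1,B:0.2):0.05,((C:0.15,D:0.1):0.08,E:0.3):0.04,F:0.2);"
        )
        labels = sorted(true.tip_labels())
        d = leaf_distances(true)
        n = len(labels)
        D = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = d[(a, b)]
        t = nj(labels, D)
        assert t.splits() == true.splits()

    def test_all_equal_matrix_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj(["A", "B", "C", "D"], D)
        t2 = nj(["A", "B", "C", "D"], D)
        assert to_newick(t1) == to_newick(t2)
        # internal branch has zero length
        (u, v), = t1.internal_edges()
        assert t1.adj[u][v] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(["A", "B"], np.zeros((2, 2)))


def _best_lsq_quartet(labels, D):
    """Least-squares oracle over the three quartet topologies."""
    best = None
    for pair in itertools.combinations(range(4), 2):
        i, j = pair
        k, l = [x for x in range(4) if x not in pair]
        # topology ij|kl; unknowns: li, lj, lk, ll, m (internal)
        A, y = [], []
        rows = {
            (i, j): [1, 1, 0, 0, 0],
            (i, k): [1, 0, 1, 0, 1],
            (i, l): [1, 0, 0, 1, 1],
            (j, k): [0, 1, 1, 0, 1],
            (j, l): [0, 1, 0, 1, 1],
            (k, l): [0, 0, 1, 1, 0],
        }
        for (a, b), row in rows.items():
            A.append(row)
            y.append(D[a, b])
        sol, res, *_ = np.linalg.lstsq(np.array(A, float), np.array(y), rcond=None)
        rss = float(np.sum((np.array(A) @ sol - np.array(y)) ** 2))
        split = frozenset({labels[i], labels[j]})
        if best is None or rss < best[0]:
            best = (rss, split)
    # canonical: side not containing the smallest label
    all_labels = frozenset(labels)
    split = best[1]
    return all_labels - split if min(labels) in split else split


class TestLoglik:
    def _two_tip_tree(self, t):
        tr = Tree()
        a = tr.new_node("a")
        b = tr.new_node("b")
        tr.add_edge(a, b, t)
        return tr

    def test_two_taxon_closed_form(self):
        # one transition, one transversion, two identical sites
        aln = Alignment([Sequence("a", "ACGT"), Sequence("b", "GCTT")])
        t, kappa = 0.3, 4.0
        P = k80_transition_matrix(t, kappa)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = sum(
            math.log(0.25 * P[idx[x], idx[y]])
            for x, y in zip("ACGT", "GCTT")
        )
        got = loglik(self._two_tip_tree(t), aln, kappa)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_identical_sequences_zero_branches(self):
        aln = Alignment([Sequence("a", "ACGTAC"), Sequence("b", "ACGTAC")])
        got = loglik(self._two_tip_tree(0.0), aln, 4.0)
        assert got == pytest.approx(6 * math.log(0.25), abs=1e-9)

    def test_kappa_one_equals_jukes_cantor_oracle(self):
        # independent JC pruning via matrix exponential of the JC generator
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(4)]
        aln = Alignment([Sequence(n, s) for n, s in zip("ABCD", seqs)])
        tree = from_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.15);")
        got = loglik(tree, aln, kappa=1.0)
        Q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(Q, -1.0)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}

        def jc_pruning(node, parent):
            if node in tree.labels:
                seq = dict(zip("ABCD", seqs))[tree.labels[node]]
                L = np.zeros((30, 4))
                for s, ch in enumerate(seq):
                    L[s, idx[ch]] = 1.0
            else:
                L = np.ones((30, 4))
            for nb, length in tree.adj[node].items():
                if nb == parent:
                    continue
                P = expm(Q * length)
                L = L * (jc_pruning(nb, node) @ P.T)
            return L

        root = tree.tips()["A"]
        L = jc_pruning(root, None)
        expected = float(np.log(0.25 * L.sum(axis=1)).sum())
        assert got == pytest.approx(expected, abs=1e-8)

    def test_transition_matrix_rows_sum_to_one(self):
        for t in (0.0, 0.1, 1.0, 10.0):
            P = k80_transition_matrix(t, 4.0)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.all(P >= 0)

    def test_invariant_under_tip_permutation_and_rerooting(self):
        rng = np.random.default_rng(3)
        seqs = {n: "".join(rng.choice(list("ACGT"), size=40)) for n in "ABCDE"}
        newick = "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08,E:0.3);"
        tree = from_newick(newick)
        base = loglik(
            Alignmentify(seqs, "ABCDE"), tree=tree
        ) if False else loglik(tree, Alignmentify(seqs, "ABCDE"), 3.0)
        # permuted alignment order
        perm = loglik(tree, Alignmentify(seqs, "EDCBA"), 3.0)
        assert perm == pytest.approx(base, abs=1e-9)
        # re-rooted (different newick embedding of the same unrooted tree)
        tree2 = from_newick("((C:0.15,D:0.1):0.08,(A:0.1,B:0.2):0.05,E:0.3);")
        assert loglik(tree2, Alignmentify(seqs, "ABCDE"), 3.0) == pytest.approx(
            base, abs=1e-9
        )

    def test_ambiguity_marginalizes_over_bases(self):
        # R at one site = sum of the A and G site likelihoods
        t, kappa = 0.2, 4.0
        tree = self._two_tip_tree(t)
        lR = loglik(tree, Alignment([Sequence("a", "R"), Sequence("b", "A")]), kappa)
        lA = loglik(tree, Alignment([Sequence("a", "A"), Sequence("b", "A")]), kappa)
        lG = loglik(tree, Alignment([Sequence("a", "G"), Sequence("b", "A")]), kappa)
        assert math.exp(lR) == pytest.approx(math.exp(lA) + math.exp(lG), rel=1e-9)


def Alignmentify(seqs: dict, order: str) -> Alignment:
    return Alignment([Sequence(n, seqs[n]) for n in order])


def _simulated_five_taxon(seed=5, n_sites=600):
    rng = np.random.default_rng(seed)
    root = "".join(rng.choice(list("ACGT"), size=n_sites))
    anc1 = evolve(root, 0.08, 4.0, rng)
    anc2 = evolve(root, 0.08, 4.0, rng)
    seqs = {
        "A": evolve(anc1, 0.06, 4.0, rng),
        "B": evolve(anc1, 0.06, 4.0, rng),
        "C": evolve(anc2, 0.06, 4.0, rng),
        "D": evolve(anc2, 0.06, 4.0, rng),
        "E": evolve(root, 0.12, 4.0, rng),
    }
    aln = Alignment([Sequence(n, s) for n, s in seqs.items()])
    true_splits = {frozenset({"C", "D", "E"}), frozenset({"C", "D"})}
    return aln, true_splits


def _all_five_taxon_topologies():
    """All 15 unrooted binary topologies on 5 tips, as newick strings."""
    out = []
    # choose the cherry {x,y}, then the attachment of z on the quartet
    for cherry in itertools.combinations("ABCDE", 2):
        rest = [t for t in "ABCDE" if t not in cherry]
        for other_pair in itertools.combinations(rest, 2):
            last = [t for t in rest if t not in other_pair][0]
            out.append(
                f"(({cherry[0]}:0.1,{cherry[1]}:0.1):0.1,"
                f"({other_pair[0]}:0.1,{other_pair[1]}:0.1):0.1,{last}:0.1);"
            )
    # dedupe by split set
    seen, unique = set(), []
    for nwk in out:
        t = from_newick(nwk)
        key = frozenset(t.splits())
        if key not in seen:
            seen.add(key)
            unique.append(nwk)
    assert len(unique) == 15
    return unique


class TestNNISearch:
    def test_search_never_decreases_loglik(self):
        aln, _ = _simulated_five_taxon()
        start = nj_from_alignment(aln)
        start_ll = optimize_branch_lengths(start.copy(), aln, 4.0)
        _, ll = nni_search(start, aln, kappa=4.0)
        assert ll >= start_ll - 1e-9

    def test_recovers_generating_topology_vs_exhaustive(self):
        aln, true_splits = _simulated_five_taxon()
        tree, ll = nni_search(nj_from_alignment(aln), aln, kappa=4.0)
        assert tree.splits() == true_splits
        # exhaustive oracle over all 15 topologies
        best_nwk, best_ll = None, -math.inf
        for nwk in _all_five_taxon_topologies():
            t = from_newick(nwk)
            cand = optimize_branch_lengths(t, aln, 4.0, rounds=5)
            if cand > best_ll:
                best_nwk, best_ll = nwk, cand
        assert from_newick(best_nwk).splits() == true_splits
        assert ll == pytest.approx(best_ll, abs=0.05)

    def test_identical_sequences_flat_likelihood(self):
        aln = Alignment([Sequence(n, "ACGTACGT") for n in "ABCDE"])
        tree = from_newick("((A:0,B:0):0,(C:0,D:0):0,E:0);")
        lls = {loglik(nb, aln, 4.0) for nb in nni_neighbors(tree)}
        assert all(
            ll == pytest.approx(loglik(tree, aln, 4.0), abs=1e-9) for ll in lls
        )

    def test_kappa_estimate_recovers_simulation_ratio(self):
        aln, _ = _simulated_five_taxon(seed=9, n_sites=2000)
        k = estimate_kappa(nj_from_alignment(aln), aln)
        assert 2.0 < k < 8.0  # generated with kappa=4


class TestBootstrap:
    def test_conserved_split_signal_gives_full_support(self):
        # two clear groups differing at 8 of 60 sites (4 ts + 4 tv)
        shared = "ACGT" * 13
        g1 = "AAAACCCC"
        g2 = "GGGGAAAA"
        a = g1 + shared
        b = g1 + shared[:-1] + "A"
        c = g2 + shared
        d = g2 + shared[:-1] + "A"
        aln = Alignment([
            Sequence("a", a), Sequence("b", b),
            Sequence("c", c), Sequence("d", d),
        ])
        tree = bootstrap(aln, nj_from_alignment, B=50, seed=1)
        (split,) = tree.splits()
        assert tree.support[split] == 100.0

    def test_single_replicate_support_binary(self):
        aln, _ = _simulated_five_taxon()
        tree = bootstrap(aln, nj_from_alignment, B=1, seed=2)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        aln, _ = _simulated_five_taxon()
        t1 = bootstrap(aln, nj_from_alignment, B=200, seed=7)
        t2 = bootstrap(aln, nj_from_alignment, B=200, seed=7)
        assert t1.support == t2.support
        assert all(0.0 <= s <= 100.0 for s in t1.support.values())

    def test_invalid_replicates_rejected(self):
        aln, _ = _simulated_five_taxon()
        with pytest.raises(ValueError):
            bootstrap(aln, nj_from_alignment, B=0)

    def test_collapse_below_threshold(self):
        aln, _ = _simulated_five_taxon()
        tree = bootstrap(aln, nj_from_alignment, B=50, seed=3)
        tree.support = {s: 40.0 for s in tree.splits()}
        collapsed = collapse_low_support(tree, 50.0)
        assert collapsed.splits() == set()


class TestMonophyly:
    def test_simple_cases(self):
        tree = from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        assert monophyly(tree, {"A1", "A2"})[0] is True
        assert monophyly(tree, {"A1", "B1"})[0] is False
        assert monophyly(tree, {"A1"}) == (True, None)
        assert monophyly(tree, {"A1", "A2", "B1", "B2"}) == (True, None)

    def test_unknown_tip_rejected(self):
        tree = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(KeyError):
            monophyly(tree, {"A", "Z"})

    def test_matches_dendropy_bipartition_oracle(self):
        import dendropy

        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(8)]
        for rep in range(10):
            # random topology by random sequential joins
            tree = Tree()
            nodes = [tree.new_node(l) for l in labels]
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                u = tree.new_node()
                tree.add_edge(nodes[i], u, 1.0)
                tree.add_edge(nodes[j], u, 1.0)
                nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [u]
            center = tree.new_node()
            for n in nodes:
                tree.add_edge(n, center, 1.0)

            dtree = dendropy.Tree.get(
                data=to_newick(tree, with_support=False), schema="newick"
            )
            dtree.encode_bipartitions()
            taxa = {t.label: t for t in dtree.taxon_namespace}
            all_bitmask = dtree.taxon_namespace.all_taxa_bitmask()
            dendropy_splits = {
                b.split_bitmask & all_bitmask for b in dtree.bipartition_encoding
            }
            for _ in range(20):
                k = int(rng.integers(2, 7))
                subset = set(rng.choice(labels, size=k, replace=False))
                got, _ = monophyly(tree, subset)
                mask = 0
                for lab in subset:
                    mask |= dtree.taxon_namespace.taxon_bitmask(taxa[lab])
                expected = (
                    mask in dendropy_splits
                    or (mask ^ all_bitmask) in dendropy_splits
                )
                assert got == expected


class TestNewick:
    def test_round_trip_preserves_splits_lengths_support(self):
        aln, _ = _simulated_five_taxon()
        tree = bootstrap(aln, nj_from_alignment, B=20, seed=4)
        back = from_newick(to_newick(tree))
        assert back.splits() == tree.splits()
        assert back.support == tree.support
        d1, d2 = leaf_distances(tree), leaf_distances(back)
        for k in d1:
            assert d2[k] == pytest.approx(d1[k], abs=1e-5)
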