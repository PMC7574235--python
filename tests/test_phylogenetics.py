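import numpy as np
import pytest
from skbio import DistanceMatrix

from famtrace import phylogenetics as ph
from famtrace.phylogenetics import MSA, _bipartitions
from famtrace.sequence_io import ProteinRecord, read_newick, write_newick

from _oracles import naive_global_score
from conftest import random_protein


class TestGlobalAlign:
    def test_identical_sequences_no_gaps(self):
        ga, gb, score = ph.global_align("MKVLW", "MKVLW")
        assert ga == gb == "MKVLW"
        assert score == 5 + 5 + 4 + 4 + 11  # BLOSUM62 diagonal

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ph.global_align("A", "")

    @pytest.mark.parametrize("seed", range(20))
    def test_score_matches_naive_recursion(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(2, 8)), start_m=False).seq
        b = random_protein(rng, int(rng.integers(2, 8)), start_m=False).seq
        _, _, score = ph.global_align(a, b)
        assert score == naive_global_score(a, b)


class TestCenterStar:
    def test_two_sequences_reduce_to_pairwise(self):
        a, b = ProteinRecord("a", "MKVLWAAC"), ProteinRecord("b", "MKVWAAC")
        msa = ph.center_star_msa([a, b])
        ga, gb, _ = ph.global_align(a.seq, b.seq)
        assert msa.rows == [ga, gb]

    def test_identical_sequences_gap_free(self):
        recs = [ProteinRecord(c, "MKVLWAAC") for c in "abc"]
        msa = ph.center_star_msa(recs)
        assert all(row == "MKVLWAAC" for row in msa.rows)

    def test_ungapping_recovers_inputs(self, rng):
        recs = [random_protein(rng, int(rng.integers(20, 40))) for _ in range(4)]
        msa = ph.center_star_msa(recs)
        for rec, row in zip(recs, msa.rows):
            assert row.replace("-", "") == rec.seq

    def test_center_choice_not_worse_than_alternatives(self, rng):
        """Sum-of-pairs of the center-star MSA is at least that of building
        the star around any non-center sequence (checked on triples)."""
        def sum_of_pairs(msa):
            total = 0
            from famtrace._scoring import score_columns, load_matrix
            for i in range(len(msa.rows)):
                for j in range(i + 1, len(msa.rows)):
                    a, b = msa.rows[i], msa.rows[j]
                    cols = [(x, y) for x, y in zip(a, b)
                            if not (x == "-" and y == "-")]
                    total += score_columns("".join(x for x, _ in cols),
                                           "".join(y for _, y in cols),
                                           load_matrix(), -11, -1)
            return total

        from famtrace import synthetic_data as syn

        base = random_protein(rng, 60)
        for trial in range(10):
            recs = [syn.mutate_protein(base, float(rng.uniform(0.6, 0.9)),
                                       int(rng.integers(2 ** 31)))
                    for _ in range(3)]
            recs = [ProteinRecord(f"r{trial}_{i}", r.seq)
                    for i, r in enumerate(recs)]
            best = sum_of_pairs(ph.center_star_msa(recs))
            alternatives = [sum_of_pairs(ph.center_star_msa(recs, center=k))
                            for k in range(3)]
            assert best >= max(alternatives) - 1e-9


class TestTrim:
    def test_gap_free_unchanged(self):
        msa = MSA(["a", "b"], ["MKVLW", "MKVLW"])
        out = ph.trim_alignment(msa)
        assert out.rows == msa.rows

    def test_gappy_row_removed(self):
        msa = MSA(["a", "b", "c"],
                  ["MKVLWMKVLW", "MKVLWMKVLW", "M---------"])
        out = ph.trim_alignment(msa, max_gap_fraction=0.5)
        assert out.ids == ["a", "b"]

    def test_too_few_survivors_rejected(self):
        msa = MSA(["a", "b"], ["M---", "MKVL"])
        with pytest.raises(ValueError):
            ph.trim_alignment(msa, max_gap_fraction=0.5)

    def test_long_internal_gap_becomes_missing(self):
        core = "M" * 30 + "-" * 40 + "M" * 30
        other = "M" * 30 + "A" * 40 + "M" * 30
        msa = MSA(["a", "b"], [core, other])
        out = ph.trim_alignment(msa, internal_gap_run=20)
        assert "?" * 40 in out.row("a")
        assert "-" not in out.row("a")

    def test_never_increases_ungapped_length(self, rng):
        recs = [random_protein(rng, 30) for _ in range(4)]
        msa = ph.center_star_msa(recs)
        out = ph.trim_alignment(msa)
        for sid in out.ids:
            before = msa.row(sid).replace("-", "")
            after = out.row(sid).replace("-", "").replace("?", "")
            assert len(after) <= len(before)


class TestDistances:
    def test_identical_rows_zero(self):
        msa = MSA(["a", "b"], ["MKVLW", "MKVLW"])
        dm = ph.distance_matrix(msa, "p")
        assert dm["a", "b"] == 0

    def test_half_mismatch_arithmetic(self):
        msa = MSA(["a", "b"], ["MK", "MV"])
        assert ph.distance_matrix(msa, "p")["a", "b"] == pytest.approx(0.5)
        assert ph.distance_matrix(msa, "poisson")["a", "b"] == pytest.approx(
            -np.log(0.5))

    def test_gaps_and_missing_excluded(self):
        msa = MSA(["a", "b"], ["MK-L?", "MKALW"])
        assert ph.distance_matrix(msa, "p")["a", "b"] == 0

    def test_no_shared_columns_rejected(self):
        msa = MSA(["a", "b"], ["M---", "---W"])
        with pytest.raises(ValueError, match="a"):
            ph.distance_matrix(msa, "p")


class TestNeighborJoining:
    ADDITIVE = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                         [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)

    def test_additive_four_taxon_exact(self):
        """NJ recovers topology ((A,B),(C,D)) and every path length of the
        generating tree ((A:1,B:2):1,(C:3,D:4))."""
        dm = DistanceMatrix(self.ADDITIVE, ids=["A", "B", "C", "D"])
        tree = ph.neighbor_joining(dm)
        assert _bipartitions(tree) == {frozenset({"C", "D"})}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.distance(a, b) == pytest.approx(
                        self.ADDITIVE[i, j])

    def test_three_leaves_unique_topology(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                     dtype=float), ids=list("abc"))
        tree = ph.neighbor_joining(dm)
        assert sorted(l.name for l in tree.get_terminals()) == ["a", "b", "c"]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_topology_recovery(self, seed):
        tree = _random_tree(np.random.default_rng(seed), 8)
        leaves = [l.name for l in tree.get_terminals()]
        mat = np.zeros((8, 8))
        for i, a in enumerate(tree.get_terminals()):
            for j, b in enumerate(tree.get_terminals()):
                if i < j:
                    mat[i, j] = mat[j, i] = tree.distance(a, b)
        rec = ph.neighbor_joining(DistanceMatrix(mat, ids=leaves))
        assert _bipartitions(rec) == _bipartitions(tree)

    def test_agrees_with_reference_nj(self):
        """Cross-check against the independent scikit-bio implementation."""
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(77)
        tree = _random_tree(rng, 6)
        leaves = [l.name for l in tree.get_terminals()]
        mat = np.zeros((6, 6))
        for i, a in enumerate(tree.get_terminals()):
            for j, b in enumerate(tree.get_terminals()):
                if i < j:
                    mat[i, j] = mat[j, i] = tree.distance(a, b)
        dm = DistanceMatrix(mat, ids=leaves)
        ours = ph.neighbor_joining(dm)
        ref = skbio_nj(dm)
        ref_splits = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            anchor = min(leaves)
            if anchor in side:
                side = frozenset(leaves) - side
            if 1 < len(side) < len(leaves) - 1:
                ref_splits.add(side)
        assert _bipartitions(ours) == ref_splits


def _random_tree(rng, n):
    from Bio.Phylo.BaseTree import Clade, Tree

    nodes = [Clade(name=f"t{i}", branch_length=float(rng.uniform(0.1, 2.0)))
             for i in range(n)]
    while len(nodes) > 2:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        a, b = nodes.pop(j), nodes.pop(i)
        nodes.append(Clade(branch_length=float(rng.uniform(0.1, 2.0)),
                           clades=[a, b]))
    return Tree(root=Clade(clades=nodes), rooted=True)


class TestFitch:
    def test_single_column_split(self):
        msa = MSA(list("ABCD"), ["A", "A", "T", "T"])
        tree = read_newick("((A,B),(C,D));")
        assert ph.fitch_parsimony_score(tree, msa) == 1

    def test_identical_column_zero(self):
        msa = MSA(list("ABCD"), ["A", "A", "A", "A"])
        assert ph.fitch_parsimony_score(read_newick("((A,B),(C,D));"), msa) == 0

    def test_gap_is_a_state_and_missing_is_free(self):
        tree = read_newick("((A,B),(C,D));")
        assert ph.fitch_parsimony_score(tree, MSA(list("ABCD"),
                                                  ["A", "A", "-", "-"])) == 1
        assert ph.fitch_parsimony_score(tree, MSA(list("ABCD"),
                                                  ["A", "A", "?", "?"])) == 0

    def test_invariant_under_rerooting(self, rng):
        msa = MSA([f"t{i}" for i in range(6)],
                  ["".join(rng.choice(list("ACDEF-"), 30)) for _ in range(6)])
        tree = _random_tree(np.random.default_rng(4), 6)
        base = ph.fitch_parsimony_score(tree, msa)
        for leaf in list(tree.get_terminals()):
            t2 = _random_tree(np.random.default_rng(4), 6)
            t2.root_with_outgroup({"name": leaf.name})
            assert ph.fitch_parsimony_score(t2, msa) == base

    def test_lower_bound_property(self, rng):
        msa = MSA([f"t{i}" for i in range(6)],
                  ["".join(rng.choice(list("ACDEF"), 20)) for _ in range(6)])
        tree = _random_tree(np.random.default_rng(9), 6)
        lower = sum(len({r[c] for r in msa.rows}) - 1
                    for c in range(msa.n_columns))
        assert ph.fitch_parsimony_score(tree, msa) >= lower

    def test_missing_leaf_row_rejected(self):
        with pytest.raises(ValueError):
            ph.fitch_parsimony_score(read_newick("((A,B),(C,E));"),
                                     MSA(list("ABCD"), ["A"] * 4))


class TestBootstrap:
    def _signal_msa(self):
        # every column supports ((a,b),(c,d))
        rows = ["AAAA", "AAAA", "CCCC", "CCCC", "GGGG"]
        return MSA(list("abcde"), rows)

    def test_unanimous_signal_full_support(self):
        msa = MSA(list("abcd"), ["AAAAAAAA", "AAAAAAAA",
                                 "CCCCCCCC", "CCCCCCCC"])
        tree = ph.bootstrap_support(msa, n_reps=20, seed=1,
                                    collapse_cutoff=50)
        confidences = [c.confidence for c in tree.get_nonterminals()
                       if c.confidence is not None]
        assert confidences and all(c == 100.0 for c in confidences)

    def test_zero_cutoff_never_collapses(self, rng):
        rows = ["".join(rng.choice(list("ACDE"), 30)) for _ in range(5)]
        msa = MSA([f"s{i}" for i in range(5)], rows)
        full = ph.bootstrap_support(msa, n_reps=10, seed=2, collapse_cutoff=0)
        plain = ph.default_tree_builder(msa)
        assert len(full.get_nonterminals()) == len(plain.get_nonterminals())

    def test_fixed_seed_reproducible(self, rng):
        rows = ["".join(rng.choice(list("ACDE"), 40)) for _ in range(5)]
        msa = MSA([f"s{i}" for i in range(5)], rows)
        t1 = ph.bootstrap_support(msa, n_reps=30, seed=7)
        t2 = ph.bootstrap_support(msa, n_reps=30, seed=7)
        assert write_newick(t1) == write_newick(t2)
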