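"""Ancestral reconstruction, altAll, topology and parsimony behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calgevo import (
    AMINO_ACIDS,
    Alignment,
    AltAllPolicy,
    PhyloTree,
    PosteriorTable,
    SimSpec,
    build_altall,
    compare_across_topologies,
    count_differences,
    enumerate_clade_topologies,
    fitch_parsimony,
    marginal_asr,
    marginal_posteriors_enumeration,
    n_rooted_topologies,
    simulate_msa,
)
from calgevo.phylo_asr import ASRError, fitch_parsimony_bruteforce

from conftest import random_alignment, random_tree


# ------------------------------------------------------------- marginal ASR


class TestMarginalASR:
    def test_zero_branch_lengths_force_identity(self):
        tree = PhyloTree.from_newick("((A:0,B:0):0,C:0);")
        aln = Alignment(["A", "B", "C"], ["A", "A", "A"])
        table = marginal_asr(tree, aln)[tree.root.name]
        assert table.probs[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert table.ml_sequence == "A"

    def test_symmetric_tips_give_symmetric_posteriors(self):
        tree = PhyloTree.from_newick("((t1:0.1,t2:0.1):0.1,(t3:0.1,t4:0.1):0.1);")
        aln = Alignment(["t1", "t2", "t3", "t4"], ["A", "A", "C", "C"])
        table = marginal_asr(tree, aln)[tree.root.name]
        pA = table.probs[0, AMINO_ACIDS.index("A")]
        pC = table.probs[0, AMINO_ACIDS.index("C")]
        assert pA == pytest.approx(pC, abs=1e-12)

    def test_five_leaf_posteriors_match_enumeration(self):
        tree = PhyloTree.from_newick(
            "(((A:0.1,B:0.1):0.1,C:0.1):0.1,(D:0.1,E:0.1):0.1);"
        )
        aln = Alignment(["A", "B", "C", "D", "E"], ["A", "A", "A", "C", "C"])
        tables = marginal_asr(tree, aln)
        oracle = marginal_posteriors_enumeration(tree, aln, site=1)
        for node, expected in oracle.items():
            np.testing.assert_allclose(
                tables[node].probs[0], expected, atol=1e-10
            )

    @pytest.mark.parametrize("trial", range(10))
    def test_random_trees_match_enumeration(self, trial):
        """Pruning equals exhaustive enumeration on random small trees."""
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(3, 6))
        tree = random_tree(rng, n)
        aln = random_alignment(rng, tree.leaf_names, n_sites=2)
        tables = marginal_asr(tree, aln)
        for site in (1, 2):
            oracle = marginal_posteriors_enumeration(tree, aln, site)
            for node, expected in oracle.items():
                np.testing.assert_allclose(
                    tables[node].probs[site - 1], expected, atol=1e-10
                )

    def test_gamma_rates_match_enumeration(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 4)
        aln = random_alignment(rng, tree.leaf_names, n_sites=1)
        tables = marginal_asr(tree, aln, gamma_shape=0.5)
        oracle = marginal_posteriors_enumeration(tree, aln, 1, gamma_shape=0.5)
        for node, expected in oracle.items():
            np.testing.assert_allclose(tables[node].probs[0], expected, atol=1e-10)

    def test_gap_sites_skipped_with_warning(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        aln = Alignment(["A", "B", "C"], ["A-", "AC", "AC"])
        with pytest.warns(UserWarning, match="gap"):
            tables = marginal_asr(tree, aln)
        table = tables[tree.root.name]
        assert table.gap_sites == (2,)
        assert table.ml_sequence[1] == "-"
        assert np.isnan(table.probs[1]).all()

    def test_missing_leaf_sequence_raises(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        aln = Alignment(["A", "B"], ["A", "A"])
        with pytest.raises(ASRError, match="without sequences"):
            marginal_asr(tree, aln)

    def test_reconstruction_accuracy_on_short_branches(self, spec):
        """ML ancestors recover the true states on slowly evolving data."""
        rng = np.random.default_rng(11)
        tree = random_tree(rng, 6, max_bl=0.1)
        aln, true_anc = simulate_msa(spec, tree, n_sites=200)
        tables = marginal_asr(tree, aln)
        matched = total = 0
        for node, truth in true_anc.items():
            ml = tables[node].ml_sequence
            matched += sum(a == b for a, b in zip(ml, truth))
            total += len(truth)
        assert matched / total >= 0.95


# ------------------------------------------------------------------ altAll


def _table(rows, node="anc"):
    return PosteriorTable(node=node, probs=np.asarray(rows, dtype=float))


def _two_state_row(p_ml, p_alt, ml="A", alt="C"):
    row = np.zeros(20)
    rest = (1.0 - p_ml - p_alt) / 18.0
    row[:] = rest
    row[AMINO_ACIDS.index(ml)] = p_ml
    row[AMINO_ACIDS.index(alt)] = p_alt
    return row


class TestAltAll:
    def test_runner_up_above_threshold_substituted(self):
        table = _table([_two_state_row(0.70, 0.25)])
        recon = build_altall(table)
        assert recon.altall_sequence == "C"
        assert recon.substituted_sites == (1,)

    def test_threshold_boundary_is_strict(self):
        row = np.zeros(20)
        row[AMINO_ACIDS.index("A")] = 0.80
        row[AMINO_ACIDS.index("C")] = 0.20
        recon = build_altall(_table([row]), AltAllPolicy(threshold=0.20))
        assert recon.altall_sequence == recon.ml_sequence == "A"
        assert recon.substituted_sites == ()

    def test_substitution_count_on_constructed_table(self):
        """Runner-up PPs {0.25, 0.21, 0.30} at 3 of 10 sites -> 3 swaps."""
        rows = []
        hot = {0: 0.25, 4: 0.21, 9: 0.30}
        for i in range(10):
            p_alt = hot.get(i, 0.10)
            rows.append(_two_state_row(1.0 - p_alt - 0.05, p_alt))
        recon = build_altall(_table(rows))
        assert recon.n_substitutions == 3
        assert recon.substituted_sites == (1, 5, 10)
        assert count_differences(recon.ml_sequence, recon.altall_sequence) == 3

    def test_non_normalized_table_rejected(self):
        row = np.zeros(20)
        row[0] = 0.5
        with pytest.raises(ASRError, match="sums to"):
            build_altall(_table([row]))

    def test_swapping_top_states_is_idempotent(self):
        """Rebuilding from a top-two-swapped table returns the ML sequence,
        never a third state."""
        rng = np.random.default_rng(21)
        probs = rng.dirichlet(np.full(20, 0.3), size=30)
        table = _table(probs)
        recon = build_altall(table)
        swapped = probs.copy()
        for site in recon.substituted_sites:
            row = swapped[site - 1]
            i, j = np.argsort(row)[-2:]
            row[i], row[j] = row[j], row[i]
        recon2 = build_altall(_table(swapped))
        for site in recon.substituted_sites:
            assert recon2.altall_sequence[site - 1] == recon.ml_sequence[site - 1]
            assert recon2.ml_sequence[site - 1] == recon.altall_sequence[site - 1]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_substituted_sites_match_hamming_distance(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.full(20, 0.5), size=15)
        recon = build_altall(_table(probs))
        assert recon.n_substitutions == count_differences(
            recon.ml_sequence, recon.altall_sequence
        )

    def test_average_posterior_is_mean_of_ml_state(self):
        probs = np.zeros((2, 20))
        probs[0, 0] = 0.9
        probs[0, 1:] = 0.1 / 19
        probs[1, 1] = 0.7
        probs[1, [0] + list(range(2, 20))] = 0.3 / 19
        assert _table(probs).average_posterior == pytest.approx(0.8)


class TestCountDifferences:
    def test_identity_and_single_mismatch(self):
        assert count_differences("ACDE", "ACDE") == 0
        assert count_differences("ACD", "ACE") == 1
        assert count_differences("AC-", "ACD") == 1  # gap vs residue counts

    def test_length_mismatch_raises(self):
        with pytest.raises(ASRError, match="lengths differ"):
            count_differences("ACD", "AC")


# --------------------------------------------------------------- topologies


class TestTopologies:
    def test_four_clades_give_fifteen_topologies(self):
        trees = enumerate_clade_topologies(["A8", "A9", "A12", "MRP126"])
        assert len(trees) == 15
        newicks = {t.to_newick(include_lengths=False) for t in trees}
        assert len(newicks) == 15  # all distinct after canonicalization

    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_count_matches_double_factorial(self, n, expected):
        names = [f"c{i}" for i in range(n)]
        assert len(enumerate_clade_topologies(names)) == expected
        assert n_rooted_topologies(n) == expected

    def test_duplicate_names_rejected(self):
        with pytest.raises(ASRError, match="duplicate"):
            enumerate_clade_topologies(["A", "A"])

    def test_compare_across_topologies(self):
        ref_probs = np.tile(np.eye(20)[0], (10, 1))  # all-A reference
        for site in (3, 8):  # altAll set {4, 9}
            ref_probs[site] = _two_state_row(0.7, 0.25)
        ref = build_altall(_table(ref_probs))
        assert ref.substituted_sites == (4, 9)
        seqs = {
            "t1": ref.ml_sequence[:3] + "C" + ref.ml_sequence[4:],  # differs at 4
            "t2": ref.ml_sequence[:3] + "C" + ref.ml_sequence[4:8] + "C"
            + ref.ml_sequence[9:],  # differs at 4 and 9
        }
        cmp = compare_across_topologies(seqs, ref)
        assert cmp.counts == {"t1": 1, "t2": 2}
        assert cmp.mean_differences == pytest.approx(1.5)
        assert cmp.union_sites == (4, 9)
        assert cmp.within_altall_set

    def test_identical_reconstructions_give_zero(self):
        ref = build_altall(_table(np.tile(np.eye(20)[0], (5, 1))))
        cmp = compare_across_topologies(
            {"a": ref.ml_sequence, "b": ref.ml_sequence}, ref
        )
        assert cmp.counts == {"a": 0, "b": 0}
        assert cmp.mean_differences == 0.0
        assert cmp.union_sites == ()


# ---------------------------------------------------------------- parsimony


class TestFitchParsimony:
    def test_uniform_tips_need_no_changes(self, calgranulin_tree):
        traits = {name: "resistant" for name in calgranulin_tree.leaf_names}
        fit = fitch_parsimony(calgranulin_tree, traits)
        assert fit.root_states == frozenset({"resistant"})
        assert fit.n_changes == 0

    def test_calgranulin_pattern_gives_resistant_root(self, calgranulin_tree):
        """Susceptible A8/A9 with resistant A12/MRP126 implies a resistant
        ancestor with a single loss of resistance."""
        traits = {
            "A8": "susceptible",
            "A9": "susceptible",
            "A12": "resistant",
            "MRP126": "resistant",
        }
        fit = fitch_parsimony(calgranulin_tree, traits)
        assert fit.root_states == frozenset({"resistant"})
        assert fit.n_changes == 1
        assert fit.n_changes == fitch_parsimony_bruteforce(calgranulin_tree, traits)

    def test_single_leaf_tree(self):
        tree = PhyloTree.from_newick("A;")
        fit = fitch_parsimony(tree, {"A": "resistant"})
        assert fit.root_states == frozenset({"resistant"})
        assert fit.n_changes == 0

    def test_unassigned_leaf_raises(self, calgranulin_tree):
        with pytest.raises(ASRError, match="without trait"):
            fitch_parsimony(calgranulin_tree, {"A8": "resistant"})

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5, 6])
    def test_matches_bruteforce_on_random_trees(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(20):
            tree = random_tree(rng, n_leaves)
            traits = {
                name: ["resistant", "susceptible"][rng.integers(2)]
                for name in tree.leaf_names
            }
            fit = fitch_parsimony(tree, traits)
            assert fit.n_changes == fitch_parsimony_bruteforce(tree, traits)
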