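"""Ancestral reconstruction: marginal ML, parsimony, substitution mapping."""

import itertools

import numpy as np
import pytest

from codonsel.alignment import CodonAlignment
from codonsel.ancestral import (AncestralStates,
                                branch_substitutions, fitch_parsimony,
                                lineage_specific_substitutions,
                                marginal_reconstruct)
from codonsel.engine import CodonModelParams, build_rate_matrix, \
    estimate_frequencies, transition_probabilities
from codonsel.genetics import AA_INDEX, AMINO_ACIDS, codon_to_aa_matrix
from codonsel.models import CodonModelFit, fit_branch_model
from codonsel.simulate import SimConfig, simulate_alignment
from codonsel.tree import TreeError, read_tree
from conftest import ladder_tree


def _fit_for(aln, tree, kappa=2.0, omega=0.4):
    pi = estimate_frequencies(aln)
    return CodonModelFit("one-ratio", 0.0, 0, kappa, pi, "F3x4", tree,
                         omega_by_class={0: omega})


class TestMarginalML:
    def test_shared_residue_reconstructed(self):
        aln = CodonAlignment.from_sequences(
            [("A", "ATGGGG"), ("B", "ATGGGA"), ("C", "ATGGGC")]
        )
        tree = read_tree("((A:0.1,B:0.1):0.05,C:0.1);")
        anc = marginal_reconstruct(aln, _fit_for(aln, tree))
        for node in (tree.mrca(["A", "B"]), tree.root):
            aa, bpp = anc.map_state(node.index, 1)
            assert aa == "M" and bpp > 0.99
            aa, bpp = anc.map_state(node.index, 2)
            assert aa == "G" and bpp > 0.99

    def test_matches_enumeration_oracle(self, code):
        """Node posteriors equal brute-force summation over all internal
        codon assignments on a 3-taxon tree."""
        rng = np.random.default_rng(3)
        sense = code.sense_codons
        aln = CodonAlignment.from_sequences(
            [(n, "".join(rng.choice(sense, 5))) for n in "ABC"]
        )
        tree = read_tree("((A:0.2,B:0.3):0.1,C:0.25);")
        fit = _fit_for(aln, tree)
        anc = marginal_reconstruct(aln, fit)

        pi = fit.pi
        q = build_rate_matrix(pi, fit.kappa, 0.4, code)
        pa = transition_probabilities(q, 0.2, pi)
        pb = transition_probabilities(q, 0.3, pi)
        pint = transition_probabilities(q, 0.1, pi)
        pc = transition_probabilities(q, 0.25, pi)
        collapse = codon_to_aa_matrix(code)
        idx = aln.codon_indices()
        inner = tree.mrca(["A", "B"])
        for s in range(5):
            a, b, c = idx[:, s]
            post_i = np.zeros(61)
            post_r = np.zeros(61)
            for r in range(61):
                for i in range(61):
                    w = pi[r] * pint[r, i] * pa[i, a] * pb[i, b] * pc[r, c]
                    post_i[i] += w
                    post_r[r] += w
            np.testing.assert_allclose(
                anc.posteriors[inner.index][s], collapse.T @ (post_i / post_i.sum()),
                atol=1e-8)
            np.testing.assert_allclose(
                anc.posteriors[tree.root.index][s], collapse.T @ (post_r / post_r.sum()),
                atol=1e-8)

    def test_posteriors_normalized(self, small_aln, small_tree):
        anc = marginal_reconstruct(small_aln, _fit_for(small_aln, small_tree))
        for node_idx, post in anc.posteriors.items():
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)


class TestFitchParsimony:
    def test_textbook_example(self):
        tree = read_tree("((A,B),C);")
        res = fitch_parsimony({"A": "G", "B": "G", "C": "A"}, tree)
        assert res.state_sets[tree.mrca(["A", "B"]).index][0] == frozenset("G")
        assert res.changes_per_site[0] == 1

    def test_root_tie_reported_not_broken(self):
        tree = read_tree("((A,B),(C,D));")
        res = fitch_parsimony({"A": "G", "B": "G", "C": "A", "D": "A"}, tree)
        assert res.state_sets[tree.root.index][0] == frozenset({"A", "G"})
        placements = [p for p in res.placements if p[1] == 1]
        assert all(p[4] for p in placements)  # every placement flagged ambiguous

    @pytest.mark.parametrize("seed", range(4))
    def test_count_matches_exhaustive_minimization(self, seed):
        """Hartigan substitution counts equal the minimum over all internal
        labelings, enumerated exhaustively on a 5-taxon tree."""
        rng = np.random.default_rng(seed)
        states = "ACD"
        tips = {t: rng.choice(list(states)) for t in "ABCDE"}
        tree = read_tree("(((A,B),(C,D)),E);")
        res = fitch_parsimony({t: s for t, s in tips.items()}, tree)

        internals = [n for n in tree.nodes if not n.is_tip]
        best = np.inf
        for labels in itertools.product(states, repeat=len(internals)):
            assign = {n.index: lab for n, lab in zip(internals, labels)}
            for t, s in tips.items():
                assign[tree.find(t).index] = s
            changes = sum(
                assign[n.index] != assign[n.parent.index] for n in tree.branches
            )
            best = min(best, changes)
        assert res.changes_per_site[0] == best

    def test_agrees_with_ml_on_low_divergence(self, uniform_pi):
        """For sites with a single unambiguous change on slowly evolving
        data, parsimony and marginal ML give the same ancestral call."""
        agree = total = 0
        for seed in range(20):
            tree = ladder_tree(6, tip_len=0.03, inner_len=0.02)
            params = CodonModelParams(2.0, {0: 0.3}, uniform_pi)
            sim = simulate_alignment(SimConfig(tree, params, 150, seed=500 + seed))
            fit = fit_branch_model(sim.alignment, tree, "one-ratio", n_restarts=0)
            anc = marginal_reconstruct(sim.alignment, fit)
            pars = fitch_parsimony(sim.alignment.translate(), fit.tree)
            for s in np.nonzero(pars.changes_per_site == 1)[0]:
                for node in fit.tree.nodes:
                    if node.is_tip or len(pars.state_sets[node.index][s]) != 1:
                        continue
                    total += 1
                    aa, _ = anc.map_state(node.index, s + 1)
                    agree += aa in pars.state_sets[node.index][s]
        assert total > 100
        assert agree / total >= 0.95


class TestBranchSubstitutions:
    def _constructed_states(self, support):
        """Two-node chain with one site whose endpoint posteriors give the
        requested joint support for a Q→R replacement."""
        tree = read_tree("(A:0.1,B:0.1);")
        n = len(AMINO_ACIDS)
        p_parent = np.full((1, n), (1 - np.sqrt(support)) / (n - 1))
        p_parent[0, AA_INDEX["Q"]] = np.sqrt(support)
        p_child = np.full((1, n), (1 - np.sqrt(support)) / (n - 1))
        p_child[0, AA_INDEX["R"]] = np.sqrt(support)
        posts = {tree.root.index: p_parent}
        for node in tree.branches:
            posts[node.index] = p_child
        return AncestralStates(tree, posts)

    def test_threshold_excludes_and_includes(self):
        anc = self._constructed_states(support=0.95)
        assert branch_substitutions(anc, support_threshold=0.99) == []
        events = branch_substitutions(anc, support_threshold=0.9)
        assert {(e.ancestral, e.derived) for e in events} == {("Q", "R")}
        assert all(0.9 <= e.support <= 1 for e in events)

    def test_constant_alignment_empty(self):
        aln = CodonAlignment.from_sequences([("A", "ATG"), ("B", "ATG"), ("C", "ATG")])
        tree = read_tree("((A:0.1,B:0.1):0.1,C:0.1);")
        anc = marginal_reconstruct(aln, _fit_for(aln, tree))
        assert branch_substitutions(anc, 0.5) == []


class TestLineageSpecific:
    def _setup(self):
        # clade (A,B) carries derived V at site 2; others carry ancestral I
        seqs = {"A": "ATGGTT", "B": "ATGGTC", "C": "ATGATT", "D": "ATGATC"}
        aln = CodonAlignment.from_sequences(list(seqs.items()))
        tree = read_tree("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.1);")
        fit = _fit_for(aln, tree, omega=0.5)
        anc = marginal_reconstruct(aln, fit)
        events = branch_substitutions(anc, 0.5)
        return aln, fit, anc, events

    def test_clade_specific_retained(self):
        aln, fit, anc, events = self._setup()
        focal = fit.tree.mrca(["A", "B"])
        kept = lineage_specific_substitutions(events, aln, fit.tree, focal)
        assert {(e.site, e.derived) for e in kept} == {(2, "V")}

    def test_derived_state_outside_clade_dropped(self):
        seqs = {"A": "ATGGTT", "B": "ATGGTC", "C": "ATGATT", "D": "ATGGTA"}
        aln = CodonAlignment.from_sequences(list(seqs.items()))
        tree = read_tree("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.1);")
        fit = _fit_for(aln, tree, omega=0.5)
        anc = marginal_reconstruct(aln, fit)
        events = branch_substitutions(anc, 0.3)
        focal = fit.tree.mrca(["A", "B"])
        kept = lineage_specific_substitutions(events, aln, fit.tree, focal)
        assert all(e.derived != "V" for e in kept)

    def test_clade_branch_mismatch(self):
        aln, fit, anc, events = self._setup()
        focal = fit.tree.mrca(["A", "B"])
        with pytest.raises(TreeError):
            lineage_specific_substitutions(events, aln, fit.tree, focal,
                                           clade=["A", "C"])
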