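"""Branch-pair convergence classification and significance tests."""

import numpy as np
import pytest

from codonsel.ancestral import AncestralStates
from codonsel.convergence import (classify_pair_site, convergence_null_test,
                                  expected_parallel_test, total_convergence)
from codonsel.engine import CodonModelParams
from codonsel.genetics import AA_INDEX, AMINO_ACIDS
from codonsel.models import fit_branch_model
from codonsel.simulate import SimConfig, simulate_alignment
from codonsel.tree import TreeError, read_tree
from conftest import ladder_tree

N_AA = len(AMINO_ACIDS)


def _point(aa):
    v = np.zeros(N_AA)
    v[AA_INDEX[aa]] = 1.0
    return v


def _states_from(tree, node_site_aa):
    """AncestralStates with point-mass posteriors; node_site_aa maps node
    index -> string of amino acids over sites."""
    posts = {}
    for idx, seq in node_site_aa.items():
        posts[idx] = np.stack([_point(a) for a in seq])
    return AncestralStates(tree, posts)


@pytest.fixture
def quartet():
    """((A,B),(C,D)): the branches to A and C are a valid non-nested pair."""
    tree = read_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
    ab = tree.mrca(["A", "B"])
    cd = tree.mrca(["C", "D"])
    root = tree.root
    return tree, ab, cd, root


class TestClassification:
    def test_parallel_point_mass(self, quartet):
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {
            root.index: "Q", ab.index: "R", cd.index: "R",
            tree.find("A").index: "R", tree.find("C").index: "R",
            tree.find("B").index: "Q", tree.find("D").index: "Q",
        })
        cls = classify_pair_site(anc, (ab, cd), 1)
        assert cls.parallel == pytest.approx(1.0)
        assert cls.convergent == pytest.approx(0.0)
        assert cls.divergent == pytest.approx(0.0)

    def test_convergent_point_mass(self, quartet):
        tree, ab, cd, root = quartet
        # make ancestral states differ: K→R on one branch, Q→R on the other
        anc = _states_from(tree, {
            root.index: "K", ab.index: "R", cd.index: "R",
            tree.find("A").index: "R", tree.find("B").index: "K",
            tree.find("C").index: "R", tree.find("D").index: "Q",
        })
        # override the cd parent (root) posterior seen from cd: use tips as pair
        a_branch = tree.find("A")
        c_branch = tree.find("C")
        anc2 = _states_from(tree, {
            root.index: "K", ab.index: "K", cd.index: "Q",
            a_branch.index: "R", tree.find("B").index: "K",
            c_branch.index: "R", tree.find("D").index: "Q",
        })
        cls = classify_pair_site(anc2, (a_branch, c_branch), 1)
        assert cls.convergent == pytest.approx(1.0)
        assert cls.parallel == pytest.approx(0.0)

    def test_divergent_point_mass(self, quartet):
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {
            root.index: "Q", ab.index: "R", cd.index: "H",
            tree.find("A").index: "R", tree.find("B").index: "Q",
            tree.find("C").index: "H", tree.find("D").index: "Q",
        })
        cls = classify_pair_site(anc, (ab, cd), 1)
        assert cls.divergent == pytest.approx(1.0)
        assert cls.parallel + cls.convergent == pytest.approx(0.0)

    def test_nested_pair_rejected(self, quartet):
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {n.index: "Q" for n in tree.nodes})
        with pytest.raises(TreeError):
            classify_pair_site(anc, (ab, tree.find("A")), 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_on_fuzzy_posteriors(self, quartet, seed):
        """Vectorized classification equals the exhaustive 20⁴ summation."""
        tree, ab, cd, root = quartet
        rng = np.random.default_rng(seed)
        posts = {n.index: rng.dirichlet(np.full(N_AA, 0.3), size=1) for n in tree.nodes}
        anc = AncestralStates(tree, posts)
        cls = classify_pair_site(anc, (ab, cd), 1)

        a1 = posts[root.index][0]
        d1 = posts[ab.index][0]
        a2 = posts[root.index][0]
        d2 = posts[cd.index][0]
        par = conv = div = 0.0
        for x1 in range(N_AA):
            for y1 in range(N_AA):
                if y1 == x1:
                    continue
                for x2 in range(N_AA):
                    for y2 in range(N_AA):
                        if y2 == x2:
                            continue
                        w = a1[x1] * d1[y1] * a2[x2] * d2[y2]
                        if y1 == y2 and x1 == x2:
                            par += w
                        elif y1 == y2:
                            conv += w
                        else:
                            div += w
        assert cls.parallel == pytest.approx(par, abs=1e-10)
        assert cls.convergent == pytest.approx(conv, abs=1e-10)
        assert cls.divergent == pytest.approx(div, abs=1e-10)


class TestTotals:
    def test_point_mass_totals_are_counts(self, quartet):
        tree, ab, cd, root = quartet
        # 3 sites: parallel, divergent, no change on cd branch
        anc = _states_from(tree, {
            root.index: "QQA", ab.index: "RHA", cd.index: "RLA",
            tree.find("A").index: "RHA", tree.find("B").index: "QQA",
            tree.find("C").index: "RLA", tree.find("D").index: "QQA",
        })
        tc, td, sites, _ = total_convergence(anc, (ab, cd))
        assert tc == pytest.approx(1.0)
        assert td == pytest.approx(1.0)
        assert [s for s, _, _ in sites] == [1]

    def test_symmetric_in_pair_order(self, quartet):
        tree, ab, cd, root = quartet
        rng = np.random.default_rng(8)
        posts = {n.index: rng.dirichlet(np.ones(N_AA), size=4) for n in tree.nodes}
        anc = AncestralStates(tree, posts)
        t1 = total_convergence(anc, (ab, cd))[:2]
        t2 = total_convergence(anc, (cd, ab))[:2]
        assert t1 == pytest.approx(t2)

    def test_no_shared_derived_states_zero(self, quartet):
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {
            root.index: "QK", ab.index: "RK", cd.index: "QW",
            tree.find("A").index: "RK", tree.find("B").index: "QK",
            tree.find("C").index: "QW", tree.find("D").index: "QK",
        })
        tc, _, sites, _ = total_convergence(anc, (ab, cd))
        assert tc == pytest.approx(0.0)
        assert sites == []


class TestNullSimulationTest:
    def test_deterministic_under_seed(self, uniform_pi):
        tree = ladder_tree(6)
        params = CodonModelParams(2.0, {0: 0.2}, uniform_pi)
        sim = simulate_alignment(SimConfig(tree, params, 100, seed=31))
        fit = fit_branch_model(sim.alignment, tree, "one-ratio", n_restarts=0)
        pair = (fit.tree.find("t0"), fit.tree.find("t3"))
        p1, obs1, _ = convergence_null_test(sim.alignment, fit, pair, n_sim=20, seed=9)
        p2, obs2, _ = convergence_null_test(sim.alignment, fit, pair, n_sim=20, seed=9)
        assert p1 == p2 and obs1 == obs2
        assert 1 / 21 <= p1 <= 1.0


class TestExpectedCount:
    def test_no_shared_sites(self, quartet):
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {n.index: "Q" for n in tree.nodes})
        assert expected_parallel_test(anc, (ab, cd)) == (0.0, 0, 1.0, 1.0)

    def test_equal_process_hand_values(self, quartet):
        """One parallel site from the same ancestral state: the chance of a
        match under the uniform process is 1/19."""
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {
            root.index: "Q", ab.index: "R", cd.index: "R",
            tree.find("A").index: "R", tree.find("B").index: "Q",
            tree.find("C").index: "R", tree.find("D").index: "Q",
        })
        expected, observed, p, corr = expected_parallel_test(anc, (ab, cd))
        assert expected == pytest.approx(1 / 19)
        assert observed == 1
        from scipy.stats import poisson

        assert p == pytest.approx(float(poisson.sf(0, 1 / 19)))

    def test_different_ancestors_hand_value(self, quartet):
        """Convergence from different ancestral states: 18 shared targets
        out of 19×19 combinations."""
        tree, ab, cd, root = quartet
        a_branch, c_branch = tree.find("A"), tree.find("C")
        anc = _states_from(tree, {
            root.index: "K", ab.index: "K", cd.index: "Q",
            a_branch.index: "R", tree.find("B").index: "K",
            c_branch.index: "R", tree.find("D").index: "Q",
        })
        expected, observed, _, _ = expected_parallel_test(anc, (a_branch, c_branch))
        assert expected == pytest.approx(18 / (19 * 19))
        assert observed == 1

    def test_correction_monotone_in_pairs(self, quartet):
        tree, ab, cd, root = quartet
        anc = _states_from(tree, {
            root.index: "Q", ab.index: "R", cd.index: "R",
            tree.find("A").index: "R", tree.find("B").index: "Q",
            tree.find("C").index: "R", tree.find("D").index: "Q",
        })
        ps = [expected_parallel_test(anc, (ab, cd), n_pairs_tested=k)[3]
              for k in (1, 2, 4, 50)]
        assert all(ps[i] <= ps[i + 1] for i in range(len(ps) - 1))
        assert ps[-1] <= 1.0
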