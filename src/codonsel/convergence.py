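"""Parallel and convergent substitution detection between branch pairs.

Per site and branch pair, the posterior probability that both branches
underwent an amino-acid substitution is partitioned by the relation between
the endpoint states: *parallel* (same ancestral, same derived), *convergent*
(different ancestral, same derived), and *divergent* (different derived).
Endpoint states are weighted by their marginal reconstruction posteriors,
treated as independent across the four endpoints.

Two significance routes are provided: a parametric-bootstrap null for the
pair's total convergence (simulating convergence-free replicates under a
fitted model and recomputing the statistic), and an expected-count test that
compares the observed number of parallel/convergent sites against its
expectation under a random substitution process, with a Poisson tail
probability and a multiple-testing correction over the branch pairs tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .alignment import CodonAlignment
from .ancestral import AncestralStates, marginal_reconstruct
from .genetics import AMINO_ACIDS
from .models import CodonModelFit
from .simulate import SimConfig, simulate_alignment
from .tree import Node, TreeError


@dataclass
class PairSitePosterior:
    parallel: float
    convergent: float
    divergent: float

    @property
    def both_substituted(self) -> float:
        return self.parallel + self.convergent + self.divergent


@dataclass
class BranchPairConvergence:
    """Full convergence report for one branch pair."""

    branch_names: tuple
    total_convergence: float  # Σ_sites (parallel + convergent)
    total_divergence: float
    parallel_sites: list  # (site, label, posterior)
    sim_p: float | None = None
    n_sim: int | None = None
    expected_parallel: float | None = None
    observed_parallel: int | None = None
    poisson_p: float | None = None
    corrected_p: float | None = None
    per_site: list = field(default_factory=list, repr=False)


def _check_pair(tree, pair):
    b1, b2 = pair
    if b1 is b2 or tree.is_ancestor(b1, b2) or tree.is_ancestor(b2, b1) \
            or b1.parent is b2 or b2.parent is b1:
        raise TreeError("branch pair must be non-nested")
    return b1, b2


def classify_pair_site(anc: AncestralStates, pair, site: int) -> PairSitePosterior:
    """Posterior of {parallel, convergent, divergent} at one site.

    Summation over all endpoint amino-acid assignments, with the four
    endpoint posteriors treated as independent; this makes the computation a
    few 20-vector contractions rather than a 20⁴ loop.
    """
    b1, b2 = _check_pair(anc.tree, pair)
    a1 = anc.posterior(b1.parent.index, site)
    d1 = anc.posterior(b1.index, site)
    a2 = anc.posterior(b2.parent.index, site)
    d2 = anc.posterior(b2.index, site)
    return _classify(a1, d1, a2, d2)


def _classify(a1, d1, a2, d2) -> PairSitePosterior:
    a1, d1, a2, d2 = (v / v.sum() for v in (a1, d1, a2, d2))
    # P(both substitute, same derived d) = Σ_d D1(d)D2(d)(1−A1(d))(1−A2(d))
    same_derived = float(np.sum(d1 * d2 * (1 - a1) * (1 - a2)))
    # parallel additionally requires equal ancestral states ≠ d
    anc_match = a1 * a2
    parallel = float(np.sum(d1 * d2 * (anc_match.sum() - anc_match)))
    convergent = max(0.0, same_derived - parallel)
    both = float((1 - np.sum(a1 * d1)) * (1 - np.sum(a2 * d2)))
    divergent = max(0.0, both - same_derived)
    return PairSitePosterior(parallel, convergent, divergent)


def total_convergence(anc: AncestralStates, pair, parallel_threshold: float = 0.5,
                      numbering=None):
    """Totals over sites for one branch pair.

    Returns (total convergence, total divergence, parallel site list) where
    totals sum the per-site posteriors of (parallel + convergent) and
    divergent, and the site list reports sites whose parallel posterior
    exceeds the threshold together with that posterior (its BPP).
    """
    _check_pair(anc.tree, pair)
    tot_c = tot_d = 0.0
    sites = []
    per_site = []
    for s in range(1, anc.n_sites + 1):
        cls = classify_pair_site(anc, pair, s)
        per_site.append(cls)
        tot_c += cls.parallel + cls.convergent
        tot_d += cls.divergent
        if cls.parallel > parallel_threshold:
            label = numbering.label(s) if numbering else str(s)
            sites.append((s, label, cls.parallel))
    return tot_c, tot_d, sites, per_site


def convergence_null_test(aln: CodonAlignment, fit: CodonModelFit, pair,
                          n_sim: int = 1000, seed: int = 0,
                          observed_total: float | None = None):
    """Parametric-bootstrap p-value for a pair's total convergence.

    Simulates ``n_sim`` convergence-free alignments under the fitted model on
    its ML tree, recomputes the pair's total convergence in each, and returns
    (sim_p, observed, null_totals) with the +1-corrected empirical p-value
    (1 + #{sim ≥ obs}) / (n_sim + 1).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    tree = fit.tree
    b1, b2 = _check_pair(tree, pair)
    if observed_total is None:
        anc = marginal_reconstruct(aln, fit)
        observed_total, _, _, _ = total_convergence(anc, pair)
    null_totals = np.empty(n_sim)
    from .simulate import replicate_seeds

    seeds = replicate_seeds(seed, n_sim)
    for r in range(n_sim):
        sim = simulate_alignment(SimConfig(tree, fit.params, aln.n_codons,
                                           seed=int(seeds[r]), mix=fit.mix))
        anc_r = marginal_reconstruct(sim.alignment, fit)
        null_totals[r], _, _, _ = total_convergence(anc_r, (b1, b2))
    sim_p = (1 + int(np.sum(null_totals >= observed_total))) / (n_sim + 1)
    return sim_p, observed_total, null_totals


def _branch_map_substitutions(anc: AncestralStates, branch: Node):
    """site -> (ancestral MAP aa, derived MAP aa) where they differ."""
    out = {}
    for s in range(1, anc.n_sites + 1):
        a, _ = anc.map_state(branch.parent.index, s)
        d, _ = anc.map_state(branch.index, s)
        if a != d:
            out[s] = (a, d)
    return out


def expected_parallel_test(anc: AncestralStates, pair, process: str = "equal",
                           n_pairs_tested: int = 1):
    """Expected-vs-observed count test for parallel/convergent substitutions.

    For every site carrying a reconstructed substitution on both branches,
    the chance that both end in the same amino acid is accumulated under the
    stated substitution process: ``equal`` draws the derived state uniformly
    from the 19 alternatives; ``empirical`` weights derived states by the
    frequency of derived residues among all substitutions reconstructed on
    the tree.  The observed count is tested against Poisson(expected), upper
    tail, and the p-value is multiplied by the number of branch pairs tested
    (capped at 1).
    """
    b1, b2 = _check_pair(anc.tree, pair)
    subs1 = _branch_map_substitutions(anc, b1)
    subs2 = _branch_map_substitutions(anc, b2)
    shared_sites = sorted(set(subs1) & set(subs2))

    if process == "equal":
        derived_w = np.full(len(AMINO_ACIDS), 1.0)
    elif process == "empirical":
        derived_w = np.full(len(AMINO_ACIDS), 1e-9)
        for br in anc.tree.branches:
            for _, (_, d) in _branch_map_substitutions(anc, br).items():
                derived_w[AMINO_ACIDS.index(d)] += 1.0
    else:
        raise ValueError(f"unknown substitution process: {process}")

    expected = 0.0
    observed = 0
    for s in shared_sites:
        a1, d1 = subs1[s]
        a2, d2 = subs2[s]
        w1 = derived_w.copy()
        w1[AMINO_ACIDS.index(a1)] = 0.0
        w2 = derived_w.copy()
        w2[AMINO_ACIDS.index(a2)] = 0.0
        p_same = float(np.sum((w1 / w1.sum()) * (w2 / w2.sum())))
        expected += p_same
        if d1 == d2:
            observed += 1

    if not shared_sites:
        return 0.0, 0, 1.0, 1.0
    poisson_p = float(poisson.sf(observed - 1, expected)) if observed > 0 else 1.0
    corrected = min(1.0, poisson_p * n_pairs_tested)
    return expected, observed, poisson_p, corrected


def analyze_pair(aln: CodonAlignment, fit: CodonModelFit, pair, *, n_sim: int = 1000,
                 seed: int = 0, process: str = "equal", n_pairs_tested: int = 1,
                 numbering=None, anc: AncestralStates | None = None) -> BranchPairConvergence:
    """One-stop convergence report for a branch pair (totals, bootstrap p,
    expected-count test)."""
    if anc is None:
        anc = marginal_reconstruct(aln, fit)
    tot_c, tot_d, sites, per_site = total_convergence(anc, pair, numbering=numbering)
    sim_p, _, _ = convergence_null_test(aln, fit, pair, n_sim=n_sim, seed=seed,
                                        observed_total=tot_c)
    expected, observed, pois_p, corr_p = expected_parallel_test(
        anc, pair, process=process, n_pairs_tested=n_pairs_tested)
    names = tuple(b.name or f"branch{b.index}" for b in pair)
    return BranchPairConvergence(
        branch_names=names, total_convergence=tot_c, total_divergence=tot_d,
        parallel_sites=sites, sim_p=sim_p, n_sim=n_sim,
        expected_parallel=expected, observed_parallel=observed,
        poisson_p=pois_p, corrected_p=corr_p, per_site=per_site,
    )
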