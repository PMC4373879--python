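"""Codon-model likelihood core.

Implements the Goldman–Yang-type codon substitution model: instantaneous
rates between sense codons differing at one nucleotide, proportional to the
target-codon frequency, multiplied by the transition/transversion ratio κ for
transitions and by ω for nonsynonymous changes.  Branch lengths are in
expected substitutions per codon.  Site-class mixtures (nearly-neutral M1a,
branch-site model A) are handled by summing class likelihoods with their
proportions; branch heterogeneity by giving each branch-class its own ω per
site class.

Likelihoods are computed by Felsenstein pruning over site patterns with
per-node rescaling; transition probabilities come from a symmetric
eigendecomposition of the reversibly-scaled generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .genetics import GeneticCode, codon_structure, standard_code
from .tree import LabeledTree


# ---------------------------------------------------------------------------
# parameters

@dataclass
class CodonModelParams:
    """Parameters of a (possibly branch-heterogeneous) codon model."""

    kappa: float
    omega_by_class: dict  # branch-class mark -> ω
    pi: np.ndarray  # stationary frequencies over sense codons
    frequency_scheme: str = "F3x4"

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError("kappa must be positive and finite")
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi < 0).any():
            raise ValueError("pi must be non-negative and sum to 1")


@dataclass
class SiteClassMix:
    """Site-class mixture: proportions and per-class ω by branch class.

    For branch-site model A the classes are (0, 1, 2a, 2b): ω0 on all
    branches, ω1 = 1 on all branches, and classes 2a/2b which keep ω0
    (resp. 1) on background branches but share ω2 on the foreground.
    """

    proportions: np.ndarray
    omega_maps: list  # per class: dict branch-class -> ω

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-6 or (self.proportions < -1e-12).any():
            raise ValueError("class proportions must be non-negative and sum to 1")
        if len(self.proportions) != len(self.omega_maps):
            raise ValueError("one omega map required per class")

    @classmethod
    def m1a(cls, p0: float, omega0: float) -> "SiteClassMix":
        from collections import defaultdict

        return cls([p0, 1 - p0], [defaultdict(lambda: omega0), defaultdict(lambda: 1.0)])

    @classmethod
    def branch_site_a(cls, p0: float, p1: float, omega0: float, omega2: float,
                      foreground_mark: int = 1) -> "SiteClassMix":
        """Branch-site model A proportions (p2a, p2b in ratio p0:p1)."""
        rest = 1.0 - p0 - p1
        denom = p0 + p1
        p2a = rest * p0 / denom
        p2b = rest * p1 / denom
        fg = foreground_mark
        maps = [
            {0: omega0, fg: omega0},
            {0: 1.0, fg: 1.0},
            {0: omega0, fg: omega2},
            {0: 1.0, fg: omega2},
        ]
        return cls([p0, p1, p2a, p2b], maps)


# ---------------------------------------------------------------------------
# frequencies

def estimate_frequencies(aln: CodonAlignment, scheme: str = "F3x4") -> np.ndarray:
    """Estimate stationary codon frequencies from the alignment.

    F3x4 uses position-specific nucleotide frequencies; F1x4 pools the three
    codon positions; ``equal`` gives the uniform distribution.  Stop-codon
    mass is redistributed by renormalizing over sense codons.
    """
    code = aln.code
    n = code.n_sense
    if scheme == "equal":
        return np.full(n, 1.0 / n)

    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for row in aln.codons:
        for codon in row:
            for pos, b in enumerate(codon):
                if b in base_idx:
                    counts[pos, base_idx[b]] += 1
    if scheme == "F1x4":
        counts = np.tile(counts.sum(axis=0), (3, 1))
    elif scheme != "F3x4":
        raise ValueError(f"unknown frequency scheme: {scheme}")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a codon position has no observed nucleotides")
    freq = counts / counts.sum(axis=1, keepdims=True)

    pi = np.array(
        [freq[0, base_idx[c[0]]] * freq[1, base_idx[c[1]]] * freq[2, base_idx[c[2]]]
         for c in code.sense_codons]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate frequency estimate")
    # floor zero-frequency sense codons: a strictly positive π keeps the
    # reversible eigendecomposition well-conditioned on sparse alignments
    pi = np.maximum(pi / total, 1e-8)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities

def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float,
                      code: GeneticCode | None = None, scale: bool = True) -> np.ndarray:
    """Goldman–Yang generator over sense codons.

    q(i→j) = 0 for multi-nucleotide changes, else ∝ π_j, ×κ for transitions,
    ×ω for nonsynonymous changes; rows sum to zero.  With ``scale`` the matrix
    is normalized to one expected substitution per codon per unit time.
    """
    code = code or standard_code()
    single, transit, synon, _ = codon_structure(code)
    pi = np.asarray(pi, dtype=float)
    q = np.where(single, pi[None, :], 0.0)
    q = np.where(single & transit, q * kappa, q)
    q = np.where(single & ~synon, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = expected_rate(q, pi)
        if rate > 0:
            q = q / rate
    return q


def expected_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time: -Σ π_i q_ii."""
    return float(-(pi * np.diag(q)).sum())


class EigenQ:
    """Eigendecomposition of a reversible generator for fast P(t).

    The generator is symmetrized as D^{1/2} Q D^{-1/2} (D = diag π), which is
    symmetric by detailed balance, so a real eigendecomposition exists.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        self.rate = expected_rate(q, self.pi)
        sqrt_pi = np.sqrt(np.maximum(self.pi, 1e-300))
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)
        w, v = np.linalg.eigh(sym)
        self.eigvals = w
        self._left = v / sqrt_pi[None, :].T  # D^{-1/2} V
        self._right = (v * sqrt_pi[:, None]).T  # V^T D^{1/2}

    def p_matrix(self, t: float) -> np.ndarray:
        if t < 0 or not np.isfinite(t):
            raise ValueError("branch length must be finite and non-negative")
        p = (self._left * np.exp(self.eigvals * t)) @ self._right
        np.maximum(p, 0.0, out=p)
        return p


def transition_probabilities(q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """Transition matrix P(t) = exp(Qt); eigendecomposition when π is given,
    scipy's Padé expm otherwise."""
    if t < 0 or not np.isfinite(t):
        raise ValueError("branch length must be finite and non-negative")
    if pi is not None:
        return EigenQ(q, pi).p_matrix(t)
    return expm(q * t)


# ---------------------------------------------------------------------------
# pruning likelihood

@dataclass
class _Patterns:
    columns: np.ndarray  # (n_taxa, n_patterns) codon indices, -1 = missing
    weights: np.ndarray  # (n_patterns,)
    inverse: np.ndarray  # original site -> pattern


def compress_patterns(aln: CodonAlignment) -> _Patterns:
    idx = aln.codon_indices()
    cols, inverse, counts = np.unique(idx.T, axis=0, return_inverse=True, return_counts=True)
    return _Patterns(cols.T, counts.astype(float), inverse.ravel())


class LikelihoodEngine:
    """Pruning log-likelihood for one (alignment, tree) pair.

    Caches site patterns and tip ordering; parameters vary between calls,
    which is what model fitting needs.
    """

    def __init__(self, aln: CodonAlignment, tree: LabeledTree):
        tree.check_against(aln.taxa)
        self.aln = aln
        self.tree = tree
        self.code = aln.code
        self.n_states = self.code.n_sense
        self.patterns = compress_patterns(aln)
        self._tip_row = {name: aln.taxa.index(name) for name in tree.tip_names}

    # -- internals -----------------------------------------------------

    def _class_machinery(self, params: CodonModelParams, mix: SiteClassMix | None):
        """Per-class ω maps/weights and branch scale factors.

        Branch lengths are expected substitutions per codon averaged over the
        site-class mixture, so each branch class c divides its generator by
        R_c = Σ_k p_k rate(Q(ω_{k,c})).
        """
        if mix is None:
            weights = np.array([1.0])
            omega_maps = [params.omega_by_class]
        else:
            weights = mix.proportions
            omega_maps = mix.omega_maps
        branch_marks = sorted({b.mark for b in self.tree.branches})
        eigen_cache: dict[float, EigenQ] = {}

        def eigen_for(omega: float) -> EigenQ:
            if omega not in eigen_cache:
                q = build_rate_matrix(params.pi, params.kappa, omega, self.code, scale=False)
                eigen_cache[omega] = EigenQ(q, params.pi)
            return eigen_cache[omega]

        scale = {}
        for c in branch_marks:
            r = sum(w * eigen_for(_omega_of(m, c)).rate for w, m in zip(weights, omega_maps))
            scale[c] = r if r > 0 else 1.0
        return weights, omega_maps, eigen_for, scale

    def branch_p_matrices(self, omega_map, eigen_for, scale) -> dict:
        """Transition matrix for every branch under one site class."""
        mats = {}
        for node in self.tree.branches:
            if node.length is None:
                raise ValueError("branch lengths must be set before likelihood")
            mats[node.index] = eigen_for(_omega_of(omega_map, node.mark)).p_matrix(
                node.length / scale[node.mark]
            )
        return mats

    def inside_partials(self, p_mats) -> tuple:
        """Post-order partial likelihoods for all nodes (rescaled columns).

        Returns (partials, logscale) where partials[node.index] is
        (n_states, n_patterns); rescaling factors are accumulated per pattern
        up the tree, so only the root's logscale is meaningful on its own.
        """
        cols = self.patterns.columns
        n_pat = cols.shape[1]
        partials = {}
        logscale = {}
        for node in self.tree.nodes:
            if node.is_tip:
                row = cols[self._tip_row[node.name]]
                part = np.zeros((self.n_states, n_pat))
                missing = row < 0
                part[:, missing] = 1.0
                obs = ~missing
                part[row[obs], np.nonzero(obs)[0]] = 1.0
                partials[node.index] = part
                logscale[node.index] = np.zeros(n_pat)
            else:
                prod = np.ones((self.n_states, n_pat))
                ls = np.zeros(n_pat)
                for ch in node.children:
                    prod *= p_mats[ch.index] @ partials[ch.index]
                    ls += logscale[ch.index]
                mx = prod.max(axis=0)
                mx[mx <= 0] = 1.0
                prod /= mx
                partials[node.index] = prod
                logscale[node.index] = ls + np.log(mx)
        return partials, logscale

    def _prune_class(self, omega_map, eigen_for, scale, pi) -> np.ndarray:
        """Per-pattern log-likelihood for one site class."""
        p_mats = self.branch_p_matrices(omega_map, eigen_for, scale)
        partials, logscale = self.inside_partials(p_mats)
        root = self.tree.root.index
        site_l = pi @ partials[root]
        with np.errstate(divide="ignore"):
            return np.log(site_l) + logscale[root]

    # -- public --------------------------------------------------------

    def log_likelihood(self, params: CodonModelParams, mix: SiteClassMix | None = None):
        """Total and per-site log-likelihood.

        Returns (ℓ, site_ll) where site_ll is over original alignment columns
        and sums exactly to ℓ.
        """
        weights, omega_maps, eigen_for, scale = self._class_machinery(params, mix)
        class_ll = np.stack(
            [self._prune_class(m, eigen_for, scale, params.pi) for m in omega_maps]
        )
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(weights, 1e-300))
        pattern_ll = logsumexp(class_ll + logw[:, None], axis=0)
        site_ll = pattern_ll[self.patterns.inverse]
        return float(site_ll.sum()), site_ll

    def class_posteriors(self, params: CodonModelParams, mix: SiteClassMix):
        """Per-site posterior over site classes (empirical Bayes, fitted
        parameters plugged in)."""
        weights, omega_maps, eigen_for, scale = self._class_machinery(params, mix)
        class_ll = np.stack(
            [self._prune_class(m, eigen_for, scale, params.pi) for m in omega_maps]
        )
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(weights, 1e-300))
        log_post = class_ll + logw[:, None]
        log_post -= logsumexp(log_post, axis=0, keepdims=True)
        return np.exp(log_post)[:, self.patterns.inverse].T  # (n_sites, n_classes)


def _omega_of(omega_map, mark: int) -> float:
    try:
        return omega_map[mark]
    except KeyError:
        raise KeyError(f"no ω defined for branch class {mark}") from None


def log_likelihood(aln: CodonAlignment, tree: LabeledTree, params: CodonModelParams,
                   mix: SiteClassMix | None = None):
    """Convenience wrapper: pruning log-likelihood of an alignment on a tree."""
    return LikelihoodEngine(aln, tree).log_likelihood(params, mix)
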