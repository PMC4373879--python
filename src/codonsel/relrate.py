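"""Pairwise relative-rate tests on synonymous and nonsynonymous rates.

Two ingroup sequences are compared against an outgroup on the three-taxon
star tree.  The codon model gives every branch its own synonymous and
nonsynonymous *length* (rate × time products, in a Muse–Gaut-style
decomposition where synonymous and nonsynonymous changes carry separate
multipliers), so the two rate components can be constrained independently.
The synonymous (resp. nonsynonymous) test constrains the two ingroup
branches to equal synonymous (resp. nonsynonymous) length under the null and
frees it under the alternative; each comparison is a likelihood-ratio test
with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .engine import EigenQ, build_rate_matrix, estimate_frequencies

_B = {"kappa": (0.05, 100.0), "len": (1e-7, 20.0)}


@dataclass
class RelativeRateResult:
    ingroup1: str
    ingroup2: str
    outgroup: str
    syn_statistic: float
    syn_p: float
    nonsyn_statistic: float
    nonsyn_p: float
    ll_alt: float


class _StarLikelihood:
    """Likelihood of three sequences on a star tree with per-branch
    synonymous/nonsynonymous lengths and shared κ."""

    def __init__(self, aln: CodonAlignment, order):
        self.code = aln.code
        self.pi = estimate_frequencies(aln)
        idx = aln.codon_indices()
        rows = np.stack([idx[aln.taxa.index(t)] for t in order])
        keep = (rows >= 0).all(axis=0)
        cols, counts = np.unique(rows[:, keep].T, axis=0, return_counts=True)
        self.patterns = cols.T  # (3, n_pat)
        self.weights = counts.astype(float)

    def _p_matrix(self, kappa, s_len, n_len):
        # Q = s·Q_syn + n·Q_nonsyn; equals s × GY(ω = n/s) unscaled
        s_len = max(s_len, 1e-9)
        q = build_rate_matrix(self.pi, kappa, n_len / s_len, self.code, scale=False)
        return EigenQ(q, self.pi).p_matrix(s_len)

    def log_likelihood(self, kappa, lengths):
        """lengths: [(s1, n1), (s2, n2), (s3, n3)] per branch."""
        ps = [self._p_matrix(kappa, s, n) for s, n in lengths]
        site_l = self.pi @ (ps[0][:, self.patterns[0]]
                           * ps[1][:, self.patterns[1]]
                           * ps[2][:, self.patterns[2]])
        if (site_l <= 0).any():
            return -np.inf
        return float(self.weights @ np.log(site_l))


def _fit(star, constrain: str | None):
    """Maximize the star likelihood; ``constrain`` ties ingroup branches'
    'syn' or 'nonsyn' lengths (ingroups are branches 0 and 1)."""

    def unpack(x):
        kappa = x[0]
        v = list(x[1:])
        if constrain == "syn":
            s12, n1, n2, s3, n3 = v
            lengths = [(s12, n1), (s12, n2), (s3, n3)]
        elif constrain == "nonsyn":
            s1, s2, n12, s3, n3 = v
            lengths = [(s1, n12), (s2, n12), (s3, n3)]
        else:
            s1, n1, s2, n2, s3, n3 = v
            lengths = [(s1, n1), (s2, n2), (s3, n3)]
        return kappa, lengths

    n_len = 5 if constrain else 6
    x0 = np.array([2.0] + [0.05] * n_len)
    bounds = [_B["kappa"]] + [_B["len"]] * n_len

    def objective(x):
        kappa, lengths = unpack(x)
        ll = star.log_likelihood(kappa, lengths)
        return 1e12 if not np.isfinite(ll) else -ll

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "maxiter": 500})
    return -res.fun


def pairwise_relative_rate(aln: CodonAlignment, ingroup1: str, ingroup2: str,
                           outgroup: str) -> RelativeRateResult:
    """Relative-rate tests between two ingroup taxa given an outgroup.

    Returns LRT statistics and χ²(1) p-values for equality of synonymous and
    of nonsynonymous rates on the two ingroup branches.
    """
    names = [ingroup1, ingroup2, outgroup]
    if len(set(names)) != 3:
        raise ValueError("ingroup and outgroup taxa must be three distinct sequences")
    for t in names:
        if t not in aln.taxa:
            raise ValueError(f"taxon {t!r} not in alignment")
    star = _StarLikelihood(aln.subset(names), names)
    ll_alt = _fit(star, None)
    ll_syn = _fit(star, "syn")
    ll_nonsyn = _fit(star, "nonsyn")
    syn_stat = max(0.0, 2.0 * (ll_alt - ll_syn))
    nonsyn_stat = max(0.0, 2.0 * (ll_alt - ll_nonsyn))
    return RelativeRateResult(
        ingroup1, ingroup2, outgroup,
        syn_stat, float(chi2.sf(syn_stat, 1)),
        nonsyn_stat, float(chi2.sf(nonsyn_stat, 1)),
        ll_alt,
    )
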