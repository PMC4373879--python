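"""Nei–Gojobori (NG86) pairwise dN/dS and sliding-window ω profiles.

Counts synonymous and nonsynonymous sites and differences with pathway
averaging (all orders of multi-nucleotide codon differences weighted
equally; pathways passing through stop codons are excluded), corrects the
proportions with the Jukes–Cantor transform, and aggregates over windows of
nucleotides along the alignment for a group of sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .genetics import NUCLEOTIDES, GeneticCode, standard_code


@dataclass
class NGCounts:
    """NG86 counts and distances for one sequence pair (or window)."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites > 0 else np.nan

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites > 0 else np.nan

    @property
    def ds(self) -> float:
        return jukes_cantor(self.ps)

    @property
    def dn(self) -> float:
        return jukes_cantor(self.pn)

    def __add__(self, other):
        return NGCounts(self.syn_sites + other.syn_sites,
                        self.nonsyn_sites + other.nonsyn_sites,
                        self.syn_diffs + other.syn_diffs,
                        self.nonsyn_diffs + other.nonsyn_diffs,
                        self.n_codons + other.n_codons)


def jukes_cantor(p: float) -> float:
    """d = −(3/4)·ln(1 − 4p/3); NaN when the correction is undefined
    (p ≥ 3/4)."""
    if not np.isfinite(p) or p >= 0.75:
        return np.nan
    return -0.75 * np.log(1 - 4.0 * p / 3.0)


def _is_sense(codon: str, code: GeneticCode) -> bool:
    return all(b in NUCLEOTIDES for b in codon) and codon not in code.stop_set


@lru_cache(maxsize=4096)
def _site_counts(codon: str, code: GeneticCode):
    """(syn, nonsyn) site counts for one codon, normalized to 3 sites.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.
    """
    aa = code.codon_to_aa[codon]
    syn = 0.0
    for pos in range(3):
        for b in NUCLEOTIDES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1:]
            if neighbor not in code.stop_set and code.codon_to_aa[neighbor] == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=65536)
def _diff_counts(codon1: str, codon2: str, code: GeneticCode):
    """Pathway-averaged (syn, nonsyn) difference counts between two codons.

    All orders of the differing positions are weighted equally; pathways
    through stop codons are excluded.  In the degenerate case where every
    pathway is blocked, stop-passing pathways are readmitted with steps
    to/from stops counted as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0.0
        current = codon1
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            if nxt in code.stop_set and not allow_stops:
                return None
            if (current in code.stop_set or nxt in code.stop_set
                    or code.codon_to_aa[current] != code.codon_to_aa[nxt]):
                nonsyn += 1.0
            else:
                syn += 1.0
            current = nxt
        return syn, nonsyn

    paths = [walk(order, False) for order in itertools.permutations(diff_pos)]
    paths = [p for p in paths if p is not None]
    if not paths:
        paths = [walk(order, True) for order in itertools.permutations(diff_pos)]
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return syn, nonsyn


def ng86_pair(codons1, codons2, code: GeneticCode | None = None) -> NGCounts:
    """NG86 counts for two equal-length codon sequences.

    Codon pairs where either member contains a gap or ambiguity are skipped.
    Site counts are averaged between the two sequences.
    """
    code = code or standard_code()
    if len(codons1) != len(codons2):
        raise ValueError("sequences must have equal codon length")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    used = 0
    for c1, c2 in zip(codons1, codons2):
        if not (_is_sense(c1, code) and _is_sense(c2, code)):
            continue
        used += 1
        s1, n1 = _site_counts(c1, code)
        s2, n2 = _site_counts(c2, code)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = _diff_counts(c1, c2, code)
        s_diffs += sd
        n_diffs += nd
    return NGCounts(s_sites, n_sites, s_diffs, n_diffs, used)


@dataclass
class WindowProfile:
    """Sliding-window ω profile for one taxon group."""

    group: str
    window: int  # nucleotides
    step: int
    table: pd.DataFrame  # start, end (1-based nt), dN, dS, omega, defined


def sliding_omega(aln: CodonAlignment, taxa=None, window: int = 90, step: int = 36,
                  group: str = "group") -> WindowProfile:
    """Mean pairwise NG86 dN/dS in sliding windows over a taxon group.

    Per window the dN and dS of all within-group pairs are averaged and
    ω = mean dN / mean dS (ratio of means); ω is undefined (NaN, flagged)
    when mean dS is 0 or any correction in the window is undefined.  Windows
    are anchored at position 1; a trailing partial window is discarded.
    """
    if window % 3 or step % 3:
        raise ValueError("window and step must be multiples of 3")
    sub = aln if taxa is None else aln.subset(list(taxa))
    if sub.n_taxa < 2:
        raise ValueError("sliding-window ω needs at least 2 sequences in the group")
    n_nt = sub.n_codons * 3
    if window > n_nt:
        raise ValueError("window longer than alignment")
    pairs = list(itertools.combinations(range(sub.n_taxa), 2))
    rows = []
    for start_nt in range(0, n_nt - window + 1, step):
        c0 = start_nt // 3
        c1 = c0 + window // 3
        dns, dss = [], []
        for i, j in pairs:
            counts = ng86_pair(sub.codons[i, c0:c1], sub.codons[j, c0:c1], sub.code)
            dns.append(counts.dn)
            dss.append(counts.ds)
        mean_dn = float(np.mean(dns))
        mean_ds = float(np.mean(dss))
        defined = np.isfinite(mean_dn) and np.isfinite(mean_ds) and mean_ds > 0
        rows.append({
            "start": start_nt + 1, "end": start_nt + window,
            "dN": mean_dn, "dS": mean_ds,
            "omega": mean_dn / mean_ds if defined else np.nan,
            "defined": defined,
        })
    return WindowProfile(group, window, step, pd.DataFrame(rows))
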