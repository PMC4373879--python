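"""Genetic codes and codon bookkeeping.

All codon-level machinery in this package works over the sense codons of a
genetic code (61 for the standard nuclear code), indexed alphabetically over
``ACGT`` triplets with stop codons removed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: Purine/pyrimidine partners: a substitution is a transition iff it stays
#: within {A,G} or {C,T}.
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

ALL_CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A genetic code: the 64-codon → amino-acid map and its sense codons."""

    name: str
    codon_to_aa: dict  # maps all 64 triplets; stops map to '*'
    stop_set: frozenset

    sense_codons: tuple = field(init=False)
    codon_index: dict = field(init=False)

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map exactly 64 codons")
        sense = tuple(c for c in ALL_CODONS if c not in self.stop_set)
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "codon_index", {c: i for i, c in enumerate(sense)})

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def translate_codon(self, codon: str) -> str:
        """Amino acid for a codon; '-' for gap, 'X' for ambiguity."""
        if codon == "---":
            return "-"
        if any(b not in NUCLEOTIDES for b in codon):
            return "X"
        return self.codon_to_aa[codon]

    @classmethod
    def from_name(cls, name: str = "Standard") -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_name[name]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(name=name, codon_to_aa=mapping, stop_set=frozenset(table.stop_codons))


@lru_cache(maxsize=4)
def standard_code() -> GeneticCode:
    return GeneticCode.from_name("Standard")


@lru_cache(maxsize=8)
def codon_structure(code: GeneticCode):
    """Pairwise structure of the sense-codon space.

    Returns (single_nt, transition, synonymous, aa_of) where the first three
    are boolean (n, n) arrays over sense-codon pairs differing at exactly one
    position, and ``aa_of`` maps sense-codon index → amino-acid index.
    """
    codons = code.sense_codons
    n = len(codons)
    single = np.zeros((n, n), dtype=bool)
    transit = np.zeros((n, n), dtype=bool)
    synon = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transit[i, j] = is_transition(*diffs[0])
            synon[i, j] = code.codon_to_aa[ci] == code.codon_to_aa[cj]
    aa_of = np.array([AA_INDEX[code.codon_to_aa[c]] for c in codons])
    return single, transit, synon, aa_of


@lru_cache(maxsize=8)
def codon_to_aa_matrix(code: GeneticCode) -> np.ndarray:
    """(n_sense, 20) indicator matrix collapsing codons to amino acids."""
    _, _, _, aa_of = codon_structure(code)
    m = np.zeros((code.n_sense, len(AMINO_ACIDS)))
    m[np.arange(code.n_sense), aa_of] = 1.0
    return m
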