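"""Codon alignments: reading, writing, validation, translation, numbering.

The atomic unit throughout the package is the codon column; all site indices
are 1-based codon/amino-acid positions.  Codons containing any non-ACGT
character (gaps included) are treated as fully missing data in likelihood
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import NUCLEOTIDES, GeneticCode, standard_code


class AlignmentError(ValueError):
    """Structural or validation problem with a codon alignment."""


@dataclass
class CodonAlignment:
    """Taxa × codon-column matrix over sense codons plus gap/ambiguity symbols.

    Attributes
    ----------
    taxa : list of str
        Unique sequence names, in input order.
    codons : np.ndarray of shape (n_taxa, n_codons), dtype '<U3'
        Codon triplets, upper-case.
    code : GeneticCode
    """

    taxa: list
    codons: np.ndarray
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2:
            raise AlignmentError("codon matrix must be 2-dimensional")
        if len(self.taxa) != self.codons.shape[0]:
            raise AlignmentError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxa: {', '.join(dup)}")
        self._validate_codons()
        self._index = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def _validate_codons(self):
        for r, name in enumerate(self.taxa):
            for c in range(self.codons.shape[1]):
                codon = self.codons[r, c]
                if len(codon) != 3:
                    raise AlignmentError(f"taxon {name}, column {c + 1}: malformed codon {codon!r}")
                if all(b in NUCLEOTIDES for b in codon) and codon in self.code.stop_set:
                    raise AlignmentError(
                        f"internal stop codon {codon} in taxon {name} at codon column {c + 1}"
                    )

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix: sense-codon index, or -1 for missing.

        Gapped or ambiguous codons are coded -1 and contribute a neutral
        partial-likelihood vector (all ones).
        """
        if self._index is None:
            idx = np.full(self.codons.shape, -1, dtype=np.int64)
            lookup = self.code.codon_index
            for r in range(self.codons.shape[0]):
                for c in range(self.codons.shape[1]):
                    idx[r, c] = lookup.get(self.codons[r, c], -1)
            self._index = idx
        return self._index

    def sequence(self, taxon: str) -> str:
        """Nucleotide sequence (with gaps) for one taxon."""
        return "".join(self.codons[self.taxa.index(taxon)])

    def subset(self, taxa) -> "CodonAlignment":
        rows = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codons[rows].copy(), self.code)

    def translate(self) -> dict:
        """Protein alignment: taxon → amino-acid string (gap '-', ambiguity 'X')."""
        out = {}
        for r, name in enumerate(self.taxa):
            out[name] = "".join(self.code.translate_codon(c) for c in self.codons[r])
        return out

    @classmethod
    def from_sequences(cls, records, code: GeneticCode | None = None) -> "CodonAlignment":
        """Build from (name, nucleotide string) pairs."""
        code = code or standard_code()
        taxa, rows = [], []
        lengths = set()
        for name, seq in records:
            seq = str(seq).upper()
            if len(seq) % 3 != 0:
                raise AlignmentError(
                    f"sequence length {len(seq)} for taxon {name} is not divisible by 3"
                )
            lengths.add(len(seq))
            taxa.append(name)
            rows.append([seq[i : i + 3] for i in range(0, len(seq), 3)])
        if len(lengths) > 1:
            raise AlignmentError("sequences have unequal lengths; alignment required")
        if not rows:
            raise AlignmentError("empty alignment")
        return cls(taxa, np.array(rows, dtype="<U3"), code)


def read_codon_alignment(path, format: str = "fasta", code: GeneticCode | None = None) -> CodonAlignment:
    """Read a codon-aware alignment from FASTA or sequential PHYLIP."""
    path = Path(path)
    if format == "fasta":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "phylip-sequential")]
    else:
        raise ValueError(f"unknown alignment format: {format}")
    return CodonAlignment.from_sequences(records, code)


def write_codon_alignment(aln: CodonAlignment, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq("".join(aln.codons[i])), id=name, description="")
        for i, name in enumerate(aln.taxa)
    ]
    fmt = {"fasta": "fasta", "phylip": "phylip-sequential"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format: {format}")
    SeqIO.write(records, str(path), fmt)


@dataclass
class SiteNumbering:
    """Map alignment codon columns to ungapped positions in a reference taxon."""

    reference: str
    column_to_position: dict  # 1-based column -> 1-based reference residue

    def position(self, column: int) -> int | None:
        return self.column_to_position.get(column)

    def label(self, column: int, derived_aa: str | None = None) -> str:
        pos = self.column_to_position.get(column)
        base = str(pos) if pos is not None else f"col{column}"
        return f"{base}{derived_aa}" if derived_aa else base


def map_site_numbers(aln: CodonAlignment, reference: str) -> SiteNumbering:
    """Number alignment columns by ungapped codon position in the reference."""
    if reference not in aln.taxa:
        raise AlignmentError(f"unknown reference taxon: {reference}")
    row = aln.codons[aln.taxa.index(reference)]
    mapping = {}
    pos = 0
    for col, codon in enumerate(row, start=1):
        if codon != "---":
            pos += 1
            mapping[col] = pos
    return SiteNumbering(reference, mapping)
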