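"""Shared fixtures: small alignments and trees built programmatically."""

import numpy as np
import pytest

from codonsel.alignment import CodonAlignment
from codonsel.engine import CodonModelParams, estimate_frequencies
from codonsel.genetics import standard_code
from codonsel.tree import read_tree


def ladder_tree(n_tips, tip_len=0.08, inner_len=0.04, fg_clade=None, fg_len=0.3,
                fg_mark=1):
    """Ladder (caterpillar) tree t0..t{n-1}; optionally mark the MRCA branch
    of ``fg_clade`` as foreground with its own length."""
    nwk = f"t0:{tip_len}"
    for i in range(1, n_tips):
        nwk = f"({nwk},t{i}:{tip_len}):{inner_len}"
    tree = read_tree(nwk[: nwk.rfind(":")] + ";")
    if fg_clade:
        node = tree.mrca(list(fg_clade)) if len(fg_clade) > 1 else tree.find(fg_clade[0])
        node.mark = fg_mark
        node.length = fg_len
    return tree


def random_sense_alignment(taxa, n_codons, seed):
    """Alignment of i.i.d. random sense codons (no phylogenetic signal)."""
    rng = np.random.default_rng(seed)
    sense = standard_code().sense_codons
    return CodonAlignment.from_sequences(
        [(t, "".join(rng.choice(sense, n_codons))) for t in taxa]
    )


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def small_aln():
    """3 taxa × 6 random sense codons."""
    return random_sense_alignment("ABC", 6, seed=11)


@pytest.fixture
def small_tree():
    return read_tree("((A:0.2,B:0.3):0.1,C:0.25);")


@pytest.fixture
def uniform_pi():
    return np.full(61, 1 / 61.0)


@pytest.fixture
def small_params(small_aln):
    pi = estimate_frequencies(small_aln)
    return CodonModelParams(kappa=2.0, omega_by_class={0: 0.4}, pi=pi)
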