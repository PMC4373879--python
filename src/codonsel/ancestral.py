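"""Ancestral sequence reconstruction and branch substitution mapping.

Two reconstruction routes are provided: marginal maximum likelihood under a
fitted codon model (posterior state distributions per internal node, obtained
from inside/outside partial likelihoods and collapsed from codons to amino
acids), and Hartigan/Fitch parsimony on the protein alignment (state sets per
node, with ties preserved rather than broken).  Substitutions are mapped onto
branches by comparing states across each branch, and can be filtered to
lineage-specific replacements (derived state fixed in a focal clade and
absent elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment, SiteNumbering
from .engine import LikelihoodEngine
from .genetics import AA_INDEX, AMINO_ACIDS, codon_to_aa_matrix
from .models import CodonModelFit
from .tree import LabeledTree, Node, TreeError


@dataclass
class AncestralStates:
    """Per-node, per-site amino-acid posteriors with MAP state and BPP.

    Tips are included as point masses on their observed residues (uniform for
    missing data) so that branch endpoints can be compared uniformly.
    """

    tree: LabeledTree
    posteriors: dict  # node index -> (n_sites, 20)
    n_sites: int = field(init=False)

    def __post_init__(self):
        any_post = next(iter(self.posteriors.values()))
        self.n_sites = any_post.shape[0]

    def posterior(self, node_index: int, site: int) -> np.ndarray:
        """20-vector for a node at a 1-based site."""
        return self.posteriors[node_index][site - 1]

    def map_state(self, node_index: int, site: int) -> tuple[str, float]:
        """(amino acid, BPP) of the maximum-posterior state."""
        p = self.posterior(node_index, site)
        i = int(np.argmax(p))
        return AMINO_ACIDS[i], float(p[i])

    def map_sequence(self, node_index: int) -> str:
        p = self.posteriors[node_index]
        return "".join(AMINO_ACIDS[i] for i in p.argmax(axis=1))


@dataclass
class SubstitutionEvent:
    """An amino-acid replacement mapped onto one branch."""

    branch_index: int
    branch_name: str | None
    site: int  # 1-based alignment column
    ancestral: str
    derived: str
    support: float  # posterior(parent MAP) × posterior(child MAP)
    site_label: str | None = None

    def label(self) -> str:
        pos = self.site_label or str(self.site)
        return f"{self.ancestral}{pos}{self.derived}"


# ---------------------------------------------------------------------------
# marginal ML reconstruction

def marginal_reconstruct(aln: CodonAlignment, fit: CodonModelFit) -> AncestralStates:
    """Marginal ML reconstruction under a fitted model.

    For each internal node the codon posterior is computed from inside and
    outside partial likelihoods; under a site-class mixture the per-class
    posteriors are weighted by the empirical-Bayes class posterior of the
    site.  Codon posteriors are collapsed to amino acids by summing synonymous
    codons.
    """
    engine = LikelihoodEngine(aln, fit.tree)
    tree = fit.tree
    pi = fit.pi
    weights, omega_maps, eigen_for, scale = engine._class_machinery(fit.params, fit.mix)

    n_pat = engine.patterns.columns.shape[1]
    n_classes = len(weights)
    # per class: per-node codon posteriors (unnormalized ok), plus class site ll
    class_site_ll = np.zeros((n_classes, n_pat))
    class_node_post = []  # list over classes of dict node -> (61, n_pat)

    for k, omap in enumerate(omega_maps):
        p_mats = engine.branch_p_matrices(omap, eigen_for, scale)
        partials, logscale = engine.inside_partials(p_mats)
        root = tree.root.index
        site_l = pi @ partials[root]
        with np.errstate(divide="ignore"):
            class_site_ll[k] = np.log(site_l) + logscale[root]

        # outside pass: marginal(node) ∝ weight_vec(node) * inside(node)
        weight_vec = {root: np.tile(pi[:, None], (1, n_pat))}
        post = {}
        for node in reversed(tree.nodes):  # pre-order
            if node.is_tip:
                continue
            wv = weight_vec[node.index]
            post[node.index] = wv * partials[node.index]
            kids = node.children
            for ch in kids:
                rest = wv.copy()
                for sib in kids:
                    if sib is not ch:
                        rest *= p_mats[sib.index] @ partials[sib.index]
                h = p_mats[ch.index].T @ rest
                mx = h.max(axis=0)
                mx[mx <= 0] = 1.0
                weight_vec[ch.index] = h / mx
        class_node_post.append(post)

    # empirical-Bayes class weights per pattern
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(weights, 1e-300))
    log_joint = class_site_ll + logw[:, None]
    log_joint -= log_joint.max(axis=0, keepdims=True)
    class_w = np.exp(log_joint)
    class_w /= class_w.sum(axis=0, keepdims=True)

    collapse = codon_to_aa_matrix(aln.code)  # (61, 20)
    inverse = engine.patterns.inverse
    posteriors = {}
    for node in tree.nodes:
        if node.is_tip:
            posteriors[node.index] = _tip_aa_posterior(aln, node.name)
            continue
        mixed = np.zeros((engine.n_states, n_pat))
        for k in range(n_classes):
            p = class_node_post[k][node.index]
            tot = p.sum(axis=0)
            tot[tot <= 0] = 1.0
            mixed += class_w[k] * (p / tot)
        aa_post = (collapse.T @ mixed).T  # (n_pat, 20)
        posteriors[node.index] = aa_post[inverse]
    return AncestralStates(tree, posteriors)


def _tip_aa_posterior(aln: CodonAlignment, name: str) -> np.ndarray:
    row = aln.codons[aln.taxa.index(name)]
    out = np.zeros((len(row), len(AMINO_ACIDS)))
    for s, codon in enumerate(row):
        aa = aln.code.translate_codon(codon)
        if aa in AA_INDEX:
            out[s, AA_INDEX[aa]] = 1.0
        else:  # gap or ambiguity: no information
            out[s] = 1.0 / len(AMINO_ACIDS)
    return out


# ---------------------------------------------------------------------------
# parsimony

@dataclass
class ParsimonyResult:
    """Hartigan/Fitch most-parsimonious reconstruction on a rooted tree."""

    tree: LabeledTree
    state_sets: dict  # node index -> list over sites of frozenset of aa
    changes_per_site: np.ndarray
    placements: list  # (branch_index, site, ancestral set, derived set, ambiguous flag)


def fitch_parsimony(protein_aln: dict, tree: LabeledTree) -> ParsimonyResult:
    """Minimum-change ancestral state sets for each site of a protein
    alignment, by Hartigan's generalization of Fitch's algorithm (handles
    polytomies; ties are reported as multi-state sets, never broken)."""
    names = tree.tip_names
    n_sites = len(next(iter(protein_aln.values())))
    all_states = frozenset(AMINO_ACIDS)

    up_sets = {}
    second = {}
    changes = np.zeros(n_sites, dtype=int)

    for node in tree.nodes:  # postorder
        if node.is_tip:
            seq = protein_aln[node.name]
            up_sets[node.index] = [
                frozenset(c) if c in AA_INDEX else all_states for c in seq
            ]
            second[node.index] = [frozenset()] * n_sites
        else:
            ups, secs = [], []
            for s in range(n_sites):
                votes = {}
                for ch in node.children:
                    for st in up_sets[ch.index][s]:
                        votes[st] = votes.get(st, 0) + 1
                kmax = max(votes.values())
                ups.append(frozenset(st for st, v in votes.items() if v == kmax))
                secs.append(frozenset(st for st, v in votes.items() if v == kmax - 1))
                changes[s] += len(node.children) - kmax
            up_sets[node.index] = ups
            second[node.index] = secs

    # downward pass (most-parsimonious reconstruction sets)
    mpr = {tree.root.index: up_sets[tree.root.index]}
    for node in reversed(tree.nodes):
        if node.is_tip and node.parent is None:
            continue
        for ch in node.children:
            out = []
            for s in range(n_sites):
                parent_set = mpr[node.index][s]
                vu, vl = up_sets[ch.index][s], second[ch.index][s]
                if parent_set <= vu:
                    out.append(parent_set)
                else:
                    out.append(vu | (parent_set & vl))
            mpr[ch.index] = out

    placements = []
    for node in tree.branches:
        for s in range(n_sites):
            parent_set = mpr[node.parent.index][s]
            child_set = mpr[node.index][s]
            if parent_set.isdisjoint(child_set):
                ambiguous = len(parent_set) > 1 or len(child_set) > 1
                placements.append((node.index, s + 1, parent_set, child_set, ambiguous))
    return ParsimonyResult(tree, mpr, changes, placements)


# ---------------------------------------------------------------------------
# substitution mapping

def branch_substitutions(anc: AncestralStates, support_threshold: float = 0.7,
                         numbering: SiteNumbering | None = None) -> list:
    """Amino-acid replacements mapped onto branches.

    One event per (branch, site) where the MAP states of the two branch
    endpoints differ and the joint support (product of the endpoint MAP
    posteriors) reaches the threshold.
    """
    events = []
    for node in anc.tree.branches:
        for s in range(1, anc.n_sites + 1):
            a_state, a_p = anc.map_state(node.parent.index, s)
            d_state, d_p = anc.map_state(node.index, s)
            if a_state == d_state:
                continue
            support = a_p * d_p
            if support < support_threshold:
                continue
            label = numbering.label(s) if numbering else None
            events.append(SubstitutionEvent(node.index, node.name, s, a_state, d_state,
                                            support, label))
    return events


def lineage_specific_substitutions(events: list, aln: CodonAlignment, tree: LabeledTree,
                                   focal_branch: Node, clade: list | None = None) -> list:
    """Filter branch substitutions to lineage-specific replacements.

    Keeps events on the focal branch whose derived residue is carried by every
    clade member and by no taxon outside the clade at that site (missing data
    ignored).  The clade defaults to the tips subtended by the focal branch.
    """
    clade = list(clade) if clade is not None else tree.clade_tips(focal_branch)
    subtended = set(tree.clade_tips(focal_branch))
    if not set(clade) <= subtended:
        raise TreeError("clade is not subtended by the focal branch")
    protein = aln.translate()
    outside = [t for t in aln.taxa if t not in set(clade)]
    kept = []
    for ev in events:
        if ev.branch_index != focal_branch.index:
            continue
        col = ev.site - 1
        inside_states = {protein[t][col] for t in clade}
        if inside_states - {"-", "X"} != {ev.derived}:
            continue
        if any(protein[t][col] == ev.derived for t in outside):
            continue
        kept.append(ev)
    return kept
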