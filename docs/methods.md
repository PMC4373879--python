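# Methods

This note documents the models, conventions, numerical choices and
calibration designs behind `codonsel`, at the level a user needs to judge
what a result does and does not mean.

## Codon substitution model

All likelihood computations use a Goldman–Yang-type codon model over the
sense codons of the genetic code (61 for the standard nuclear code, the
default; other tables can be supplied by name). The instantaneous rate from
codon *i* to codon *j* is

- 0 if *i* and *j* differ at more than one nucleotide,
- π_j · κ · ω for a nonsynonymous transition,
- π_j · κ for a synonymous transition,
- π_j · ω for a nonsynonymous transversion,
- π_j for a synonymous transversion,

with the diagonal set so rows sum to zero. κ > 0 is the
transition/transversion rate ratio; ω ≥ 0 is the nonsynonymous/synonymous
rate ratio; π is the stationary codon distribution.

**Frequencies.** π defaults to F3×4: products of position-specific
nucleotide frequencies estimated from the alignment, renormalized over
sense codons (stop-codon mass redistributed). F1×4 and equal frequencies
are available. Zero-frequency codons are floored at 1e-8 and renormalized
so the reversible eigendecomposition stays well-conditioned on sparse
alignments; frequencies are not counted as free parameters (they are
estimated by counting, the convention behind the np columns of codon-model
software).

**Branch lengths** are expected substitutions per codon. Each generator is
scaled so that one unit of time produces one expected substitution; under a
site-class mixture the scale factor for a branch class is the
mixture-weighted average of the class rates, so a branch length means
expected substitutions averaged over site classes. Under branch models each
branch class carries its own scale, so a foreground branch length is
measured under its own ω.

**Likelihood** is computed by Felsenstein pruning over compressed site
patterns, with per-node column rescaling (accumulated in log space) against
underflow. Transition matrices come from the symmetric eigendecomposition
of D^{1/2} Q D^{-1/2} (D = diag π), exact for this reversible model; a
Padé `expm` route is used when no stationary vector is supplied. Codons
containing any non-ACGT character (gaps included) contribute a neutral
partial-likelihood vector — fully missing data. The likelihood is invariant
to rerooting, which the tests verify.

## Model suite and tests

- **Branch models.** One-ratio (single ω), two-ratio (ω per branch-class
  mark, marks read from `#<int>` labels in the Newick input), free-ratio
  (one ω per branch). Parameter count np = branches + 1 (κ) + number of
  free ω (+ mixture parameters), matching the usual np accounting.
- **M1a** (nearly neutral): site classes ω0 ∈ (0, 1) with proportion p0
  and ω1 = 1 with 1 − p0.
- **Branch-site model A**: classes 0 (ω0 everywhere), 1 (neutral
  everywhere), 2a and 2b (ω0 resp. 1 on background, shared ω2 ≥ 1 on the
  foreground), with p2a : p2b = p0 : p1. Test 1 compares model A to M1a
  (df = 2); test 2 compares it to the ω2 = 1 null (df = 1). Plain χ² is
  used by default for test 2 — conservative because the null pins ω2 at the
  boundary; the 50:50 χ² point-mass mixture is available as an option.
- **LRT statistics** are clamped at zero (optimizer noise can leave the
  alternative marginally below the null).
- **Site identification** uses naive empirical Bayes: fitted parameters
  plugged in, per-site class posteriors, sites flagged when the combined
  class-2a/2b posterior exceeds 0.5. NEB ignores parameter uncertainty
  (unlike BEB) and the flagged set should be read accordingly.

**Optimization.** Box-constrained L-BFGS-B over κ ∈ [0.05, 100],
ω ∈ [1e-6, 50] (ω2 ∈ [1, 50] in the branch-site alternative), proportions
in (0, 1) via a nested parameterization, branch lengths ∈ [1e-7, 20];
convergence tolerance 1e-8 in ℓ, at most 500 iterations. Each fit starts
from a heuristic point (κ = 2, ω = 0.2) plus, by default, one random
restart (log-uniform draws); more restarts can be requested. Branch lengths
are re-optimized under every model by default; fits also accept fixed
branch lengths (typically the one-ratio ML lengths), the fast path used in
the large replicate calibrations below. Alignments with no variable sites
are flagged as unidentifiable rather than failed.

## Ancestral reconstruction

**Marginal ML.** Per internal node and site, the codon posterior is
computed from inside (subtree) and outside (rest-of-tree) partial
likelihoods under the fitted model; for mixtures, per-class posteriors are
weighted by the empirical-Bayes class posterior of the site. Codon
posteriors are collapsed to amino acids by summing synonymous codons; the
reconstruction is at the codon level throughout. BPP is the posterior of
the maximum-posterior state. Tips enter as point masses (uniform for
missing data) so branch endpoints are handled uniformly.

**Parsimony.** Hartigan's generalization of Fitch's algorithm on the
protein alignment (handles polytomies, which species trees routinely
contain). Ties are never broken: ambiguous nodes keep multi-state sets and
ambiguous placements are flagged. Rooting follows the input tree; use the
outgroup-rooted species tree for directional inference.

**Substitution mapping.** One event per (branch, site) where the MAP
states of the branch endpoints differ; support = posterior(parent MAP) ×
posterior(child MAP), default threshold 0.7 (no published cutoff exists
for this quantity; 0.7 keeps only events where both endpoints are
individually well resolved). Lineage-specific filtering keeps events on a
focal branch whose derived residue is carried by every member of the
subtended clade and by no taxon outside it.

## Convergence between branch pairs

For a non-nested branch pair and site, the posterior that both branches
substituted is partitioned into parallel (same ancestral and same derived
state), convergent (different ancestral, same derived) and divergent
(different derived), summing over endpoint amino-acid assignments weighted
by their marginal posteriors, treated as independent across the four
endpoints (the standard approximation for this statistic; the tests verify
the closed form against exhaustive 20⁴ enumeration). Totals are per-site
sums; the pair's "total convergence" is Σ(parallel + convergent).

**Bootstrap null.** Replicate alignments are simulated under the fitted
one-ratio model with its ML branch lengths — a convergence-free null — and
the pair's total convergence is recomputed per replicate with the same
fitted parameters (the model is not refitted per replicate; at the null
the plug-in reconstruction is the dominant cost and refitting changes the
statistic negligibly relative to its simulation spread). The empirical
p-value uses the +1 correction: p = (1 + #{sim ≥ obs}) / (n_sim + 1),
never exactly zero.

**Expected-count test.** For each site with a reconstructed substitution
on both branches, the probability that both end in the same amino acid is
accumulated under a stated substitution process: `equal` (uniform over the
19 non-ancestral residues; 1/19 for identical ancestral states, 18/361
otherwise) or `empirical` (derived residues weighted by their frequency
among all substitutions reconstructed on the tree). The observed count of
same-derived sites is tested against Poisson(expected), upper tail, and
multiplied by the number of branch pairs tested (capped at 1). `equal` is
the default and is echoed in output metadata.

## Relative-rate tests

Two ingroup sequences and an outgroup on a star tree, with a Muse–Gaut-
style decomposition: each branch carries separate synonymous and
nonsynonymous length parameters (shared κ), so the two rate components can
be constrained independently. The synonymous (nonsynonymous) test
constrains the two ingroup synonymous (nonsynonymous) lengths equal under
the null; each LRT has df = 1. Note that under the total-rate branch-length
convention, equal branch lengths with different ω imply *different*
synonymous rates — the decomposition here avoids that confound.

## Sliding-window dN/dS

NG86 counting: per codon, each position contributes the fraction of its
three single-nucleotide changes that are synonymous (changes to stops count
as nonsynonymous); differences are averaged over all orders of the
differing positions, excluding pathways through stop codons (if every
pathway is blocked — possible only for triple differences — stop-passing
pathways are readmitted with stop steps counted as nonsynonymous).
Proportions are corrected with the Jukes–Cantor transform
d = −(3/4)·ln(1 − 4p/3), undefined (flagged, NaN) at p ≥ 3/4. Gapped or
ambiguous codon pairs are skipped.

Windows are anchored at position 1, default 90 nt with 36 nt step (both
must be codon multiples); the trailing partial window is discarded, so a
1818-nt alignment yields 49 windows. The group ω per window is the ratio
of group-mean dN to group-mean dS (not the mean of per-pair ratios, which
is undefined whenever any pair has dS = 0); ω is flagged undefined when
mean dS is 0. These conventions are recorded in the output.

## Simulator

Sequences evolve down the tree from a root drawn from π (or supplied).
Default mode samples each codon per branch directly from P(t) — exact, no
time discretization; an event-resolved mode draws exponential waiting times
and records every substitution (branch, site, time, from, to), used for
substitution accounting. Site classes are drawn once per site and inherited
across the whole tree; classes 2a/2b switch to the foreground ω only on
foreground branches. Branch-length semantics match the likelihood engine
exactly (mixture-averaged scaling), which the round-trip recovery tests
depend on. One master seed; per-replicate streams are derived
deterministically so any replicate is reproducible in isolation.

## Synthetic study conditions and what the tests show

The packaged generator and the calibration suite use conditions chosen to
mirror a single-gene mammalian study: ~600 codons (the scale of a complete
coding sequence), 6–12 taxa on a ladder tree with tip branches of 0.08 and
internal branches of 0.04 expected substitutions/codon, κ = 2, strong
purifying background (ω ≈ 0.1), and a foreground ancestral branch of 0.3 —
long enough, as real ancestral branches spanning tens of millions of years
are, to accumulate the handful of substitutions the branch-site and
convergence machinery needs. Fixture data sets: (i) neutral one-ratio
evolution, (ii) two-ratio with elevated foreground ω, (iii) branch-site
positive selection (ω2 = 4 on 10% of sites), (iv) forced parallel
substitutions (three sites overwritten with the same derived codon in two
independent clades on top of purifying background evolution).

Calibration designs (fixed, seeded):

- one-ratio ω recovery: 600 codons × 12 taxa × 20 replicates, median
  absolute error ≤ 0.05;
- branch-site test-2 type-I error: 100 replicates at 150 codons × 6 taxa
  simulated under the ω2 = 1 null, rejections at α = 0.05 at or below
  nominal within binomial error (χ² at the boundary is conservative, so
  the observed rate is typically near zero);
- branch-site test-2 power: 50 replicates at 600 codons × 8 taxa with
  ω2 = 4 on 10% of sites, majority rejection;
- bootstrap-p calibration: 50 replicates of convergence-free data, 200
  simulations each, fraction with p ≤ 0.05 within binomial error of 0.05.

The generator emulates the substitution process the models assume — no
indels, no recombination, no rate variation beyond the branch-site
classes, site-independent evolution, correct model family. Passing tests
therefore demonstrate internal correctness and statistical calibration
*under the model*, not robustness to alignment error, model
misspecification, or recombination in real data; the toolkit likewise
assumes its input alignment is recombination-free and codon-aware.

## Known limitations

- Site identification is NEB, not BEB; with few foreground substitutions
  the flagged site set is sensitive to parameter uncertainty.
- No gamma rate variation across sites; no empirical codon models.
- The independence approximation in the convergence posteriors ignores
  correlation between a node and its neighbor induced by shared data.
- Joint ancestral reconstruction and stochastic mapping are out of scope;
  marginal MAP sequences need not form a jointly optimal assignment.
- Free-ratio fits on large trees are expensive (one ω per branch,
  numerically differentiated); use them for exploration, not inference at
  scale.
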