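"""Maximum-likelihood fitting of branch and branch-site codon models.

The model battery mirrors the standard dN/dS toolbox: the one-ratio model
(single ω for the whole tree), the two-ratio model (separate ω on marked
foreground branches), the free-ratio model (independent ω per branch), the
nearly-neutral site model M1a, and branch-site model A with its ω2 = 1 null.
Nested fits are compared with likelihood-ratio tests against χ².

Optimization is box-constrained L-BFGS-B over (κ, ω values, mixture
proportions, branch lengths), with a heuristic start (ω = 0.2, κ = 2) plus
optional random restarts.  Branch lengths are re-optimized under every model
by default, matching the parameter accounting of codon-model software (np =
branches + κ + model-specific free parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .engine import (CodonModelParams, LikelihoodEngine, SiteClassMix,
                     estimate_frequencies)
from .tree import LabeledTree

_KAPPA_BOUNDS = (0.05, 100.0)
_OMEGA_BOUNDS = (1e-6, 50.0)
_LENGTH_BOUNDS = (1e-7, 20.0)
_PROP_BOUNDS = (1e-6, 1 - 1e-6)


@dataclass
class CodonModelFit:
    """A fitted codon model: parameters, log-likelihood, and bookkeeping."""

    model: str
    ll: float
    n_params: int
    kappa: float
    pi: np.ndarray
    frequency_scheme: str
    tree: LabeledTree  # copy carrying ML branch lengths
    omega_by_class: dict | None = None  # branch models
    mix: SiteClassMix | None = None  # site/branch-site models
    mix_params: dict = field(default_factory=dict)
    converged: bool = True
    n_restarts: int = 0
    warnings: list = field(default_factory=list)

    @property
    def params(self) -> CodonModelParams:
        omega = self.omega_by_class if self.omega_by_class is not None else {0: 1.0}
        return CodonModelParams(self.kappa, omega, self.pi, self.frequency_scheme)

    def engine(self, aln: CodonAlignment) -> LikelihoodEngine:
        return LikelihoodEngine(aln, self.tree)

    def summary(self) -> dict:
        out = {
            "model": self.model,
            "np": self.n_params,
            "lnL": self.ll,
            "kappa": self.kappa,
            "converged": self.converged,
        }
        if self.omega_by_class is not None:
            for c, w in sorted(self.omega_by_class.items()):
                out[f"omega_class{c}"] = w
        out.update(self.mix_params)
        return out


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models."""

    statistic: float
    df: int
    p: float
    alt_model: str = ""
    null_model: str = ""


def lrt(alt: CodonModelFit, null: CodonModelFit, df: int | None = None,
        boundary_mixture: bool = False) -> LRTResult:
    """2Δℓ against χ²(df); the statistic is clamped at zero.

    ``boundary_mixture`` applies the 50:50 mixture of χ²(df) and a point mass
    at zero appropriate when the null pins a parameter at the boundary (the
    conventional plain-χ² test is the default and is conservative).
    """
    if df is None:
        df = alt.n_params - null.n_params
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    stat = max(0.0, 2.0 * (alt.ll - null.ll))
    p = float(chi2.sf(stat, df))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return LRTResult(stat, df, min(p, 1.0), alt.model, null.model)


# ---------------------------------------------------------------------------
# optimizer scaffolding

def _starts(n_restarts: int, seed: int):
    """Heuristic start followed by random draws (log-uniform rates)."""
    rng = np.random.default_rng(seed)
    yield {"kappa": 2.0, "omega": 0.2, "length": 0.1}
    for _ in range(n_restarts):
        yield {
            "kappa": float(np.exp(rng.uniform(np.log(0.5), np.log(8.0)))),
            "omega": float(np.exp(rng.uniform(np.log(0.02), np.log(2.0)))),
            "length": float(rng.uniform(0.02, 0.3)),
        }


def _run_optimizer(objective, x0, bounds, tol):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "gtol": 1e-7, "maxiter": 500})
    return res


def _no_variable_sites(aln: CodonAlignment) -> bool:
    idx = aln.codon_indices()
    for col in idx.T:
        states = {v for v in col if v >= 0}
        if len(states) > 1:
            return False
    return True


class _FitProblem:
    """Shared machinery: pack/unpack parameter vectors and evaluate −ℓ."""

    def __init__(self, aln, tree, pi, scheme, optimize_branch_lengths, init_lengths):
        self.engine = LikelihoodEngine(aln, tree)
        self.tree = tree
        self.pi = pi
        self.scheme = scheme
        self.opt_lengths = optimize_branch_lengths
        self.n_branches = tree.n_branches
        self.init_lengths = init_lengths
        if not optimize_branch_lengths and any(t is None for t in tree.get_lengths()):
            raise ValueError("branch lengths must be set when not optimized")

    def length_block(self, start):
        if not self.opt_lengths:
            return [], []
        if self.init_lengths is not None:
            x0 = list(self.init_lengths)
        else:
            current = self.tree.get_lengths()
            x0 = [t if t is not None else start["length"] for t in current]
        x0 = [min(max(t, _LENGTH_BOUNDS[0]), _LENGTH_BOUNDS[1]) for t in x0]
        return x0, [_LENGTH_BOUNDS] * self.n_branches

    def apply_lengths(self, x_tail):
        if self.opt_lengths:
            self.tree.set_lengths(x_tail)

    def neg_ll(self, params, mix):
        try:
            ll, _ = self.engine.log_likelihood(params, mix)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll


def _finalize(problem, best, model_name, extra_np, n_restarts, build_fit):
    converged = best["success"]
    fit = build_fit(best)
    fit.model = model_name
    fit.n_params = problem.n_branches + 1 + extra_np
    fit.converged = converged
    fit.n_restarts = n_restarts
    return fit


# ---------------------------------------------------------------------------
# branch models

def fit_branch_model(aln: CodonAlignment, tree: LabeledTree, class_assignment=None,
                     *, frequency_scheme: str = "F3x4", pi=None,
                     optimize_branch_lengths: bool = True, init_lengths=None,
                     n_restarts: int = 1, seed: int = 0, tol: float = 1e-8) -> CodonModelFit:
    """Fit a branch model: one ω per branch class.

    ``class_assignment`` is ``None`` (use the tree's branch marks),
    ``"one-ratio"``, ``"free-ratio"``, or a dict branch-index → class.
    """
    work = tree.copy()
    if class_assignment == "one-ratio":
        for b in work.branches:
            b.mark = 0
    elif class_assignment == "free-ratio":
        for i, b in enumerate(work.branches):
            b.mark = i
    elif isinstance(class_assignment, dict):
        for i, b in enumerate(work.branches):
            b.mark = class_assignment[i]
    elif class_assignment is not None:
        raise ValueError(f"bad class_assignment: {class_assignment!r}")

    classes = sorted({b.mark for b in work.branches})
    if pi is None:
        pi = estimate_frequencies(aln, frequency_scheme)
    problem = _FitProblem(aln, work, pi, frequency_scheme, optimize_branch_lengths, init_lengths)

    fit_warnings = []
    if _no_variable_sites(aln):
        fit_warnings.append("alignment has no variable sites; ω and κ are unidentifiable")

    best = None
    for start in _starts(n_restarts, seed):
        x0 = [start["kappa"]] + [start["omega"]] * len(classes)
        bounds = [_KAPPA_BOUNDS] + [_OMEGA_BOUNDS] * len(classes)
        lb, lbb = problem.length_block(start)
        x0 += lb
        bounds += lbb

        def objective(x):
            kappa = x[0]
            omega = {c: x[1 + i] for i, c in enumerate(classes)}
            problem.apply_lengths(x[1 + len(classes):])
            params = CodonModelParams(kappa, omega, pi, frequency_scheme)
            return problem.neg_ll(params, None)

        res = _run_optimizer(objective, x0, bounds, tol)
        if best is None or -res.fun > best["ll"]:
            best = {"ll": -res.fun, "x": res.x, "success": bool(res.success)}

    x = best["x"]
    omega = {c: float(x[1 + i]) for i, c in enumerate(classes)}
    problem.apply_lengths(x[1 + len(classes):])
    if class_assignment == "one-ratio" or classes == [0]:
        model_name = "one-ratio"
    elif class_assignment == "free-ratio":
        model_name = "free-ratio"
    elif len(classes) == 2:
        model_name = "two-ratio"
    else:
        model_name = f"branch-{len(classes)}-ratio"

    fit = CodonModelFit(
        model=model_name, ll=best["ll"], n_params=work.n_branches + 1 + len(classes),
        kappa=float(x[0]), pi=pi, frequency_scheme=frequency_scheme, tree=work,
        omega_by_class=omega, converged=best["success"], n_restarts=n_restarts,
        warnings=fit_warnings,
    )
    return fit


def fit_m1a(aln: CodonAlignment, tree: LabeledTree, *, frequency_scheme: str = "F3x4",
            pi=None, optimize_branch_lengths: bool = True, init_lengths=None,
            n_restarts: int = 1, seed: int = 0, tol: float = 1e-8) -> CodonModelFit:
    """Nearly-neutral site model M1a: purifying class (ω0 < 1, proportion p0)
    plus a neutral class (ω1 = 1)."""
    work = tree.copy()
    if pi is None:
        pi = estimate_frequencies(aln, frequency_scheme)
    problem = _FitProblem(aln, work, pi, frequency_scheme, optimize_branch_lengths, init_lengths)

    fit_warnings = []
    if _no_variable_sites(aln):
        fit_warnings.append("alignment has no variable sites; mixture is unidentifiable")

    best = None
    for start in _starts(n_restarts, seed):
        x0 = [start["kappa"], min(start["omega"], 0.9), 0.8]
        bounds = [_KAPPA_BOUNDS, (1e-6, 1.0), _PROP_BOUNDS]
        lb, lbb = problem.length_block(start)
        x0 += lb
        bounds += lbb

        def objective(x):
            problem.apply_lengths(x[3:])
            params = CodonModelParams(x[0], {0: 1.0}, pi, frequency_scheme)
            return problem.neg_ll(params, SiteClassMix.m1a(x[2], x[1]))

        res = _run_optimizer(objective, x0, bounds, tol)
        if best is None or -res.fun > best["ll"]:
            best = {"ll": -res.fun, "x": res.x, "success": bool(res.success)}

    x = best["x"]
    problem.apply_lengths(x[3:])
    return CodonModelFit(
        model="M1a", ll=best["ll"], n_params=work.n_branches + 1 + 2,
        kappa=float(x[0]), pi=pi, frequency_scheme=frequency_scheme, tree=work,
        mix=SiteClassMix.m1a(float(x[2]), float(x[1])),
        mix_params={"p0": float(x[2]), "p1": 1 - float(x[2]), "omega0": float(x[1]), "omega1": 1.0},
        converged=best["success"], n_restarts=n_restarts, warnings=fit_warnings,
    )


def fit_branch_site_a(aln: CodonAlignment, tree: LabeledTree, foreground_mark: int = 1,
                      fix_omega2: bool = False, *, frequency_scheme: str = "F3x4", pi=None,
                      optimize_branch_lengths: bool = True, init_lengths=None,
                      n_restarts: int = 1, seed: int = 0, tol: float = 1e-8) -> CodonModelFit:
    """Branch-site model A on the branches carrying ``foreground_mark``.

    Four site classes: 0 (ω0 everywhere), 1 (neutral everywhere), 2a/2b
    (ω0/1 on background, shared ω2 on foreground).  The alternative estimates
    ω2 ≥ 1; the null (``fix_omega2``) pins ω2 = 1.
    """
    work = tree.copy()
    fg = [b for b in work.branches if b.mark == foreground_mark]
    if not fg:
        raise ValueError(f"no branch carries foreground mark {foreground_mark}")
    # collapse marks to binary background/foreground for the mixture maps
    for b in work.branches:
        b.mark = 1 if b.mark == foreground_mark else 0
    if pi is None:
        pi = estimate_frequencies(aln, frequency_scheme)
    problem = _FitProblem(aln, work, pi, frequency_scheme, optimize_branch_lengths, init_lengths)

    def mix_from(q1, q2, omega0, omega2):
        return SiteClassMix.branch_site_a(q1 * q2, q1 * (1 - q2), omega0, omega2, foreground_mark=1)

    best = None
    for start in _starts(n_restarts, seed):
        x0 = [start["kappa"], min(start["omega"], 0.9), 0.85, 0.85]
        bounds = [_KAPPA_BOUNDS, (1e-6, 1.0), _PROP_BOUNDS, _PROP_BOUNDS]
        if not fix_omega2:
            x0.append(2.0)
            bounds.append((1.0, _OMEGA_BOUNDS[1]))
        lb, lbb = problem.length_block(start)
        n_head = len(x0)
        x0 += lb
        bounds += lbb

        def objective(x):
            omega2 = 1.0 if fix_omega2 else x[4]
            problem.apply_lengths(x[n_head:])
            params = CodonModelParams(x[0], {0: 1.0, 1: 1.0}, pi, frequency_scheme)
            return problem.neg_ll(params, mix_from(x[2], x[3], x[1], omega2))

        res = _run_optimizer(objective, x0, bounds, tol)
        if best is None or -res.fun > best["ll"]:
            best = {"ll": -res.fun, "x": res.x, "success": bool(res.success)}

    x = best["x"]
    omega2 = 1.0 if fix_omega2 else float(x[4])
    n_head = 4 if fix_omega2 else 5
    problem.apply_lengths(x[n_head:])
    mix = mix_from(float(x[2]), float(x[3]), float(x[1]), omega2)
    p = mix.proportions
    return CodonModelFit(
        model="branch-site-A-null" if fix_omega2 else "branch-site-A",
        ll=best["ll"], n_params=work.n_branches + 1 + (3 if fix_omega2 else 4),
        kappa=float(x[0]), pi=pi, frequency_scheme=frequency_scheme, tree=work,
        mix=mix,
        mix_params={"p0": float(p[0]), "p1": float(p[1]), "p2a": float(p[2]),
                    "p2b": float(p[3]), "omega0": float(x[1]), "omega2": omega2},
        converged=best["success"], n_restarts=n_restarts,
    )


def site_posteriors(fit: CodonModelFit, aln: CodonAlignment, elevated_threshold: float = 0.5):
    """Per-site posterior over site classes under a fitted mixture model
    (naive empirical Bayes: fitted parameters treated as known).

    Returns (posteriors, elevated) where ``posteriors`` is (n_sites,
    n_classes) and ``elevated`` flags sites whose combined class-2a/2b
    posterior exceeds the threshold (branch-site models only).
    """
    if fit.mix is None:
        raise ValueError("site posteriors require a fitted mixture model")
    engine = LikelihoodEngine(aln, fit.tree)
    post = engine.class_posteriors(fit.params, fit.mix)
    if post.shape[1] >= 4:
        elevated = (post[:, 2] + post[:, 3]) > elevated_threshold
    else:
        elevated = np.zeros(post.shape[0], dtype=bool)
    return post, elevated
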