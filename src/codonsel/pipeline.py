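"""End-to-end analysis pipeline and packaged synthetic fixtures.

``run_pipeline`` drives the full battery from a YAML config: branch-model
fits and LRTs, branch-site tests, ancestral reconstruction with
lineage-specific substitution extraction, branch-pair convergence tests,
pairwise relative-rate tests, and sliding-window ω profiles.  Every stage
writes a TSV; a manifest records input hashes, all effective parameter
values (including defaults the analysis leaves open: frequency scheme,
support thresholds, simulating model for nulls), seeds, and per-stage
status, so a rerun with the same manifest reproduces the same outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (map_site_numbers, read_codon_alignment,
                        write_codon_alignment)
from .ancestral import (branch_substitutions, lineage_specific_substitutions,
                        marginal_reconstruct)
from .convergence import analyze_pair
from .engine import CodonModelParams, SiteClassMix
from .models import fit_branch_model, fit_branch_site_a, fit_m1a, lrt, site_posteriors
from .relrate import pairwise_relative_rate
from .simulate import SimConfig, simulate_alignment
from .tree import LabeledTree, read_tree
from .windows import sliding_omega


def resolve_branch(tree: LabeledTree, spec):
    """A branch from a config spec: tip name, internal node name, or a list
    of tip names whose MRCA's parent branch is meant."""
    if isinstance(spec, str):
        return tree.find(spec)
    return tree.mrca(list(spec))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config_path, outdir=None) -> dict:
    """Run the configured stages; returns the manifest (also written as JSON).

    A stage failure is recorded and dependent downstream stages are skipped
    with explicit status rather than aborting the run.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    outdir = Path(outdir or cfg.get("outdir", config_path.parent / "results"))
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(cfg.get("seed", 0))
    scheme = cfg.get("frequency_scheme", "F3x4")
    n_restarts = int(cfg.get("n_restarts", 1))
    manifest = {
        "tool": "codonsel",
        "version": __version__,
        "inputs": {
            "alignment": {"path": str(cfg["alignment"]), "sha256": _sha256(cfg["alignment"])},
            "tree": {"path": str(cfg["tree"]), "sha256": _sha256(cfg["tree"])},
        },
        "parameters": {
            "seed": seed,
            "frequency_scheme": scheme,
            "n_restarts": n_restarts,
            "support_threshold": cfg.get("support_threshold", 0.7),
            "null_simulation_model": "fitted one-ratio (ML branch lengths)",
            "n_sim": cfg.get("n_sim", 1000),
            "substitution_process": cfg.get("substitution_process", "equal"),
            "window": cfg.get("window", 90),
            "step": cfg.get("step", 36),
        },
        "stages": {},
    }

    aln = read_codon_alignment(cfg["alignment"], cfg.get("alignment_format", "fasta"))
    tree = read_tree(Path(cfg["tree"]).read_text())
    numbering = None
    if cfg.get("reference_taxon"):
        numbering = map_site_numbers(aln, cfg["reference_taxon"])

    skip = set(cfg.get("skip_stages", []))

    def stage(name, fn, *, requires=()):
        if name in skip:
            manifest["stages"][name] = {"status": "skipped (config)"}
            return None
        for dep in requires:
            if manifest["stages"].get(dep, {}).get("status") != "ok":
                manifest["stages"][name] = {"status": f"skipped (requires {dep})"}
                return None
        t0 = time.time()
        try:
            result = fn()
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            return result
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            manifest["stages"][name] = {"status": f"error: {exc}",
                                        "seconds": round(time.time() - t0, 2)}
            return None

    fits = {}

    def do_fits():
        rows = []
        one = fit_branch_model(aln, tree, "one-ratio", frequency_scheme=scheme,
                               n_restarts=n_restarts, seed=seed)
        fits["one-ratio"] = one
        rows.append(one.summary())
        init = one.tree.get_lengths()
        marks = sorted({b.mark for b in tree.branches} - {0})
        for mark in marks:
            assign = {i: (1 if b.mark == mark else 0) for i, b in enumerate(tree.branches)}
            two = fit_branch_model(aln, tree, assign, frequency_scheme=scheme,
                                   init_lengths=init, n_restarts=n_restarts, seed=seed)
            two.model = f"two-ratio (mark {mark})"
            fits[f"two-ratio-{mark}"] = two
            row = two.summary()
            test = lrt(two, one)
            row.update({"compared_to": "one-ratio", "2dl": test.statistic,
                        "df": test.df, "P": test.p})
            rows.append(row)
        if cfg.get("free_ratio", True):
            free = fit_branch_model(aln, tree, "free-ratio", frequency_scheme=scheme,
                                    init_lengths=init, n_restarts=0, seed=seed)
            fits["free-ratio"] = free
            row = free.summary()
            test = lrt(free, one)
            row.update({"compared_to": "one-ratio", "2dl": test.statistic,
                        "df": test.df, "P": test.p})
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "branch_models.tsv", sep="\t", index=False)
        return rows

    def do_branch_site():
        rows = []
        m1a = fit_m1a(aln, tree, frequency_scheme=scheme, n_restarts=n_restarts,
                      seed=seed, init_lengths=fits["one-ratio"].tree.get_lengths())
        fits["M1a"] = m1a
        rows.append(m1a.summary())
        init = m1a.tree.get_lengths()
        marks = sorted({b.mark for b in tree.branches} - {0})
        for mark in marks:
            alt = fit_branch_site_a(aln, tree, foreground_mark=mark,
                                    frequency_scheme=scheme, init_lengths=init,
                                    n_restarts=n_restarts, seed=seed)
            null = fit_branch_site_a(aln, tree, foreground_mark=mark, fix_omega2=True,
                                     frequency_scheme=scheme, init_lengths=init,
                                     n_restarts=n_restarts, seed=seed)
            fits[f"bsA-{mark}"] = alt
            t1 = lrt(alt, m1a, df=2)
            t2 = lrt(alt, null, df=1)
            post, elevated = site_posteriors(alt, aln)
            sites = [
                numbering.label(s + 1) if numbering else str(s + 1)
                for s in np.nonzero(elevated)[0]
            ]
            row = alt.summary()
            row.update({"foreground_mark": mark,
                        "test1_2dl": t1.statistic, "test1_P": t1.p,
                        "test2_2dl": t2.statistic, "test2_P": t2.p,
                        "elevated_sites_NEB": ",".join(sites)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "branch_site.tsv", sep="\t", index=False)
        return rows

    anc_box = {}

    def do_ancestral():
        fit = fits["one-ratio"]
        anc = marginal_reconstruct(aln, fit)
        anc_box["anc"] = anc
        events = branch_substitutions(anc, manifest["parameters"]["support_threshold"],
                                      numbering)
        rows = [{
            "branch": ev.branch_name or f"node{ev.branch_index}", "site": ev.site,
            "label": ev.label(), "from": ev.ancestral, "to": ev.derived,
            "support": round(ev.support, 4),
        } for ev in events]
        pd.DataFrame(rows).to_csv(outdir / "branch_substitutions.tsv", sep="\t", index=False)
        lineage_rows = []
        for spec in cfg.get("lineage_branches", []):
            focal = resolve_branch(tree_of(fit), spec)
            specific = lineage_specific_substitutions(events, aln, fit.tree, focal)
            for ev in specific:
                lineage_rows.append({"focal": str(spec), "label": ev.label(),
                                     "support": round(ev.support, 4)})
        if cfg.get("lineage_branches"):
            pd.DataFrame(lineage_rows).to_csv(outdir / "lineage_specific.tsv",
                                              sep="\t", index=False)
        return events

    def tree_of(fit):
        return fit.tree

    def do_convergence():
        fit = fits["one-ratio"]
        pairs = cfg.get("branch_pairs", [])
        rows = []
        for pair_spec in pairs:
            b1 = resolve_branch(fit.tree, pair_spec[0])
            b2 = resolve_branch(fit.tree, pair_spec[1])
            rep = analyze_pair(aln, fit, (b1, b2), n_sim=manifest["parameters"]["n_sim"],
                               seed=seed, process=manifest["parameters"]["substitution_process"],
                               n_pairs_tested=len(pairs), numbering=numbering,
                               anc=anc_box.get("anc"))
            rows.append({
                "pair": f"{rep.branch_names[0]} vs {rep.branch_names[1]}",
                "total_convergence": round(rep.total_convergence, 4),
                "total_divergence": round(rep.total_divergence, 4),
                "parallel_sites": ";".join(f"{lbl} ({p:.3f})" for _, lbl, p in rep.parallel_sites),
                "sim_p": rep.sim_p,
                "expected_parallel": round(rep.expected_parallel, 4),
                "observed_parallel": rep.observed_parallel,
                "poisson_p": rep.poisson_p,
                "corrected_p": rep.corrected_p,
            })
        pd.DataFrame(rows).to_csv(outdir / "convergence.tsv", sep="\t", index=False)
        return rows

    def do_relrate():
        rows = []
        for trio in cfg.get("relative_rate", []):
            res = pairwise_relative_rate(aln, trio["ingroup1"], trio["ingroup2"],
                                         trio["outgroup"])
            rows.append({
                "ingroup1": res.ingroup1, "ingroup2": res.ingroup2,
                "outgroup": res.outgroup,
                "syn_LRT": round(res.syn_statistic, 3), "syn_P": res.syn_p,
                "nonsyn_LRT": round(res.nonsyn_statistic, 3), "nonsyn_P": res.nonsyn_p,
            })
        pd.DataFrame(rows).to_csv(outdir / "relative_rate.tsv", sep="\t", index=False)
        return rows

    def do_windows():
        frames = []
        for group, taxa in (cfg.get("groups") or {}).items():
            prof = sliding_omega(aln, taxa, manifest["parameters"]["window"],
                                 manifest["parameters"]["step"], group=group)
            t = prof.table.copy()
            t.insert(0, "group", group)
            frames.append(t)
        if frames:
            pd.concat(frames).to_csv(outdir / "window_omega.tsv", sep="\t", index=False)
        return len(frames)

    stage("fit", do_fits)
    stage("branch_site", do_branch_site, requires=("fit",))
    stage("ancestral", do_ancestral, requires=("fit",))
    stage("convergence", do_convergence, requires=("fit",))
    stage("relrate", do_relrate)
    stage("windows", do_windows)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# synthetic fixtures

def _balanced_tree(n_tips: int, tip_len: float = 0.08, inner_len: float = 0.04,
                   marks: dict | None = None, mark_len: float = 0.3) -> LabeledTree:
    """Ladder tree with uniform branch lengths; ``marks`` maps tip name (or
    tuple of tip names → MRCA branch) to a branch-class mark.  Marked
    branches get ``mark_len`` — foreground branches model an ancestral
    lineage long enough to accumulate substitutions."""
    nwk = f"t0:{tip_len}"
    for i in range(1, n_tips):
        nwk = f"({nwk},t{i}:{tip_len}):{inner_len}"
    tree = read_tree(nwk[: nwk.rfind(":")] + ";")
    for key, mark in (marks or {}).items():
        node = tree.find(key) if isinstance(key, str) else tree.mrca(list(key))
        node.mark = mark
        node.length = mark_len
    return tree


def make_fixtures(seed: int, outdir) -> dict:
    """Write the four packaged synthetic data sets, each with truth tables.

    (i) a 12-taxon neutral-evolution alignment (single ω = 1); (ii) a
    two-ratio alignment with elevated foreground ω; (iii) a branch-site
    positive-selection alignment; (iv) a forced-parallel-substitution
    alignment.  Regeneration under the same seed is bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .simulate import replicate_seeds

    seeds = replicate_seeds(seed, 4)
    pi = np.full(61, 1 / 61.0)
    info = {}

    def emit(name, tree, sim, truth: dict):
        write_codon_alignment(sim.alignment, outdir / f"{name}.fasta")
        (outdir / f"{name}.nwk").write_text(tree.to_newick() + "\n")
        pd.DataFrame([truth]).to_csv(outdir / f"{name}_truth.tsv", sep="\t", index=False)
        info[name] = truth

    # (i) neutral one-ratio
    tree = _balanced_tree(12)
    params = CodonModelParams(2.0, {0: 1.0}, pi)
    sim = simulate_alignment(SimConfig(tree, params, 300, seed=int(seeds[0])))
    emit("neutral", tree, sim, {"model": "one-ratio", "omega": 1.0, "kappa": 2.0,
                                "n_codons": 300, "seed": int(seeds[0])})

    # (ii) two-ratio with elevated foreground ω on the branch above (t0, t1)
    tree = _balanced_tree(12, marks={("t0", "t1"): 1})
    params = CodonModelParams(2.0, {0: 0.1, 1: 0.9}, pi)
    sim = simulate_alignment(SimConfig(tree, params, 300, seed=int(seeds[1])))
    emit("two_ratio", tree, sim, {"model": "two-ratio", "omega_bg": 0.1, "omega_fg": 0.9,
                                  "kappa": 2.0, "n_codons": 300, "seed": int(seeds[1])})

    # (iii) branch-site positive selection on the same foreground branch
    tree = _balanced_tree(12, marks={("t0", "t1"): 1})
    params = CodonModelParams(2.0, {0: 1.0, 1: 1.0}, pi)
    mix = SiteClassMix.branch_site_a(0.72, 0.18, 0.1, 4.0)
    sim = simulate_alignment(SimConfig(tree, params, 300, seed=int(seeds[2]), mix=mix))
    emit("branch_site", tree, sim, {"model": "branch-site-A", "omega0": 0.1, "omega2": 4.0,
                                    "p0": 0.72, "p1": 0.18, "n_codons": 300,
                                    "seed": int(seeds[2])})

    # (iv) forced parallel substitutions on two independent branches
    tree = _balanced_tree(12, marks={("t0", "t1"): 1, "t5": 2})
    params = CodonModelParams(2.0, {0: 0.05, 1: 0.05, 2: 0.05}, pi)
    sim = simulate_alignment(SimConfig(tree, params, 300, seed=int(seeds[3])))
    aln = sim.alignment
    rng = np.random.default_rng(int(seeds[3]))
    sense = aln.code.sense_codons
    forced_sites = sorted(rng.choice(np.arange(10, 290), size=3, replace=False))
    clade1 = {"t0", "t1"}
    clade2 = {"t5"}
    for s in forced_sites:
        current = aln.codons[aln.taxa.index("t2"), s]
        target_aa = aln.code.codon_to_aa[current]
        choices = [c for c in sense if aln.code.codon_to_aa[c] not in (target_aa,)]
        derived = str(rng.choice(choices))
        for t in clade1 | clade2:
            aln.codons[aln.taxa.index(t), s] = derived
    write_codon_alignment(aln, outdir / "parallel.fasta")
    (outdir / "parallel.nwk").write_text(tree.to_newick() + "\n")
    truth = {"model": "one-ratio + forced parallel", "omega": 0.05,
             "forced_sites": ",".join(str(s + 1) for s in forced_sites),
             "n_codons": 300, "seed": int(seeds[3])}
    pd.DataFrame([truth]).to_csv(outdir / "parallel_truth.tsv", sep="\t", index=False)
    info["parallel"] = truth
    return info
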