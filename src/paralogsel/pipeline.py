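"""End-to-end orchestration: config handling, derived seeds, run reports.

Three entry points mirror the analyses: ``run_trait_pipeline`` (trait
extraction -> model comparison -> fossilization scans -> Bayes factors),
``run_selection_pipeline`` (global nuisance -> FEL per partition ->
Contrast-FEL), and ``run_physiology`` (per-trace SSI -> group tests ->
expression calls).  All randomness flows from one top-level seed through
per-stage derived seeds.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon import CodonPartitionAlignment, contrast_fel_site_test, fel_site_test, fit_global_nuisance
from .ctmc import (
    McmcConfig,
    NodeConstraint,
    SteppingStoneConfig,
    ancestral_constraint_scan,
    fit_ml,
    log_bayes_factor,
    lrt_dependent_vs_independent,
    run_mcmc,
    stepping_stone_logml,
)
from .phylo import BranchClassSpec, read_newick_file
from .physio import CurrentTrace, compare_groups, expression_call, ssi_from_trace
from .traits import ProteinMSA, SiteDefinition, assign_traits, read_trait_csv

__all__ = ["ConfigError", "StageError", "RunReport", "run_trait_pipeline",
           "run_selection_pipeline", "run_physiology", "load_config", "stage_seed"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    pipeline: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return str(obj)


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**32)


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _branch_spec(block: list | None) -> BranchClassSpec | None:
    if not block:
        return None
    classes = []
    for entry in block:
        _check_keys(entry, {"class", "taxa"}, "branch_classes entry")
        classes.append((entry["class"], set(entry["taxa"])))
    return BranchClassSpec(classes)


def _constraints(block: list | None) -> list[tuple[str, NodeConstraint]]:
    out = []
    for entry in block or []:
        _check_keys(entry, {"name", "taxa", "state"}, "constraints entry")
        name = entry.get("name") or f"{entry['state']}@{len(out)}"
        out.append((name, NodeConstraint(frozenset(entry["taxa"]), entry["state"])))
    return out


# ---------------------------------------------------------------------------
# trait pipeline
# ---------------------------------------------------------------------------

_TRAIT_KEYS = {"tree", "traits", "msa", "site", "branch_classes", "constraints",
               "root_prior", "mcmc", "stepping_stone", "ml", "outdir", "seed"}


def run_trait_pipeline(config: dict) -> RunReport:
    _check_keys(config, _TRAIT_KEYS, "trait pipeline config")
    seed = int(config.get("seed", 0))
    report = RunReport(pipeline="trait", seed=seed, parameters={k: config[k] for k in config if k != "outdir"})
    outdir = _prepare_outdir(config.get("outdir"))

    stage = "load_inputs"
    try:
        tree = read_newick_file(config["tree"])
        if "traits" in config:
            traits = read_trait_csv(config["traits"])
        elif "msa" in config:
            site_block = dict(config["site"])
            _check_keys(site_block, {"reference_id", "position", "target_residue", "window", "gap_at_site"}, "site")
            traits = assign_traits(ProteinMSA.from_fasta(config["msa"]), SiteDefinition(**site_block))
        else:
            raise ConfigError("provide either 'traits' or 'msa' + 'site'")
        spec = _branch_spec(config.get("branch_classes"))
        if spec is not None:
            tree = tree.tag_branches(spec)
        delta_classes = frozenset(c for c, _ in spec.classes) if spec else frozenset({"delta"})
        constraints = _constraints(config.get("constraints"))
        root_prior = config.get("root_prior", "stationary")
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "ml_and_lrt"
    try:
        ml_block = dict(config.get("ml", {}))
        _check_keys(ml_block, {"n_starts"}, "ml")
        n_starts = int(ml_block.get("n_starts", 5))
        fit_i = fit_ml(tree, traits, "independent", delta_classes=delta_classes,
                       root_prior=root_prior, n_starts=n_starts, seed=stage_seed(seed, "ml_indep"))
        init = list(fit_i.model.rates()) + [fit_i.model.q10]
        fit_d = fit_ml(tree, traits, "dependent", delta_classes=delta_classes,
                       root_prior=root_prior, n_starts=n_starts, init=init,
                       seed=stage_seed(seed, "ml_dep"))
        statistic, p = lrt_dependent_vs_independent(fit_i.log_likelihood, fit_d.log_likelihood)
        report.results["ml"] = {
            "independent": {"params": fit_i.params, "log_likelihood": fit_i.log_likelihood},
            "dependent": {"params": fit_d.params, "log_likelihood": fit_d.log_likelihood},
            "lrt": {"statistic": statistic, "p_value": p},
        }
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "mcmc"
    try:
        mcmc_block = dict(config.get("mcmc", {}))
        _check_keys(mcmc_block, {"iterations", "burn_in", "thinning", "prior_mean", "proposal_scale"}, "mcmc")
        runs = {"unconstrained": []}
        runs.update({name: [c] for name, c in constraints})
        mcmc_out = {}
        for name, cons in runs.items():
            cfg = McmcConfig(seed=stage_seed(seed, f"mcmc:{name}"), **mcmc_block)
            res = run_mcmc(tree, traits, "dependent", cons, cfg,
                           delta_classes=delta_classes, root_prior=root_prior,
                           init=list(fit_d.model.rates()))
            mcmc_out[name] = {
                "medians": res.medians, "ratio_medians": res.ratio_medians,
                "acceptance_rate": res.acceptance_rate, "ess": res.ess,
                "warnings": res.warnings,
            }
            if outdir is not None:
                pd.DataFrame(res.samples).to_csv(outdir / f"mcmc_samples_{name}.csv", index=False)
        report.results["mcmc"] = mcmc_out
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "bayes_factors"
    try:
        ss_block = dict(config.get("stepping_stone", {}))
        _check_keys(ss_block, {"n_stones", "iterations_per_stone", "shape", "prior_mean", "proposal_scale"},
                    "stepping_stone")
        logml = {}
        for name, cons in runs.items():
            cfg = SteppingStoneConfig(seed=stage_seed(seed, f"ss:{name}"), **ss_block)
            logml[name] = stepping_stone_logml(tree, traits, "dependent", cons, cfg,
                                              delta_classes=delta_classes,
                                              root_prior=root_prior).log_marginal_likelihood
        bf = {}
        for name in logml:
            if name == "unconstrained":
                continue
            value, verdict = log_bayes_factor(logml[name], logml["unconstrained"])
            bf[f"{name}_vs_unconstrained"] = {"log_bf": value, "verdict": verdict}
        names = [n for n in logml if n != "unconstrained"]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                value, verdict = log_bayes_factor(logml[a], logml[b])
                bf[f"{a}_vs_{b}"] = {"log_bf": value, "verdict": verdict}
        report.results["log_marginal_likelihoods"] = logml
        report.results["bayes_factors"] = bf
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "constraint_scans"
    try:
        scans = {}
        for name, cons in constraints:
            scan = ancestral_constraint_scan(tree, traits, fit_d.model, cons.taxa)
            scans[name] = {
                "ll_present": scan.ll_present, "ll_absent": scan.ll_absent,
                "ll_unconstrained": scan.ll_unconstrained,
                "identity_ok": scan.identity_ok, "identity_gap": scan.identity_gap,
            }
        report.results["constraint_scans"] = scans
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    if outdir is not None:
        report.to_json(outdir / "trait_report.json")
    return report


# ---------------------------------------------------------------------------
# selection (dN/dS) pipeline
# ---------------------------------------------------------------------------

_SEL_KEYS = {"tree", "alignment", "partition", "sites", "reroot_on", "outdir", "seed", "nuisance"}

SELECTION_COLUMNS = ["site", "dnds_alpha", "p_alpha", "dnds_delta", "p_delta", "p_contrast"]


def run_selection_pipeline(config: dict) -> RunReport:
    _check_keys(config, _SEL_KEYS, "selection pipeline config")
    seed = int(config.get("seed", 0))
    report = RunReport(pipeline="selection", seed=seed,
                       parameters={k: config[k] for k in config if k != "outdir"})
    outdir = _prepare_outdir(config.get("outdir"))

    stage = "load_inputs"
    try:
        tree = read_newick_file(config["tree"])
        if config.get("reroot_on"):
            tree = tree.reroot_on_tip(config["reroot_on"])
        partition = {}
        with open(config["partition"], newline="") as fh:
            for row in csv.DictReader(fh):
                partition[row["id"]] = row["partition"]
        aln = CodonPartitionAlignment.from_fasta(config["alignment"], tree, partition)
        sites = []
        for entry in config["sites"]:
            _check_keys(entry, {"index", "label"}, "sites entry")
            sites.append((int(entry["index"]) - 1, entry.get("label", f"site{entry['index']}")))
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "nuisance_fit"
    try:
        nuis_block = dict(config.get("nuisance", {}))
        _check_keys(nuis_block, {"n_starts"}, "nuisance")
        nuisance = fit_global_nuisance(aln, seed=stage_seed(seed, "nuisance"), **nuis_block)
        report.results["nuisance"] = {
            "kappa": nuisance.kappa, "omega": nuisance.omega,
            "branch_scale": nuisance.branch_scale,
            "log_likelihood": nuisance.log_likelihood,
        }
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "site_tests"
    try:
        rows = []
        for site_idx, label in sites:
            fa = fel_site_test(aln, site_idx, "alpha", nuisance, site_label=label)
            fd = fel_site_test(aln, site_idx, "delta", nuisance, site_label=label)
            cf = contrast_fel_site_test(aln, site_idx, nuisance, site_label=label)
            rows.append({
                "site": label,
                "dnds_alpha": fa.dnds["tested"], "p_alpha": fa.p_value,
                "dnds_delta": fd.dnds["tested"], "p_delta": fd.p_value,
                "p_contrast": cf.p_value,
            })
        table = pd.DataFrame(rows, columns=SELECTION_COLUMNS)
        report.results["site_table"] = rows
        if outdir is not None:
            table.to_csv(outdir / "site_tests.csv", index=False)
            (outdir / "nuisance.json").write_text(json.dumps(report.results["nuisance"], indent=2))
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    if outdir is not None:
        report.to_json(outdir / "selection_report.json")
    return report


# ---------------------------------------------------------------------------
# physiology pipeline
# ---------------------------------------------------------------------------

_PHYS_KEYS = {"traces", "design", "windows", "expression", "outdir", "seed"}


def run_physiology(config: dict) -> RunReport:
    _check_keys(config, _PHYS_KEYS, "physiology config")
    seed = int(config.get("seed", 0))
    report = RunReport(pipeline="physiology", seed=seed,
                       parameters={k: config[k] for k in config if k != "outdir"})
    outdir = _prepare_outdir(config.get("outdir"))

    stage = "ssi"
    try:
        windows = dict(config.get("windows", {}))
        _check_keys(windows, {"peak_window_s", "steady_state_at_s", "steady_state_halfwidth_s",
                              "amiloride_equilibration_s", "amiloride_window_s"}, "windows")
        rows = []
        groups: dict[str, list[float]] = {}
        for entry in config.get("traces", []):
            _check_keys(entry, {"path", "group", "t_switch", "t_amiloride"}, "traces entry")
            trace = CurrentTrace.from_csv(entry["path"], entry["t_switch"], entry["t_amiloride"], **windows)
            res = ssi_from_trace(trace)
            rows.append({"path": str(entry["path"]), "group": entry["group"],
                         "i_peak": res.i_peak, "i_ss": res.i_ss, "i_amil": res.i_amil,
                         "ssi": res.ssi, "undefined": res.undefined})
            groups.setdefault(entry["group"], []).append(res.ssi)
        report.results["ssi"] = rows
        report.results["windows"] = windows or "defaults"
        if len(groups) >= 2:
            comparison = compare_groups(groups, design=config.get("design", "two-sample"))
            report.results["group_test"] = {
                "design": comparison.design, "statistic": comparison.statistic,
                "p_value": comparison.p_value, "pairwise": comparison.pairwise,
                "flags": comparison.flags,
            }
        if outdir is not None and rows:
            pd.DataFrame(rows).to_csv(outdir / "ssi.csv", index=False)
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    stage = "expression"
    try:
        if "expression" in config:
            block = dict(config["expression"])
            _check_keys(block, {"table", "library_total", "metric", "threshold"}, "expression")
            df = pd.read_csv(block["table"])
            calls = expression_call(
                df["count"], df["length_bp"], float(block["library_total"]),
                gene_ids=df["gene"], metric=block.get("metric", "RPKM"),
                threshold=float(block.get("threshold", 0.3)),
            )
            report.results["expression"] = calls.to_dict(orient="records")
            if outdir is not None:
                calls.to_csv(outdir / "expression_calls.csv", index=False)
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        raise StageError(stage, exc) from exc

    if outdir is not None:
        report.to_json(outdir / "physiology_report.json")
    return report


def _prepare_outdir(path) -> Path | None:
    if path is None:
        return None
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
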