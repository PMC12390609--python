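"""End-to-end orchestration: simulate -> classify -> LCA -> evaluate -> TG-ROC.

Each step writes its artifact (CSV/JSON) into the output directory and the
run finishes with a manifest recording the configuration, per-step seeds,
log lines and a SHA-256 hash of every file written. Steps are
checkpointable: a downstream step re-run in a later invocation reads the
saved intermediates and produces the same outputs as an end-to-end run.
A single global seed deterministically derives an independent substream
per step, so identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import evaluate_groups
from .classify import call_record, call_sample
from .lca import assign_classes, label_classes, select_model
from .qpcr_io import (
    Dataset,
    read_results_table,
    to_patterns,
    write_patterns,
    write_results_table,
)
from .simulate import (
    SimConfig,
    default_edna_params,
    default_tissue_params,
    generate_edna_panel,
    generate_tissue_panel,
)
from .tgroc import curves_by_group

logger = logging.getLogger(__name__)

STEPS = ("simulate", "classify", "lca", "evaluate", "tgroc")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    steps: tuple[str, ...] = STEPS
    n_sites: int = 168
    replicates_per_site: int = 3
    lca_classes: tuple[int, ...] = (2, 3, 4)
    lca_starts: int = 20
    tgroc_step: float = 0.5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.steps = tuple(self.steps)
        unknown = [s for s in self.steps if s not in STEPS]
        if unknown:
            raise ConfigError(f"unknown step(s): {unknown}")
        order = {s: i for i, s in enumerate(STEPS)}
        if list(self.steps) != sorted(self.steps, key=order.__getitem__):
            raise ConfigError(f"steps must respect dependency order {STEPS}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        if "lca_classes" in raw:
            raw["lca_classes"] = tuple(raw["lca_classes"])
        return cls(**raw)


def _step_seed(seed: int, step: str) -> int:
    idx = STEPS.index(step)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, step: str) -> Path:
    if not path.exists():
        raise ConfigError(f"step {step!r} needs {path.name}, which was neither "
                          f"produced in this run nor found in the output directory")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured steps and return the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    tissue_csv = out / "tissue_results.csv"
    edna_csv = out / "edna_results.csv"
    patterns_csv = out / "patterns.csv"
    calls_csv = out / "calls.csv"
    fit_json = out / "lca_fit.json"
    assignments_csv = out / "assignments.csv"
    metrics_csv = out / "metrics.csv"
    tgroc_csv = out / "tgroc.csv"
    manifest_path = out / "manifest.json"

    # validate dependencies before running anything
    have = {"simulate": tissue_csv.exists() and edna_csv.exists(),
            "lca": assignments_csv.exists()}
    for step in ("classify", "lca", "evaluate", "tgroc"):
        if step in config.steps and "simulate" not in config.steps and not have["simulate"]:
            raise ConfigError(f"step {step!r} requires 'simulate' outputs")
    if "evaluate" in config.steps and "lca" not in config.steps and not have["lca"]:
        raise ConfigError("eDNA evaluation requires the 'lca' step (proxy truth)")

    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    written: list[Path] = []
    tissue: Dataset | None = None
    edna: Dataset | None = None

    if "simulate" in config.steps:
        seed = _step_seed(config.seed, "simulate")
        log(f"simulate: seed {seed}, {config.n_sites} eDNA pattern rows")
        tissue = generate_tissue_panel(default_tissue_params(), seed)
        edna = generate_edna_panel(
            default_edna_params(),
            SimConfig(seed=seed + 1, n_sites=config.n_sites,
                      replicates_per_site=config.replicates_per_site),
        )
        write_results_table(tissue, tissue_csv)
        write_results_table(edna, edna_csv)
        (out / "sim_params.json").write_text(
            json.dumps({"tissue": tissue.metadata["params"],
                        "edna": edna.metadata["params"],
                        "seed": config.seed}, indent=2)
        )
        written += [tissue_csv, edna_csv, out / "sim_params.json"]

    def load_tissue() -> Dataset:
        nonlocal tissue
        if tissue is None:
            tissue = read_results_table(_require(tissue_csv, "downstream"))
        return tissue

    def load_edna() -> Dataset:
        nonlocal edna
        if edna is None:
            edna = read_results_table(_require(edna_csv, "downstream"))
        return edna

    if "classify" in config.steps:
        log("classify: calling tissue specimens and eDNA replicates")
        rows = []
        for rec in load_tissue().records + load_edna().records:
            for rep in sorted({r.replicate for r in rec.results}):
                if rec.sample_kind == "tissue":
                    call = call_record(rec)
                else:
                    # eDNA is interpreted per extraction replicate
                    call = call_sample([r for r in rec.results if r.replicate == rep])
                rows.append(
                    {
                        "sample_id": rec.sample_id,
                        "replicate": rep,
                        "call": call.call,
                        "deciding_probe": call.deciding_probe.value
                        if call.deciding_probe
                        else "",
                        "deciding_ct": call.deciding_ct if call.deciding_ct else "",
                        "tie_flag": call.tie,
                    }
                )
        pd.DataFrame(rows).to_csv(calls_csv, index=False)
        written.append(calls_csv)

    if "lca" in config.steps:
        seed = _step_seed(config.seed, "lca")
        patterns = to_patterns(load_edna())
        write_patterns(patterns, patterns_csv)
        log(f"lca: fitting classes {config.lca_classes} with {config.lca_starts} starts")
        fit, table = select_model(
            patterns, config.lca_classes, n_starts=config.lca_starts, seed=seed
        )
        labeling = label_classes(fit)
        assignments = assign_classes(fit, labeling, patterns)
        assignments.to_csv(assignments_csv, index=False)
        fit_json.write_text(
            json.dumps(
                {
                    "n_classes": fit.model.n_classes,
                    "prevalence": fit.model.prevalence.tolist(),
                    "response": fit.model.response.tolist(),
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "g_squared": fit.g_squared,
                    "chi_squared": fit.chi_squared,
                    "df_fit": fit.df_fit,
                    "converged": fit.converged,
                    "labeling": {str(k): v for k, v in labeling.mapping.items()},
                    "separation_score": labeling.separation_score,
                    "comparison": table.reset_index().to_dict(orient="records"),
                    "criterion_choices": table.attrs["criterion_choices"],
                },
                indent=2,
            )
        )
        written += [patterns_csv, assignments_csv, fit_json]

    if "evaluate" in config.steps:
        log("evaluate: tissue groups (verified truth) and eDNA classes (LCA proxy)")
        results = evaluate_groups(load_tissue(), "verified")
        assignments = pd.read_csv(_require(assignments_csv, "evaluate"))
        proxy = dict(zip(assignments["sample_id"], assignments["assigned_class"]))
        results += evaluate_groups(load_edna(), "lca_proxy", proxy_truth=proxy)
        rows = []
        for res in results:
            rows.append(
                {
                    "group": res.group_label,
                    "tp": res.counts.tp,
                    "fp": res.counts.fp,
                    "tn": res.counts.tn,
                    "fn": res.counts.fn,
                    "sensitivity": "" if res.sensitivity is None else round(res.sensitivity.p, 6),
                    "sens_lo": "" if res.sensitivity is None else round(res.sensitivity.lower, 6),
                    "sens_hi": "" if res.sensitivity is None else round(res.sensitivity.upper, 6),
                    "specificity": "" if res.specificity is None else round(res.specificity.p, 6),
                    "spec_lo": "" if res.specificity is None else round(res.specificity.lower, 6),
                    "spec_hi": "" if res.specificity is None else round(res.specificity.upper, 6),
                }
            )
        pd.DataFrame(rows).to_csv(metrics_csv, index=False)
        written.append(metrics_csv)

    if "tgroc" in config.steps:
        log("tgroc: sweeping max-Ct cutoffs per tissue group")
        rows = []
        for label, curve in curves_by_group(load_tissue(), step=config.tgroc_step).items():
            for c, se, sp in zip(curve.cutoffs, curve.se_at, curve.sp_at):
                rows.append(
                    {
                        "group": label,
                        "cutoff": c,
                        "sensitivity": round(float(se), 6),
                        "specificity": round(float(sp), 6),
                        "selected": curve.selected_cutoff,
                        "rule": curve.selection_rule,
                    }
                )
        pd.DataFrame(rows).to_csv(tgroc_csv, index=False)
        written.append(tgroc_csv)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "steps": list(config.steps),
        "n_sites": config.n_sites,
        "replicates_per_site": config.replicates_per_site,
        "lca_classes": list(config.lca_classes),
        "lca_starts": config.lca_starts,
        "log": log_lines,
        "files": {p.name: _sha256(p) for p in written},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
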