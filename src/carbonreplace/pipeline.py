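"""Configuration-driven end-to-end orchestration of the replacement study.

Stage order: ingest/generate -> plot selection -> recruitment models ->
compositions -> ordination -> carbon models -> replacement indicator ->
group statistics.  Every stage's inputs, outputs, seed and wall time are
recorded in a manifest; identical config + seed reproduces byte-identical
result tables.  Per-stage seeds are derived deterministically from the
top-level seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import carbon_model as cm
from . import ordination as ordn
from . import recruitment as rec
from . import replacement as repl
from .errors import ConfigError
from .inventory import (InventoryTables, carbon_change_rate, filter_plots,
                        live_species_carbon, plot_carbon, plot_carbon_table,
                        plot_condition_table, read_inventory, write_inventory)
from .synthetic import GeneratorConfig, generate_inventory

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"
_STAGES = ("ingest", "filter", "recruitment", "compositions", "ordination",
           "carbon_model", "replacement", "tests")


@dataclass
class RunConfig:
    """Every tunable of the study in one place.

    Thresholds default to the analysis settings: 1% rare-species cutoff,
    20-plot group minimum, 5 Mg/ha replacement threshold, 30-subplot
    species-model threshold, 4 ordination axes, 1000 forest trees,
    reference age 100 with a 60-140 year sensitivity sweep.
    """
    seed: int | None = None
    output_dir: str = "run"
    input_dir: str | None = None                # read inventory from disk ...
    generator: GeneratorConfig | None = None    # ... or generate it

    rare_species_cutoff: float = 0.01
    group_min_plots: int = 20
    excluded_forest_types: tuple[str, ...] = ("red pine", "jack pine")
    replacement_threshold: float = 5.0
    species_threshold: int = 30

    nmds_k: int = 4
    nmds_starts: int = 250
    nmds_max_iter: int = 999
    nmds_eps: float = 1e-7

    n_trees: int = 1000
    covariate_set: str = "latlon"               # latlon | climate | compare
    reference_age: float = 100.0
    sensitivity_ages: tuple[float, ...] = repl.DEFAULT_SENSITIVITY_AGES

    # boosted-tree profile for the recruitment models; lighter than the
    # canonical library default so a full synthetic study stays cheap
    brt: rec.BRTSettings = field(default_factory=lambda: rec.BRTSettings(
        learning_rate=0.05, max_trees=250, cv_folds=3))


def validate_config(config: RunConfig) -> dict:
    """Name every invalid or missing field; echo the effective settings."""
    errors = []
    if config.seed is None:
        errors.append("seed is required")
    if config.input_dir is None and config.generator is None:
        errors.append("either input_dir or a generator config is required")
    for name in ("rare_species_cutoff", "group_min_plots", "species_threshold",
                 "nmds_k", "nmds_starts", "nmds_max_iter", "n_trees",
                 "reference_age"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if config.replacement_threshold < 0:   # zero is a meaningful limit case
        errors.append("replacement_threshold must be non-negative")
    if config.covariate_set not in ("latlon", "climate", "compare"):
        errors.append(f"unknown covariate_set '{config.covariate_set}'")
    echo = {k: v for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)}
    echo.pop("generator", None)
    return {"errors": errors, "settings": echo}


@dataclass
class PipelineResult:
    summary: dict
    artifacts: dict[str, Path]
    manifest: list[dict]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGES, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)
    return path


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study; raises on stage failure after writing a
    failure manifest alongside any partial artifacts."""
    report = validate_config(config)
    if report["errors"]:
        raise ConfigError("; ".join(report["errors"]))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: list[dict] = []
    artifacts: dict[str, Path] = {}
    state: dict = {}

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn(seeds[name])
        except Exception as exc:
            manifest.append({"stage": name, "status": "failed", "error": str(exc),
                             "seed": seeds[name]})
            _write_json({"stages": manifest, "status": "failed"},
                        out / "manifest.json")
            raise
        entry = {"stage": name, "status": "ok", "seed": seeds[name],
                 "wall_time_s": round(time.perf_counter() - t0, 3),
                 "outputs": {}}
        for key, path in (outputs or {}).items():
            artifacts[key] = path
            entry["outputs"][key] = {"file": path.name, "sha256": _sha256(path)}
        manifest.append(entry)

    # ------------------------------------------------------------------
    def ingest(seed):
        if config.input_dir is not None:
            state["tables"] = read_inventory(config.input_dir)
            state["truth"] = None
            return {}
        gen = dataclasses.replace(config.generator, seed=seed)
        tables, truth = generate_inventory(gen)
        state["tables"], state["truth"] = tables, truth
        inv_dir = out / "inventory"
        paths = write_inventory(tables, inv_dir)
        arts = {f"inventory_{k}": v for k, v in paths.items()}
        arts["ground_truth"] = _write_csv(truth.plots, inv_dir / "ground_truth.csv")
        meta = dataclasses.asdict(gen)
        meta["species_pool"] = {g: [dataclasses.asdict(s) for s in pool]
                                for g, pool in gen.species_pool.items()}
        arts["run_meta"] = _write_json({"generator": _jsonable(meta), "seed": seed},
                                       inv_dir / "run_meta.json")
        return arts

    def filter_stage(seed):
        tables: InventoryTables = state["tables"]
        kept = sorted(filter_plots(tables))
        state["plot_ids"] = kept
        state["covariates"] = plot_condition_table(tables, kept)
        return {"selected_plots": _write_csv(pd.DataFrame({"plot_id": kept}),
                                             out / "selected_plots.csv")}

    def recruitment_stage(seed):
        tables = state["tables"]
        training = rec.build_training_table(tables, plot_ids=state["plot_ids"])
        settings = dataclasses.replace(config.brt, seed=seed)
        model_set = rec.fit_recruitment_models(
            training, threshold=config.species_threshold, settings=settings)
        probs = rec.predict_recruitment(model_set, tables,
                                        plot_ids=state["plot_ids"], time=2)
        comp, empty = rec.recruitment_composition_table(probs, state["plot_ids"])
        state["model_set"], state["recruit_comp"] = model_set, comp
        state["no_regen_plots"] = empty
        return {"recruitment_composition":
                _write_csv(comp, out / "recruitment_composition.csv")}

    def compositions_stage(seed):
        tables = state["tables"]
        cov = state["covariates"]
        kept = ordn.filter_groups(
            cov.forest_type_group, cov.forest_type,
            min_plots=config.group_min_plots,
            excluded_forest_types=set(config.excluded_forest_types))
        kept = sorted(kept)
        state["group_plots"] = kept
        live = live_species_carbon(tables, time=2, plot_ids=kept)
        recruit = state["recruit_comp"]
        recruit = recruit[recruit.plot_id.isin(set(kept))]
        matrix = ordn.collapse_rare_species(live, recruit,
                                            cutoff=config.rare_species_cutoff)
        state["matrix"] = matrix
        return {}

    def ordination_stage(seed):
        result = ordn.run_nmds(state["matrix"], k=config.nmds_k,
                               n_starts=config.nmds_starts,
                               max_iter=config.nmds_max_iter,
                               seed=seed, eps=config.nmds_eps)
        state["ordination"] = result
        scores = result.scores.reset_index()
        report = {"stress": result.stress, "n_starts": result.n_starts,
                  "converged": result.converged, "k": config.nmds_k,
                  "max_iter": config.nmds_max_iter, "seed": seed,
                  "n_rows": int(result.scores.shape[0])}
        return {"scores": _write_csv(scores, out / "scores.csv"),
                "ordination_report": _write_json(report, out / "ordination.json")}

    def carbon_stage(seed):
        tables = state["tables"]
        scores = state["ordination"].scores
        tree_rows = scores.xs("treeC", level="source")
        carbon2 = plot_carbon_table(tables, time=2, plot_ids=tree_rows.index)
        model_table = (tree_rows.join(state["covariates"], how="inner")
                       .join(carbon2, how="inner"))
        model_table["live_c"] = model_table.live_total
        model_table["total_c"] = model_table.grand_total
        state["model_table"] = model_table

        fits = {}
        report = {}
        for resp in ("live_c", "total_c"):
            if config.covariate_set == "compare" and resp == "live_c":
                comparison = cm.compare_covariate_sets(
                    model_table, cm.CarbonModelSpec(response=resp,
                                                    n_trees=config.n_trees,
                                                    seed=seed))
                fits[resp] = comparison.pop("model")
                report["covariate_comparison"] = {
                    k: v for k, v in comparison.items()}
            else:
                covset = ("latlon" if config.covariate_set == "compare"
                          else config.covariate_set)
                spec = cm.CarbonModelSpec(
                    response=resp, predictors=cm.default_predictors(covset),
                    n_trees=config.n_trees, seed=seed)
                fits[resp] = cm.fit_carbon_model(model_table, spec)
            report[f"oob_pseudo_r2_{resp}"] = fits[resp].oob_pseudo_r2
        state["carbon_fits"] = fits
        importance = cm.permutation_importance(fits["live_c"], seed=seed)
        imp = importance.rename("importance").rename_axis("predictor").reset_index()
        state["carbon_report"] = report
        return {"importance": _write_csv(imp, out / "importance.csv"),
                "carbon_report": _write_json(_jsonable(report),
                                             out / "carbon_models.json")}

    def replacement_stage(seed):
        model = state["carbon_fits"]["live_c"]
        plot_table = state["model_table"]
        scores = state["ordination"].scores
        results = repl.counterfactual_predictions(
            model, plot_table, scores, reference_age=config.reference_age,
            threshold=config.replacement_threshold)
        sweep, stability = repl.sensitivity_sweep(
            model, plot_table, scores, ages=config.sensitivity_ages,
            threshold=config.replacement_threshold)
        state["results"], state["stability"] = results, stability
        res_out = results.reset_index()[
            ["plot_id", "pred_treec", "pred_recruitment", "delta", "category",
             "reference_age", "assessable"]]
        return {"results": _write_csv(res_out, out / "results.csv"),
                "sensitivity": _write_csv(
                    sweep[["plot_id", "reference_age", "delta", "category",
                           "assessable"]], out / "sensitivity.csv")}

    def tests_stage(seed):
        tables = state["tables"]
        results = state["results"]
        carbon2 = plot_carbon_table(tables, time=2, plot_ids=results.index)
        rates = {}
        for pid in results.index:
            c1 = plot_carbon(tables, pid, 1)
            c2 = plot_carbon(tables, pid, 2)
            interval = float(tables.plots.set_index("plot_id")
                             .loc[pid, "interval_years"])
            rates[pid] = carbon_change_rate(c1, c2, interval)
        vars_table = state["covariates"].loc[results.index].copy()
        vars_table["live_c"] = carbon2.live_total
        vars_table["snag_c"] = carbon2.snag_total
        vars_table["cwm_c"] = carbon2.dwm_total
        vars_table["live_c_change"] = pd.Series(rates)
        tests = repl.group_comparisons(results, vars_table)
        state["tests"] = tests

        summary = repl.summarize_categories(results, config.replacement_threshold)
        summary.update(
            seed=config.seed,
            stress=state["ordination"].stress,
            nmds_converged=state["ordination"].converged,
            stability=state["stability"],
            n_species_models=len(state["model_set"].species_models),
            no_regeneration_plots=len(state["no_regen_plots"]),
            **{k: v for k, v in state["carbon_report"].items()
               if k.startswith("oob_")})
        state["summary"] = summary
        return {"tests": _write_csv(tests, out / "tests.csv"),
                "summary": _write_json(_jsonable(summary), out / "summary.json")}

    for name, fn in (("ingest", ingest), ("filter", filter_stage),
                     ("recruitment", recruitment_stage),
                     ("compositions", compositions_stage),
                     ("ordination", ordination_stage),
                     ("carbon_model", carbon_stage),
                     ("replacement", replacement_stage),
                     ("tests", tests_stage)):
        _run_stage(name, fn)
        logger.info("stage %s done", name)

    artifacts["manifest"] = _write_json({"stages": manifest, "status": "ok",
                                         "seed": config.seed},
                                        out / "manifest.json")
    return PipelineResult(summary=state["summary"], artifacts=artifacts,
                          manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
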