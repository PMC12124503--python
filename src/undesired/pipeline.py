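"""End-to-end orchestration: simulate -> filter -> classify -> tabulate ->
associate -> model -> evaluate, with a provenance manifest.

A run is configured by a :class:`RunConfig` (usually parsed from YAML),
names exactly one input source (CSV paths or a simulation block), and
writes every stage artifact plus ``manifest.json`` with content hashes,
seeds and per-stage row counts into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assoc, classify, descriptives, ml, mvprobit, schema, synthdata

logger = logging.getLogger("undesired")


class PipelineConfigError(ValueError):
    """Invalid run configuration (CLI exit code 1)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 2)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 0
    mothers_csv: Path | None = None
    children_csv: Path | None = None
    sim: synthdata.SimConfig | None = None
    dual_rule: str = "sex_and_parity"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "filter", "classify", "tables", "pca", "mvprobit", "ml"]
    )
    background_vars: list[str] = field(
        default_factory=lambda: ["sex_ch", "mage", "resid", "prov", "wealth", "edu", "exc_m", "wsw"]
    )
    corr_method: str = "tetrachoric"
    pca_n_keep: int | None = None
    mvp_outcomes: list[str] = field(
        default_factory=lambda: ["ari", "cough", "diarrhea", "fever", "srb"]
    )
    mvp_regressors: list[str] = field(
        default_factory=lambda: ["ep", "ed", "eg", "eb", "bord", "mage"]
    )
    mvp_draws: int = 100
    ml_models: list[str] = field(default_factory=lambda: ["rf", "nn"])
    ml_outcomes: list[str] = field(default_factory=lambda: list(schema.ALL_OUTCOMES))
    ml_features: list[str] = field(
        default_factory=lambda: [
            "ep", "ed", "eg", "eb", "bord", "mage", "edu", "wealth", "resid",
            "prov", "sex_ch", "age_ch", "wsw", "exc_m", "empment", "visit_hw",
        ]
    )
    ml_options: dict = field(default_factory=dict)

    def validate(self) -> None:
        has_paths = self.mothers_csv is not None and self.children_csv is not None
        has_sim = self.sim is not None
        if has_paths == has_sim:
            raise PipelineConfigError(
                "exactly one of (mothers_csv, children_csv) or a sim block is required"
            )
        if self.dual_rule not in classify.DUAL_RULES:
            raise PipelineConfigError(f"invalid dual_rule {self.dual_rule!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        sim = None
        if "sim" in raw:
            simraw = dict(raw["sim"])
            simraw.setdefault("seed", raw.get("seed", 0))
            if simraw.pop("default", False):
                sim = synthdata.default_config(
                    n_mothers=simraw.get("n_mothers", 2000), seed=simraw["seed"]
                )
            else:
                simraw["ideal_dist"] = [
                    (tuple(t), p) for t, p in simraw["ideal_dist"]
                ]
                simraw["births_dist"] = [tuple(kp) for kp in simraw["births_dist"]]
                if "covariate_spec" in simraw:
                    simraw["covariate_spec"] = {
                        k: (list(v[0]), list(v[1]))
                        for k, v in simraw["covariate_spec"].items()
                    }
                if simraw.get("outcome_sigma") is not None:
                    simraw["outcome_sigma"] = np.asarray(simraw["outcome_sigma"], float)
                sim = synthdata.SimConfig(**simraw)
        cfg = RunConfig(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            mothers_csv=Path(raw["mothers_csv"]) if "mothers_csv" in raw else None,
            children_csv=Path(raw["children_csv"]) if "children_csv" in raw else None,
            sim=sim,
            dual_rule=raw.get("dual_rule", "sex_and_parity"),
        )
        for key in (
            "stages", "background_vars", "corr_method", "pca_n_keep", "mvp_outcomes",
            "mvp_regressors", "mvp_draws", "ml_models", "ml_outcomes", "ml_features",
            "ml_options",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
    except (KeyError, TypeError, synthdata.ConfigError) as exc:
        raise PipelineConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def validate_input(
    mothers_path: str | Path, children_path: str | Path
) -> dict[str, Any]:
    """Schema report for input CSVs: fatal errors vs non-fatal warnings."""
    report: dict[str, Any] = {"errors": [], "warnings": []}
    try:
        mothers = pd.read_csv(mothers_path)
        children = pd.read_csv(children_path)
    except OSError as exc:
        report["errors"].append(f"unreadable file: {exc}")
        return report
    for col in ("mother_id", "B_m", "G_m", "N_m", "C_m"):
        if col not in mothers.columns:
            report["errors"].append(f"mothers: missing column {col!r}")
    for col in ("mother_id", "birth_order", "sex", "alive"):
        if col not in children.columns:
            report["errors"].append(f"children: missing column {col!r}")
    if report["errors"]:
        return report
    try:
        _, remapped = schema.remap_sex(children["sex"])
        if remapped:
            report["warnings"].append("children: sex coded 1/2, remapped to M/F")
    except ValueError as exc:
        report["errors"].append(str(exc))
    try:
        schema.as_binary(children["alive"], "alive")
    except ValueError as exc:
        report["errors"].append(str(exc))
    orphans = ~children["mother_id"].isin(set(mothers["mother_id"]))
    if orphans.any():
        report["warnings"].append(
            f"children: {int(orphans.sum())} rows reference unknown mothers"
        )
    return report


def _merge_analysis_table(
    mothers: pd.DataFrame, children: pd.DataFrame, flags: pd.DataFrame
) -> pd.DataFrame:
    """Child-level analysis table: covariates + sequential excess flags."""
    child_flags = flags[flags["level"] == "child"][
        ["mother_id", "birth_order"] + schema.EXCESS_CATEGORIES
    ]
    merged = children.merge(mothers, on="mother_id", how="inner", sort=False)
    merged = merged.merge(child_flags, on=["mother_id", "birth_order"], how="left")
    merged["bord"] = merged["birth_order"]
    merged["sex_ch"] = merged["sex"]
    for alias, cat in schema.EXCESS_ALIASES.items():
        merged[alias] = merged[cat]
    return merged


def _encoded(analysis: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    resolved = [schema.EXCESS_ALIASES.get(c, c) for c in columns]
    enc = schema.encode_frame(analysis, resolved)
    enc.columns = columns
    return enc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "dual_rule": config.dual_rule,
        "stages": [],
        "artifacts": {},
        "row_counts": {},
    }
    artifacts: dict[str, Path] = {}

    def emit(name: str, obj) -> Path:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        artifacts[name] = path
        return path

    # --- load or simulate -------------------------------------------------
    stage = "simulate" if config.sim is not None else "load"
    try:
        if config.sim is not None:
            pop = synthdata.simulate_population(config.sim)
            mothers, children = pop.mothers, pop.children
            paths = synthdata.write_population(pop, outdir)
            for key, path in paths.items():
                artifacts[path.name] = path
        else:
            report = validate_input(config.mothers_csv, config.children_csv)
            if report["errors"]:
                raise PipelineConfigError("; ".join(report["errors"]))
            for w in report["warnings"]:
                logger.warning(w)
            mothers = pd.read_csv(config.mothers_csv)
            children = pd.read_csv(config.children_csv)
            children["sex"], _ = schema.remap_sex(children["sex"])
        manifest["stages"].append(stage)
        manifest["row_counts"]["input"] = {
            "mothers": len(mothers),
            "children": len(children),
        }
        logger.info("%s: %d mothers, %d children", stage, len(mothers), len(children))
    except (PipelineConfigError, synthdata.ConfigError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc) from exc

    if config.sim is not None and "simulate" in config.stages and len(config.stages) == 1:
        emit("manifest.json", _finalize_manifest(manifest, artifacts))
        return manifest

    # --- filter -----------------------------------------------------------
    if "filter" in config.stages:
        try:
            mothers, children, freport = classify.apply_eligibility_filters(
                mothers, children
            )
            emit("filter_report.json", freport)
            manifest["stages"].append("filter")
            manifest["row_counts"]["filtered"] = {
                "mothers": len(mothers),
                "children": len(children),
            }
            logger.info(
                "filter: kept %d mothers, %d children", len(mothers), len(children)
            )
        except Exception as exc:
            raise StageError("filter", exc) from exc

    # --- classify ---------------------------------------------------------
    flags = None
    if "classify" in config.stages:
        try:
            flags = classify.classify_population(mothers, children, config.dual_rule)
            emit("excess_flags.csv", flags.set_index("mother_id"))
            prevalence = classify.aggregate_excess(flags)
            emit("excess_prevalence.json", prevalence)
            manifest["stages"].append("classify")
            manifest["row_counts"]["flags"] = len(flags)
        except Exception as exc:
            raise StageError("classify", exc) from exc

    analysis = None
    if flags is not None:
        analysis = _merge_analysis_table(mothers, children, flags)

    # --- descriptive tables ----------------------------------------------
    if "tables" in config.stages and analysis is not None:
        try:
            numeric = _encoded(
                analysis,
                ["ep", "ed", "eg", "eb", "bord", "mage", "edu", "wealth", "resid",
                 "prov", "sex_ch", "age_ch", "wsw", "exc_m", "empment", "visit_hw"],
            )
            emit("table1_summary.csv", descriptives.summarize_variables(numeric).round(4))
            outcomes = [o for o in schema.ALL_OUTCOMES if o in analysis.columns]
            if outcomes:
                emit(
                    "table3_morbidity.csv",
                    descriptives.outcome_composition_table(analysis, outcomes).round(2),
                )
                rates = pd.concat(
                    {
                        out: descriptives.prevalence_by_excess(analysis, out)
                        for out in outcomes
                    },
                    names=["outcome"],
                )
                emit("morbidity_rates.csv", rates.round(2))
            crosstabs = pd.concat(
                {
                    var: descriptives.crosstab_background(analysis, var)
                    for var in config.background_vars
                    if var in analysis.columns
                },
                names=["background"],
            )
            emit("table2_background.csv", crosstabs.round(2))
            manifest["stages"].append("tables")
        except Exception as exc:
            raise StageError("tables", exc) from exc

    # --- association / PCA ------------------------------------------------
    selected = list(config.mvp_regressors)
    if "pca" in config.stages and analysis is not None:
        try:
            binary_cols = ["ep", "ed", "eg", "eb", "wsw", "exc_m", "empment", "visit_hw"]
            binary = _encoded(analysis, binary_cols).astype(int)
            corr = assoc.tetrachoric_matrix(binary, method=config.corr_method)
            emit("corr_matrix.csv", corr.values.round(4))
            overall_kmo, per_var = assoc.kmo(corr)
            stat, dof, pval = assoc.bartlett_sphericity(corr, n=len(binary))
            result = assoc.pca(corr, n_keep=config.pca_n_keep)
            scree = pd.DataFrame(
                {
                    "eigenvalue": result.eigenvalues,
                    "pct_variance": result.pct_variance,
                },
                index=result.loadings.columns,
            )
            emit("pca_scree.csv", scree.round(4))
            emit("pca_contributions.csv", result.contributions.round(4))
            emit(
                "selected_features.json",
                {
                    "kmo": overall_kmo,
                    "kmo_per_variable": per_var.to_dict(),
                    "bartlett": {"statistic": stat, "dof": dof, "p_value": pval},
                    "retained_components": [int(i + 1) for i in result.retained],
                    "selected": assoc.select_features(result),
                    "psd_repaired": corr.psd_repaired,
                },
            )
            manifest["stages"].append("pca")
        except Exception as exc:
            raise StageError("pca", exc) from exc

    # --- multivariate probit ----------------------------------------------
    if "mvprobit" in config.stages and analysis is not None:
        try:
            frame = pd.concat(
                [analysis[config.mvp_outcomes], _encoded(analysis, selected)], axis=1
            )
            fit_res = mvprobit.fit(
                frame,
                outcomes=config.mvp_outcomes,
                regressors=selected,
                R=config.mvp_draws,
                seed=config.seed,
            )
            table = mvprobit.format_fit(fit_res)
            emit("mvp_fit.csv", table.round(4))
            emit(
                "mvp_fit.json",
                {
                    "loglik": fit_res.loglik,
                    "converged": fit_res.converged,
                    "n_obs": fit_res.n_obs,
                    "draws": fit_res.draws,
                    "beta": fit_res.beta.to_dict(),
                    "sigma": fit_res.sigma.to_dict(),
                    "diagnostics": fit_res.diagnostics,
                },
            )
            manifest["stages"].append("mvprobit")
        except Exception as exc:
            raise StageError("mvprobit", exc) from exc

    # --- ML evaluation ----------------------------------------------------
    if "ml" in config.stages and analysis is not None:
        try:
            opts = {**ml.DEFAULTS, **config.ml_options}
            features = [f for f in config.ml_features if
                        schema.EXCESS_ALIASES.get(f, f) in analysis.columns]
            enc = _encoded(analysis, features)
            perf_rows, imp_rows = [], []
            for out in config.ml_outcomes:
                if out not in analysis.columns:
                    continue
                frame = pd.concat(
                    [enc, schema.as_binary(analysis[out], out).rename(out)], axis=1
                ).dropna().reset_index(drop=True)
                train, test = ml.split_train_test(
                    frame, opts["split_fraction"], seed=config.seed, stratify=out
                )
                Xtr, ytr = train[features].to_numpy(float), train[out].to_numpy(int)
                Xte, yte = test[features].to_numpy(float), test[out].to_numpy(int)
                models = {}
                if "rf" in config.ml_models:
                    models["rf"] = ml.train_rf(
                        Xtr, ytr, n_trees=opts["n_trees"], seed=config.seed,
                        feature_names=features,
                    )
                if "nn" in config.ml_models:
                    models["nn"] = ml.train_mlp(
                        Xtr, ytr, hidden_size=opts["hidden_size"],
                        epochs=opts["epochs"], learning_rate=opts["learning_rate"],
                        seed=config.seed, feature_names=features,
                    )
                for name, model in models.items():
                    row = ml.evaluate(model, Xte, yte)
                    perf_rows.append({"outcome": out, "model": name, **row})
                    imp = ml.importance(
                        model, Xte, yte, "mean_decrease_accuracy", seed=config.seed
                    )
                    imp.insert(0, "model", name)
                    imp.insert(0, "outcome", out)
                    imp.insert(2, "method", "mean_decrease_accuracy")
                    imp_rows.append(imp)
                    if name == "rf":
                        impg = ml.importance(model, Xte, yte, "mean_decrease_gini")
                        impg.insert(0, "model", name)
                        impg.insert(0, "outcome", out)
                        impg.insert(2, "method", "mean_decrease_gini")
                        imp_rows.append(impg)
            emit("ml_performance.csv", pd.DataFrame(perf_rows).set_index("outcome").round(2))
            emit(
                "ml_importance.csv",
                pd.concat(imp_rows, ignore_index=True).set_index("outcome").round(4),
            )
            manifest["stages"].append("ml")
        except Exception as exc:
            raise StageError("ml", exc) from exc

    emit("manifest.json", _finalize_manifest(manifest, artifacts))
    return manifest


def _finalize_manifest(manifest: dict, artifacts: dict[str, Path]) -> dict:
    import undesired

    manifest["version"] = getattr(undesired, "__version__", "unknown")
    for name, path in sorted(artifacts.items()):
        manifest["artifacts"][name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
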