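"""End-to-end orchestration: synthesize/load -> preprocess -> score ->
model suite -> symbolic regression -> consensus -> ablation -> enrichment.

A single config mapping (YAML-friendly) drives the run; every stage writes
its artifacts into the run directory and the manifest records the seed,
parameters, package version and a SHA-256 digest of each artifact, so a
rerun with the same config bit-reproduces all JSON/CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .core import (
    CompositeScore,
    FeatureTable,
    PotencyAssayPanel,
    ValidationError,
    logger,
    read_feature_table,
    read_gmt,
    save_json,
    write_feature_table,
)
from .consensus import (
    ConsensusPanel,
    ablation_refit,
    build_consensus,
    consensus_refit,
    top_fraction_features,
)
from .enrichment import apply_id_mapping, map_query, ora, results_frame
from .models import FAMILIES, fit_suite, importance_by_class
from .potency import composite_score, univariate_screen
from .preprocess import (
    autoscale,
    blank_qc_filter,
    combat_correct,
    day_difference,
    median_normalize,
    rsd_filter,
    variance_filter_select,
)
from .symreg import SRSettings, sr_fit, sr_important_features
from .synth import SyntheticSpec, generate_blanks_and_qcs, generate_study

MS_PLATFORMS = ("ms_lipid", "ms_polar")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "synth": {},  # SyntheticSpec keyword overrides; remove when loading real data
    "preprocess": {
        "blank_ratio": 5.0,
        "qc_presence": 0.5,
        "rsd_threshold": 0.25,
        "rsd_mode": "remove_below",
        "baseline_day": 1,
        "target_days": [2, 3],
    },
    "suite": {"families": list(FAMILIES), "cv_folds": 5},
    "sr": {
        "enabled": True,
        "restarts": 5,
        "population_size": 100,
        "generations": 20,
        "r2_min": 0.90,
        "complexity_max": 300,
        "presence_min": 0.10,
    },
    "consensus": {"min_models": 2, "top_fraction": 0.20},
}

DEMO_CONFIG: dict[str, Any] = {
    **DEFAULT_CONFIG,
    "synth": {
        "n_features": {"ms_lipid": 60, "ms_polar": 60, "nmr": 40},
        "n_replicates_nmr": 4,
    },
    "suite": {
        "families": list(FAMILIES),
        "cv_folds": 5,
        # lighter ensemble grids keep the bundled demo around a minute
        "grids": {
            "RF": {"n_estimators": [100], "max_depth": [2, 3, None]},
            "GBR": {"n_estimators": [100], "max_depth": [2, 3, None]},
        },
    },
    "sr": {**DEFAULT_CONFIG["sr"], "restarts": 3, "population_size": 80,
           "generations": 15},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: Mapping) -> tuple[dict[str, FeatureTable], PotencyAssayPanel]:
    inputs = cfg["inputs"]
    tables = {}
    for plat in ("ms_lipid", "ms_polar", "nmr"):
        if plat in inputs:
            spec = inputs[plat]
            tables[plat] = read_feature_table(
                spec["values"], spec["samples"], spec.get("features"))
    assays = pd.read_csv(inputs["assays"], index_col=0)
    return tables, PotencyAssayPanel(assays)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    if "synth" not in config and "inputs" not in config:
        raise ValidationError("config needs a 'synth' block or an 'inputs' block")
    cfg = _merge(DEFAULT_CONFIG, config)
    if "synth" in config:
        cfg.pop("inputs", None)
    else:
        cfg.pop("synth", None)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"

    try:
        # -- inputs ---------------------------------------------------------
        truth = None
        if "synth" in cfg:
            stage = "synth"
            spec = SyntheticSpec(**{**cfg["synth"], "seed": seed})
            lipid, polar, nmr, panel, truth = generate_study(spec)
            # blanks/QCs exercise the MS filters; plant a few failing features
            tables = {}
            for i, (plat, tab) in enumerate((("ms_lipid", lipid), ("ms_polar", polar))):
                noise_feats = [f for f in tab.feature_ids
                               if f not in truth.informative[plat]]
                tables[plat] = generate_blanks_and_qcs(
                    tab, seed=seed + 101 + i,
                    blank_dominated=noise_feats[:3],
                    qc_dropout={noise_feats[3]: 0.6},
                )
            tables["nmr"] = nmr
            for plat, tab in tables.items():
                artifacts.update({
                    f"{plat}_{k}": p
                    for k, p in write_feature_table(tab, out / plat).items()
                })
            panel.assays.to_csv(out / "assays.csv", index_label="line_id")
            artifacts["assays"] = out / "assays.csv"
            artifacts["ground_truth"] = save_json(
                {
                    "latent_potency": truth.latent_potency.to_dict(),
                    "informative": truth.informative,
                    "signs": truth.signs,
                },
                out / "ground_truth.json",
            )
        else:
            stage = "load"
            tables, panel = _load_inputs(cfg)

        # -- composite potency score ---------------------------------------
        stage = "potency"
        score = composite_score(panel)
        artifacts["scores"] = save_json(
            {
                "scores": score.scores.to_dict(),
                "variance_explained": score.variance_explained,
                "loadings": score.loadings.to_dict(),
                "orientation": score.orientation,
            },
            out / "scores.json",
        )

        # -- preprocessing --------------------------------------------------
        pp = cfg["preprocess"]
        datasets: dict[str, pd.DataFrame] = {}
        filter_reports: dict[str, list] = {}
        for plat in MS_PLATFORMS:
            if plat not in tables:
                continue
            stage = f"preprocess:{plat}"
            tab = tables[plat]
            reports = []
            if (tab.sample_meta["role"] == "blank").any() and (
                    tab.sample_meta["role"] == "qc_pool").any():
                tab, rep = blank_qc_filter(tab, pp["blank_ratio"], pp["qc_presence"])
                reports.append(rep)
            tab, rep = rsd_filter(tab, pp["rsd_threshold"], pp["rsd_mode"])
            reports.append(rep)
            tab = median_normalize(tab)
            tab = combat_correct(tab)
            tab = autoscale(tab)
            filter_reports[plat] = reports
            datasets[plat] = tab.aggregate_by_line()

        nmr_choices = {}
        if "nmr" in tables:
            stage = "preprocess:nmr"
            nmr_c = combat_correct(tables["nmr"])
            for day in pp["target_days"]:
                diff = day_difference(nmr_c, target_day=day,
                                      baseline_day=pp["baseline_day"])
                line_mat = diff.aggregate_by_line()
                grid = pp.get("percent_grid")
                sel, frac, grid_scores = variance_filter_select(
                    line_mat, score,
                    percent_grid=tuple(grid) if grid else
                    tuple(round(0.05 * i, 2) for i in range(1, 21)),
                )
                datasets[f"nmr_day{day}"] = sel
                nmr_choices[f"nmr_day{day}"] = {
                    "chosen_fraction": frac,
                    "grid_loo_r2": {str(k): v for k, v in grid_scores.items()},
                }
        if nmr_choices:
            artifacts["nmr_variance_filter"] = save_json(
                nmr_choices, out / "nmr_variance_filter.json")
        artifacts["filter_reports"] = save_json(
            {p: [asdict(r) for r in reps] for p, reps in filter_reports.items()},
            out / "filter_reports.json",
        )

        # -- univariate screening ------------------------------------------
        stage = "screen"
        for name, X in datasets.items():
            screen = univariate_screen(X, score)
            path = out / f"screen_{name}.csv"
            screen.to_csv(path, index_label="feature_id")
            artifacts[f"screen_{name}"] = path

        # -- model suite + SR + per-dataset consensus -----------------------
        suite_cfg = cfg["suite"]
        sr_cfg = cfg["sr"]
        cons_cfg = cfg["consensus"]
        suites: dict[str, dict] = {}
        panels: dict[str, ConsensusPanel] = {}
        for name, X in datasets.items():
            stage = f"suite:{name}"
            fitted = fit_suite(X, score, families=suite_cfg["families"],
                               seed=seed, cv_folds=suite_cfg["cv_folds"],
                               grids=suite_cfg.get("grids"))
            suites[name] = fitted
            family_sets = {
                fam: top_fraction_features(m, cons_cfg["top_fraction"])
                for fam, m in fitted.items()
            }
            if sr_cfg.get("enabled", True):
                stage = f"sr:{name}"
                settings = SRSettings(
                    restarts=sr_cfg["restarts"],
                    population_size=sr_cfg["population_size"],
                    generations=sr_cfg["generations"],
                )
                run = sr_fit(X, score, settings=settings, seed=seed)
                family_sets["SR"] = sr_important_features(
                    run, presence_min=sr_cfg["presence_min"],
                    r2_min=sr_cfg["r2_min"],
                    complexity_max=sr_cfg["complexity_max"],
                )
            stage = f"consensus:{name}"
            panels[name] = build_consensus(
                family_sets, min_models=cons_cfg["min_models"],
                top_fraction=cons_cfg["top_fraction"],
            )
            artifacts[f"models_{name}"] = save_json(
                {fam: asdict(m) for fam, m in fitted.items()},
                out / f"models_{name}.json",
            )
            if name in tables:  # chem-class importance breakdown (MS platforms)
                cls = importance_by_class(fitted, tables[name].feature_meta)
                path = out / f"class_importance_{name}.csv"
                cls.to_csv(path, index_label="chem_class")
                artifacts[f"class_importance_{name}"] = path
            artifacts[f"panel_{name}"] = save_json(
                {f: sorted(v) for f, v in panels[name].membership.items()},
                out / f"panel_{name}.json",
            )

        # -- consensus models ----------------------------------------------
        consensus_sets: dict[str, tuple[pd.DataFrame, ConsensusPanel]] = {}
        ms_present = [p for p in MS_PLATFORMS if p in datasets]
        if len(ms_present) == 2 and all(p in panels for p in ms_present):
            merged = {}
            for p in ms_present:
                merged.update(panels[p].membership)
            if merged:
                X_ms = pd.concat([datasets[p] for p in ms_present], axis=1)
                consensus_sets["ms"] = (
                    X_ms,
                    ConsensusPanel(membership=merged,
                                   min_models=cons_cfg["min_models"],
                                   top_fraction=cons_cfg["top_fraction"]),
                )
        for name in datasets:
            if name.startswith("nmr_") and panels[name].membership:
                consensus_sets[name] = (datasets[name], panels[name])

        consensus_models: dict[str, dict] = {}
        for name, (X, pan) in consensus_sets.items():
            stage = f"consensus_refit:{name}"
            refit = consensus_refit(pan, X, score,
                                    families=suite_cfg["families"], seed=seed,
                                    cv_folds=suite_cfg["cv_folds"],
                                    grids=suite_cfg.get("grids"))
            consensus_models[name] = refit
            artifacts[f"consensus_{name}"] = save_json(
                {fam: asdict(m) for fam, m in refit.items()},
                out / f"consensus_{name}.json",
            )

        nmr_panels = [panels[n] for n in datasets if n.startswith("nmr_")]
        if len(nmr_panels) == 2:
            common = sorted(set(nmr_panels[0].membership) & set(nmr_panels[1].membership))
            artifacts["nmr_common_features"] = save_json(
                {"common_to_both_timepoints": common}, out / "nmr_common_features.json")

        # -- ablation --------------------------------------------------------
        if cfg.get("ablation", {}).get("exclude_line"):
            stage = "ablation"
            excl = cfg["ablation"]["exclude_line"]
            folds = cfg["ablation"].get("cv_folds", 3)
            abl = {}
            for name, (X, pan) in consensus_sets.items():
                abl[name] = {
                    fam: m.loo_r2
                    for fam, m in ablation_refit(
                        pan, X, score, exclude_line=excl,
                        families=suite_cfg["families"], seed=seed, cv_folds=folds,
                        grids=suite_cfg.get("grids"),
                    ).items()
                }
            artifacts["ablation"] = save_json(
                {"exclude_line": excl, "loo_r2": abl}, out / "ablation.json")

        # -- enrichment ------------------------------------------------------
        if cfg.get("enrichment", {}).get("gmt"):
            stage = "enrichment"
            db = read_gmt(cfg["enrichment"]["gmt"])
            query_set = cfg["enrichment"].get("dataset", "ms")
            if query_set not in consensus_sets:
                raise ValidationError(f"no consensus panel named {query_set!r}")
            query = consensus_sets[query_set][1].features
            mapping_path = cfg["enrichment"].get("id_mapping")
            if mapping_path:
                mp = pd.read_csv(mapping_path, index_col=0).iloc[:, 0].to_dict()
                query = apply_id_mapping(query, mp)
            mapped, unmapped = map_query(query, db)
            if mapped:
                frame = results_frame(ora(mapped, db))
                frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                artifacts["enrichment"] = out / "enrichment.tsv"
            artifacts["enrichment_mapping"] = save_json(
                {"mapped": sorted(mapped), "unmapped": unmapped},
                out / "enrichment_mapping.json",
            )

    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} (artifacts so far in {out})"
        ) from err

    # -- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(cfg, default=str)),
        "summary": {
            "datasets": {name: list(X.shape) for name, X in datasets.items()},
            "loo_r2": {name: {fam: m.loo_r2 for fam, m in fams.items()}
                       for name, fams in suites.items()},
            "consensus_loo_r2": {name: {fam: m.loo_r2 for fam, m in fams.items()}
                                 for name, fams in consensus_models.items()},
            "panel_sizes": {name: len(p.membership) for name, p in panels.items()},
        },
        "artifacts": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                      for k, p in sorted(artifacts.items())},
    }
    save_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest


def run_demo(out_dir: str | Path, seed: int = 1) -> dict:
    """Bundled small synthetic end-to-end run (no external data needed)."""
    cfg = _merge(DEMO_CONFIG, {"seed": seed})
    return run_pipeline(cfg, out_dir)


def default_panel_recovery(
    seed: int,
    platform: str = "ms_lipid",
    include_sr: bool = False,
    sr_settings: "SRSettings | None" = None,
) -> dict:
    """Planted-feature recovery of the consensus panel on one default study.

    Generates the default synthetic study for ``seed``, runs the MS
    preprocessing chain (RSD filter, median normalization, ComBat,
    autoscaling), fits the regression suite, builds the >=2-family consensus
    panel (optionally with symbolic regression as a seventh family), and
    scores the panel against the planted informative set.
    """
    spec = SyntheticSpec(seed=seed)
    lipid, polar, nmr, panel, truth = generate_study(spec)
    table = {"ms_lipid": lipid, "ms_polar": polar}[platform]
    tab, _ = rsd_filter(table)
    tab = autoscale(combat_correct(median_normalize(tab)))
    X = tab.aggregate_by_line()
    score = composite_score(panel)

    fitted = fit_suite(X, score, seed=seed)
    family_sets = {fam: top_fraction_features(m, 0.20) for fam, m in fitted.items()}
    if include_sr:
        run = sr_fit(X, score, settings=sr_settings or SRSettings(
            restarts=5, population_size=100, generations=20), seed=seed)
        family_sets["SR"] = sr_important_features(run)
    cons = build_consensus(family_sets, min_models=2)

    planted = set(truth.informative[platform])
    got = set(cons.features)
    return {
        "recall": len(got & planted) / len(planted),
        "precision": len(got & planted) / max(1, len(got)),
        "panel_size": len(got),
        "panel": sorted(got),
        "planted": sorted(planted),
        "loo_r2": {fam: m.loo_r2 for fam, m in fitted.items()},
    }
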