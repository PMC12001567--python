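"""End-to-end orchestration: simulate/load → VIF → fit → evaluate → ensemble →
project → change accounting → importance/response curves.

A run consumes one :class:`~esdm.config.PipelineConfig` and writes, under the
configured output directory:

* ``manifest.json`` — resolved config, its hash, seed and package version;
* ``vif_report.json`` — retained/removed predictors with VIF values;
* ``evaluation.json`` — per-algorithm replicate mean ± SD of threshold,
  sensitivity, specificity, TSS, kappa, overall accuracy and AUC, plus the
  cross-algorithm average (report-table layout);
* ``ensemble.json`` — member TSS, weights, the ensemble MTSS threshold and the
  ensemble's evaluation at that threshold;
* ``change_report.json`` — suitable/unsuitable and loss/stable/gain areas in
  km² per scenario, with the accounting identities asserted;
* ``importance.csv`` / ``response_curves.csv`` — explanation outputs;
* ``*.asc`` rasters — current and per-scenario suitability, binary and
  three-class maps, and change-code maps.

Reports contain no timestamps, so two runs under the same seed are
byte-identical.  The global seed is expanded via ``numpy.random.SeedSequence``
into independent per-stage streams.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .collinearity import vifcor, vifstep
from .config import PipelineConfig
from .ensemble import make_ensemble
from .evaluation import EvalResult, mtss_threshold, replicate_summary
from .importance import response_curve, variable_importance
from .projection import binarize, change_report, classify_suitability
from .raster_io import (
    cell_area_km2,
    extract_features,
    read_occurrences,
    read_stack,
    write_grid,
    write_occurrences,
    write_stack,
)
from .sdm_fit import AveragedModel, fit, make_background, split
from .synthetic import (
    FIXTURE_RESPONSES,
    default_fixture,
    make_future,
)

logger = logging.getLogger(__name__)

#: default scenario shifts (SD units) emulating a low- and a high-emission
#: pathway in synthetic mode; the causal layer and its correlated decoy shift
#: together, as co-varying climate layers do under a real warming scenario
DEFAULT_SYNTHETIC_SCENARIOS = {
    "ssp126_2041-2060": {"env1": 0.5, "env3": 0.5},
    "ssp585_2041-2060": {"env1": 1.5, "env3": 1.5},
}


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> Path:
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "log.txt", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("esdm")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(cfg: PipelineConfig, out: Path) -> Path:
    ss = np.random.SeedSequence(cfg.seed)
    s_synth, s_bg, s_split, s_fit, s_perm = ss.spawn(5)

    # ----- inputs -------------------------------------------------------
    if cfg.mode == "synthetic":
        stack, vs, occ = default_fixture(
            seed=_stage_seed(s_synth),
            shape=cfg.synthetic.shape,
            n_presence=cfg.synthetic.n_presence,
            autocorr_range=cfg.synthetic.autocorr_range,
            species=cfg.synthetic.species,
        )
        scenarios = cfg.scenarios or DEFAULT_SYNTHETIC_SCENARIOS
        future_stacks = {name: make_future(stack, shifts) for name, shifts in scenarios.items()}
        write_stack(stack, out / "stack")
        write_occurrences(out / "occurrences.csv", occ)
    else:
        stack = read_stack(cfg.paths.layers, cfg.paths.layer_names, crs=cfg.paths.crs)
        occ = read_occurrences(cfg.paths.occurrences, cfg.paths.species)
        future_stacks = {
            name: read_stack(spec["layers"], spec.get("layer_names", cfg.paths.layer_names),
                             crs=cfg.paths.crs)
            for name, spec in cfg.scenarios.items()
        }
    logger.info("stack: %d layers, shape %s, %d valid cells",
                len(stack.layers), stack.shape, stack.n_valid)

    # ----- presence/background features ---------------------------------
    occ_all = make_background(
        stack, occ, n_background=cfg.model.n_background, seed=_stage_seed(s_bg)
    )
    table = extract_features(stack, occ_all)
    labels = (table["label"] == "presence").to_numpy().astype(int)
    features = table[stack.layer_names]
    logger.info("dataset: %d presences, %d background", labels.sum(), (1 - labels).sum())

    # ----- collinearity --------------------------------------------------
    if cfg.vif.method == "vifcor":
        report = vifcor(features, cfg.vif.corr_threshold, cfg.vif.vif_threshold)
    else:
        report = vifstep(features, cfg.vif.vif_threshold)
    retained = report.retained_names
    logger.info("VIF (%s): retained %s, removed %s",
                cfg.vif.method, retained, report.removed_names)
    _json_dump(report.to_dict(), out / "vif_report.json")
    X = features[retained]

    # ----- replicate fits and evaluation ---------------------------------
    split_seeds = s_split.spawn(cfg.model.replicates)
    fit_seeds = s_fit.spawn(cfg.model.replicates)
    models: dict[str, list] = {a: [] for a in cfg.model.algorithms}
    results: dict[str, list[EvalResult]] = {a: [] for a in cfg.model.algorithms}
    for r in range(cfg.model.replicates):
        ds = split(X, labels, cfg.model.train_frac, seed=_stage_seed(split_seeds[r]),
                   species=occ.species)
        Xtr, ytr = ds.part("train")
        Xte, yte = ds.part("test")
        for alg in cfg.model.algorithms:
            model = fit(alg, Xtr, ytr, variables=retained,
                        hyperparameters=cfg.model.hyperparameters.get(alg),
                        seed=_stage_seed(fit_seeds[r]), replicate=r)
            _, res = mtss_threshold(model.predict(Xte), yte)
            models[alg].append(model)
            results[alg].append(res)
            logger.debug("replicate %d %s: TSS %.3f AUC %.3f", r, alg, res.tss, res.auc)

    evaluation = {alg: replicate_summary(results[alg]) for alg in cfg.model.algorithms}
    pooled = [r for alg in cfg.model.algorithms for r in results[alg]]
    evaluation["average"] = replicate_summary(pooled)
    _json_dump(evaluation, out / "evaluation.json")

    # ----- ensemble -------------------------------------------------------
    members = [AveragedModel(alg, models[alg]) for alg in cfg.model.algorithms]
    member_tss = [evaluation[alg]["tss"]["mean"] for alg in cfg.model.algorithms]
    em = make_ensemble(list(zip(members, member_tss)))
    ens_scores = em.predict(X)
    ens_thr, ens_eval = mtss_threshold(ens_scores, labels)
    _json_dump(
        {
            "members": {a: t for a, t in zip(cfg.model.algorithms, member_tss)},
            "weights": {a: float(w) for a, w in zip(cfg.model.algorithms, em.weights)},
            "mtss_threshold": ens_thr,
            "evaluation": ens_eval.to_dict(),
        },
        out / "ensemble.json",
    )
    logger.info("ensemble: weights %s, MTSS threshold %.4f, TSS %.3f",
                dict(zip(cfg.model.algorithms, np.round(em.weights, 4))), ens_thr, ens_eval.tss)

    # ----- projections and change accounting ------------------------------
    areas = cell_area_km2(stack)
    current_map = em.predict_map(stack)
    write_grid(out / "suitability_current.asc", current_map, stack.transform)
    current_bin = binarize(current_map, ens_thr, scenario="current")
    write_grid(out / "binary_current.asc",
               np.where(current_bin.mask, np.nan, current_bin.values), stack.transform)
    classes = classify_suitability(current_map, cfg.class_boundaries)
    write_grid(out / "classes_current.asc",
               np.where(classes < 0, np.nan, classes), stack.transform)

    future_bins = {}
    for name, fstack in future_stacks.items():
        fmap = em.predict_map(fstack)
        write_grid(out / f"suitability_{name}.asc", fmap, stack.transform)
        fbin = binarize(fmap, ens_thr, scenario=name)
        future_bins[name] = fbin
        write_grid(out / f"binary_{name}.asc",
                   np.where(fbin.mask, np.nan, fbin.values), stack.transform)
        cm_codes = (fbin.values.astype(np.int8) * 2 - current_bin.values.astype(np.int8))
        write_grid(out / f"change_{name}.asc",
                   np.where(fbin.mask, np.nan, cm_codes), stack.transform)

    change = change_report(current_bin, future_bins, areas)
    change["class_boundaries"] = list(cfg.class_boundaries)
    change["rounded_km2"] = _rounded_change(change)
    _json_dump(change, out / "change_report.json")

    # ----- importance and response curves ---------------------------------
    imp_rows = []
    ens_imp = variable_importance(em, X, cfg.importance.n_permutations,
                                  seed=_stage_seed(s_perm), method="correlation")
    for rec in ens_imp.table.to_dict("records"):
        imp_rows.append({"model": "ensemble", **rec})
    member_seeds = s_perm.spawn(len(members))
    for member, mseed in zip(members, member_seeds):
        rep = variable_importance(member, X, cfg.importance.n_permutations,
                                  seed=_stage_seed(mseed), method="correlation")
        for rec in rep.table.to_dict("records"):
            imp_rows.append({"model": member.algorithm, **rec})
    pd.DataFrame(imp_rows).to_csv(out / "importance.csv", index=False)

    curves = []
    for var in retained:
        curve = response_curve(em, X, var, n_grid=cfg.importance.n_grid)
        curve.insert(0, "variable", var)
        curves.append(curve)
    pd.concat(curves, ignore_index=True).to_csv(out / "response_curves.csv", index=False)

    # ----- manifest -------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "species": occ.species,
        "n_presence": int(labels.sum()),
        "n_background": int((1 - labels).sum()),
        "retained_variables": retained,
        "ensemble_mtss_threshold": ens_thr,
    }
    if cfg.mode == "synthetic":
        manifest["true_responses"] = [
            {"variable": r.variable, "shape": r.shape, "loc": r.loc, "scale": r.scale}
            for r in FIXTURE_RESPONSES
        ]
    _json_dump(manifest, out / "manifest.json")
    return out


def _rounded_change(change: dict) -> dict:
    from .projection import _round_half_up

    out = {
        "current": {k: _round_half_up(v) for k, v in change["current"].items()},
        "scenarios": {
            name: {k: _round_half_up(v) for k, v in row.items()}
            for name, row in change["scenarios"].items()
        },
    }
    return out
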