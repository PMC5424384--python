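"""End-to-end analysis pipeline: describe -> fit -> substitute.

Runs the whole compositional analysis from a participant table and
writes a report bundle: compositional means and variation matrices
(descriptives), coefficient and Type II ANOVA tables per outcome model,
regression diagnostics, predicted means at each baseline, and
substitution grids (tidy and square 15-min layouts) for the full sample
and per weight-status group.  A manifest records the configuration,
library versions, and which stages completed; given the same config and
input, outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import (
    Composition,
    SequentialBinaryPartition,
    close,
    compositional_mean,
    variation_matrix,
)
from .io import PipelineConfig, read_records
from .model import OUTCOMES, fit_outcome_model
from .reallocation import difference_grid, grid_table, group_baseline_grids

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _sbp_for(cfg: PipelineConfig) -> SequentialBinaryPartition:
    if cfg.sbp == "pivot":
        return SequentialBinaryPartition.pivot(cfg.parts)
    if cfg.sbp == "pivot_reversed":
        return SequentialBinaryPartition.pivot_reversed(cfg.parts)
    raise ValueError(f"unknown sbp choice {cfg.sbp!r}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure halts the run but still writes a manifest marking
    the stages that completed.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sbp = _sbp_for(cfg)
    manifest: dict = {
        "tool": {"name": "codasub", "version": __version__},
        "versions": _library_versions(),
        "config": cfg.to_dict(),
        "sbp_sign_matrix": sbp.sign_matrix.tolist(),
        "stages": {},
    }
    header = (f"# parts={','.join(cfg.parts)} kappa={cfg.kappa:g} "
              f"sbp={cfg.sbp} seed={cfg.seed}\n")

    try:
        records, issues = read_records(cfg.input_path, cfg)
        manifest["stages"]["read"] = {
            "ok": True, "n_records": len(records), "n_rejected": len(issues)}
        logger.info("read %d records (%d rejected)", len(records), len(issues))

        _describe(cfg, sbp, records, outdir, header, manifest)
        models = _fit(cfg, sbp, records, outdir, manifest)
        _substitute(cfg, records, models, outdir, header, manifest)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(outdir / "manifest.json", manifest)
        raise
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _describe(cfg, sbp, records, outdir: Path, header: str, manifest: dict) -> None:
    parts = list(cfg.parts)
    X = records[parts].to_numpy(dtype=float)
    mean_all = compositional_mean(X, cfg.kappa, cfg.parts, sbp)
    rows = [{"group": "all", "n": len(records),
             **dict(zip(parts, mean_all.values))}]
    variations = {"all": variation_matrix(X, cfg.parts).entries.tolist()}
    if cfg.group_column in records.columns:
        for group, sub in records.groupby(cfg.group_column, observed=True, sort=False):
            Xg = sub[parts].to_numpy(dtype=float)
            m = compositional_mean(Xg, cfg.kappa, cfg.parts, sbp)
            rows.append({"group": group, "n": len(sub), **dict(zip(parts, m.values))})
            if len(sub) >= 2:
                variations[str(group)] = variation_matrix(Xg, cfg.parts).entries.tolist()
    means = pd.DataFrame(rows)
    _write_csv(outdir / "compositional_means.csv", means, header)
    vm_all = pd.DataFrame(variations["all"], index=parts, columns=parts)
    _write_csv(outdir / "variation_matrix.csv", vm_all.reset_index(names="part"), header)
    _write_json(outdir / "descriptives.json", {
        "kappa": cfg.kappa, "parts": parts,
        "compositional_means": rows, "variation_matrices": variations})
    manifest["stages"]["describe"] = {"ok": True, "n_groups": len(rows) - 1}


def _fit(cfg, sbp, records, outdir: Path, manifest: dict) -> dict:
    models, anova_rows, coef_rows, diags = {}, [], [], {}
    for outcome in cfg.outcomes:
        spec = OUTCOMES.get(outcome, {})
        covariates = spec.get("covariates", cfg.covariates)
        model = fit_outcome_model(records, outcome, covariates=covariates,
                                  sbp=sbp, parts=cfg.parts,
                                  zero_policy=cfg.zero_policy,
                                  zero_delta=cfg.zero_delta)
        models[outcome] = model
        tab = model.anova().reset_index(names="term").assign(outcome=outcome)
        anova_rows.append(tab)
        coef_rows.append(model.coef_table().reset_index(names="coef_name")
                         .assign(outcome=outcome))
        diags[outcome] = model.diagnostics().to_dict()
    anova = pd.concat(anova_rows, ignore_index=True)
    coefs = pd.concat(coef_rows, ignore_index=True)
    anova.to_csv(outdir / "anova.csv", index=False, lineterminator="\n")
    coefs.to_csv(outdir / "coefficients.csv", index=False, lineterminator="\n")
    _write_json(outdir / "anova.json",
                anova.to_dict(orient="records"))
    _write_json(outdir / "diagnostics.json", diags)
    manifest["stages"]["fit"] = {
        "ok": True, "outcomes": list(cfg.outcomes),
        "n_obs": {o: int(m.results_.nobs) for o, m in models.items()}}
    return models


def _substitute(cfg, records, models, outdir: Path, header: str, manifest: dict) -> None:
    parts = list(cfg.parts)
    baseline = compositional_mean(records[parts].to_numpy(dtype=float),
                                  cfg.kappa, cfg.parts)
    predicted_means = []
    for outcome, model in models.items():
        grid = difference_grid(model, baseline, cfg.durations, outcome=outcome)
        grid.insert(0, "group", "all")
        pieces = [grid]
        if cfg.group_column in records.columns:
            per_group = group_baseline_grids(model, records, cfg.group_column,
                                             cfg.durations, cfg.parts, outcome,
                                             cfg.kappa)
            pieces.extend(per_group.values())
        tidy = pd.concat(pieces, ignore_index=True)
        safe = outcome.replace("/", "_")
        _write_csv(outdir / f"substitutions_{safe}.csv", tidy, header)
        square = grid_table(model, baseline, cfg.table_minutes, outcome)
        _write_csv(outdir / f"table15_{safe}.csv", square.reset_index(), header)
        predicted_means.append({"outcome": outcome, "group": "all",
                                "predicted": model.predict_composition(baseline)})
        if cfg.group_column in records.columns:
            for group, sub in records.groupby(cfg.group_column, observed=True,
                                              sort=False):
                m = compositional_mean(sub[parts].to_numpy(dtype=float),
                                       cfg.kappa, cfg.parts)
                predicted_means.append({"outcome": outcome, "group": group,
                                        "predicted": model.predict_composition(m)})
    pm = pd.DataFrame(predicted_means)
    _write_csv(outdir / "predicted_means.csv", pm, header)
    _write_json(outdir / "predicted_means.json", predicted_means)
    manifest["stages"]["substitute"] = {
        "ok": True, "durations": list(cfg.durations),
        "baseline_all": dict(zip(parts, baseline.values))}


def _write_csv(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def _library_versions() -> dict:
    import pandas
    import numpy
    import scipy
    import statsmodels
    return {"numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__, "statsmodels": statsmodels.__version__}
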