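"""End-to-end orchestration: data in, fitted charts and inference out.

``run_end_to_end`` drives the whole workflow from a single JSON-style
configuration: load site CSVs (or generate a synthetic scenario), run the
distributed protocol (or the pooled reference fit), perform the inference
round, and write the artifacts — fit JSON, coefficient/inference CSV, centile
chart CSV, and the communication-round log.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .charts import DEFAULT_CENTILES, reference_chart
from .dataio import fit_state_to_dict, load_run_config, model_spec_from_config, read_site_csv
from .federation import RoundLog, SiteData, fit_distributed
from .inference import distributed_inference, pooled_inference
from .pooled import fit_pooled
from .synthgen import generate, scenario

logger = logging.getLogger(__name__)


def _load_sites(cfg) -> list[SiteData]:
    if "scenario" in cfg:
        sc_cfg = cfg["scenario"]
        sc = scenario(
            sc_cfg["name"],
            seed=int(sc_cfg.get("seed", cfg.get("seed", 0))),
            n_total=sc_cfg.get("n_total"),
        )
        return list(generate(sc).sites)
    spec = model_spec_from_config(cfg["model"])
    covs = spec.covariates()
    return [read_site_csv(p, cfg["outcome"], covs) for p in cfg["sites"]]


def _default_grid(model, sites_df: pd.DataFrame, cfg) -> dict:
    grid_cfg = cfg.get("grid", {})
    grid: dict = {}
    for cov, val in grid_cfg.items():
        if isinstance(val, dict):
            grid[cov] = np.linspace(val["from"], val["to"], int(val.get("n", 100))).tolist()
        else:
            grid[cov] = val
    for cov in model.spec.smooth_covariates():
        if cov not in grid:
            rp = next(p for p in model.params if p.smooth_cov == cov)
            grid[cov] = np.linspace(rp.basis.lower, rp.basis.upper, 100).tolist()
    if "sex" in model.levels and "sex" not in grid:
        grid["sex"] = list(model.levels["sex"])
    return grid


def run_end_to_end(config) -> dict:
    """Run the configured analysis; returns paths and key results.

    Artifacts written to ``out_dir``: ``fit.json``, ``inference.csv``,
    ``chart.csv``, ``rounds.csv`` (distributed mode only).
    """
    cfg = load_run_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    spec = model_spec_from_config(cfg["model"])
    sites = _load_sites(cfg)

    if cfg["mode"] == "distributed":
        state, log, model = fit_distributed(sites, spec)
        result = distributed_inference(sites, state, log)
    else:
        y = np.concatenate([s.y for s in sites])
        df = pd.concat([s.covariates for s in sites], ignore_index=True)
        state, model = fit_pooled(y, df, spec)
        log = None
        result = pooled_inference(y, df, model, state)

    pooled_df = pd.concat([s.covariates for s in sites], ignore_index=True)
    grid = _default_grid(model, pooled_df, cfg)
    chart = reference_chart(state, model, grid, cfg.get("centiles", DEFAULT_CENTILES))

    paths = {
        "fit": out / "fit.json",
        "inference": out / "inference.csv",
        "chart": out / "chart.csv",
    }
    paths["fit"].write_text(json.dumps(fit_state_to_dict(state, log), indent=2))
    result.table.to_csv(paths["inference"], index=False)
    chart.to_csv(paths["chart"], index=False)
    if log is not None:
        paths["rounds"] = out / "rounds.csv"
        log.to_frame().to_csv(paths["rounds"], index=False)
    logger.info(
        "finished: converged=%s deviance=%.3f rounds=%s",
        state.converged,
        state.global_deviance,
        None if log is None else log.n_rounds,
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "state": state,
        "round_log": log,
        "model": model,
        "inference": result,
    }
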