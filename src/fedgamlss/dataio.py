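"""Site CSV reading, model configuration parsing, and the formula
mini-language.

Formulas are one string per distribution parameter, e.g.::

    "~ bs(age, knots=6, mode=fixed) + sex + site"
    "~ bs(age, knots=20, mode=fixed_penalty, edf=4.2) + cat(sex)"
    "~ bs(age, knots=20, mode=auto) + sex"
    "~ 1"

Terms are separated by ``+``.  ``bs(cov, ...)`` declares the (single) smooth
term with options ``knots`` (required), ``mode`` (fixed | fixed_penalty |
auto), ``lambda`` or ``edf`` (fixed_penalty only), ``degree`` and ``order``.
Bare names and ``cat(name)`` are fixed-effect covariates (categorical
detection happens from the data, ``cat`` is allowed for explicitness);
``1`` is the intercept, implied whenever no smooth is present.
"""
from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .federation import SiteData
from .model import ModelSpec, ParamSpec, SmoothTerm

logger = logging.getLogger(__name__)


def read_site_csv(path, outcome: str, covariates: list[str], site_id: str | None = None) -> SiteData:
    """Load one site's rows; incomplete rows are dropped (and counted)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in [outcome, *covariates] if c not in df.columns]
    if missing:
        raise KeyError(f"{path.name}: missing column(s) {missing}")
    keep = df[[outcome, *covariates]].notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("%s: dropped %d row(s) with missing outcome/covariates", path.name, n_drop)
    df = df.loc[keep].reset_index(drop=True)
    return SiteData(site_id or path.stem, df[outcome].to_numpy(dtype=float), df[covariates])


_BS_RE = re.compile(r"^bs\(\s*([A-Za-z_]\w*)\s*(?:,(.*))?\)$")
_CAT_RE = re.compile(r"^cat\(\s*([A-Za-z_]\w*)\s*\)$")


class ConfigError(ValueError):
    pass


def parse_formula(formula: str, param: str = "") -> ParamSpec:
    """One parameter's formula string -> :class:`ParamSpec`."""
    body = formula.strip()
    if body.startswith("~"):
        body = body[1:]
    smooth = None
    fixed: list[str] = []
    intercept = True
    for raw in body.split("+"):
        term = raw.strip()
        if not term or term == "1":
            continue
        m = _BS_RE.match(term)
        if m:
            if smooth is not None:
                raise ConfigError(
                    f"{param}: at most one smooth term per parameter "
                    "(multiple-smooth backfitting is not supported)"
                )
            smooth = _parse_bs(m, param)
            continue
        m = _CAT_RE.match(term)
        if m:
            fixed.append(m.group(1))
            continue
        if re.fullmatch(r"[A-Za-z_]\w*", term):
            fixed.append(term)
            continue
        raise ConfigError(f"{param}: cannot parse term {term!r}")
    return ParamSpec(fixed=tuple(fixed), smooth=smooth, intercept=intercept)


def _parse_bs(m: re.Match, param: str) -> SmoothTerm:
    cov = m.group(1)
    opts: dict[str, str] = {}
    for kv in (m.group(2) or "").split(","):
        kv = kv.strip()
        if not kv:
            continue
        if "=" not in kv:
            raise ConfigError(f"{param}: bs() option {kv!r} must be key=value")
        key, val = (s.strip() for s in kv.split("=", 1))
        opts[key] = val
    if "knots" not in opts:
        raise ConfigError(f"{param}: bs({cov}, ...) requires knots=<int>")
    known = {"knots", "mode", "lambda", "edf", "degree", "order"}
    unknown = set(opts) - known
    if unknown:
        raise ConfigError(f"{param}: unknown bs() option(s) {sorted(unknown)}")
    return SmoothTerm(
        covariate=cov,
        n_knots=int(opts["knots"]),
        mode=opts.get("mode", "fixed"),
        lam=float(opts["lambda"]) if "lambda" in opts else None,
        target_edf=float(opts["edf"]) if "edf" in opts else None,
        degree=int(opts.get("degree", 3)),
        order=int(opts.get("order", 2)),
    )


def model_spec_from_config(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from the ``model`` section of a run configuration."""
    from .families import get_family

    if "family" not in cfg:
        raise ConfigError("model.family is required")
    fam = get_family(cfg["family"])
    formulas = cfg.get("formulas")
    if not isinstance(formulas, dict):
        raise ConfigError("model.formulas must map parameter names to formula strings")
    missing = [pn for pn in fam.param_names if pn not in formulas]
    if missing:
        raise ConfigError(f"model.formulas missing parameter(s) {missing} for {fam.name}")
    extra = set(formulas) - set(fam.param_names)
    if extra:
        raise ConfigError(f"model.formulas has unknown parameter(s) {sorted(extra)}")
    params = tuple(parse_formula(formulas[pn], pn) for pn in fam.param_names)
    kwargs = {}
    for key in ("c", "max_inner", "max_outer", "criterion", "gaic_k", "max_step_halvings"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "lambda_grid" in cfg:
        grid = tuple(float(v) for v in cfg["lambda_grid"])
        if any(v < 0 for v in grid):
            raise ConfigError("model.lambda_grid values must be nonnegative")
        kwargs["lambda_grid"] = grid
    try:
        return ModelSpec(family=fam.name, params=params, **kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid model section: {err}") from err


def load_run_config(path_or_dict) -> dict:
    """Load and validate a run configuration; field-level error messages."""
    if isinstance(path_or_dict, (str, Path)):
        cfg = json.loads(Path(path_or_dict).read_text())
    else:
        cfg = dict(path_or_dict)
    if "model" not in cfg:
        raise ConfigError("config requires a 'model' section")
    model_spec_from_config(cfg["model"])  # validate early
    has_sites = "sites" in cfg
    has_scenario = "scenario" in cfg
    if has_sites == has_scenario:
        raise ConfigError("config needs exactly one of 'sites' (CSV paths) or 'scenario'")
    if has_sites:
        if "outcome" not in cfg:
            raise ConfigError("config with 'sites' requires 'outcome' (column name)")
        for p in cfg["sites"]:
            if not Path(p).exists():
                raise ConfigError(f"site file not found: {p}")
    if has_scenario:
        sc = cfg["scenario"]
        if "name" not in sc:
            raise ConfigError("scenario.name is required")
    cfg.setdefault("out_dir", "fedgamlss_out")
    cfg.setdefault("seed", 0)
    cfg.setdefault("mode", "distributed")
    if cfg["mode"] not in ("distributed", "pooled"):
        raise ConfigError("mode must be 'distributed' or 'pooled'")
    return cfg


def write_coef_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def fit_state_to_dict(state, log=None) -> dict:
    d = {
        "family": state.family,
        "converged": state.converged,
        "n_total": state.n_total,
        "n_outer": state.n_outer,
        "n_inner": list(state.n_inner),
        "lambdas": [None if l is None else float(l) for l in state.lambdas],
        "edf": [float(e) for e in state.edf],
        "edf_total": state.edf_total,
        "global_deviance": state.global_deviance,
        "n_step_halvings": state.n_step_halvings,
        "coefficients": [
            {"terms": list(cn), "values": [float(v) for v in c]}
            for cn, c in zip(state.colnames, state.coefficients)
        ],
    }
    if state.global_deviance is not None:
        d["bic"] = state.criterion_value("BIC")
    if log is not None:
        d["communication_rounds"] = {
            "total": log.n_rounds,
            "basis_setup": log.count("basis_setup"),
            "update": log.count("update"),
            "penalty_grid": log.count("penalty_grid"),
            "inference": log.count("inference"),
        }
    return d
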