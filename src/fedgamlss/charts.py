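"""Predicted quantiles and centile reference charts.

After a fit, every covariate combination maps to a full predicted outcome
distribution (all fitted parameters pushed through their inverse links).  Two
consumers:

* the predicted quantile of an *observed* outcome — the CDF of y under the
  subject's predicted distribution, the number used to flag atypical
  measurements (e.g. below the 2.5th or above the 97.5th centile);
* reference charts — family quantiles evaluated over a covariate grid, the
  centile (= 100 x quantile) curves clinicians plot against age.

Both are pure functions of (fitted coefficients, resolved model, covariates):
no site data is touched, so the central site can produce charts alone.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .model import ResolvedModel, build_design
from .rs import FitState

DEFAULT_CENTILES = (2.5, 10.0, 25.0, 50.0, 75.0, 90.0, 97.5)


def predict_theta(state: FitState, model: ResolvedModel, covariates: pd.DataFrame):
    """Per-row predicted distribution parameters (inverse-linked)."""
    fam = model.family
    theta = []
    for k, rp in enumerate(model.params):
        X = build_design(covariates, rp, model.levels)
        theta.append(fam.links[k].g_inverse(X @ state.coefficients[k]))
    return theta


def predict_quantile_of_observation(
    state: FitState, model: ResolvedModel, covariates: pd.DataFrame, y
) -> np.ndarray:
    """CDF of each observed outcome under its predicted distribution."""
    y = np.asarray(y, dtype=float)
    model.family.check_support(y)
    theta = predict_theta(state, model, covariates)
    return model.family.cdf(y, theta)


def reference_chart(
    state: FitState,
    model: ResolvedModel,
    grid_spec: dict,
    centiles=DEFAULT_CENTILES,
) -> pd.DataFrame:
    """Centile table over the cartesian grid of the supplied covariate values.

    ``grid_spec`` maps covariate names to value lists (scalars allowed).
    Covariates required by the model but absent from the grid default to
    their reference level when categorical (first level alphabetically);
    missing continuous covariates are an error, since no principled default
    exists.  Output columns: the grid covariates plus one ``c<centile>``
    column per requested centile; values are nondecreasing across centiles at
    every grid point by construction (quantile functions are monotone).
    """
    grid_spec = {
        k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v])
        for k, v in grid_spec.items()
    }
    needed = set(model.spec.covariates())
    for cov in needed - set(grid_spec):
        if cov in model.levels:
            grid_spec[cov] = [model.levels[cov][0]]  # reference level
        else:
            raise KeyError(
                f"continuous covariate {cov!r} needs grid values (no reference "
                "level exists for continuous covariates)"
            )
    for cov in grid_spec:
        if cov in model.levels:
            unseen = set(map(str, grid_spec[cov])) - set(model.levels[cov])
            if unseen:
                raise ValueError(
                    f"covariate {cov!r}: level(s) {sorted(unseen)} were not in "
                    f"the fitted data (levels: {list(model.levels[cov])})"
                )
    names = list(grid_spec)
    rows = list(itertools.product(*(grid_spec[n] for n in names)))
    grid = pd.DataFrame(rows, columns=names)
    theta = predict_theta(state, model, grid)
    out = grid.copy()
    qs = np.asarray(centiles, dtype=float) / 100.0
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("centiles must lie strictly between 0 and 100")
    for cent, q in zip(centiles, qs):
        out[f"c{cent:g}"] = model.family.ppf(np.full(len(grid), q), theta)
    return out
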