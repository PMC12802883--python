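"""Pooled GAMLSS fitting: the RS cycles run directly on the full data.

This is the reference ("gold standard") path the distributed protocol must
reproduce: all subjects' rows are available in one place, and every Newton
step forms X'WX and X'Wz from the full design matrices.  It doubles as the
exactness oracle for the federated fitter in the test-suite.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .families import Family, Moments, ScoreWeights, score_and_weights
from .model import ModelSpec, ResolvedModel, build_design, collect_levels, resolve_model
from .rs import DataInterface, FitState, run_rs, solve_penalized


def adjusted_dependent(eta: np.ndarray, scores: ScoreWeights) -> np.ndarray:
    """Working response z = eta + u/w of the Newton-as-WLS step."""
    return eta + scores.u / scores.w


def wls_solve(
    X: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    penalty: np.ndarray | None = None,
    lam: float = 0.0,
) -> np.ndarray:
    """Penalized weighted least squares: (X'WX + lam*P) b = X'Wz."""
    from scipy import linalg

    from .rs import _check_rank

    Xw = X * np.asarray(w, dtype=float)[:, None]
    M1 = X.T @ Xw
    M2 = Xw.T @ np.asarray(z, dtype=float)

    class _Cols:
        name = "wls"
        colnames = tuple(f"col{i}" for i in range(X.shape[1]))

    _check_rank(M1, _Cols())
    A = M1 if penalty is None or lam == 0.0 else M1 + lam * penalty
    c, low = linalg.cho_factor(A)
    return linalg.cho_solve((c, low), M2)


class PooledData(DataInterface):
    """Full-data backend for the RS driver."""

    def __init__(self, y: np.ndarray, covariates: pd.DataFrame, model: ResolvedModel):
        self.model = model
        self.family: Family = model.family
        self.y = np.asarray(y, dtype=float)
        self.family.check_support(self.y)
        self.n_total = int(self.y.size)
        self.X = [build_design(covariates, rp, model.levels) for rp in model.params]

    def moments(self) -> Moments:
        return Moments.from_outcome(self.y)

    def _theta(self, coefs):
        return [
            self.family.links[j].g_inverse(self.X[j] @ coefs[j])
            for j in range(self.family.n_params)
        ]

    def update(self, k, coefs):
        theta = self._theta(coefs)
        dev = -2.0 * float(np.sum(self.family.loglik(self.y, theta)))
        sw = score_and_weights(self.family, k, self.y, theta)
        eta_k = self.X[k] @ coefs[k]
        Xw = self.X[k] * sw.w[:, None]
        M1 = self.X[k].T @ Xw
        # X'W z computed as X'(w*eta + u): identical algebra, no u/w ratio
        M2 = self.X[k].T @ (sw.w * eta_k + sw.u)
        return M1, M2, dev

    def deviance_at(self, coef_sets):
        return [
            -2.0 * float(np.sum(self.family.loglik(self.y, self._theta(cs))))
            for cs in coef_sets
        ]


def prepare_pooled(
    y: np.ndarray, covariates: pd.DataFrame, spec: ModelSpec
) -> tuple[PooledData, ResolvedModel]:
    """Resolve the model against the pooled data and build the backend."""
    covs = spec.covariates()
    levels = collect_levels([covariates], covs)
    ranges = {
        cov: (float(covariates[cov].min()), float(covariates[cov].max()))
        for cov in spec.smooth_covariates()
    }
    model = resolve_model(spec, ranges, levels)
    return PooledData(y, covariates, model), model


def fit_pooled(
    y: np.ndarray,
    covariates: pd.DataFrame,
    spec: ModelSpec,
    keep_history: bool = False,
) -> tuple[FitState, ResolvedModel]:
    """Fit a GAMLSS model on pooled data; returns the fit and the resolved
    model (basis, levels) needed for prediction and charting."""
    data, model = prepare_pooled(y, covariates, spec)
    state = run_rs(data, model, keep_history=keep_history)
    state.global_deviance = data.deviance_at([state.coefficients])[0]
    return state, model
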