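"""Post-fit distributed inference.

One extra communication round after convergence: the final coefficients are
broadcast, and every site returns (a) the numerical negative Hessian of its
own log-likelihood with respect to the full stacked coefficient vector,
evaluated jointly across all distribution parameters, and (b) its site
deviance.  Because log-likelihoods add over subjects, the pooled Hessian is
the exact sum of site Hessians; the joint coefficient covariance is

    Sigma = (sum_i H_i)^{-1},

its diagonal gives Wald standard errors and t-statistics (two-sided normal
p-values), and summed site deviances give the global deviance.

Smooth-term significance uses a likelihood-ratio test against a reduced model
that is intercept-only *for the tested parameter* (all other parameters keep
their smooths), with a chi-square null whose df is the smooth's column count
(fixed-effect regime) or its effective degrees of freedom (fixed-penalty
regime); non-integer df uses the continuous chi-square.  For automated-
penalty smooths the test is refused: the data-driven penalty choice makes the
chi-square reference liberal and no exact correction is implemented.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .federation import RoundLog, SiteData
from .model import ResolvedModel
from .rs import FitState

HESS_STEP = 1e-4  # relative central-difference step for the numerical Hessian


def _stack(coefs: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([np.asarray(c, dtype=float) for c in coefs])


def _unstack(vec: np.ndarray, template: list[np.ndarray]) -> list[np.ndarray]:
    out, pos = [], 0
    for c in template:
        out.append(vec[pos : pos + c.size])
        pos += c.size
    return out


def negative_numerical_hessian(f, x0: np.ndarray, rel_step: float = HESS_STEP) -> np.ndarray:
    """-d2f/dx2 by central differences, h_j = rel_step * max(1, |x_j|)."""
    x0 = np.asarray(x0, dtype=float)
    q = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((q, q))
    f0 = f(x0)

    def fp(i, si, j=None, sj=0.0):
        x = x0.copy()
        x[i] += si * h[i]
        if j is not None:
            x[j] += sj * h[j]
        return f(x)

    for i in range(q):
        H[i, i] = (fp(i, 1.0) - 2.0 * f0 + fp(i, -1.0)) / h[i] ** 2
        for j in range(i + 1, q):
            H[i, j] = H[j, i] = (
                fp(i, 1.0, j, 1.0) - fp(i, 1.0, j, -1.0) - fp(i, -1.0, j, 1.0) + fp(i, -1.0, j, -1.0)
            ) / (4.0 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        bad = np.argwhere(~np.isfinite(H))[0]
        raise FloatingPointError(
            f"non-finite Hessian entry at coefficient indices {tuple(bad)}"
        )
    return -H


@dataclass(frozen=True)
class HessianMessage:
    """Site -> aggregator, inference round: aggregates only."""

    site_id: str
    H: np.ndarray = field(repr=False)
    deviance: float
    n_i: int


def site_hessian(site: SiteData, coefficients: list[np.ndarray]) -> HessianMessage:
    """The site's negative numerical Hessian at the broadcast coefficients."""
    template = [np.asarray(c, dtype=float) for c in coefficients]

    def f(vec):
        coefs = _unstack(vec, template)
        return float(np.sum(site._family.loglik(site.y, site._theta(coefs))))

    H = negative_numerical_hessian(f, _stack(template))
    return HessianMessage(
        site_id=site.site_id,
        H=H,
        deviance=site._site_deviance(template),
        n_i=site.n_i,
    )


@dataclass
class LRTRecord:
    parameter: str
    statistic: float
    df: float
    p: float


@dataclass
class InferenceResult:
    covariance: np.ndarray = field(repr=False)
    table: pd.DataFrame
    global_deviance: float
    edf: list[float]
    flagged: list[str] = field(default_factory=list)  # coefficients with unusable SEs
    lrt: list[LRTRecord] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return self.table["se"].to_numpy()


def aggregate_inference(
    hessians: list[HessianMessage],
    state: FitState,
) -> InferenceResult:
    """Invert the summed site Hessians into Wald inference.

    A non-positive-definite sum (typical for spline basis columns supported by
    almost no observations) falls back to the pseudo-inverse with a warning,
    and coefficients with non-positive variance are flagged with NaN standard
    errors instead of silently misleading numbers.
    """
    if not hessians:
        raise ValueError("no site Hessians to aggregate")
    H = np.sum([m.H for m in hessians], axis=0)
    flagged: list[str] = []
    names = [
        f"{pn}:{cn}"
        for pn, cns in zip(_param_names(state), state.colnames)
        for cn in cns
    ]
    try:
        c, low = linalg.cho_factor(H)
        cov = linalg.cho_solve((c, low), np.eye(H.shape[0]))
    except linalg.LinAlgError:
        warnings.warn(
            "summed Hessian not positive definite; using pseudo-inverse "
            "(expect this for spline tails with few supporting observations)",
            stacklevel=2,
        )
        cov = linalg.pinvh(H)
    var = np.diag(cov).copy()
    bad = var <= 0
    if np.any(bad):
        flagged = [names[i] for i in np.flatnonzero(bad)]
        var[bad] = np.nan
    se = np.sqrt(var)
    est = _stack(state.coefficients)
    t = est / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    table = pd.DataFrame(
        {
            "parameter": [n.split(":", 1)[0] for n in names],
            "term": [n.split(":", 1)[1] for n in names],
            "estimate": est,
            "se": se,
            "t": t,
            "p": p,
        }
    )
    return InferenceResult(
        covariance=cov,
        table=table,
        global_deviance=float(sum(m.deviance for m in hessians)),
        edf=list(state.edf),
        flagged=flagged,
    )


def _param_names(state: FitState):
    from .families import get_family

    return get_family(state.family).param_names


def distributed_inference(
    sites: list[SiteData], state: FitState, log: RoundLog | None = None
) -> InferenceResult:
    """The single post-fit inference round across all sites."""
    msgs = [site_hessian(s, state.coefficients) for s in sites]
    if log is not None:
        log.log("inference", {m.site_id: m.H.size * 8 + 16 for m in msgs})
    result = aggregate_inference(msgs, state)
    state.global_deviance = result.global_deviance
    return result


def pooled_inference(y, covariates, model: ResolvedModel, state: FitState) -> InferenceResult:
    """Same computation on pooled data (a single 'site' holding everything)."""
    site = SiteData("pooled", y, covariates)
    site.receive_model(model)
    return aggregate_inference([site_hessian(site, state.coefficients)], state)


def lrt_smooth(
    full_deviance: float, reduced_deviance: float, df: float
) -> tuple[float, float]:
    """Likelihood-ratio test of a smooth term: statistic = reduced - full
    deviance, null chi-square with (possibly non-integer) df."""
    stat = reduced_deviance - full_deviance
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic {stat:.3g}: models not nested or not converged"
        )
    stat = max(stat, 0.0)
    if df <= 0:
        raise ValueError("df must be positive")
    return stat, float(stats.chi2.sf(stat, df))


def smooth_lrt_df(model: ResolvedModel, state: FitState, k: int) -> float:
    """Null df for testing parameter k's smooth against intercept-only.

    Fixed-effect smooth: basis column count minus the intercept the reduced
    model regains.  Fixed-penalty smooth: the smooth term's effective degrees
    of freedom minus one, on the same accounting.  Automated-penalty smooths
    are refused.
    """
    rp = model.params[k]
    if rp.basis is None:
        raise ValueError(f"parameter {rp.name} has no smooth term")
    if rp.mode == "auto":
        raise ValueError(
            "likelihood-ratio testing is not offered for automated-penalty "
            "smooths: the chi-square reference does not account for the "
            "data-driven penalty and would be liberal"
        )
    if rp.mode == "fixed":
        return float(rp.basis.n_cols - 1)
    n_fixed = rp.n_cols - rp.basis.n_cols
    return float(state.edf[k] - n_fixed - 1.0)


def reduced_spec_for_lrt(spec, k: int):
    """Model with parameter k reduced to intercept-only; all other parameters
    keep their full smooth terms (the nesting the chi-square null assumes)."""
    from .model import ModelSpec, ParamSpec

    params = list(spec.params)
    params[k] = ParamSpec(fixed=(), smooth=None, intercept=True)
    return ModelSpec(
        family=spec.family,
        params=tuple(params),
        c=spec.c,
        max_inner=spec.max_inner,
        max_outer=spec.max_outer,
        lambda_grid=spec.lambda_grid,
        criterion=spec.criterion,
        gaic_k=spec.gaic_k,
        max_step_halvings=spec.max_step_halvings,
    )
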