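"""The RS (Rigby-Stasinopoulos) fitting cycle, written once for both the
pooled and the distributed paths.

The outer cycle sweeps the distribution parameters; the inner cycle performs
Newton-Raphson updates on one parameter's coefficients while all other
parameters are held fixed.  Each Newton step is a penalized weighted least
squares solve on the adjusted dependent variable

    z_k = eta_k + u_k / w_k,      b_new = (X'WX + lambda*P~)^{-1} X'Wz,

and the only quantities the driver ever consumes are the cross-products
M1 = X'WX, M2 = X'Wz, scalar deviances, and counts.  A
:class:`DataInterface` supplies them: the pooled backend computes them on the
full data, the federated backend as sums of per-site messages.  Because both
backends feed the identical driver, the distributed fit reproduces the pooled
iterate sequence exactly (up to float summation order) — which is precisely
the algorithm's exactness claim.

Convergence is coefficient-based: a coefficient has converged when the
proportion change against its previous value is below the threshold ``c``
(absolute change below ``c * 1e-8`` when the previous value is essentially
zero).  The inner cycle stops when every coefficient of the active parameter
passes; the outer cycle stops when every coefficient of every parameter
passes against its value at the end of the previous outer cycle.

Step control: if the *penalized* global deviance (deviance plus the quadratic
penalty sum lambda_k * gamma_k' P_k gamma_k, which the aggregator computes
from coefficients it already holds) observed at the most recently accepted
coefficients exceeds the previous accepted value, the last move is halved
(up to ``max_step_halvings`` times) before being accepted.  The raw deviance
alone is not monotone under penalized updates, so the penalized objective is
the right descent quantity; its deviance part is the one reported together
with each update — i.e. the check runs one round *behind* the move, matching
the distributed setting where global deviance estimation is delayed by one
communication round.  The baseline resets whenever a smoothing parameter
changes (the objective itself changes then).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .families import Moments
from .model import ResolvedModel, ResolvedParam
from .splines import RIDGE_REL, edf as edf_trace

logger = logging.getLogger(__name__)

_DEV_SLACK = 1e-7  # relative penalized-deviance increase tolerated before halving
_ZERO_COEF = 1e-8  # |old| below this switches to the absolute convergence rule


# ---------------------------------------------------------------------------


class DataInterface:
    """What the RS driver needs from data, pooled or federated."""

    n_total: int

    def moments(self) -> Moments:  # pragma: no cover - abstract
        raise NotImplementedError

    def update(self, k: int, coefs: list[np.ndarray]):
        """Return (M1, M2, deviance-at-coefs) for parameter k."""
        raise NotImplementedError  # pragma: no cover

    def deviance_at(self, coef_sets: list[list[np.ndarray]]) -> list[float]:
        raise NotImplementedError  # pragma: no cover


@dataclass
class FitState:
    """Converged (or capped) coefficients plus fitting diagnostics."""

    family: str
    coefficients: list[np.ndarray]
    colnames: list[tuple[str, ...]]
    converged: bool
    n_outer: int
    n_inner: list[int]
    lambdas: list[float | None]
    edf: list[float]
    n_total: int
    global_deviance: float | None = None
    n_step_halvings: int = 0
    penalty_stalls: int = 0
    history: list = field(default_factory=list, repr=False)

    @property
    def edf_total(self) -> float:
        return float(sum(self.edf))

    def criterion_value(self, name: str = "BIC", gaic_k: float = 2.0) -> float:
        if self.global_deviance is None:
            raise ValueError("global deviance not yet evaluated (run inference)")
        return information_criterion(
            name, self.global_deviance, self.edf_total, self.n_total, gaic_k
        )


def information_criterion(
    name: str, deviance: float, edf_total: float, n: int, gaic_k: float = 2.0
) -> float:
    """BIC = dev + log(n)*EDF; GAIC(k) = dev + k*EDF; GCV = n*dev/(n-EDF)^2."""
    if name == "BIC":
        return deviance + np.log(n) * edf_total
    if name == "GAIC":
        return deviance + gaic_k * edf_total
    if name == "GCV":
        return n * deviance / (n - edf_total) ** 2
    raise ValueError(f"unknown criterion {name!r}")


def solve_penalized(M1: np.ndarray, M2: np.ndarray, rp: ResolvedParam, lam: float) -> np.ndarray:
    """Solve (M1 + lam*P~) b = M2 by a symmetric positive-definite solve.

    Shared by both fitting paths so pooled and distributed updates go through
    bit-identical linear algebra given identical inputs.
    """
    A = M1
    if rp.penalty_full is not None and lam > 0:
        A = M1 + lam * rp.penalty_full
    _check_rank(M1, rp)
    try:
        c, low = linalg.cho_factor(A)
        return linalg.cho_solve((c, low), M2)
    except linalg.LinAlgError:
        ridge = RIDGE_REL * float(np.mean(np.diag(A)))
        logger.warning("WLS system not SPD; retrying with ridge %.3e", ridge)
        c, low = linalg.cho_factor(A + ridge * np.eye(A.shape[0]))
        return linalg.cho_solve((c, low), M2)


def _check_rank(M1: np.ndarray, rp: ResolvedParam) -> None:
    """Catch (near-)duplicate design columns, which a numerically 'successful'
    Cholesky of the Gram matrix would otherwise turn into garbage estimates."""
    d = np.sqrt(np.maximum(np.diag(M1), 1e-300))
    C = np.abs(M1 / np.outer(d, d))
    np.fill_diagonal(C, 0.0)
    i, j = np.unravel_index(int(np.argmax(C)), C.shape)
    if C[i, j] > 1.0 - 1e-10:
        names = getattr(rp, "colnames", None)
        a = names[i] if names else f"col{i}"
        b = names[j] if names else f"col{j}"
        raise np.linalg.LinAlgError(
            f"rank-deficient design for parameter {rp.name}: columns "
            f"{a!r} and {b!r} appear collinear"
        )


def coef_converged(old: np.ndarray, new: np.ndarray, c: float) -> bool:
    """Proportion-change rule, with an absolute fallback at (near-)zero."""
    old = np.asarray(old, dtype=float)
    new = np.asarray(new, dtype=float)
    small = np.abs(old) <= _ZERO_COEF
    tol = np.where(small, c * _ZERO_COEF, c * np.abs(old))
    return bool(np.all(np.abs(new - old) < tol))


def initial_coefficients(model: ResolvedModel, moments: Moments) -> list[np.ndarray]:
    """Constant-predictor start from aggregate outcome moments only.

    Each parameter starts at the family's moment-based initial value pushed
    through its link; with a smooth present, every basis coefficient is set to
    that constant (partition of unity makes the predictor flat)."""
    fam = model.family
    theta0 = fam.initial_theta(moments)
    coefs = []
    for k, rp in enumerate(model.params):
        eta0 = float(fam.links[k].g(np.array([theta0[k]]))[0])
        b = np.zeros(rp.n_cols)
        if rp.basis is not None:
            b[rp.smooth_slice] = eta0
        elif rp.colnames and rp.colnames[0] == "(Intercept)":
            b[0] = eta0
        coefs.append(b)
    return coefs


# ---------------------------------------------------------------------------


def run_rs(iface: DataInterface, model: ResolvedModel, keep_history: bool = False) -> FitState:
    """Run the nested RS cycles to convergence (or the iteration caps)."""
    spec = model.spec
    fam = model.family
    p = fam.n_params
    coefs = initial_coefficients(model, iface.moments())

    lambdas: list[float | None] = []
    for rp in model.params:
        if rp.basis is None or rp.mode == "fixed":
            lambdas.append(0.0 if rp.basis is not None else None)
        elif rp.mode == "fixed_penalty":
            lambdas.append(rp.lam0 if rp.lam0 is not None else None)  # resolved per-iter via EDF
        else:  # auto: start mid-grid, replaced at the first selection
            lambdas.append(float(spec.lambda_grid[len(spec.lambda_grid) // 2]))

    cached_M1: list[np.ndarray | None] = [None] * p
    last_crit: list[float | None] = [None] * p
    dev_accepted: float | None = None
    lambdas_at_accept: list = list(lambdas)
    last_move: tuple[int, np.ndarray] | None = None
    halvings_left = spec.max_step_halvings
    n_halvings_total = 0
    stalls = 0
    n_inner = [0] * p
    history: list[dict] = []
    converged = False
    n_outer = 0

    from .splines import lambda_for_edf  # local import to avoid cycle at module load

    for outer in range(spec.max_outer):
        n_outer = outer + 1
        outer_start = [b.copy() for b in coefs]
        for k in range(p):
            rp = model.params[k]
            inner_done = False
            select_this_cycle = rp.basis is not None and rp.mode == "auto"
            n_inner_at_cycle_start = n_inner[k]
            for _ in range(spec.max_inner):
                M1, M2, dev = iface.update(k, coefs)
                n_inner[k] += 1
                # delayed step control on the penalized deviance: dev is the
                # deviance at the current coefficients, i.e. *after* the
                # previous accepted move; the penalty term is added centrally
                dev_pen = dev + _penalty_term(model, lambdas, coefs)
                if lambdas != lambdas_at_accept:
                    dev_accepted = None  # objective changed with lambda
                if (
                    dev_accepted is not None
                    and last_move is not None
                    and dev_pen > dev_accepted + _DEV_SLACK * max(1.0, abs(dev_accepted))
                    and halvings_left > 0
                ):
                    km, old_b = last_move
                    coefs[km] = 0.5 * (coefs[km] + old_b)
                    halvings_left -= 1
                    n_halvings_total += 1
                    continue
                dev_accepted = dev_pen
                lambdas_at_accept = list(lambdas)
                halvings_left = spec.max_step_halvings
                cached_M1[k] = M1

                if (
                    rp.basis is not None
                    and rp.mode == "fixed_penalty"
                    and rp.lam0 is None
                    and (lambdas[k] is None or n_inner_at_cycle_start == n_inner[k] - 1)
                ):
                    # EDF-matched penalty: resolve lambda from the current
                    # aggregated X'WX once per outer cycle, then hold it so
                    # the inner cycle converges at a fixed objective
                    lambdas[k] = lambda_for_edf(M1, rp.penalty_full, rp.target_edf)

                if select_this_cycle:
                    # penalty selection once per outer cycle; the remaining
                    # inner iterations polish coefficients at the chosen lambda
                    b_new, lambdas[k], last_crit[k], stalled = _select_penalty(
                        iface, model, k, coefs, M1, M2, lambdas, cached_M1, last_crit[k]
                    )
                    stalls += int(stalled)
                    select_this_cycle = False
                else:
                    b_new = solve_penalized(M1, M2, rp, lambdas[k] or 0.0)

                done = coef_converged(coefs[k], b_new, spec.c)
                last_move = (k, coefs[k].copy())
                if keep_history:
                    last_state = [c.copy() for c in coefs]  # input to this update
                coefs[k] = b_new
                if keep_history:
                    history.append(
                        {
                            "outer": outer,
                            "k": k,
                            "coefs_in": [c.copy() for c in last_state],
                            "coef": b_new.copy(),
                            "lam": lambdas[k],
                            "deviance": dev,
                        }
                    )
                if done:
                    inner_done = True
                    break
            if not inner_done:
                logger.warning(
                    "inner cycle for %s hit max_inner=%d without converging",
                    rp.name,
                    spec.max_inner,
                )
        if all(
            coef_converged(o, b, spec.c) for o, b in zip(outer_start, coefs)
        ):
            converged = True
            break

    if not converged:
        logger.warning("outer cycle hit max_outer=%d without converging", spec.max_outer)

    edfs = []
    for k, rp in enumerate(model.params):
        if rp.basis is None or not lambdas[k]:
            edfs.append(float(rp.n_cols))
        else:
            edfs.append(edf_trace(cached_M1[k], rp.penalty_full, lambdas[k]))

    return FitState(
        family=fam.name,
        coefficients=[b.copy() for b in coefs],
        colnames=[rp.colnames for rp in model.params],
        converged=converged,
        n_outer=n_outer,
        n_inner=n_inner,
        lambdas=list(lambdas),
        edf=edfs,
        n_total=iface.n_total,
        n_step_halvings=n_halvings_total,
        penalty_stalls=stalls,
        history=history,
    )


def _penalty_term(model, lambdas, coefs) -> float:
    """Quadratic roughness penalty sum over smooth parameters."""
    total = 0.0
    for k, rp in enumerate(model.params):
        if rp.basis is not None and lambdas[k]:
            total += float(lambdas[k]) * float(coefs[k] @ rp.penalty_full @ coefs[k])
    return total


def _edf_other_params(model, lambdas, cached_M1, skip_k):
    total = 0.0
    for j, rp in enumerate(model.params):
        if j == skip_k:
            continue
        if rp.basis is None or not lambdas[j] or cached_M1[j] is None:
            total += float(rp.n_cols)
        else:
            total += edf_trace(cached_M1[j], rp.penalty_full, lambdas[j])
    return total


def _select_penalty(iface, model, k, coefs, M1, M2, lambdas, cached_M1, prev_crit):
    """One automated-penalty selection: candidate coefficients for every
    lambda on the grid, then the information criterion evaluated at each
    candidate from summed site deviances (one extra evaluation round).

    Ties break to the smallest lambda; if no candidate improves on the
    previous criterion value for this parameter, the previous lambda is kept
    (stall) but its candidate coefficients are still accepted.
    """
    spec = model.spec
    rp = model.params[k]
    grid = list(spec.lambda_grid)
    cands = [solve_penalized(M1, M2, rp, lam) for lam in grid]
    coef_sets = []
    for b in cands:
        cs = [c.copy() for c in coefs]
        cs[k] = b
        coef_sets.append(cs)
    devs = iface.deviance_at(coef_sets)
    edf_rest = _edf_other_params(model, lambdas, cached_M1, k)
    crits = [
        information_criterion(
            spec.criterion,
            devs[i],
            edf_trace(M1, rp.penalty_full, grid[i]) + edf_rest,
            iface.n_total,
            spec.gaic_k,
        )
        for i in range(len(grid))
    ]
    best = int(np.argmin(crits))  # argmin returns the first (smallest-lambda) tie
    stalled = False
    if prev_crit is not None and crits[best] > prev_crit and lambdas[k] in grid:
        logger.info(
            "penalty selection stalled for %s; keeping lambda=%.4g", rp.name, lambdas[k]
        )
        best = grid.index(lambdas[k])
        stalled = True
    return cands[best], grid[best], crits[best], stalled
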