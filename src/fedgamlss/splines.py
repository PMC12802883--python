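"""Penalized B-spline bases (P-splines) for smooth terms.

A basis is defined by a covariate range [lower, upper], a *total knot count*
``n_knots`` (the equally spaced knots partitioning the range, boundary knots
included), and a polynomial ``degree`` (cubic by default).  The augmented knot
vector repeats each boundary knot ``degree`` extra times, giving

    n_cols = n_knots + degree - 1

basis columns.  Bases are deterministic functions of (lower, upper, n_knots,
degree) and serialize to JSON, so a central aggregator can broadcast one basis
and every site evaluates bit-identical design columns — a requirement for the
distributed fit to reproduce the pooled fit exactly.

Smoothing uses the standard P-spline difference penalty P = D'D (order-2
differences by default, null space = constants and linear-in-index
coefficient vectors) scaled by lambda >= 0.  The effective degrees of freedom
of a parameter's design are

    EDF(lambda) = trace[(X'WX + lambda * P~)^{-1} X'WX]

with P~ the penalty embedded in the full design (zero block for unpenalized
fixed-effect columns); EDF is monotone nonincreasing in lambda, from the
design rank at lambda=0 down to (null-space dim + n fixed columns) as
lambda -> inf.  ``lambda_for_edf`` inverts this map by root-finding on
log(lambda), which is how a penalty is matched to a known target EDF.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

RIDGE_REL = 1e-10  # relative ridge jitter for near-singular penalized solves


@dataclass(frozen=True)
class SplineBasis:
    """Regular-interval B-spline basis on [lower, upper]."""

    lower: float
    upper: float
    n_knots: int
    degree: int = 3
    knot_vector: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.upper > self.lower:
            raise ValueError("upper must exceed lower")
        if self.n_knots < 2:
            raise ValueError("need at least 2 knots (the range boundaries)")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        inner = np.linspace(self.lower, self.upper, self.n_knots)
        kv = np.concatenate(
            [np.full(self.degree, self.lower), inner, np.full(self.degree, self.upper)]
        )
        object.__setattr__(self, "knot_vector", kv)

    @property
    def n_cols(self) -> int:
        return self.n_knots + self.degree - 1

    def evaluate(self, x) -> np.ndarray:
        """Design matrix (len(x) x n_cols); x clamped to [lower, upper]."""
        x = np.asarray(x, dtype=float)
        n_out = int(np.sum((x < self.lower) | (x > self.upper)))
        if n_out:
            logger.warning(
                "%d covariate value(s) outside basis range [%g, %g]; clamped",
                n_out,
                self.lower,
                self.upper,
            )
        xc = np.clip(x, self.lower, self.upper)
        return BSpline.design_matrix(
            xc, self.knot_vector, self.degree, extrapolate=False
        ).toarray()

    def to_json(self) -> str:
        return json.dumps(
            {
                "lower": self.lower,
                "upper": self.upper,
                "n_knots": self.n_knots,
                "degree": self.degree,
            }
        )

    @staticmethod
    def from_json(s: str) -> "SplineBasis":
        d = json.loads(s)
        return SplineBasis(**d)


def build_basis(lower: float, upper: float, n_knots: int, degree: int = 3) -> SplineBasis:
    """Construct the regular-interval basis; see module docstring for the
    knot-count convention (n_cols = n_knots + degree - 1)."""
    return SplineBasis(float(lower), float(upper), int(n_knots), int(degree))


def difference_penalty(n_cols: int, order: int = 2) -> np.ndarray:
    """P-spline penalty P = D'D with D the order-th difference operator.

    P is symmetric PSD with null-space dimension ``order`` (constants are
    unpenalized for order>=1, linear coefficient trends for order 2).
    """
    if order < 1 or order >= n_cols:
        raise ValueError(f"difference order {order} invalid for {n_cols} columns")
    D = np.diff(np.eye(n_cols), n=order, axis=0)
    return D.T @ D


def greville_abscissae(basis: SplineBasis) -> np.ndarray:
    """Greville sites t*_j (means of degree consecutive inner knots); the
    B-spline identity sum_j t*_j B_j(x) = x makes them the natural x-positions
    of the coefficients."""
    kv, d = basis.knot_vector, basis.degree
    return np.array([kv[j + 1 : j + 1 + d].mean() for j in range(basis.n_cols)])


def greville_penalty(basis: SplineBasis, order: int = 2) -> np.ndarray:
    """Difference penalty with divided differences taken at the Greville
    abscissae.

    With repeated boundary knots the Greville sites are unevenly spaced near
    the edges, so plain index differences would penalize *linear functions of
    x* there; divided differences keep the null space exactly {constants}
    (order 1) or {affine functions of x} (order 2).  Rows are rescaled by the
    mean Greville spacing so the matrix reduces to the plain difference
    operator when the sites are uniform.
    """
    t = greville_abscissae(basis)
    n = basis.n_cols
    if order not in (1, 2):
        raise ValueError("supported difference orders: 1, 2")
    if order >= n:
        raise ValueError(f"difference order {order} invalid for {n} columns")
    h = float(np.mean(np.diff(t)))
    rows = []
    if order == 1:
        for j in range(n - 1):
            r = np.zeros(n)
            r[j], r[j + 1] = -1.0, 1.0
            rows.append(r * h / (t[j + 1] - t[j]))
    else:
        for j in range(n - 2):
            r = np.zeros(n)
            d1, d2 = t[j + 1] - t[j], t[j + 2] - t[j + 1]
            r[j] = 1.0 / d1
            r[j + 1] = -1.0 / d1 - 1.0 / d2
            r[j + 2] = 1.0 / d2
            rows.append(r * 2.0 * h**2 / (t[j + 2] - t[j]))
    D = np.array(rows)
    return D.T @ D


def embed_penalty(P: np.ndarray, n_total: int, offset: int) -> np.ndarray:
    """Place the smooth-block penalty inside the full-design (n_total x
    n_total) penalty, zeros everywhere else (fixed effects unpenalized)."""
    full = np.zeros((n_total, n_total))
    q = P.shape[0]
    full[offset : offset + q, offset : offset + q] = P
    return full


def _penalized_solve_matrix(XtWX: np.ndarray, lam: float, P_full: np.ndarray) -> np.ndarray:
    A = XtWX + lam * P_full
    try:
        return np.linalg.solve(A, XtWX)
    except np.linalg.LinAlgError:
        ridge = RIDGE_REL * np.mean(np.diag(A))
        logger.warning("penalized system near-singular; adding ridge %.3e", ridge)
        try:
            return np.linalg.solve(A + ridge * np.eye(A.shape[0]), XtWX)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "penalized cross-product singular even after ridge jitter; "
                "check for collinear design columns"
            ) from err


def edf(XtWX: np.ndarray, P_full: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom trace[(X'WX + lam*P~)^{-1} X'WX],
    inclusive of any unpenalized fixed-effect columns in the design."""
    return float(np.trace(_penalized_solve_matrix(XtWX, lam, P_full)))


def edf_by_column(XtWX: np.ndarray, P_full: np.ndarray, lam: float) -> np.ndarray:
    """Per-column EDF contributions (diagonal of the hat-type matrix)."""
    return np.diag(_penalized_solve_matrix(XtWX, lam, P_full)).copy()


def lambda_for_edf(
    XtWX: np.ndarray,
    P_full: np.ndarray,
    target_edf: float,
    log10_bounds: tuple[float, float] = (-8.0, 12.0),
    tol: float = 1e-6,
) -> float:
    """Solve for the lambda whose EDF equals ``target_edf``.

    EDF(lambda) is continuous and monotone nonincreasing, so a sign change of
    EDF(lambda) - target over the log-lambda bracket guarantees a root; Brent
    root-finding on log10(lambda) then converges to |edf - target| < 1e-4.
    Targets outside the attainable [EDF(lam_max), EDF(0)] interval raise with
    the attainable range in the message.
    """
    lo, hi = log10_bounds
    e_max = edf(XtWX, P_full, 10.0**lo)
    e_min = edf(XtWX, P_full, 10.0**hi)
    if target_edf >= e_max:
        if target_edf > e_max + 1e-3:
            raise ValueError(
                f"target EDF {target_edf:.4f} not attainable; range is "
                f"[{e_min:.4f}, {e_max:.4f}]"
            )
        return 0.0
    if target_edf < e_min - 1e-3:
        raise ValueError(
            f"target EDF {target_edf:.4f} not attainable; range is "
            f"[{e_min:.4f}, {e_max:.4f}]"
        )
    sol = optimize.brentq(
        lambda t: edf(XtWX, P_full, 10.0**t) - target_edf, lo, hi, xtol=tol
    )
    return float(10.0**sol)


def bspline_cox_de_boor(x: float, knots: np.ndarray, degree: int, i: int) -> float:
    """Textbook Cox-de Boor recursion for one basis function; slow, used only
    as an independent oracle in the tests."""
    if degree == 0:
        # right-closed on the last interval so the boundary point is covered
        last = knots[i + 1] == knots[-1]
        if knots[i] <= x < knots[i + 1] or (last and x == knots[i + 1] and knots[i] < knots[i + 1]):
            return 1.0
        return 0.0
    out = 0.0
    d1 = knots[i + degree] - knots[i]
    if d1 > 0:
        out += (x - knots[i]) / d1 * bspline_cox_de_boor(x, knots, degree - 1, i)
    d2 = knots[i + degree + 1] - knots[i + 1]
    if d2 > 0:
        out += (knots[i + degree + 1] - x) / d2 * bspline_cox_de_boor(x, knots, degree - 1, i + 1)
    return out
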