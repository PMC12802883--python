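"""Model specification and design-matrix construction.

A :class:`ModelSpec` names the outcome family and, for each distribution
parameter, an additive design: optional smooth term in one continuous
covariate (at most one smooth per parameter) plus fixed-effect covariates.
Categorical covariates are expanded to treatment contrasts against the
alphabetically first level, with the level dictionary agreed globally before
fitting so that every site builds column-for-column identical designs.

When a parameter carries a smooth, the full (non-orthogonalized) B-spline
basis replaces the intercept: the basis columns sum to one at every point, so
they span the constant function and a separate intercept column would be
exactly collinear.

Smooth-term regimes:

``fixed``          lambda = 0; the basis dimension alone controls flexibility.
``fixed_penalty``  lambda supplied directly, or resolved each iteration from a
                   target EDF ("EDF-matched" penalty).
``auto``           lambda selected from a grid by an information criterion
                   (BIC by default) during fitting.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .families import Family, get_family
from .splines import SplineBasis, build_basis, embed_penalty, greville_penalty

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4.0, 6.0, 20))
SMOOTH_MODES = ("fixed", "fixed_penalty", "auto")
CRITERIA = ("BIC", "GAIC", "GCV")


@dataclass(frozen=True)
class SmoothTerm:
    """One penalized B-spline smooth in a continuous covariate."""

    covariate: str
    n_knots: int
    mode: str = "fixed"
    lam: float | None = None
    target_edf: float | None = None
    degree: int = 3
    order: int = 2

    def __post_init__(self):
        if self.mode not in SMOOTH_MODES:
            raise ValueError(f"smooth mode must be one of {SMOOTH_MODES}, got {self.mode!r}")
        if self.mode == "fixed_penalty" and self.lam is None and self.target_edf is None:
            raise ValueError("fixed_penalty smooth needs either lam or target_edf")


@dataclass(frozen=True)
class ParamSpec:
    """Design description for one distribution parameter."""

    fixed: tuple[str, ...] = ()
    smooth: SmoothTerm | None = None
    intercept: bool = True


@dataclass(frozen=True)
class ModelSpec:
    family: str
    params: tuple[ParamSpec, ...]
    c: float = 0.05
    max_inner: int = 50
    max_outer: int = 100
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    criterion: str = "BIC"
    gaic_k: float = 2.0
    max_step_halvings: int = 5

    def __post_init__(self):
        fam = get_family(self.family)
        if len(self.params) != fam.n_params:
            raise ValueError(
                f"family {self.family} has {fam.n_params} parameters; "
                f"spec lists {len(self.params)}"
            )
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        for pn, ps in zip(fam.param_names, self.params):
            if ps.smooth is None and not ps.intercept and not ps.fixed:
                raise ValueError(f"parameter {pn} has no design columns")

    @property
    def family_obj(self) -> Family:
        return get_family(self.family)

    def smooth_covariates(self) -> list[str]:
        return sorted({ps.smooth.covariate for ps in self.params if ps.smooth is not None})

    def covariates(self) -> list[str]:
        names: set[str] = set(self.smooth_covariates())
        for ps in self.params:
            names.update(ps.fixed)
        return sorted(names)


@dataclass(frozen=True)
class ResolvedParam:
    """A parameter design with its basis, penalty, and column layout frozen."""

    name: str
    colnames: tuple[str, ...]
    basis: SplineBasis | None
    smooth_cov: str | None
    smooth_start: int  # first smooth column (0 when a smooth exists)
    penalty_full: np.ndarray | None = field(repr=False, default=None)
    mode: str | None = None
    lam0: float | None = None
    target_edf: float | None = None

    @property
    def n_cols(self) -> int:
        return len(self.colnames)

    @property
    def smooth_slice(self) -> slice | None:
        if self.basis is None:
            return None
        return slice(self.smooth_start, self.smooth_start + self.basis.n_cols)


@dataclass(frozen=True)
class ResolvedModel:
    """ModelSpec bound to global covariate ranges and categorical levels."""

    spec: ModelSpec
    params: tuple[ResolvedParam, ...]
    levels: dict[str, tuple]

    @property
    def family(self) -> Family:
        return self.spec.family_obj


def collect_levels(frames: list[pd.DataFrame], covariates: list[str]) -> dict[str, tuple]:
    """Global categorical level dictionary (union over sites, sorted).

    A covariate is categorical when its dtype is object/category/bool in any
    frame.  Exchanging levels costs one entry in the setup round and is what
    guarantees identical treatment-contrast columns at every site.
    """
    levels: dict[str, set] = {}
    for df in frames:
        for cov in covariates:
            if cov not in df.columns:
                raise KeyError(f"covariate {cov!r} missing from site data")
            col = df[cov]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
                levels.setdefault(cov, set()).update(col.astype(str).unique())
    return {cov: tuple(sorted(vals)) for cov, vals in levels.items()}


def resolve_model(
    spec: ModelSpec,
    ranges: dict[str, tuple[float, float]],
    levels: dict[str, tuple],
) -> ResolvedModel:
    """Freeze the design layout given global covariate ranges and levels."""
    fam = spec.family_obj
    resolved = []
    for pname, ps in zip(fam.param_names, spec.params):
        colnames: list[str] = []
        basis = None
        smooth_cov = None
        penalty_full = None
        mode = lam0 = target = None
        if ps.smooth is not None:
            st = ps.smooth
            if st.covariate in levels:
                raise ValueError(f"smooth covariate {st.covariate!r} is categorical")
            lo, hi = ranges[st.covariate]
            basis = build_basis(lo, hi, st.n_knots, st.degree)
            smooth_cov = st.covariate
            colnames += [f"bs({st.covariate}).{j + 1}" for j in range(basis.n_cols)]
            mode, lam0, target = st.mode, st.lam, st.target_edf
        elif ps.intercept:
            colnames.append("(Intercept)")
        for cov in ps.fixed:
            if cov in levels:
                colnames += [f"{cov}[{lv}]" for lv in levels[cov][1:]]
            else:
                colnames.append(cov)
        if ps.smooth is not None:
            # divided differences at Greville sites: null space = affine
            # functions of the covariate even with clamped boundary knots
            P = greville_penalty(basis, ps.smooth.order)
            penalty_full = embed_penalty(P, len(colnames), 0)
        resolved.append(
            ResolvedParam(
                name=pname,
                colnames=tuple(colnames),
                basis=basis,
                smooth_cov=smooth_cov,
                smooth_start=0,
                penalty_full=penalty_full,
                mode=mode,
                lam0=lam0,
                target_edf=target,
            )
        )
    return ResolvedModel(spec=spec, params=tuple(resolved), levels=dict(levels))


def build_design(df: pd.DataFrame, rp: ResolvedParam, levels: dict[str, tuple]) -> np.ndarray:
    """Design matrix for one parameter; identical column layout everywhere."""
    n = len(df)
    blocks: list[np.ndarray] = []
    ps_fixed_start = 0
    if rp.basis is not None:
        blocks.append(rp.basis.evaluate(df[rp.smooth_cov].to_numpy(dtype=float)))
        ps_fixed_start = rp.basis.n_cols
    elif rp.colnames and rp.colnames[0] == "(Intercept)":
        blocks.append(np.ones((n, 1)))
        ps_fixed_start = 1
    for cn in rp.colnames[ps_fixed_start:]:
        if "[" in cn and cn.endswith("]"):
            cov, lv = cn[:-1].split("[", 1)
            vals = df[cov].astype(str)
            unseen = set(vals.unique()) - set(levels[cov])
            if unseen:
                raise ValueError(
                    f"covariate {cov!r} has level(s) {sorted(unseen)} absent from "
                    f"the agreed level dictionary {list(levels[cov])}"
                )
            blocks.append((vals == lv).to_numpy(dtype=float)[:, None])
        elif cn.startswith("bs("):
            continue  # already emitted with the basis block
        else:
            blocks.append(df[cn].to_numpy(dtype=float)[:, None])
    X = np.hstack(blocks) if blocks else np.empty((n, 0))
    if X.shape[1] != rp.n_cols:
        raise RuntimeError("design width mismatch against resolved layout")
    return X


def with_lambda(rp: ResolvedParam, lam: float) -> ResolvedParam:
    return replace(rp, lam0=lam)
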