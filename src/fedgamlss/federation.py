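"""The distributed GAMLSS protocol: sites, messages, and the aggregator.

Raw rows live only inside :class:`SiteData`.  Everything that crosses the
site/aggregator boundary is one of the message dataclasses below, and those
carry nothing but q_k x q_k cross-products, q_k vectors, scalar deviances,
covariate ranges, categorical level lists and counts — the privacy boundary
of the algorithm.  One update round per inner-cycle Newton iteration is
enough because the pooled weighted-least-squares solve factors exactly into
per-site sums:

    X'WX = sum_i X_i'W_i X_i = sum_i M1_i,
    X'Wz = sum_i X_i'W_i z_i = sum_i M2_i.

Protocol rounds (all synchronous; a missing site aborts the fit):

1. setup: sites report covariate ranges, categorical levels, and aggregate
   outcome moments; the aggregator broadcasts the frozen model (spline basis,
   level dictionary) back.  One round, matching the one basis-establishment
   round of the algorithm.
2. update rounds: one per inner-cycle iteration; each reply carries M1, M2
   and the site deviance at the broadcast coefficients (so global deviance
   runs one round behind, which is also what the step-halving control uses).
3. penalty-grid rounds (automated mode only): candidate coefficient sets for
   the whole lambda grid are broadcast and sites return one deviance per
   candidate.
4. inference round: handled in :mod:`fedgamlss.inference` (site Hessians and
   final deviances).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import Family, Moments, score_and_weights
from .model import ModelSpec, ResolvedModel, ResolvedParam, build_design, resolve_model
from .rs import DataInterface, FitState, run_rs, solve_penalized

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# messages


def _mat_to_payload(M: np.ndarray) -> dict:
    M = np.asarray(M, dtype=float)
    return {"shape": list(M.shape), "data": M.ravel(order="C").tolist()}


def _mat_from_payload(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


@dataclass(frozen=True)
class SetupReply:
    """Site -> aggregator, round 0: ranges/levels/moments, never rows."""

    site_id: str
    n_i: int
    ranges: dict[str, tuple[float, float]]
    levels: dict[str, tuple[str, ...]]
    moments: Moments

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "n_i": self.n_i,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "levels": {k: list(v) for k, v in self.levels.items()},
            "moments": self.moments.__dict__,
        }


@dataclass(frozen=True)
class UpdateRequest:
    """Aggregator -> sites: current coefficients for every parameter."""

    round: int
    k: int
    coefficients: tuple[tuple[float, ...], ...]

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "purpose": "update",
            "k": self.k,
            "coefficients": [list(c) for c in self.coefficients],
        }


@dataclass(frozen=True)
class UpdateMessage:
    """Site -> aggregator: the M1/M2 cross-products plus the site deviance
    evaluated at the *received* coefficients."""

    site_id: str
    k: int
    M1: np.ndarray = field(repr=False)
    M2: np.ndarray = field(repr=False)
    n_i: int
    deviance: float

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "k": self.k,
            "M1": _mat_to_payload(self.M1),
            "M2": _mat_to_payload(self.M2),
            "n_i": self.n_i,
            "deviance": self.deviance,
        }

    @staticmethod
    def from_dict(d: dict) -> "UpdateMessage":
        return UpdateMessage(
            site_id=d["site_id"],
            k=d["k"],
            M1=_mat_from_payload(d["M1"]),
            M2=_mat_from_payload(d["M2"]),
            n_i=d["n_i"],
            deviance=d["deviance"],
        )


@dataclass(frozen=True)
class DevianceRequest:
    """Aggregator -> sites: candidate coefficient sets to score."""

    round: int
    candidates: tuple  # tuple of coefficient tuples

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "purpose": "penalty_grid",
            "candidates": [[list(c) for c in cs] for cs in self.candidates],
        }


@dataclass(frozen=True)
class DevianceMessage:
    site_id: str
    deviances: tuple[float, ...]

    def to_dict(self) -> dict:
        return {"site_id": self.site_id, "deviances": list(self.deviances)}


@dataclass
class RoundLog:
    """Ordered communication-round ledger: (round, purpose, bytes/site)."""

    entries: list[tuple[int, str, dict[str, int]]] = field(default_factory=list)

    def log(self, purpose: str, site_bytes: dict[str, int]) -> int:
        rnd = len(self.entries) + 1
        self.entries.append((rnd, purpose, site_bytes))
        return rnd

    @property
    def n_rounds(self) -> int:
        return len(self.entries)

    def count(self, purpose: str) -> int:
        return sum(1 for _, p, _ in self.entries if p == purpose)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"round": r, "purpose": p, "total_bytes": sum(b.values())}
                for r, p, b in self.entries
            ]
        )


# ---------------------------------------------------------------------------
# the site


class SiteData:
    """One site's raw data plus locally cached designs.

    Only the ``reply_*`` methods are part of the protocol; everything they
    return is a message object holding aggregates.
    """

    def __init__(self, site_id: str, y, covariates: pd.DataFrame, family: Family | None = None):
        self.site_id = str(site_id)
        self.y = np.asarray(y, dtype=float)
        self.covariates = covariates.reset_index(drop=True)
        if len(self.covariates) != self.y.size:
            raise ValueError(f"site {site_id}: outcome/covariate length mismatch")
        self._family: Family | None = family
        self._model: ResolvedModel | None = None
        self._X: list[np.ndarray] | None = None

    @property
    def n_i(self) -> int:
        return int(self.y.size)

    # -- round 0 ------------------------------------------------------------
    def reply_setup(self, covariate_names: list[str]) -> SetupReply:
        from .model import collect_levels

        for cov in covariate_names:
            if cov not in self.covariates.columns:
                raise KeyError(
                    f"site {self.site_id}: covariate {cov!r} missing from site data"
                )
        levels = collect_levels([self.covariates], covariate_names)
        ranges = {
            cov: (float(self.covariates[cov].min()), float(self.covariates[cov].max()))
            for cov in covariate_names
            if cov not in levels
        }
        return SetupReply(
            site_id=self.site_id,
            n_i=self.n_i,
            ranges=ranges,
            levels={k: tuple(v) for k, v in levels.items()},
            moments=Moments.from_outcome(self.y),
        )

    # -- model broadcast ----------------------------------------------------
    def receive_model(self, model: ResolvedModel) -> None:
        self._model = model
        self._family = model.family
        self._family.check_support(self.y)
        self._X = [build_design(self.covariates, rp, model.levels) for rp in model.params]

    def _theta(self, coefs):
        return [
            self._family.links[j].g_inverse(self._X[j] @ np.asarray(coefs[j], dtype=float))
            for j in range(self._family.n_params)
        ]

    def _site_deviance(self, coefs) -> float:
        return -2.0 * float(np.sum(self._family.loglik(self.y, self._theta(coefs))))

    # -- update round -------------------------------------------------------
    def reply_update(self, req: UpdateRequest) -> UpdateMessage:
        if self._X is None:
            raise RuntimeError(f"site {self.site_id}: model not yet broadcast")
        coefs = [np.asarray(c, dtype=float) for c in req.coefficients]
        theta = self._theta(coefs)
        dev = -2.0 * float(np.sum(self._family.loglik(self.y, theta)))
        sw = score_and_weights(self._family, req.k, self.y, theta)
        Xk = self._X[req.k]
        eta_k = Xk @ coefs[req.k]
        M1 = Xk.T @ (Xk * sw.w[:, None])
        M2 = Xk.T @ (sw.w * eta_k + sw.u)
        return UpdateMessage(
            site_id=self.site_id, k=req.k, M1=M1, M2=M2, n_i=self.n_i, deviance=dev
        )

    # -- penalty-grid / evaluation round -------------------------------------
    def reply_deviances(self, req: DevianceRequest) -> DevianceMessage:
        devs = tuple(self._site_deviance(cs) for cs in req.candidates)
        return DevianceMessage(site_id=self.site_id, deviances=devs)


# ---------------------------------------------------------------------------
# standalone protocol operations


def basis_setup_round(
    sites: list[SiteData], spec: ModelSpec
) -> tuple[ResolvedModel, dict[str, tuple[float, float]], Moments, RoundLog]:
    """Round 0: collect ranges/levels/moments, freeze and broadcast the model.

    The global range of each smooth covariate is the union (min of mins, max
    of maxes) of the site ranges; disjoint site ranges leave interior gaps
    where the spline basis is unsupported, which is logged as a warning.
    """
    if not sites:
        raise ValueError("no sites")
    covs = spec.covariates()
    replies = [s.reply_setup(covs) for s in sites]
    log = RoundLog()
    log.log("basis_setup", {r.site_id: len(json.dumps(r.to_dict())) for r in replies})

    levels: dict[str, set] = {}
    for r in replies:
        for cov, lv in r.levels.items():
            levels.setdefault(cov, set()).update(lv)
    level_dict = {cov: tuple(sorted(v)) for cov, v in levels.items()}

    ranges: dict[str, tuple[float, float]] = {}
    for cov in spec.smooth_covariates():
        site_ranges = [r.ranges[cov] for r in replies if cov in r.ranges]
        if not site_ranges:
            raise KeyError(f"smooth covariate {cov!r} not numeric at any site")
        lo = min(lo for lo, _ in site_ranges)
        hi = max(hi for _, hi in site_ranges)
        covered = sorted(site_ranges)
        reach = covered[0][1]
        for s_lo, s_hi in covered[1:]:
            if s_lo > reach:
                logger.warning(
                    "site ranges for %r leave the gap (%g, %g) with no data; "
                    "spline fit is unsupported there",
                    cov,
                    reach,
                    s_lo,
                )
            reach = max(reach, s_hi)
        ranges[cov] = (lo, hi)

    moments = replies[0].moments
    for r in replies[1:]:
        moments = moments + r.moments

    model = resolve_model(spec, ranges, level_dict)
    for s in sites:
        s.receive_model(model)
    return model, ranges, moments, log


def site_update(site: SiteData, k: int, coefficients: list[np.ndarray]) -> UpdateMessage:
    """One site's contribution to the Newton update for parameter k."""
    req = UpdateRequest(
        round=-1, k=k, coefficients=tuple(tuple(map(float, c)) for c in coefficients)
    )
    return site.reply_update(req)


def aggregate_and_update(
    messages: list[UpdateMessage], rp: ResolvedParam, lam: float = 0.0
) -> np.ndarray:
    """Sum the site cross-products and solve the pooled WLS system exactly."""
    if not messages:
        raise ValueError("no site messages to aggregate")
    q = messages[0].M1.shape[0]
    for m in messages:
        if m.M1.shape != (q, q) or m.M2.shape != (q,):
            raise ValueError(f"site {m.site_id}: message dimensions disagree with design")
    M1 = np.sum([m.M1 for m in messages], axis=0)
    M2 = np.sum([m.M2 for m in messages], axis=0)
    return solve_penalized(M1, M2, rp, lam)


# ---------------------------------------------------------------------------
# the aggregator-side data interface


class FederatedData(DataInterface):
    """Aggregator view of the site collection; feeds the shared RS driver by
    exchanging messages only, and logs every communication round."""

    def __init__(self, sites: list[SiteData], model: ResolvedModel, moments: Moments, log: RoundLog):
        self.sites = sites
        self.model = model
        self._moments = moments
        self.log = log
        self.n_total = int(sum(s.n_i for s in sites))

    def moments(self) -> Moments:
        return self._moments

    def update(self, k, coefs):
        req = UpdateRequest(
            round=self.log.n_rounds + 1,
            k=k,
            coefficients=tuple(tuple(map(float, c)) for c in coefs),
        )
        replies = [s.reply_update(req) for s in self.sites]
        self.log.log("update", {r.site_id: len(json.dumps(r.to_dict())) for r in replies})
        M1 = np.sum([r.M1 for r in replies], axis=0)
        M2 = np.sum([r.M2 for r in replies], axis=0)
        dev = float(sum(r.deviance for r in replies))
        return M1, M2, dev

    def deviance_at(self, coef_sets):
        req = DevianceRequest(
            round=self.log.n_rounds + 1,
            candidates=tuple(
                tuple(tuple(map(float, c)) for c in cs) for cs in coef_sets
            ),
        )
        replies = [s.reply_deviances(req) for s in self.sites]
        self.log.log(
            "penalty_grid", {r.site_id: len(json.dumps(r.to_dict())) for r in replies}
        )
        return [float(sum(r.deviances[i] for r in replies)) for i in range(len(coef_sets))]


def fit_distributed(
    sites: list[SiteData], spec: ModelSpec, keep_history: bool = False
) -> tuple[FitState, RoundLog, ResolvedModel]:
    """Run the full distributed protocol (setup round + RS update rounds).

    On the same data and spline basis the result matches :func:`fit_pooled`
    to numerical precision for any partition of the rows into sites.
    """
    model, _, moments, log = basis_setup_round(sites, spec)
    fed = FederatedData(sites, model, moments, log)
    state = run_rs(fed, model, keep_history=keep_history)
    return state, log, model
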