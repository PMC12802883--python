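"""Monotone link functions mapping distribution parameters to linear predictors.

Each GAMLSS distribution parameter theta_k is modelled on a transformed scale
eta_k = g(theta_k); the link guarantees the additive predictor can range over
the whole real line while theta stays in its domain.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

# clip bounds keep logit/log inverses strictly inside their open domains
_EXP_MAX = 700.0
_UNIT_EPS = 1e-12


@dataclass(frozen=True)
class LinkSpec:
    """A monotone link g: theta -> eta with inverse and d(theta)/d(eta)."""

    name: str
    g: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    g_inverse: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    dtheta_deta: Callable[[np.ndarray], np.ndarray] = field(repr=False)


def _logit(theta):
    theta = np.clip(theta, _UNIT_EPS, 1.0 - _UNIT_EPS)
    return np.log(theta / (1.0 - theta))


def _expit(eta):
    out = 1.0 / (1.0 + np.exp(-np.clip(eta, -_EXP_MAX, _EXP_MAX)))
    return np.clip(out, _UNIT_EPS, 1.0 - _UNIT_EPS)


IDENTITY = LinkSpec(
    name="identity",
    g=lambda theta: np.asarray(theta, dtype=float),
    g_inverse=lambda eta: np.asarray(eta, dtype=float),
    dtheta_deta=lambda eta: np.ones_like(np.asarray(eta, dtype=float)),
)

LOG = LinkSpec(
    name="log",
    g=lambda theta: np.log(theta),
    g_inverse=lambda eta: np.exp(np.clip(eta, -_EXP_MAX, _EXP_MAX)),
    dtheta_deta=lambda eta: np.exp(np.clip(eta, -_EXP_MAX, _EXP_MAX)),
)

LOGIT = LinkSpec(
    name="logit",
    g=_logit,
    g_inverse=_expit,
    dtheta_deta=lambda eta: _expit(eta) * (1.0 - _expit(eta)),
)

LINKS = {"identity": IDENTITY, "log": LOG, "logit": LOGIT}


def get_link(name: str) -> LinkSpec:
    try:
        return LINKS[name]
    except KeyError:
        raise KeyError(f"unknown link {name!r}; available: {sorted(LINKS)}") from None
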