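"""The distributed protocol: message-sum exactness, partition invariance,
round accounting, the privacy boundary, and the penalty-selection round."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedgamlss.federation import (
    DevianceRequest,
    SiteData,
    UpdateMessage,
    UpdateRequest,
    aggregate_and_update,
    basis_setup_round,
    fit_distributed,
    site_update,
)
from fedgamlss.model import ModelSpec, ParamSpec, ResolvedParam, SmoothTerm
from fedgamlss.pooled import fit_pooled, prepare_pooled
from fedgamlss.rs import coef_converged, run_rs

from conftest import random_partition


def _gaussian_sites(rng, n=240, m=3, smooth=False):
    x = rng.uniform(0.0, 10.0, n)
    y = 1.0 + np.sin(x) + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"x": x})
    labels = random_partition(rng, n, m)
    sites = [
        SiteData(f"s{g}", y[labels == g], df[labels == g]) for g in range(m)
    ]
    ps = ParamSpec(smooth=SmoothTerm("x", 5)) if smooth else ParamSpec(fixed=("x",))
    spec = ModelSpec(family="NO", params=(ps, ParamSpec()), c=1e-8, max_outer=200)
    return y, df, sites, spec


# ---------------------------------------------------------------------------
# setup round


def test_basis_setup_takes_union_of_site_ranges():
    df1 = pd.DataFrame({"age": np.linspace(0, 50, 30)})
    df2 = pd.DataFrame({"age": np.linspace(30, 100, 30)})
    sites = [SiteData("a", np.zeros(30), df1), SiteData("b", np.ones(30), df2)]
    spec = ModelSpec(
        family="NO", params=(ParamSpec(smooth=SmoothTerm("age", 4)), ParamSpec())
    )
    model, ranges, moments, log = basis_setup_round(sites, spec)
    assert ranges["age"] == (0.0, 100.0)
    assert moments.n == 60
    assert log.count("basis_setup") == 1
    # single site: its own range
    model1, ranges1, _, _ = basis_setup_round([SiteData("a", np.zeros(30), df1)], spec)
    assert ranges1["age"] == (0.0, 50.0)


def test_disjoint_site_ranges_warn_but_span_union(caplog):
    df1 = pd.DataFrame({"age": np.linspace(0, 10, 20)})
    df2 = pd.DataFrame({"age": np.linspace(90, 100, 20)})
    sites = [SiteData("a", np.zeros(20), df1), SiteData("b", np.ones(20), df2)]
    spec = ModelSpec(
        family="NO", params=(ParamSpec(smooth=SmoothTerm("age", 4)), ParamSpec())
    )
    with caplog.at_level("WARNING", logger="fedgamlss.federation"):
        _, ranges, _, _ = basis_setup_round(sites, spec)
    assert ranges["age"] == (0.0, 100.0)
    assert any("gap" in r.message for r in caplog.records)


def test_setup_errors_name_missing_covariate_and_site():
    sites = [SiteData("siteX", np.zeros(5), pd.DataFrame({"other": range(5)}))]
    spec = ModelSpec(
        family="NO", params=(ParamSpec(smooth=SmoothTerm("age", 4)), ParamSpec())
    )
    with pytest.raises(KeyError, match="siteX.*'age'"):
        basis_setup_round(sites, spec)


# ---------------------------------------------------------------------------
# update messages


def test_site_update_scalar_example():
    """n_i=1, X=[1], w=3, z=2 must give M1=[3], M2=[6]."""
    site = SiteData("s", np.array([2.0]), pd.DataFrame(index=[0]))
    spec = ModelSpec(family="NO", params=(ParamSpec(), ParamSpec()))
    basis_setup_round([site], spec)
    # mu=0, sigma exp(eta)... choose coefficients so w = 1/sigma^2 = 3, z = y = 2
    sigma = 1.0 / np.sqrt(3.0)
    msg = site_update(site, 0, [np.array([0.0]), np.array([np.log(sigma)])])
    assert np.allclose(msg.M1, [[3.0]])
    assert np.allclose(msg.M2, [6.0])
    assert msg.n_i == 1


def test_update_message_sums_reproduce_pooled_crossproducts(rng):
    """The central exactness identity: M1/M2 summed over an arbitrary row
    partition equal the unpartitioned X'WX and X'Wz."""
    y, df, sites, spec = _gaussian_sites(rng, n=300, m=3)
    data, model = prepare_pooled(y, df, spec)
    for s in sites:
        s.receive_model(model)
    coefs = [np.array([0.5, 0.1]), np.array([0.2])]
    M1p, M2p, devp = data.update(0, coefs)
    msgs = [site_update(s, 0, coefs) for s in sites]
    assert np.allclose(np.sum([m.M1 for m in msgs], axis=0), M1p, atol=1e-10)
    assert np.allclose(np.sum([m.M2 for m in msgs], axis=0), M2p, atol=1e-10)
    assert np.isclose(sum(m.deviance for m in msgs), devp, atol=1e-8)


def test_aggregate_single_site_equals_pooled_wls(rng):
    y, df, sites, spec = _gaussian_sites(rng, n=120, m=1)
    data, model = prepare_pooled(y, df, spec)
    sites[0].receive_model(model)
    coefs = [np.array([0.0, 0.0]), np.array([0.0])]
    msg = site_update(sites[0], 0, coefs)
    b = aggregate_and_update([msg], model.params[0])
    M1, M2, _ = data.update(0, coefs)
    assert np.allclose(b, np.linalg.solve(M1, M2), atol=1e-10)


def test_zero_weight_dummy_site_leaves_solution_unchanged(rng):
    y, df, sites, spec = _gaussian_sites(rng, n=120, m=2)
    _, model = prepare_pooled(y, df, spec)
    for s in sites:
        s.receive_model(model)
    coefs = [np.array([0.3, 0.05]), np.array([0.1])]
    msgs = [site_update(s, 0, coefs) for s in sites]
    q = msgs[0].M1.shape[0]
    dummy = UpdateMessage("dummy", 0, np.zeros((q, q)), np.zeros(q), 0, 0.0)
    b1 = aggregate_and_update(msgs, model.params[0])
    b2 = aggregate_and_update(msgs + [dummy], model.params[0])
    assert np.allclose(b1, b2, atol=0)


def test_aggregate_rejects_dimension_mismatch():
    good = UpdateMessage("a", 0, np.eye(2), np.ones(2), 5, 0.0)
    bad = UpdateMessage("b", 0, np.eye(3), np.ones(3), 5, 0.0)
    rp = ResolvedParam(name="mu", colnames=("a", "b"), basis=None, smooth_cov=None, smooth_start=0)
    with pytest.raises(ValueError, match="site b"):
        aggregate_and_update([good, bad], rp)


# ---------------------------------------------------------------------------
# full fits


def test_convergence_rule_examples():
    assert coef_converged(np.array([1.00]), np.array([1.04]), 0.05)
    assert not coef_converged(np.array([1.00]), np.array([1.06]), 0.05)


def test_gaussian_intercept_converges_to_global_mean_in_one_update(rng):
    n = 200
    y = rng.normal(4.0, 1.0, n)
    labels = random_partition(rng, n, 4)
    sites = [SiteData(f"s{g}", y[labels == g], pd.DataFrame(index=range(int((labels == g).sum())))) for g in range(4)]
    spec = ModelSpec(family="NO", params=(ParamSpec(), ParamSpec()), c=1e-8, max_outer=100)
    state, log, model = fit_distributed(sites, spec)
    assert state.converged
    assert state.coefficients[0][0] == pytest.approx(y.mean(), abs=1e-10)


@settings(max_examples=8, deadline=None)
@given(st.integers(1, 8), st.integers(0, 10_000))
def test_partition_invariance_property(m, seed):
    """For ANY partition into 1..m sites the distributed iterate trajectory
    equals the pooled one — the exactness claim as a property test."""
    rng = np.random.default_rng(seed)
    y, df, sites, spec = _gaussian_sites(rng, n=160, m=m, smooth=True)
    pooled_state, model = fit_pooled(y, df, spec, keep_history=True)
    dist_state, _, _ = fit_distributed(sites, spec, keep_history=True)
    assert len(pooled_state.history) == len(dist_state.history)
    for hp, hd in zip(pooled_state.history, dist_state.history):
        assert (hp["outer"], hp["k"]) == (hd["outer"], hd["k"])
        assert np.max(np.abs(hp["coef"] - hd["coef"])) < 1e-10


def test_round_accounting_matches_iteration_counts(rng):
    y, df, sites, spec = _gaussian_sites(rng, n=240, m=3, smooth=True)
    state, log, _ = fit_distributed(sites, spec)
    assert log.count("basis_setup") == 1
    assert log.count("update") == sum(state.n_inner)
    assert log.count("penalty_grid") == 0
    entries = [e[0] for e in log.entries]
    assert entries == list(range(1, log.n_rounds + 1))


def test_automated_mode_adds_penalty_grid_rounds(rng):
    n = 400
    x = rng.uniform(0, 1, n)
    y = np.sin(6 * x) + rng.normal(0, 0.3, n)
    labels = random_partition(rng, n, 3)
    df = pd.DataFrame({"x": x})
    sites = [SiteData(f"s{g}", y[labels == g], df[labels == g]) for g in range(3)]
    spec = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 12, mode="auto")), ParamSpec()),
        c=1e-4,
        max_outer=60,
    )
    state, log, _ = fit_distributed(sites, spec)
    assert state.converged
    assert log.count("penalty_grid") >= 1
    assert log.count("update") == sum(state.n_inner)


def test_automated_penalty_smooths_hard_when_truth_is_linear(rng):
    """Straight-line truth with a rich basis: the criterion must drive the
    smooth's EDF to (near) its null-space dimension."""
    n = 600
    x = rng.uniform(0, 1, n)
    y = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"x": x})
    spec = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 12, mode="auto")), ParamSpec()),
        c=1e-4,
        max_outer=60,
    )
    state, model = fit_pooled(y, df, spec)
    assert state.edf[0] < 3.0  # smooth shrunk towards the 2-dim null space


def test_automated_penalty_keeps_wiggle_when_truth_is_wiggly(rng):
    n = 1500
    x = rng.uniform(0, 1, n)
    y = np.sin(8.0 * x) + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"x": x})
    spec = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 12, mode="auto")), ParamSpec()),
        c=1e-4,
        max_outer=60,
    )
    state, model = fit_pooled(y, df, spec)
    assert state.edf[0] > 5.0


def test_single_candidate_grid_equals_fixed_penalty(rng):
    n = 400
    x = rng.uniform(0, 1, n)
    y = np.sin(4 * x) + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"x": x})
    lam0 = 10.0
    auto = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 10, mode="auto")), ParamSpec()),
        lambda_grid=(lam0,),
        c=1e-6,
        max_outer=100,
    )
    fixed = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 10, mode="fixed_penalty", lam=lam0)), ParamSpec()),
        c=1e-6,
        max_outer=100,
    )
    sa, _ = fit_pooled(y, df, auto)
    sf, _ = fit_pooled(y, df, fixed)
    for a, b in zip(sa.coefficients, sf.coefficients):
        assert np.max(np.abs(a - b)) < 1e-8


# ---------------------------------------------------------------------------
# privacy boundary


def test_messages_carry_only_small_aggregates(rng):
    """Static privacy check: everything a site emits is O(q^2), never O(n_i)."""
    y, df, sites, spec = _gaussian_sites(rng, n=300, m=3, smooth=True)
    recorded = []
    orig_update = SiteData.reply_update
    orig_dev = SiteData.reply_deviances

    def spy_update(self, req):
        msg = orig_update(self, req)
        recorded.append(msg.to_dict())
        return msg

    def spy_dev(self, req):
        msg = orig_dev(self, req)
        recorded.append(msg.to_dict())
        return msg

    SiteData.reply_update = spy_update
    SiteData.reply_deviances = spy_dev
    try:
        state, _, model = fit_distributed(sites, spec)
    finally:
        SiteData.reply_update = orig_update
        SiteData.reply_deviances = orig_dev
    assert recorded
    q_max = max(rp.n_cols for rp in model.params)
    min_n = min(s.n_i for s in sites)

    def leaf_sizes(obj):
        if isinstance(obj, dict):
            for v in obj.values():
                yield from leaf_sizes(v)
        elif isinstance(obj, (list, tuple)):
            yield len(obj)
            for v in obj:
                if isinstance(v, (dict, list, tuple)):
                    yield from leaf_sizes(v)

    for msg in recorded:
        json.dumps(msg)  # must be serializable: no row arrays can hide inside
        for size in leaf_sizes(msg):
            assert size <= q_max * q_max
            assert size < min_n or size <= q_max * q_max


def test_update_message_json_round_trip():
    msg = UpdateMessage("s1", 1, np.arange(4.0).reshape(2, 2), np.array([1.0, 2.0]), 7, -3.5)
    back = UpdateMessage.from_dict(json.loads(json.dumps(msg.to_dict())))
    assert back.site_id == "s1" and back.n_i == 7
    assert np.array_equal(back.M1, msg.M1) and np.array_equal(back.M2, msg.M2)
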