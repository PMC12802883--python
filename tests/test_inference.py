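"""Distributed inference: Hessian additivity, Wald agreement with closed
forms and with the pooled fit, and likelihood-ratio testing of smooths."""

import numpy as np
import pandas as pd
import pytest

from fedgamlss.federation import SiteData, fit_distributed
from fedgamlss.inference import (
    aggregate_inference,
    distributed_inference,
    lrt_smooth,
    pooled_inference,
    reduced_spec_for_lrt,
    site_hessian,
    smooth_lrt_df,
)
from fedgamlss.model import ModelSpec, ParamSpec, SmoothTerm
from fedgamlss.pooled import fit_pooled, prepare_pooled

from conftest import random_partition


def test_gaussian_intercept_hessian_is_sample_size(rng):
    """With sigma fixed at 1 via a known-sigma trick, the mu information is
    n; here both are free, so the mu-mu block must equal n/sigma^2."""
    n = 80
    y = rng.normal(2.0, 1.0, n)
    spec = ModelSpec(family="NO", params=(ParamSpec(), ParamSpec()), c=1e-10, max_outer=300)
    state, model = fit_pooled(y, pd.DataFrame(index=range(n)), spec)
    site = SiteData("s", y, pd.DataFrame(index=range(n)))
    site.receive_model(model)
    msg = site_hessian(site, state.coefficients)
    sigma2 = np.exp(2 * state.coefficients[1][0])
    assert msg.H[0, 0] == pytest.approx(n / sigma2, rel=1e-5)


def test_hessians_add_over_partitions(rng, gaussian_smooth_fixture):
    f = gaussian_smooth_fixture
    y, df, model, state = f["y"], f["df"], f["model"], f["state"]
    whole = SiteData("all", y, df)
    whole.receive_model(model)
    H_all = site_hessian(whole, state.coefficients).H
    labels = random_partition(rng, len(y), 3)
    H_sum = np.zeros_like(H_all)
    for g in range(3):
        s = SiteData(f"s{g}", y[labels == g], df[labels == g])
        s.receive_model(model)
        H_sum += site_hessian(s, state.coefficients).H
    assert np.max(np.abs(H_sum - H_all)) <= 1e-6 * max(1.0, np.max(np.abs(H_all)))


def test_hessian_computes_at_non_optimum(gaussian_linear_fixture):
    f = gaussian_linear_fixture
    site = SiteData("s", f["y"], f["df"])
    site.receive_model(f["model"])
    perturbed = [c + 0.3 for c in f["state"].coefficients]
    msg = site_hessian(site, perturbed)
    assert np.all(np.isfinite(msg.H))


def test_wald_se_match_closed_form_gaussian(gaussian_linear_fixture):
    """SEs from the aggregated Hessian vs sigma^2 (X'X)^-1 exactly."""
    f = gaussian_linear_fixture
    res = pooled_inference(f["y"], f["df"], f["model"], f["state"])
    X = np.column_stack([np.ones(len(f["y"])), f["df"]["x"]])
    sigma2 = np.exp(2 * f["state"].coefficients[1][0])
    ref = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    got = res.table.query("parameter=='mu'")["se"].to_numpy()
    assert np.allclose(got, ref, rtol=1e-4)


def test_distributed_and_pooled_inference_agree(rng):
    n = 400
    x = rng.uniform(0, 10, n)
    y = 1.0 + np.sin(x) + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"x": x})
    spec = ModelSpec(
        family="NO", params=(ParamSpec(smooth=SmoothTerm("x", 5)), ParamSpec()), c=1e-8, max_outer=200
    )
    ps, model = fit_pooled(y, df, spec)
    res_pooled = pooled_inference(y, df, model, ps)
    labels = random_partition(rng, n, 4)
    sites = [SiteData(f"s{g}", y[labels == g], df[labels == g]) for g in range(4)]
    ds, log, _ = fit_distributed(sites, spec)
    res_dist = distributed_inference(sites, ds, log)
    assert log.count("inference") == 1
    se_p = res_pooled.table["se"].to_numpy()
    se_d = res_dist.table["se"].to_numpy()
    assert np.max(np.abs(se_d - se_p) / se_p) <= 1e-4
    assert res_dist.global_deviance == pytest.approx(res_pooled.global_deviance, abs=1e-6)


def test_single_site_covariance_is_inverse_hessian(gaussian_linear_fixture):
    f = gaussian_linear_fixture
    site = SiteData("s", f["y"], f["df"])
    site.receive_model(f["model"])
    msg = site_hessian(site, f["state"].coefficients)
    res = aggregate_inference([msg], f["state"])
    assert np.allclose(res.covariance, np.linalg.inv(msg.H), rtol=1e-8)
    assert np.allclose(res.table["se"], np.sqrt(np.diag(np.linalg.inv(msg.H))))


def test_lrt_basic_values():
    stat, p = lrt_smooth(100.0, 100.0, df=3)
    assert stat == 0.0 and p == 1.0
    stat, p = lrt_smooth(96.16, 100.0, df=1)
    assert p == pytest.approx(0.05, abs=0.001)  # 3.84 is the chi2_1 critical value
    with pytest.raises(ValueError, match="nested"):
        lrt_smooth(100.0, 90.0, df=2)


def test_lrt_refused_for_automated_penalty_smooth(rng):
    n = 300
    x = rng.uniform(0, 1, n)
    y = np.sin(3 * x) + rng.normal(0, 0.4, n)
    spec = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 10, mode="auto")), ParamSpec()),
        c=1e-4,
        max_outer=60,
    )
    state, model = fit_pooled(y, pd.DataFrame({"x": x}), spec)
    with pytest.raises(ValueError, match="liberal"):
        smooth_lrt_df(model, state, 0)


def test_smooth_lrt_detects_a_real_effect(rng):
    n = 400
    x = rng.uniform(0, 1, n)
    y = np.sin(5 * x) + rng.normal(0, 0.4, n)
    df = pd.DataFrame({"x": x})
    full = ModelSpec(
        family="NO", params=(ParamSpec(smooth=SmoothTerm("x", 5)), ParamSpec()), c=1e-6, max_outer=200
    )
    red = reduced_spec_for_lrt(full, 0)
    sf, mf = fit_pooled(y, df, full)
    sr, _ = fit_pooled(y, df, red)
    df_null = smooth_lrt_df(mf, sf, 0)
    assert df_null == mf.params[0].basis.n_cols - 1
    stat, p = lrt_smooth(sf.global_deviance, sr.global_deviance, df_null)
    assert p < 1e-6


def test_pseudo_inverse_fallback_flags_unidentified_columns(gaussian_smooth_fixture):
    """A near-unsupported spline column gives a non-positive-definite Hessian
    sum; inference must warn, fall back to the pseudo-inverse, and flag the
    affected coefficient instead of reporting misleading standard errors."""
    f = gaussian_smooth_fixture
    site = SiteData("s", f["y"], f["df"])
    site.receive_model(f["model"])
    msg = site_hessian(site, f["state"].coefficients)
    msg.H[3, 3] = -abs(msg.H[3, 3])  # emulate an indefinite tail block
    with pytest.warns(UserWarning, match="positive definite"):
        res = aggregate_inference([msg], f["state"])
    assert res.flagged  # some coefficient got a NaN standard error
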