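"""Distribution-layer checks: densities normalize, scores match independent
finite differences of the log-likelihood, quantile/CDF round trips hold, and
documented reductions to simpler distributions are exact."""

import numpy as np
import pytest
from scipy import special, stats
from scipy.integrate import quad

from fedgamlss.families import (
    FAMILIES,
    Moments,
    SupportError,
    get_family,
    score_and_weights,
    validate_family,
)

# representative parameter values per family used across the tests
THETAS = {
    "NO": [0.5, 1.3],
    "BCPE": [22.0, 0.12, -0.6, 2.4],
    "BEZI": [0.25, 0.5, 0.08],
    "GG": [3.0, 0.25, 1.4],
}


def _theta_arrays(name, n=1):
    return [np.full(n, v) for v in THETAS[name]]


@pytest.mark.parametrize("name", sorted(FAMILIES))
def test_density_normalizes_to_one(name):
    fam = get_family(name)
    th = THETAS[name]
    mass = 0.0
    if name == "NO":
        lo, hi = th[0] - 15 * th[1], th[0] + 15 * th[1]
    elif name == "BEZI":
        mass = th[2]
        lo, hi = 1e-12, 1 - 1e-12
    else:
        med = float(fam.ppf(np.array([0.5]), _theta_arrays(name))[0])
        lo, hi = med * 1e-6, med * 60.0

    def dens(v):
        return float(np.exp(fam._logpdf(np.array([v]), _theta_arrays(name))[0]))

    total = mass + quad(dens, lo, hi, limit=300)[0]
    assert abs(total - 1.0) < 1e-6


@pytest.mark.parametrize("name", sorted(FAMILIES))
def test_scores_and_weights_match_loglik_derivatives(name, rng):
    """Analytic scores against central differences of the log-likelihood, and
    weights against an independent second-difference estimate (different
    formula and step than the implementation uses)."""
    fam = get_family(name)
    report = validate_family(fam, n_draws=100, seed=3)
    assert report["ok"], report
    # direct weight check on representative values
    y = fam.ppf(rng.uniform(0.05, 0.95, 50), _theta_arrays(name, 50))
    if name == "BEZI":
        y = np.where(y == 0, 0.01, y)
    theta = _theta_arrays(name, 50)
    for k in range(fam.n_params):
        sw = score_and_weights(fam, k, y, theta)
        link = fam.links[k]
        eta = link.g(theta[k])
        h = 1e-4 * np.maximum(1.0, np.abs(eta))

        def ll(e, k=k):
            th = list(theta)
            th[k] = link.g_inverse(e)
            return fam._logpdf(y, th)

        w_num = -(ll(eta + h) - 2.0 * ll(eta) + ll(eta - h)) / h**2
        # only where neither floor nor fallback nor Fisher-vs-observed applies
        if name == "NO" or (name == "BEZI" and k == 2) or name == "GG":
            ok = w_num > 1e-3
            assert np.allclose(sw.w[ok], w_num[ok], rtol=1e-4)
        assert np.all(sw.w > 0)
        assert np.all(np.isfinite(sw.u))


@pytest.mark.parametrize("name", sorted(FAMILIES))
def test_quantile_cdf_round_trip(name):
    fam = get_family(name)
    qs = np.array([0.025, 0.1, 0.5, 0.9, 0.975])
    th = _theta_arrays(name, qs.size)
    yq = fam.ppf(qs, th)
    back = fam.cdf(yq, th)
    if name == "BEZI":
        keep = qs > THETAS[name][2]
        assert np.allclose(back[keep], qs[keep], atol=1e-8)
        assert np.all(yq[qs <= THETAS[name][2]] == 0.0)
    else:
        assert np.allclose(back, qs, atol=1e-8)
    # monotone cdf and support limits
    grid = fam.ppf(np.linspace(0.01, 0.99, 25), _theta_arrays(name, 25))
    c = fam.cdf(np.sort(grid), _theta_arrays(name, 25))
    assert np.all(np.diff(c) >= -1e-12)


def test_normal_loglik_standard_value():
    fam = get_family("NO")
    ll = fam.loglik(np.array([0.0]), [np.array([0.0]), np.array([1.0])])
    assert np.isclose(ll[0], -0.5 * np.log(2 * np.pi))


def test_normal_score_example():
    fam = get_family("NO")
    sw = score_and_weights(fam, 0, np.array([2.0]), [np.array([1.0]), np.array([1.0])])
    assert np.isclose(sw.u[0], 1.0) and np.isclose(sw.w[0], 1.0)


def test_score_vanishes_at_interior_optimum():
    """mu at the observed value maximizes the Gaussian likelihood."""
    fam = get_family("NO")
    sw = score_and_weights(fam, 0, np.array([3.3]), [np.array([3.3]), np.array([0.7])])
    assert abs(sw.u[0]) < 1e-12


def test_zero_inflated_beta_point_mass():
    fam = get_family("BEZI")
    th = [np.array([0.4]), np.array([0.5]), np.array([0.3])]
    assert np.isclose(fam.loglik(np.array([0.0]), th)[0], np.log(0.3))
    assert np.isclose(fam.cdf(np.array([0.0]), th)[0], 0.3)
    assert fam.ppf(np.array([0.2]), th)[0] == 0.0


def test_normal_median_and_quantiles():
    fam = get_family("NO")
    th = [np.array([3.0]), np.array([2.0])]
    assert np.isclose(fam.ppf(np.array([0.5]), th)[0], 3.0)
    assert np.isclose(fam.ppf(np.array([0.975]), th)[0], 3.0 + 1.959964 * 2.0, atol=1e-5)


def test_bcpe_quantile_against_quadrature():
    """BCPE 97.5% point checked by adaptive quadrature of the density."""
    th = [np.array([20.0]), np.array([0.15]), np.array([0.5]), np.array([2.0])]
    fam = get_family("BCPE")
    x975 = float(fam.ppf(np.array([0.975]), th)[0])

    def dens(v):
        return float(np.exp(fam._logpdf(np.array([v]), th)[0]))

    below = quad(dens, 1e-6, x975, limit=300)[0]
    assert abs(below - 0.975) < 1e-6


def test_bcpe_reduces_to_box_cox_normal():
    """tau=2 collapses the power-exponential kernel to a Gaussian: the BCPE
    density must equal an independently coded Box-Cox normal density."""
    mu, sigma, nu = 20.0, 0.1, 0.7
    y = np.linspace(12.0, 30.0, 40)
    fam = get_family("BCPE")
    ours = fam._logpdf(y, [np.full(40, mu), np.full(40, sigma), np.full(40, nu), np.full(40, 2.0)])
    z = ((y / mu) ** nu - 1.0) / (nu * sigma)
    bcn = stats.norm.logpdf(z) + (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma)
    assert np.allclose(ours, bcn, atol=1e-8)


def test_gg_reduces_to_gamma():
    """nu=1 must match scipy's gamma distribution exactly."""
    mu, sigma = 3.0, 0.4
    th = 1.0 / sigma**2
    y = np.linspace(0.3, 12.0, 50)
    fam = get_family("GG")
    ours = fam._logpdf(y, [np.full(50, mu), np.full(50, sigma), np.full(50, 1.0)])
    ref = stats.gamma.logpdf(y, a=th, scale=mu / th)
    assert np.allclose(ours, ref, atol=1e-8)
    assert np.allclose(
        fam.cdf(y, [np.full(50, mu), np.full(50, sigma), np.full(50, 1.0)]),
        stats.gamma.cdf(y, a=th, scale=mu / th),
        atol=1e-8,
    )


def test_out_of_support_outcome_raises_with_index():
    fam = get_family("GG")
    with pytest.raises(SupportError, match=r"y\[2\].*positive"):
        fam.loglik(np.array([1.0, 2.0, -3.0]), [np.ones(3), np.ones(3), np.ones(3)])


def test_quantile_rejects_invalid_probability():
    fam = get_family("NO")
    th = [np.array([0.0]), np.array([1.0])]
    with pytest.raises((ValueError, FloatingPointError)):
        bad = fam.ppf(np.array([1.5]), th)
        if not np.all(np.isfinite(bad)):
            raise ValueError("quantile outside (0,1)")


def test_validate_family_flags_corrupted_derivative():
    """Negative control: a family with a broken score must be caught."""

    class Broken(type(get_family("NO"))):
        def _score(self, y, theta, k):
            u = super()._score(y, theta, k)
            return u * 1.5 if k == 0 else u

    report = validate_family(Broken(), n_draws=20, seed=0)
    assert not report["ok"]
    assert "mu" in report["failing_params"]


def test_moments_additive_and_initialization():
    rng = np.random.default_rng(0)
    y = rng.gamma(4.0, 1.0, 200)
    m_all = Moments.from_outcome(y)
    m_sum = Moments.from_outcome(y[:80]) + Moments.from_outcome(y[80:])
    assert m_all.n == m_sum.n and m_all.n_zero == m_sum.n_zero
    assert np.isclose(m_all.sum_y, m_sum.sum_y, rtol=1e-14)
    assert np.isclose(m_all.sum_y2, m_sum.sum_y2, rtol=1e-14)
    mu0, sigma0, nu0 = get_family("GG").initial_theta(m_all)
    assert np.isclose(mu0, y.mean()) and nu0 == 1.0
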