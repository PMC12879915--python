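"""Likelihood components and joint log-posteriors against independent oracles."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from cortrhythm import model_core as mc
from cortrhythm.preprocess import ModelData

_LOG_2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# censored lognormal
# ---------------------------------------------------------------------------

def test_lognormal_density_at_median():
    y, sigma = 3.7, 0.8
    got = mc.lognormal_censored_loglik(y, np.log(y), sigma)
    assert got == pytest.approx(-np.log(y) - np.log(sigma) - 0.5 * _LOG_2PI)


def test_lognormal_censored_at_median_is_half():
    assert mc.lognormal_censored_loglik(5.0, np.log(5.0), 1.3, censored_high=True) \
        == pytest.approx(np.log(0.5))


def test_lognormal_censored_matches_quadrature():
    rng = np.random.default_rng(8)
    for _ in range(200):
        mu = rng.uniform(-1, 2)
        sigma = rng.uniform(0.2, 1.5)
        y = float(np.exp(mu + sigma * rng.uniform(-2.5, 2.5)))
        tail, _ = integrate.quad(
            lambda x: stats.lognorm.pdf(x, s=sigma, scale=np.exp(mu)),
            y, np.inf, limit=200, epsabs=1e-12, epsrel=1e-12)
        got = np.exp(mc.lognormal_censored_loglik(y, mu, sigma, True))
        assert got == pytest.approx(tail, abs=1e-8)


def test_lognormal_domain_errors():
    with pytest.raises(ValueError):
        mc.lognormal_censored_loglik(-1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        mc.lognormal_censored_loglik(1.0, 0.0, -1.0)


# ---------------------------------------------------------------------------
# ordinal / bernoulli
# ---------------------------------------------------------------------------

def test_ordinal_binary_symmetric():
    for k in (1, 2):
        assert mc.ordinal_logit_loglik(k, 0.0, [0.0]) == pytest.approx(np.log(0.5))


def test_ordinal_probabilities_normalize():
    rng = np.random.default_rng(4)
    for _ in range(100):
        K = int(rng.integers(2, 8))
        cut = np.sort(rng.normal(0, 2, size=K - 1))
        if np.any(np.diff(cut) == 0):
            continue
        phi = rng.normal(0, 2)
        total = sum(np.exp(mc.ordinal_logit_loglik(k, phi, cut))
                    for k in range(1, K + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_ordinal_matches_logistic_difference_oracle():
    cut = np.array([-2.0, -1.0, 1.0, 2.0])
    phi = 0.7
    full = np.concatenate([[-np.inf], cut, [np.inf]])
    for k in range(1, 6):
        oracle = np.log(special.expit(full[k] - phi)
                        - special.expit(full[k - 1] - phi))
        assert mc.ordinal_logit_loglik(k, phi, cut) == \
            pytest.approx(oracle, abs=1e-12)


def test_ordinal_rejects_bad_inputs():
    with pytest.raises(ValueError):
        mc.ordinal_logit_loglik(1, 0.0, [1.0, 0.5])
    with pytest.raises(ValueError):
        mc.ordinal_logit_loglik(4, 0.0, [0.0, 1.0])


def test_bernoulli_logit():
    assert mc.bernoulli_logit_loglik(1, 0.0) == pytest.approx(np.log(0.5))
    assert mc.bernoulli_logit_loglik(1, 1.3) == \
        pytest.approx(np.log(special.expit(1.3)), abs=1e-12)
    # log P(0) -> -inf monotonically as eta grows
    lls = [mc.bernoulli_logit_loglik(0, e) for e in (0.0, 2.0, 10.0, 40.0)]
    assert all(a > b for a, b in zip(lls, lls[1:]))
    with pytest.raises(ValueError):
        mc.bernoulli_logit_loglik(2, 0.0)


# ---------------------------------------------------------------------------
# latent effects prior
# ---------------------------------------------------------------------------

def test_latent_prior_identity_reduces_to_univariate():
    rng = np.random.default_rng(1)
    eff = rng.normal(size=(7, 3))
    sds = np.array([0.5, 1.0, 2.0])
    got = mc.latent_effects_logprior(eff, sds, np.eye(3))
    expected = stats.norm.logpdf(eff, scale=sds).sum()
    assert got == pytest.approx(expected, abs=1e-10)


def test_latent_prior_matches_closed_form_bivariate():
    rho, sds = 0.5, np.array([0.7, 1.4])
    corr = np.array([[1, rho], [rho, 1.0]])
    rng = np.random.default_rng(2)
    eff = rng.normal(size=(5, 2))
    x, y = eff[:, 0] / sds[0], eff[:, 1] / sds[1]
    q = (x * x - 2 * rho * x * y + y * y) / (1 - rho ** 2)
    oracle = np.sum(-0.5 * q - np.log(2 * np.pi * sds[0] * sds[1]
                                      * np.sqrt(1 - rho ** 2)))
    assert mc.latent_effects_logprior(eff, sds, corr) == \
        pytest.approx(oracle, abs=1e-10)


def test_latent_prior_mode_at_zero_and_pd_check():
    sds = np.array([1.0, 1.0])
    corr = np.array([[1.0, 0.3], [0.3, 1.0]])
    at_zero = mc.latent_effects_logprior(np.zeros((4, 2)), sds, corr)
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert mc.latent_effects_logprior(rng.normal(size=(4, 2)), sds, corr) \
            < at_zero
    with pytest.raises(np.linalg.LinAlgError):
        mc.latent_effects_logprior(np.zeros((1, 2)), sds,
                                   np.array([[1.0, 1.2], [1.2, 1.0]]))


# ---------------------------------------------------------------------------
# structured log-posteriors
# ---------------------------------------------------------------------------

def _single_sample_data():
    return ModelData(
        y=np.array([2e5]), rel_time_h=np.array([0.0]),
        pid_index=np.array([0]), censored_high=np.array([False]),
        participant_ids=["A"], age_z=np.array([0.0]),
        woman=np.array([0]), community=np.array([0]),
        community_levels=["1"])


def _params0(n=1, **overrides):
    base = dict(mu0=12.0, beta_time=0.0, beta_age=0.0, beta_gender=0.0,
                beta_community=np.zeros(0), beta_time_age=0.0,
                beta_time_gender=0.0, beta_age_gender=0.0,
                beta_time_age_gender=0.0, sigma_resid=0.5,
                sd_pid_intercept=0.4, sd_pid_slope=0.05, rho_int_slope=0.0,
                pid_effects=np.zeros((n, 2)))
    base.update(overrides)
    return mc.Model0Params(**base)


def test_model0_single_sample_reduction():
    data = _single_sample_data()
    params = _params0()
    priors = mc.PriorSpec()
    got = mc.model0_logposterior(params, data, priors)
    expected = (
        mc.lognormal_censored_loglik(2e5, 12.0, 0.5)
        + stats.norm.logpdf(12.0, scale=100.0)
        + 7 * stats.norm.logpdf(0.0, scale=2.0)     # the 7 remaining betas
        + stats.expon.logpdf([0.5, 0.4, 0.05], scale=0.5).sum()
        + mc.latent_effects_logprior(np.zeros((1, 2)), [0.4, 0.05], np.eye(2)))
    assert got == pytest.approx(expected, abs=1e-9)


def test_model0_mu0_shift_hits_only_priors(small_model0_data):
    data = small_model0_data
    rng = np.random.default_rng(6)
    eff = rng.normal(0, 0.3, size=(data.n_participants, 2))
    params = _params0(n=data.n_participants,
                      beta_community=np.zeros(len(data.community_levels) - 1),
                      pid_effects=eff)
    c = 0.37
    shifted = _params0(n=data.n_participants, mu0=params.mu0 + c,
                       beta_community=np.zeros(len(data.community_levels) - 1),
                       pid_effects=eff - np.array([c, 0.0]))
    lp0 = mc.model0_logposterior(params, data)
    lp1 = mc.model0_logposterior(shifted, data)
    d_prior = (stats.norm.logpdf(shifted.mu0, scale=100)
               - stats.norm.logpdf(params.mu0, scale=100)
               + mc.latent_effects_logprior(shifted.pid_effects, [0.4, 0.05],
                                            np.eye(2))
               - mc.latent_effects_logprior(eff, [0.4, 0.05], np.eye(2)))
    assert lp1 - lp0 == pytest.approx(d_prior, abs=1e-8)


def _item_params(data, rng):
    items = {}
    for nm, info in data.items.items():
        K = info["n_categories"]
        items[nm] = mc.ItemSubmodelParams(
            variable=nm,
            beta_age=rng.normal(0, 0.3), beta_gender=rng.normal(0, 0.3),
            beta_community=rng.normal(0, 0.3, len(data.community_levels) - 1),
            sd_translator=0.4,
            translator_effects=rng.normal(0, 0.3, len(data.translator_levels)),
            sd_pid=1.1,
            cutpoints=(np.sort(rng.normal(0, 1.5, K - 1))
                       if info["kind"] == "ordinal" else None),
            intercept=(rng.normal() if info["kind"] == "binary" else 0.0))
    return items


def _item_contribution(it, info, data, eps, priors):
    """Independent per-item log-density using only public components."""
    from cortrhythm.model_core import item_design
    Xi, _ = item_design(data)
    fe = np.concatenate([[it.beta_age, it.beta_gender], it.beta_community])
    phi = Xi @ fe + it.translator_effects[data.translator_index] + eps
    lp = 0.0
    if info["kind"] == "binary":
        lp += np.sum(mc.bernoulli_logit_loglik(info["codes"], it.intercept + phi))
        lp += stats.norm.logpdf(it.intercept, scale=priors.beta_sd)
    else:
        lp += np.sum(mc.ordinal_logit_loglik(info["codes"], phi, it.cutpoints))
        lp += stats.norm.logpdf(it.cutpoints, scale=priors.cutpoint_sd).sum()
    lp += stats.norm.logpdf(fe, scale=priors.beta_sd).sum()
    lp += stats.norm.logpdf(it.translator_effects, scale=it.sd_translator).sum()
    lp += stats.expon.logpdf([it.sd_translator, it.sd_pid], scale=0.5).sum()
    lp += stats.norm.logpdf(eps, scale=it.sd_pid).sum()
    return float(lp)


def test_model1_identity_corr_separates(small_model1_data):
    data = small_model1_data
    rng = np.random.default_rng(9)
    n = data.n_participants
    d = len(data.items) + 2
    priors = mc.PriorSpec()
    items = _item_params(data, rng)
    latent = rng.normal(0, 0.5, size=(n, d))
    cort = _params0(n=n, beta_community=np.zeros(len(data.community_levels) - 1),
                    pid_effects=None)
    joint = mc.JointModelParams(cortisol=cort, items=items,
                                corr_matrix=np.eye(d), latent_effects=latent)
    got = mc.model1_logposterior(joint, data, priors)

    cort0 = _params0(n=n, beta_community=np.zeros(len(data.community_levels) - 1),
                     pid_effects=latent[:, [d - 1, d - 2]])
    expected = mc.model0_logposterior(cort0, data, priors)
    # remove the bivariate latent prior that model0 adds; the joint identity
    # prior treats (intercept, slope) as independent univariate normals
    expected -= mc.latent_effects_logprior(
        cort0.pid_effects, [cort0.sd_pid_intercept, cort0.sd_pid_slope],
        np.eye(2))
    expected += stats.norm.logpdf(latent[:, d - 1], scale=cort.sd_pid_intercept).sum()
    expected += stats.norm.logpdf(latent[:, d - 2], scale=cort.sd_pid_slope).sum()
    for m, (nm, it) in enumerate(items.items()):
        expected += _item_contribution(it, data.items[nm], data,
                                       latent[:, m], priors)
    assert got == pytest.approx(expected, rel=1e-10)


def test_model1_item_permutation_exchangeable(small_model1_data):
    data = small_model1_data
    rng = np.random.default_rng(10)
    n = data.n_participants
    names = list(data.items)
    d = len(names) + 2
    A = rng.normal(size=(d, d + 2))
    R = A @ A.T
    R = R / np.sqrt(np.outer(np.diag(R), np.diag(R)))
    items = _item_params(data, rng)
    latent = rng.normal(0, 0.5, size=(n, d))
    cort = _params0(n=n, beta_community=np.zeros(len(data.community_levels) - 1))
    lp = mc.model1_logposterior(
        mc.JointModelParams(cort, items, R, latent), data)

    perm = list(rng.permutation(len(names)))
    order = perm + [len(names), len(names) + 1]
    R_p = R[np.ix_(order, order)]
    items_p = {names[i]: items[names[i]] for i in perm}
    latent_p = latent[:, order]
    lp_p = mc.model1_logposterior(
        mc.JointModelParams(cort, items_p, R_p, latent_p), data)
    assert lp_p == pytest.approx(lp, rel=1e-12)


def test_model1_item_removal_decomposition(small_model1_data):
    data = small_model1_data
    rng = np.random.default_rng(12)
    n = data.n_participants
    names = list(data.items)
    d = len(names) + 2
    priors = mc.PriorSpec()
    items = _item_params(data, rng)
    latent = rng.normal(0, 0.5, size=(n, d))
    cort = _params0(n=n, beta_community=np.zeros(len(data.community_levels) - 1))
    full = mc.model1_logposterior(
        mc.JointModelParams(cort, items, np.eye(d), latent), data, priors)

    drop = names[1]
    sub_data = ModelData(
        y=data.y, rel_time_h=data.rel_time_h, pid_index=data.pid_index,
        censored_high=data.censored_high, participant_ids=data.participant_ids,
        age_z=data.age_z, woman=data.woman, community=data.community,
        community_levels=data.community_levels,
        translator_index=data.translator_index,
        translator_levels=data.translator_levels,
        items={k: v for k, v in data.items.items() if k != drop})
    keep = [i for i, nm in enumerate(names) if nm != drop] + [d - 2, d - 1]
    sub = mc.model1_logposterior(
        mc.JointModelParams(cort, {k: v for k, v in items.items() if k != drop},
                            np.eye(d - 1), latent[:, keep]),
        sub_data, priors)
    contribution = _item_contribution(items[drop], data.items[drop], data,
                                      latent[:, 1], priors)
    assert full - sub == pytest.approx(contribution, rel=1e-10)


def test_model1_dimension_mismatch_errors(small_model1_data):
    data = small_model1_data
    rng = np.random.default_rng(13)
    items = _item_params(data, rng)
    cort = _params0(n=data.n_participants,
                    beta_community=np.zeros(len(data.community_levels) - 1))
    with pytest.raises(ValueError):
        mc.model1_logposterior(
            mc.JointModelParams(cort, items, np.eye(3),
                                np.zeros((data.n_participants, 3))), data)


# ---------------------------------------------------------------------------
# unconstrained builders
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("stage", ["model0", "model1"])
def test_builder_gradients_match_finite_differences(
        stage, small_model0_data, small_model1_data):
    data = small_model0_data if stage == "model0" else small_model1_data
    model = (mc.build_model0 if stage == "model0" else mc.build_model1)(data)
    rng = np.random.default_rng(14)
    theta = 0.3 * rng.standard_normal(model.n_dim)
    lp, g = model.logp_and_grad(theta)
    assert np.isfinite(lp)
    idx = rng.choice(model.n_dim, size=40, replace=False)
    eps = 1e-6
    for i in idx:
        e = np.zeros(model.n_dim)
        e[i] = eps
        num = (model.logp_and_grad(theta + e)[0]
               - model.logp_and_grad(theta - e)[0]) / (2 * eps)
        assert g[i] == pytest.approx(num, rel=1e-5, abs=1e-4)


def test_prior_only_builder_is_finite_everywhere():
    rng = np.random.default_rng(15)
    data = _single_sample_data()
    model = mc.build_model0(data, likelihood=False)
    for _ in range(10):
        lp, g = model.logp_and_grad(2.0 * rng.standard_normal(model.n_dim))
        assert np.isfinite(lp) and np.all(np.isfinite(g))


def test_cpc_vine_reproduces_lkj_marginals():
    """Sampling CPCs from their shifted-Beta factorization must reproduce
    the known LKJ(eta) marginal, 2*Beta(a, a)-1 with a = eta - 1 + d/2."""
    d, eta = 4, 2.0
    rng = np.random.default_rng(16)
    n = 4000
    pairs, alpha = mc._cpc_levels(d)
    r12 = np.empty(n)
    for s in range(n):
        z = 2.0 * rng.beta(eta + alpha, eta + alpha) - 1.0
        R = mc.corr_from_cpc(np.arctanh(z), d)
        r12[s] = R[0, 1]
    a = eta - 1 + d / 2
    ks = stats.kstest(r12, lambda x: stats.beta.cdf((x + 1) / 2, a, a))
    assert ks.pvalue > 0.001
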