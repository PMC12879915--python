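"""Generative model for diurnal urinary cortisol and psychosocial stressors.

Two models are defined.

**Model 0 (cortisol only).** Cortisol is lognormal::

    CORT_ij ~ LogNormal(mu_ij, sigma)
    mu_ij = mu0 + b_t*time + b_a*age_z + b_g*woman + b_c*community
            + interactions + u_i + v_i*time

with individual random intercepts ``u_i`` and slopes ``v_i`` drawn from a
bivariate normal with SDs ``(sd_int, sd_slope)`` and correlation ``rho``.
Assay values at/above the highest standard are right-censored: their
likelihood contribution is the lognormal upper-tail probability.

**Model 1 (joint multivariate).** The cortisol submodel is retained in full
and each stressor item gets its own submodel: cumulative ordinal logit with
cutpoints ``kappa`` for Likert items, Bernoulli-logit for debt, each with
age/gender/community fixed effects, translator random intercepts, and an
individual latent residual ``eps_i``. All individual-level latents
``(eps_i per item, v_i, u_i)`` are jointly multivariate normal with a
correlation matrix ``R`` under an LKJ(2) prior; the residual correlations in
``R`` between item latents and the cortisol intercept/slope are the
quantities of scientific interest.

Priors: ``mu0 ~ Normal(0, 100)``, other coefficients ``Normal(0, 2)``, all
SDs ``Exponential(2)``, ``R ~ LKJcorr(2)``, cutpoints ``Normal(0, 10)``
(ordering enforced by transformation).

The structured functions here (:func:`model0_logposterior`,
:func:`model1_logposterior`) are plain-numpy densities over interpretable
parameter objects. :func:`build_model0` / :func:`build_model1` compile the
same models onto a flat unconstrained vector with autodiff gradients for the
NUTS sampler in :mod:`cortrhythm.inference`; the LKJ prior is placed on the
canonical partial correlations of the C-vine factorization, whose shifted-
Beta marginals reproduce LKJ exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from . import autodiff as ad
from .preprocess import ModelData

__all__ = [
    "PriorSpec", "Model0Params", "ItemSubmodelParams", "JointModelParams",
    "lognormal_censored_loglik", "ordinal_logit_loglik",
    "bernoulli_logit_loglik", "latent_effects_logprior",
    "model0_logposterior", "model1_logposterior",
    "build_model0", "build_model1", "UnconstrainedModel",
    "cortisol_design", "item_design",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters (regularizing defaults of the analysis)."""

    intercept_sd: float = 100.0
    beta_sd: float = 2.0
    scale_rate: float = 2.0
    lkj_eta: float = 2.0
    cutpoint_sd: float = 10.0

    def __post_init__(self):
        for f in ("intercept_sd", "beta_sd", "scale_rate", "lkj_eta", "cutpoint_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# likelihood components
# ---------------------------------------------------------------------------

def lognormal_censored_loglik(y, mu, sigma, censored_high=False):
    """Log-density of (possibly right-censored) lognormal observations.

    Uncensored values contribute the lognormal density at ``y``; censored
    values contribute ``log P(Y > y)`` (the observation is only known to lie
    at/above the assay ceiling). Elementwise over broadcastable inputs.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    z = (np.log(y) - mu) / sigma
    dens = -np.log(y) - np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z
    tail = sp.log_ndtr(-z)
    out = np.where(censored_high, tail, dens)
    return float(out) if out.ndim == 0 else out


def ordinal_logit_loglik(k, phi, cutpoints):
    """Log-probability of ordinal category ``k`` under a cumulative logit.

    ``P(cat = k) = logistic(kappa_k - phi) - logistic(kappa_{k-1} - phi)``
    with ``kappa_0 = -inf`` and ``kappa_K = +inf``. ``k`` is 1-based.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.ndim != 1 or (cut.size > 1 and np.any(np.diff(cut) <= 0)):
        raise ValueError("cutpoints must be strictly increasing")
    k = np.asarray(k, dtype=int)
    K = cut.size + 1
    if np.any(k < 1) or np.any(k > K):
        raise ValueError(f"category index outside 1..{K}")
    full = np.concatenate([[-np.inf], cut, [np.inf]])
    a = full[k] - phi          # upper cutpoint
    b = full[k - 1] - phi      # lower cutpoint
    # log(sigmoid(a) - sigmoid(b)) = logsig(a) + logsig(-b) + log(1-exp(b-a))
    with np.errstate(invalid="ignore", over="ignore"):
        la = -np.logaddexp(0.0, -a)
        lb = -np.logaddexp(0.0, b)
        diff = np.where(np.isneginf(b), 0.0,
                        np.where(np.isposinf(a), 0.0,
                                 _log1mexp(np.minimum(b - a, -1e-300))))
    out = np.where(np.isposinf(a), 0.0, la) + np.where(np.isneginf(b), 0.0, lb) + diff
    return float(out) if np.ndim(out) == 0 else out


def _log1mexp(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(x < -np.log(2.0), np.log1p(-np.exp(x)), np.log(-np.expm1(x)))


def bernoulli_logit_loglik(d, eta):
    """Bernoulli log-probability on the logit scale."""
    d = np.asarray(d)
    if np.any((d != 0) & (d != 1)):
        raise ValueError("d must be 0/1")
    out = np.where(d == 1, -np.logaddexp(0.0, -np.asarray(eta, float)),
                   -np.logaddexp(0.0, np.asarray(eta, float)))
    return float(out) if np.ndim(out) == 0 else out


def latent_effects_logprior(effects, sds, corr):
    """Sum of MVN log-densities of per-individual latent vectors.

    Covariance is ``diag(sds) @ corr @ diag(sds)``.
    """
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("sds must be positive")
    L = np.linalg.cholesky(corr)  # raises LinAlgError if not PD
    d = sds.size
    w = np.linalg.solve(L, (effects / sds).T)
    quad = np.sum(w * w)
    n = effects.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diag(L))) + 2.0 * np.sum(np.log(sds))
    return -0.5 * (n * d * _LOG_2PI + n * logdet + quad)


# ---------------------------------------------------------------------------
# structured parameter objects
# ---------------------------------------------------------------------------

@dataclass
class Model0Params:
    """Interpretable Model 0 parameters (original scales)."""

    mu0: float
    beta_time: float
    beta_age: float
    beta_gender: float
    beta_community: np.ndarray          # one per non-reference community
    beta_time_age: float
    beta_time_gender: float
    beta_age_gender: float
    beta_time_age_gender: float
    sigma_resid: float
    sd_pid_intercept: float
    sd_pid_slope: float
    rho_int_slope: float = 0.0
    pid_effects: np.ndarray | None = None   # (n, 2): intercept, slope deviations

    def fixed_effects(self) -> np.ndarray:
        return np.concatenate([
            [self.mu0, self.beta_time, self.beta_age, self.beta_gender],
            np.atleast_1d(self.beta_community),
            [self.beta_time_age, self.beta_time_gender,
             self.beta_age_gender, self.beta_time_age_gender]])


@dataclass
class ItemSubmodelParams:
    """One stressor item's submodel parameters."""

    variable: str
    beta_age: float
    beta_gender: float
    beta_community: np.ndarray
    sd_translator: float
    translator_effects: np.ndarray
    sd_pid: float
    cutpoints: np.ndarray | None = None   # ordinal items
    intercept: float = 0.0                # binary (debt) item


@dataclass
class JointModelParams:
    """All Model 1 parameters: cortisol submodel, item submodels, joint latents.

    ``corr_matrix`` is over ``(eps per item ..., slope deviation, intercept
    deviation)``; ``latent_effects`` has one row per individual in the same
    column order.
    """

    cortisol: Model0Params
    items: dict                           # name -> ItemSubmodelParams, ordered
    corr_matrix: np.ndarray
    latent_effects: np.ndarray            # (n, n_items + 2)

    def latent_sds(self) -> np.ndarray:
        return np.concatenate([
            [it.sd_pid for it in self.items.values()],
            [self.cortisol.sd_pid_slope, self.cortisol.sd_pid_intercept]])


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def cortisol_design(data: ModelData):
    """Sample-level fixed-effect design matrix for the cortisol submodel."""
    t = data.rel_time_h
    age = data.age_z[data.pid_index]
    woman = data.woman[data.pid_index].astype(float)
    cols = [np.ones_like(t), t, age, woman]
    names = ["mu0", "beta_time", "beta_age_z", "beta_woman"]
    for lvl in range(1, len(data.community_levels)):
        cols.append((data.community[data.pid_index] == lvl).astype(float))
        names.append(f"beta_community_{data.community_levels[lvl]}")
    cols += [t * age, t * woman, age * woman, t * age * woman]
    names += ["beta_time_age_z", "beta_time_woman", "beta_age_z_woman",
              "beta_time_age_z_woman"]
    return np.column_stack(cols), names


def item_design(data: ModelData):
    """Participant-level fixed-effect design (no intercept column)."""
    cols = [data.age_z, data.woman.astype(float)]
    names = ["beta_age_z", "beta_woman"]
    for lvl in range(1, len(data.community_levels)):
        cols.append((data.community == lvl).astype(float))
        names.append(f"beta_community_{data.community_levels[lvl]}")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# structured log-posteriors
# ---------------------------------------------------------------------------

def _normal_lp(x, sd):
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI))


def _exponential_lp(x, rate):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("scale parameter must be positive")
    return float(np.sum(np.log(rate) - rate * x))


def model0_logposterior(params: Model0Params, data: ModelData,
                        priors: PriorSpec = PriorSpec()) -> float:
    """Joint log-density of Model 0 at a structured parameter point.

    Sum of the censored-lognormal likelihood, the bivariate-normal prior on
    individual effects, and the stated parameter priors (LKJ term
    unnormalized).
    """
    if params.sigma_resid <= 0 or params.sd_pid_intercept <= 0 or params.sd_pid_slope <= 0:
        raise ValueError("scale parameters must be positive")
    if not -1 < params.rho_int_slope < 1:
        raise ValueError("rho must be in (-1, 1)")
    X, _ = cortisol_design(data)
    beta = params.fixed_effects()
    eff = params.pid_effects if params.pid_effects is not None \
        else np.zeros((data.n_participants, 2))
    mu = X @ beta + eff[data.pid_index, 0] + eff[data.pid_index, 1] * data.rel_time_h
    ll = np.sum(lognormal_censored_loglik(data.y, mu, params.sigma_resid,
                                          data.censored_high))
    rho = params.rho_int_slope
    corr = np.array([[1.0, rho], [rho, 1.0]])
    lp = (ll
          + _normal_lp(params.mu0, priors.intercept_sd)
          + _normal_lp(beta[1:], priors.beta_sd)
          + _exponential_lp([params.sigma_resid, params.sd_pid_intercept,
                             params.sd_pid_slope], priors.scale_rate)
          + (priors.lkj_eta - 1.0) * np.log1p(-rho * rho)
          + latent_effects_logprior(
              eff, [params.sd_pid_intercept, params.sd_pid_slope], corr))
    return float(lp)


def model1_logposterior(params: JointModelParams, data: ModelData,
                        priors: PriorSpec = PriorSpec()) -> float:
    """Joint log-density of Model 1 at a structured parameter point."""
    if data.items is None:
        raise ValueError("data was not prepared for model1")
    d = len(params.items) + 2
    if params.corr_matrix.shape != (d, d):
        raise ValueError(
            f"corr_matrix must be {d}x{d} for {len(params.items)} items")
    c = params.cortisol
    if c.sigma_resid <= 0:
        raise ValueError("sigma must be positive")

    X, _ = cortisol_design(data)
    lat = params.latent_effects
    mu = (X @ c.fixed_effects() + lat[data.pid_index, -1]
          + lat[data.pid_index, -2] * data.rel_time_h)
    lp = np.sum(lognormal_censored_loglik(data.y, mu, c.sigma_resid,
                                          data.censored_high))
    lp += _normal_lp(c.mu0, priors.intercept_sd)
    lp += _normal_lp(c.fixed_effects()[1:], priors.beta_sd)
    lp += _exponential_lp(c.sigma_resid, priors.scale_rate)

    Xi, _ = item_design(data)
    for m, (name, it) in enumerate(params.items.items()):
        info = data.items[name]
        fe = np.concatenate([[it.beta_age, it.beta_gender],
                             np.atleast_1d(it.beta_community)])
        phi = Xi @ fe + it.translator_effects[data.translator_index] + lat[:, m]
        if info["kind"] == "binary":
            lp += np.sum(bernoulli_logit_loglik(info["codes"], it.intercept + phi))
            lp += _normal_lp(it.intercept, priors.beta_sd)
        else:
            lp += np.sum(ordinal_logit_loglik(info["codes"], phi, it.cutpoints))
            lp += _normal_lp(it.cutpoints, priors.cutpoint_sd)
        lp += _normal_lp(fe, priors.beta_sd)
        lp += _normal_lp(it.translator_effects, it.sd_translator)
        lp += _exponential_lp([it.sd_translator, it.sd_pid], priors.scale_rate)

    sds = params.latent_sds()
    lp += _exponential_lp([c.sd_pid_intercept, c.sd_pid_slope], priors.scale_rate)
    sign, logdet = np.linalg.slogdet(params.corr_matrix)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix not positive definite")
    lp += (priors.lkj_eta - 1.0) * logdet
    lp += latent_effects_logprior(lat, sds, params.corr_matrix)
    return float(lp)


# ---------------------------------------------------------------------------
# unconstrained compiled models (for NUTS)
# ---------------------------------------------------------------------------

class UnconstrainedModel:
    """A model compiled onto a flat unconstrained parameter vector.

    Attributes
    ----------
    n_dim : total unconstrained dimension
    logp_and_grad : theta -> (float, gradient array)
    constrain : draw matrix (ndraw, n_dim) -> dict of named parameter arrays
    latent : draw matrix -> (ndraw, n, k) latent effect deviations
    """

    def __init__(self, n_dim, logp_and_grad, constrain, latent, names, meta):
        self.n_dim = n_dim
        self.logp_and_grad = logp_and_grad
        self.constrain = constrain
        self.latent = latent
        self.names = names
        self.meta = meta

    def logp(self, theta):
        return self.logp_and_grad(theta)[0]


def _cpc_levels(d):
    """(row, col) pairs and Beta-exponent per CPC for the C-vine LKJ factorization."""
    pairs, alpha = [], []
    for i in range(1, d):
        for j in range(i):
            pairs.append((i, j))
            alpha.append((d - 2 - j) / 2.0)  # add eta to get the Beta shape
    return pairs, np.array(alpha)


def _chol_from_cpc(u_node, d):
    """Cholesky factor of a correlation matrix from CPC nodes, as a (d, d) Node.

    Row ``i`` of the factor is ``z_ij * sqrt(prod_{k<j}(1 - z_ik^2))`` off the
    diagonal with ``sqrt(prod_{k<i}(1 - z_ik^2))`` on it. Implemented as one
    fused primitive with a hand-derived reverse pass.
    """
    uv = np.asarray(ad.value(u_node), dtype=float)
    zs, ss, sqp = [], [], []   # per-row CPCs, 1-z^2, sqrt prefix products
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    off = 0
    for i in range(1, d):
        z = np.tanh(uv[off:off + i])
        off += i
        s = 1.0 - z * z
        pref = np.concatenate([[1.0], np.cumprod(s)])   # length i+1
        sq = np.sqrt(pref)
        L[i, :i] = z * sq[:i]
        L[i, i] = sq[i]
        zs.append(z)
        ss.append(s)
        sqp.append(sq)

    def vjp(G):
        du = np.empty_like(uv)
        off2 = 0
        for i in range(1, d):
            z, s, sq = zs[i - 1], ss[i - 1], sqp[i - 1]
            Grow = G[i, :i + 1] if G.ndim == 2 else np.zeros(i + 1)
            GL = Grow * L[i, :i + 1]
            # T_k = sum_{j>k} G_ij L_ij (including the diagonal term)
            T = np.cumsum(GL[::-1])[::-1]
            dz = Grow[:i] * sq[:i] - (z / s) * T[1:]
            du[off2:off2 + i] = dz * s
            off2 += i
        return du

    if isinstance(u_node, ad.Node):
        return ad.Node(L, ((u_node, vjp),))
    return ad.Node(L)


def _censored_lognormal_node(mu, log_sigma, logy, idx_unc, idx_cen):
    """Fused censored-lognormal log-likelihood (constants dropped).

    ``mu`` (N,) and ``log_sigma`` (scalar) are Nodes. Censored observations
    contribute the upper-tail log-probability; their gradient uses the
    normal hazard ``phi(r)/SF(r)``.
    """
    muv = ad.value(mu)
    lsv = float(ad.value(log_sigma))
    sig = np.exp(lsv)
    r = (logy - muv) / sig
    ru = r[idx_unc]
    val = -0.5 * float(np.dot(ru, ru)) - idx_unc.size * lsv
    d_mu = np.zeros_like(muv)
    d_mu[idx_unc] = ru / sig
    d_ls = float(np.dot(ru, ru)) - idx_unc.size
    if idx_cen.size:
        rc = r[idx_cen]
        logsf = sp.log_ndtr(-rc)
        val += float(logsf.sum())
        hazard = np.exp(-0.5 * rc * rc - 0.5 * _LOG_2PI - logsf)
        d_mu[idx_cen] = hazard / sig
        d_ls += float(np.dot(hazard, rc))
    parents = []
    if isinstance(mu, ad.Node):
        parents.append((mu, lambda g: g * d_mu))
    if isinstance(log_sigma, ad.Node):
        parents.append((log_sigma, lambda g: g * d_ls))
    return ad.Node(val, tuple(parents))


def _ordinal_loglik_node(phi, kappa, codes):
    """Fused cumulative-logit log-likelihood sum as one autodiff primitive.

    ``phi`` (n,) and ``kappa`` (K-1,) are Nodes; ``codes`` are 1-based
    observed categories. The score has the closed form
    ``d lp / d phi = 1 - sigmoid(a) - sigmoid(b)`` with
    ``a = kappa_k - phi``, ``b = kappa_{k-1} - phi``.
    """
    kv = np.asarray(ad.value(kappa), dtype=float).ravel()
    pv = ad.value(phi)
    K = kv.size + 1
    full = np.concatenate([[-np.inf], kv, [np.inf]])
    a = full[codes] - pv
    b = full[codes - 1] - pv
    hi = codes == K
    lo = codes == 1
    la = np.where(hi, 0.0, -np.logaddexp(0.0, -a))
    lnb = np.where(lo, 0.0, -np.logaddexp(0.0, b))
    with np.errstate(invalid="ignore"):
        diff = np.where(lo | hi, 0.0, _log1mexp(np.where(lo | hi, -1.0, b - a)))
    lp_el = la + lnb + diff
    val = float(lp_el.sum())

    p = np.exp(lp_el)
    p = np.maximum(p, 1e-300)
    sa = sp.expit(a)
    sb = sp.expit(b)
    d_a = np.where(hi, 0.0, sa * (1.0 - sa) / p)
    d_b = np.where(lo, 0.0, -sb * (1.0 - sb) / p)
    d_phi = -(d_a + d_b)
    d_kap = np.zeros(K - 1)
    np.add.at(d_kap, codes[~hi] - 1, d_a[~hi])
    np.add.at(d_kap, codes[~lo] - 2, d_b[~lo])
    if np.ndim(ad.value(kappa)) == 0:
        d_kap = d_kap[0]

    parents = []
    if isinstance(phi, ad.Node):
        parents.append((phi, lambda g: g * d_phi))
    if isinstance(kappa, ad.Node):
        parents.append((kappa, lambda g: g * d_kap))
    return ad.Node(val, tuple(parents))


def _cpc_logprior(u_node, d, eta):
    """LKJ(eta) prior on CPCs plus the tanh Jacobian (unnormalized)."""
    _, alpha = _cpc_levels(d)
    z = ad.tanh(u_node)
    # (eta + alpha - 1) from the Beta density, +1 from d tanh/du = 1 - z^2
    coef = eta + alpha
    return ad.asum(ad.log(1.0 - ad.square(z)) * coef)


def corr_from_cpc(u: np.ndarray, d: int) -> np.ndarray:
    """Plain-numpy correlation matrix from a CPC vector (for reporting)."""
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    off = 0
    for i in range(1, d):
        z = np.tanh(u[off:off + i])
        off += i
        s = np.concatenate([[1.0], np.cumprod(1.0 - z * z)])
        L[i, :i] = z * np.sqrt(s[:i])
        L[i, i] = np.sqrt(s[i])
    return L @ L.T


def _slicer():
    state = {"off": 0}

    def take(n):
        sl = slice(state["off"], state["off"] + n)
        state["off"] += n
        return sl

    return take, state


def build_model0(data: ModelData, priors: PriorSpec = PriorSpec(),
                 likelihood: bool = True) -> UnconstrainedModel:
    """Compile Model 0 onto an unconstrained vector (non-centered latents)."""
    X, beta_names = cortisol_design(data)
    p = X.shape[1]
    n = data.n_participants
    t = data.rel_time_h
    pid = data.pid_index
    logy = np.log(data.y)
    cens = np.asarray(data.censored_high, dtype=bool)
    idx_unc = np.where(~cens)[0]
    idx_cen = np.where(cens)[0]
    lik_scale = 1.0 if likelihood else 0.0

    nxt, state = _slicer()
    sl_beta = nxt(p)
    sl_scales = nxt(3)          # log sigma, log sd_int, log sd_slope
    sl_u = nxt(1)               # atanh-scale intercept-slope correlation
    sl_z_int = nxt(n)
    sl_z_slope = nxt(n)
    n_dim = state["off"]

    beta_prior_sd = np.full(p, priors.beta_sd)
    beta_prior_sd[0] = priors.intercept_sd

    def logp_and_grad(theta):
        th = ad.var(theta)
        beta = th[sl_beta]
        log_scales = th[sl_scales]
        scales = ad.exp(log_scales)
        sd_int, sd_slope = scales[1], scales[2]
        u = th[sl_u][0]
        rho = ad.tanh(u)
        z1 = th[sl_z_int]
        z2 = th[sl_z_slope]

        b_int = sd_int * z1
        b_slope = sd_slope * (rho * z1 + ad.sqrt(1.0 - ad.square(rho)) * z2)
        mu = ad.dot(X, beta) + b_int[pid] + b_slope[pid] * t

        lp = 0.0
        if lik_scale:
            lp = lp + _censored_lognormal_node(mu, log_scales[0], logy,
                                               idx_unc, idx_cen)
        # priors
        lp = lp + (-0.5) * ad.asum(ad.square(beta / beta_prior_sd))
        lp = lp + (-priors.scale_rate) * ad.asum(scales) + ad.asum(log_scales)
        # LKJ(eta) on the 2x2 correlation plus the tanh Jacobian: exponent eta
        lp = lp + priors.lkj_eta * ad.log(1.0 - ad.square(rho))
        lp = lp + (-0.5) * (ad.asum(ad.square(z1)) + ad.asum(ad.square(z2)))
        g = ad.grad(lp, th)
        return float(ad.value(lp)), g

    param_names = beta_names + ["sigma_resid", "sd_pid_intercept",
                                "sd_pid_slope", "rho_intercept_slope"]

    def constrain(draws):
        draws = np.atleast_2d(draws)
        out = {nm: draws[:, i] for i, nm in enumerate(beta_names)}
        out["sigma_resid"] = np.exp(draws[:, sl_scales][:, 0])
        out["sd_pid_intercept"] = np.exp(draws[:, sl_scales][:, 1])
        out["sd_pid_slope"] = np.exp(draws[:, sl_scales][:, 2])
        out["rho_intercept_slope"] = np.tanh(draws[:, sl_u][:, 0])
        return out

    def latent(draws):
        draws = np.atleast_2d(draws)
        sd_int = np.exp(draws[:, sl_scales][:, 1])[:, None]
        sd_slope = np.exp(draws[:, sl_scales][:, 2])[:, None]
        rho = np.tanh(draws[:, sl_u])
        z1 = draws[:, sl_z_int]
        z2 = draws[:, sl_z_slope]
        b_int = sd_int * z1
        b_slope = sd_slope * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)
        return np.stack([b_int, b_slope], axis=-1)  # (ndraw, n, 2)

    meta = {"model": "model0", "n_participants": n, "likelihood": likelihood,
            "latent_dims": ["intercept", "slope"]}
    return UnconstrainedModel(n_dim, logp_and_grad, constrain, latent,
                              param_names, meta)


def build_model1(data: ModelData, priors: PriorSpec = PriorSpec(),
                 likelihood: bool = True) -> UnconstrainedModel:
    """Compile Model 1 (joint multivariate) onto an unconstrained vector.

    Latent dimension order: one per stressor item (in ``data.items`` order),
    then cortisol slope, then cortisol intercept.
    """
    if data.items is None:
        raise ValueError("data was not prepared for model1")
    X, beta_names = cortisol_design(data)
    Xi, item_fe_names = item_design(data)
    p, q = X.shape[1], Xi.shape[1]
    n = data.n_participants
    t = data.rel_time_h
    pid = data.pid_index
    tr = data.translator_index
    n_tr = len(data.translator_levels)
    logy = np.log(data.y)
    cens = np.asarray(data.censored_high, dtype=bool)
    idx_unc = np.where(~cens)[0]
    idx_cen = np.where(cens)[0]
    lik_scale = 1.0 if likelihood else 0.0

    item_names = list(data.items)
    n_items = len(item_names)
    d = n_items + 2
    n_cpc = d * (d - 1) // 2

    # per ordinal item: index sets by category position (low/high/interior)
    item_obs = {}
    for name in item_names:
        info = data.items[name]
        codes = np.asarray(info["codes"], dtype=int)
        if info["kind"] == "binary":
            item_obs[name] = {"kind": "binary", "y": codes}
        else:
            item_obs[name] = {"kind": "ordinal", "K": info["n_categories"],
                              "codes": codes}

    nxt, state = _slicer()
    sl_beta = nxt(p)
    sl_sigma = nxt(1)
    sl_item_fe = nxt(n_items * q)       # item-major blocks of q
    sl_debt_int = nxt(1)
    sl_cut = {}
    for nm in item_names:
        if item_obs[nm]["kind"] == "ordinal":
            sl_cut[nm] = nxt(item_obs[nm]["K"] - 1)   # first cutpoint + log-gaps
    sl_tr_sd = nxt(n_items)
    sl_tr_z = nxt(n_items * n_tr)       # item-major blocks of n_tr
    sl_lat_sd = nxt(d)          # log SDs, latent-dim order
    sl_u = nxt(n_cpc)
    sl_z = nxt(n * d)           # non-centered latents, participant-major
    n_dim = state["off"]

    beta_prior_sd = np.full(p, priors.beta_sd)
    beta_prior_sd[0] = priors.intercept_sd

    def _cutpoints_node(th, nm):
        """Ordered cutpoints from (first value, log gaps); fused primitive.

        Returns ``(kappa_node, log_jacobian)`` of the ordering transform.
        """
        raw = th[sl_cut[nm]]
        K = item_obs[nm]["K"]
        rv = np.atleast_1d(np.asarray(ad.value(raw), dtype=float))
        gaps = np.exp(rv[1:])
        kap = rv[0] + np.concatenate([[0.0], np.cumsum(gaps)])

        def vjp(g):
            dr = np.empty_like(rv)
            dr[0] = g.sum()
            if gaps.size:
                dr[1:] = gaps * np.cumsum(g[::-1])[::-1][1:]
            return dr

        kap_node = ad.Node(kap, ((raw, vjp),))
        jac = float(rv[1:].sum())
        # the Jacobian term's gradient w.r.t. the log-gaps is 1
        jac_node = ad.Node(jac, ((raw, lambda g, k=K: g * np.concatenate(
            [[0.0], np.ones(k - 2)])),))
        return kap_node, jac_node

    def logp_and_grad(theta):
        th = ad.var(theta)
        beta = th[sl_beta]
        log_sigma = th[sl_sigma][0]
        sigma = ad.exp(log_sigma)
        log_lat_sd = th[sl_lat_sd]
        lat_sd = ad.exp(log_lat_sd)
        u = th[sl_u]
        Lc = _chol_from_cpc(u, d)
        zflat = th[sl_z]
        Z = ad.reshape(zflat, (n, d))
        # latent effect deviations, (n, d): scaled Cholesky mix per individual
        eff_mat = ad.dot(Z, ad.transpose(Lc)) * lat_sd

        lp = 0.0
        # cortisol submodel
        mu = ad.dot(X, beta) + eff_mat[(slice(None), d - 1)][pid] \
            + eff_mat[(slice(None), d - 2)][pid] * t
        if lik_scale:
            lp = lp + _censored_lognormal_node(mu, log_sigma, logy,
                                               idx_unc, idx_cen)

        # item linear predictors, batched: (n, n_items)
        FE = ad.reshape(th[sl_item_fe], (n_items, q))
        log_tr_sd = th[sl_tr_sd]
        tr_sd = ad.exp(log_tr_sd)
        TRZ = ad.reshape(th[sl_tr_z], (n_items, n_tr))
        tr_eff = ad.transpose(TRZ) * tr_sd            # (n_tr, n_items)
        PHI = ad.dot(Xi, ad.transpose(FE)) + tr_eff[(tr, slice(None))] \
            + eff_mat[(slice(None), slice(0, n_items))]

        for m, nm in enumerate(item_names):
            phi = PHI[(slice(None), m)]
            obs = item_obs[nm]
            if obs["kind"] == "binary":
                eta = th[sl_debt_int][0] + phi
                if lik_scale:
                    sgn = np.where(obs["y"] == 1, 1.0, -1.0)
                    lp = lp + ad.asum(ad.log_sigmoid(eta * sgn))
            else:
                kap, jac = _cutpoints_node(th, nm)
                if lik_scale:
                    lp = lp + _ordinal_loglik_node(phi, kap, obs["codes"])
                # cutpoint prior (on the constrained values) + transform Jacobian
                lp = lp + (-0.5) * ad.asum(ad.square(kap / priors.cutpoint_sd)) + jac

        # priors: item fixed effects, translator effects, debt intercept
        lp = lp + (-0.5) * ad.asum(ad.square(th[sl_item_fe] / priors.beta_sd))
        lp = lp + (-priors.scale_rate) * ad.asum(tr_sd) + ad.asum(log_tr_sd)
        lp = lp + (-0.5) * ad.asum(ad.square(th[sl_tr_z]))
        lp = lp + (-0.5) * ad.square(th[sl_debt_int][0] / priors.beta_sd)
        # sigma, latent sds: Exponential(rate) + log-Jacobian
        lp = lp + (-priors.scale_rate) * sigma + log_sigma
        lp = lp + (-priors.scale_rate) * ad.asum(lat_sd) + ad.asum(log_lat_sd)
        # LKJ prior on CPCs (incl. tanh Jacobian)
        lp = lp + _cpc_logprior(u, d, priors.lkj_eta)
        # standard-normal latents
        lp = lp + (-0.5) * ad.asum(ad.square(zflat))
        g = ad.grad(lp, th)
        return float(ad.value(lp)), g

    # ---- reporting ----
    latent_dim_names = item_names + ["slope", "intercept"]

    def constrain(draws):
        draws = np.atleast_2d(draws)
        out = {nm: draws[:, i] for i, nm in enumerate(beta_names)}
        out["sigma_resid"] = np.exp(draws[:, sl_sigma][:, 0])
        fe_block = draws[:, sl_item_fe].reshape(-1, n_items, q)
        tr_sd_block = np.exp(draws[:, sl_tr_sd])
        for m, nm in enumerate(item_names):
            for jf, fn in enumerate(item_fe_names):
                out[f"{nm}_{fn}"] = fe_block[:, m, jf]
            out[f"{nm}_sd_translator"] = tr_sd_block[:, m]
            if nm in sl_cut:
                raw = draws[:, sl_cut[nm]]
                K = item_obs[nm]["K"]
                kap = np.empty_like(raw)
                kap[:, 0] = raw[:, 0]
                if K > 2:
                    kap[:, 1:] = raw[:, [0]] + np.cumsum(np.exp(raw[:, 1:]), axis=1)
                for j in range(K - 1):
                    out[f"{nm}_cut_{j + 1}"] = kap[:, j]
        out["debt_intercept"] = draws[:, sl_debt_int][:, 0]
        lat_sd = np.exp(draws[:, sl_lat_sd])
        for m, dn in enumerate(latent_dim_names):
            key = {"slope": "sd_pid_slope", "intercept": "sd_pid_intercept"}.get(
                dn, f"sd_latent_{dn}")
            out[key] = lat_sd[:, m]
        # correlation entries from CPC draws
        U = draws[:, sl_u]
        R = np.empty((draws.shape[0], d, d))
        for i in range(draws.shape[0]):
            R[i] = corr_from_cpc(U[i], d)
        for nm_i, m in zip(latent_dim_names, range(d)):
            for nm_j, mj in zip(latent_dim_names, range(d)):
                if mj <= m:
                    continue
                out[f"r_{nm_i}_{nm_j}"] = R[:, m, mj]
        out["rho_intercept_slope"] = R[:, d - 2, d - 1]
        return out

    def latent(draws):
        draws = np.atleast_2d(draws)
        ndraw = draws.shape[0]
        lat_sd = np.exp(draws[:, sl_lat_sd])
        eff = np.empty((ndraw, n, d))
        for i in range(ndraw):
            Lc = np.linalg.cholesky(corr_from_cpc(draws[i, sl_u], d))
            Z = draws[i, sl_z].reshape(n, d)
            eff[i] = (Z @ Lc.T) * lat_sd[i]
        return eff

    param_names = (beta_names + ["sigma_resid", "sd_pid_intercept",
                                 "sd_pid_slope", "rho_intercept_slope"]
                   + [f"sd_latent_{nm}" for nm in item_names]
                   + [f"r_{nm}_intercept" for nm in item_names]
                   + [f"r_{nm}_slope" for nm in item_names])

    meta = {"model": "model1", "n_participants": n, "likelihood": likelihood,
            "latent_dims": latent_dim_names, "items": item_names,
            "mappings": {nm: data.items[nm]["mapping"] for nm in item_names}}
    return UnconstrainedModel(n_dim, logp_and_grad, constrain, latent,
                              param_names, meta)
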