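"""Posterior sampling for the cortisol models.

A dynamic Hamiltonian Monte Carlo sampler (NUTS-style: multinomial sampling
over a doubling trajectory with a no-U-turn stopping rule, dual-averaging
step-size adaptation and windowed diagonal mass-matrix adaptation) runs on
the unconstrained model builders from :mod:`cortrhythm.model_core`, whose
gradients come from the package's reverse-mode autodiff.

Sampling is deterministic given (data, config, seed). Convergence problems
(split R-hat above threshold, divergences) attach warnings to the result
rather than aborting, so exploratory refits remain possible.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (PriorSpec, UnconstrainedModel, build_model0,
                         build_model1)
from .preprocess import ModelData

__all__ = [
    "SamplerConfig", "PosteriorDraws", "InsufficientChainsError",
    "fit_model", "compute_diagnostics", "sample_nuts",
]


class InsufficientChainsError(ValueError):
    """Split R-hat needs at least two chains."""


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings. Defaults suit hierarchical models with correlations."""

    chains: int = 4
    warmup_draws: int = 1000
    kept_draws: int = 1000
    target_accept: float = 0.95
    seed: int = 0
    max_treedepth: int = 10

    def __post_init__(self):
        if self.chains < 1 or self.warmup_draws < 1 or self.kept_draws < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


# ---------------------------------------------------------------------------
# core sampler
# ---------------------------------------------------------------------------

def _leapfrog(logp_and_grad, theta, r, grad, eps, minv):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * minv * r1
    logp1, grad1 = logp_and_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, grad1, logp1


def _uturn(dtheta, r_minus, r_plus, minv):
    return (np.dot(dtheta, minv * r_minus) < 0) or (np.dot(dtheta, minv * r_plus) < 0)


class _Tree:
    __slots__ = ("theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
                 "theta_prop", "grad_prop", "logp_prop", "logw", "sum_alpha",
                 "n_alpha", "divergent", "turning")


def _build_tree(f, theta, r, grad, v, depth, eps, minv, H0, rng):
    """Recursively double the trajectory in direction v; multinomial weights."""
    out = _Tree()
    if depth == 0:
        theta1, r1, grad1, logp1 = _leapfrog(f, theta, r, grad, v * eps, minv)
        H = -logp1 + 0.5 * np.dot(r1, minv * r1)
        logw = H0 - H
        if not np.isfinite(logw):
            logw = -np.inf
        out.theta_m = out.theta_p = out.theta_prop = theta1
        out.r_m = out.r_p = r1
        out.grad_m = out.grad_p = out.grad_prop = grad1
        out.logp_prop = logp1
        out.logw = logw
        out.sum_alpha = min(1.0, np.exp(min(logw, 0.0)))
        out.n_alpha = 1
        out.divergent = logw < -1000.0
        out.turning = False
        return out

    first = _build_tree(f, theta, r, grad, v, depth - 1, eps, minv, H0, rng)
    if first.divergent or first.turning:
        return first
    if v > 0:
        second = _build_tree(f, first.theta_p, first.r_p, first.grad_p, v,
                             depth - 1, eps, minv, H0, rng)
        out.theta_m, out.r_m, out.grad_m = first.theta_m, first.r_m, first.grad_m
        out.theta_p, out.r_p, out.grad_p = second.theta_p, second.r_p, second.grad_p
    else:
        second = _build_tree(f, first.theta_m, first.r_m, first.grad_m, v,
                             depth - 1, eps, minv, H0, rng)
        out.theta_m, out.r_m, out.grad_m = second.theta_m, second.r_m, second.grad_m
        out.theta_p, out.r_p, out.grad_p = first.theta_p, first.r_p, first.grad_p
    out.sum_alpha = first.sum_alpha + second.sum_alpha
    out.n_alpha = first.n_alpha + second.n_alpha
    out.divergent = second.divergent
    out.logw = np.logaddexp(first.logw, second.logw)
    if second.divergent:
        out.turning = False
        out.theta_prop, out.grad_prop, out.logp_prop = \
            first.theta_prop, first.grad_prop, first.logp_prop
        return out
    # multinomial sampling between the halves
    if np.log(rng.uniform()) < second.logw - out.logw:
        out.theta_prop, out.grad_prop, out.logp_prop = \
            second.theta_prop, second.grad_prop, second.logp_prop
    else:
        out.theta_prop, out.grad_prop, out.logp_prop = \
            first.theta_prop, first.grad_prop, first.logp_prop
    out.turning = second.turning or _uturn(out.theta_p - out.theta_m,
                                           out.r_m, out.r_p, minv)
    return out


def _find_epsilon(f, theta, logp, grad, minv, rng):
    eps = 0.1
    r = rng.standard_normal(theta.size) / np.sqrt(minv)
    H0 = -logp + 0.5 * np.dot(r, minv * r)
    _, r1, _, logp1 = _leapfrog(f, theta, r, grad, eps, minv)
    H1 = -logp1 + 0.5 * np.dot(r1, minv * r1)
    dH = H0 - H1 if np.isfinite(H1) else -np.inf
    direction = 1 if dH > np.log(0.8) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, _, logp1 = _leapfrog(f, theta, r, grad, eps, minv)
        H1 = -logp1 + 0.5 * np.dot(r1, minv * r1)
        dH = H0 - H1 if np.isfinite(H1) else -np.inf
        if (direction == 1 and dH < np.log(0.8)) or \
           (direction == -1 and dH > np.log(0.8)):
            break
    return eps


def _nuts_chain(f, n_dim, rng, n_warmup, n_kept, target_accept, max_treedepth,
                theta0):
    theta = np.array(theta0, dtype=float)
    logp, grad = f(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")
    minv = np.ones(n_dim)

    eps = _find_epsilon(f, theta, logp, grad, minv, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # adaptation windows (Stan-like schedule, scaled to warmup length)
    init_buf = max(15, int(0.15 * n_warmup))
    term_buf = max(25, int(0.10 * n_warmup))
    window_starts = []
    w = max(25, int(0.1 * n_warmup))
    pos = init_buf
    while pos + w < n_warmup - term_buf:
        window_starts.append((pos, pos + w))
        pos += w
        w *= 2
    if window_starts:
        window_starts[-1] = (window_starts[-1][0], n_warmup - term_buf)
    elif n_warmup > init_buf + term_buf + 10:
        window_starts = [(init_buf, n_warmup - term_buf)]

    welford_n = 0
    welford_mean = np.zeros(n_dim)
    welford_m2 = np.zeros(n_dim)

    draws = np.empty((n_kept, n_dim))
    divergences = 0
    depth_hits = 0

    for it in range(n_warmup + n_kept):
        warm = it < n_warmup
        r = rng.standard_normal(n_dim) / np.sqrt(minv)
        H0 = -logp + 0.5 * np.dot(r, minv * r)
        theta_prop, grad_prop, logp_prop = theta, grad, logp
        logw_tot = 0.0
        tm, rm, gm = theta, r, grad
        tp, rp, gp = theta, r, grad
        sum_alpha, n_alpha = 0.0, 0
        divergent = False
        for depth in range(max_treedepth):
            v = 1 if rng.uniform() < 0.5 else -1
            if v > 0:
                sub = _build_tree(f, tp, rp, gp, v, depth, eps, minv, H0, rng)
                tp, rp, gp = sub.theta_p, sub.r_p, sub.grad_p
            else:
                sub = _build_tree(f, tm, rm, gm, v, depth, eps, minv, H0, rng)
                tm, rm, gm = sub.theta_m, sub.r_m, sub.grad_m
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            if sub.divergent:
                divergent = True
                break
            if sub.turning:
                break
            # biased progressive sampling toward the new subtree
            if np.log(rng.uniform()) < sub.logw - logw_tot:
                theta_prop, grad_prop, logp_prop = \
                    sub.theta_prop, sub.grad_prop, sub.logp_prop
            logw_tot = np.logaddexp(logw_tot, sub.logw)
            if _uturn(tp - tm, rm, rp, minv):
                break
        else:
            depth_hits += 1
        theta, grad, logp = theta_prop, grad_prop, logp_prop
        accept = sum_alpha / max(n_alpha, 1)

        if warm:
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar \
                + (target_accept - accept) / (da_count + t0)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w_k = da_count ** -kappa
            log_eps_bar = w_k * log_eps + (1 - w_k) * log_eps_bar
            eps = np.exp(log_eps)
            for (a, b) in window_starts:
                if a <= it < b:
                    welford_n += 1
                    delta = theta - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (theta - welford_mean)
                    if it == b - 1 and welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        minv = (welford_n / (welford_n + 5.0)) * var \
                            + (5.0 / (welford_n + 5.0)) * 1e-3
                        welford_n = 0
                        welford_mean[:] = 0.0
                        welford_m2[:] = 0.0
                        eps = _find_epsilon(f, theta, logp, grad, minv, rng)
                        mu = np.log(10.0 * eps)
                        log_eps_bar, h_bar, da_count = np.log(eps), 0.0, 0
                    break
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            if divergent:
                divergences += 1
            draws[it - n_warmup] = theta
    return draws, divergences, depth_hits


def sample_nuts(model: UnconstrainedModel, cfg: SamplerConfig):
    """Run NUTS chains on a compiled model; returns (chains, draws, dim) array."""
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(cfg.chains)
    all_draws = np.empty((cfg.chains, cfg.kept_draws, model.n_dim))
    div_total = 0
    depth_total = 0
    for c in range(cfg.chains):
        rng = np.random.default_rng(child_seeds[c])
        theta0 = 0.1 * rng.standard_normal(model.n_dim)
        draws, divs, hits = _nuts_chain(
            model.logp_and_grad, model.n_dim, rng, cfg.warmup_draws,
            cfg.kept_draws, cfg.target_accept, cfg.max_treedepth, theta0)
        all_draws[c] = draws
        div_total += divs
        depth_total += hits
    return all_draws, div_total, depth_total


# ---------------------------------------------------------------------------
# results container & diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Labelled posterior draws with convergence diagnostics.

    ``params`` maps parameter names to ``(chains, draws)`` arrays on original
    scales (correlations back-transformed to (-1, 1)). ``raw`` keeps the
    unconstrained draws so latent per-individual effects can be reconstructed
    via ``model.latent``.
    """

    params: dict
    raw: np.ndarray
    model: UnconstrainedModel
    diagnostics: pd.DataFrame
    divergence_count: int
    warnings: list = field(default_factory=list)
    config: SamplerConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.raw.shape[0]

    @property
    def n_draws(self) -> int:
        return self.raw.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        return self.params[name].reshape(-1)

    def latent_effects(self) -> np.ndarray:
        """Per-individual latent deviations, shape (total draws, n, k)."""
        flat = self.raw.reshape(-1, self.raw.shape[-1])
        return self.model.latent(flat)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.reshape(-1) for k, v in self.params.items()})


def compute_diagnostics(params: dict, rhat_threshold: float = 1.01):
    """Split R-hat and effective sample size per parameter (via ArviZ)."""
    import arviz as az

    first = next(iter(params.values()))
    if first.ndim < 2 or first.shape[0] < 2:
        raise InsufficientChainsError("need >= 2 chains for split R-hat")
    rows = []
    for name, arr in params.items():
        if np.allclose(arr.var(), 0):
            rows.append((name, np.nan, np.nan))
            continue
        rows.append((name, float(az.rhat(arr)), float(az.ess(arr))))
    df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    df["ok"] = (df["rhat"] < rhat_threshold) | df["rhat"].isna()
    return df


def fit_model(model_stage: str, data: ModelData,
              priors: PriorSpec = PriorSpec(),
              cfg: SamplerConfig = SamplerConfig(),
              likelihood: bool = True) -> PosteriorDraws:
    """Fit Model 0 or Model 1 and return labelled draws with diagnostics.

    ``likelihood=False`` samples from the priors alone (prior-recovery
    checks). Identical (data, priors, cfg) give bit-identical draws.
    """
    if model_stage == "model0":
        model = build_model0(data, priors, likelihood=likelihood)
    elif model_stage == "model1":
        model = build_model1(data, priors, likelihood=likelihood)
    else:
        raise ValueError(f"unknown model stage {model_stage!r}")

    raw, divergences, depth_hits = sample_nuts(model, cfg)
    flat = raw.reshape(-1, model.n_dim)
    constrained = model.constrain(flat)
    params = {k: v.reshape(cfg.chains, cfg.kept_draws)
              for k, v in constrained.items()}

    warnings = []
    diagnostics = pd.DataFrame()
    if cfg.chains >= 2:
        diagnostics = compute_diagnostics(params, rhat_threshold=1.01)
        bad = diagnostics[diagnostics["rhat"] > 1.05]
        if len(bad):
            warnings.append(
                "convergence: R-hat > 1.05 for "
                + ", ".join(bad["parameter"].tolist()[:8]))
    total = cfg.chains * cfg.kept_draws
    if divergences > 0.01 * total:
        warnings.append(f"convergence: {divergences} divergent transitions "
                        f"({100 * divergences / total:.1f}% of draws)")
    if depth_hits:
        warnings.append(f"{depth_hits} transitions hit max treedepth")
    for w in warnings:
        _warnings.warn(w, RuntimeWarning, stacklevel=2)

    return PosteriorDraws(params=params, raw=raw, model=model,
                          diagnostics=diagnostics,
                          divergence_count=divergences,
                          warnings=warnings, config=cfg)
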