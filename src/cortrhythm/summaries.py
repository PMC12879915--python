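"""Posterior summaries: residual correlations, ICCs, diurnal curves, tables.

Reporting conventions follow the analysis: posterior medians with 89%
equal-tailed credible intervals, and directional probabilities (the share
of posterior mass supporting a positive or negative association) instead of
significance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .preprocess import ModelData

__all__ = [
    "CorrelationSummary", "IccReport",
    "directional_probability", "residual_correlation_summary", "compute_icc",
    "predict_diurnal_curve", "descriptive_table", "hourly_percent_change",
]

_CI = (0.055, 0.945)  # 89% equal-tailed


@dataclass
class CorrelationSummary:
    """One stressor's residual correlations with cortisol intercept & slope."""

    variable: str
    r_intercept_median: float
    r_slope_median: float
    p_gt0_intercept: float
    p_lt0_intercept: float
    p_gt0_slope: float
    p_lt0_slope: float
    ci89_intercept: tuple
    ci89_slope: tuple

    def to_dict(self):
        return asdict(self)


@dataclass
class IccReport:
    """Intraclass correlation of individual intercepts and slopes."""

    icc_intercept_mean: float
    icc_intercept_sd: float
    icc_slope_mean: float
    icc_slope_sd: float

    def to_dict(self):
        return asdict(self)


def directional_probability(param_draws) -> tuple[float, float]:
    """Fractions of draws strictly above and strictly below zero.

    Exact zeros (measure-zero for continuous draws) count in neither, so the
    two probabilities are complementary on continuous posteriors.
    """
    x = np.asarray(param_draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw vector")
    return float(np.mean(x > 0)), float(np.mean(x < 0))


def hourly_percent_change(beta_time: float) -> float:
    """Percent change in cortisol per hour implied by a log-scale slope.

    A slope of -0.03/h gives ``100*(1 - exp(-0.03))`` = a ~3% hourly decline
    (returned positive for a decline).
    """
    return 100.0 * (1.0 - np.exp(beta_time))


def residual_correlation_summary(draws: PosteriorDraws,
                                 variables=None) -> list[CorrelationSummary]:
    """Per-stressor medians, 89% intervals and directional probabilities of
    the latent correlations with cortisol intercept and slope."""
    if variables is None:
        variables = draws.model.meta.get("items")
        if variables is None:
            raise KeyError("draws carry no stressor items; pass variables")
    out = []
    for v in variables:
        key_i, key_s = f"r_{v}_intercept", f"r_{v}_slope"
        if key_i not in draws.params or key_s not in draws.params:
            raise KeyError(f"no correlation draws for variable {v!r}")
        ri = draws.stacked(key_i)
        rs = draws.stacked(key_s)
        pgi, pli = directional_probability(ri)
        pgs, pls = directional_probability(rs)
        out.append(CorrelationSummary(
            variable=v,
            r_intercept_median=float(np.median(ri)),
            r_slope_median=float(np.median(rs)),
            p_gt0_intercept=pgi, p_lt0_intercept=pli,
            p_gt0_slope=pgs, p_lt0_slope=pls,
            ci89_intercept=tuple(np.quantile(ri, _CI)),
            ci89_slope=tuple(np.quantile(rs, _CI)),
        ))
    return out


def icc_components(sd_int, sd_slope, rho, sigma_resid, rel_times):
    """Variance-partition shares (intercept, slope, residual) per draw.

    Total variance is evaluated at the observed time moments:
    ``V = sd_int^2 + sd_slope^2 E[t^2] + 2 rho sd_int sd_slope E[t]
    + sigma^2``.
    """
    t = np.asarray(rel_times, dtype=float)
    m1, m2 = t.mean(), np.mean(t * t)
    v_int = np.asarray(sd_int) ** 2
    v_slope = np.asarray(sd_slope) ** 2 * m2
    cov = 2.0 * np.asarray(rho) * np.asarray(sd_int) * np.asarray(sd_slope) * m1
    v_res = np.asarray(sigma_resid) ** 2
    v_tot = v_int + v_slope + cov + v_res
    return v_int / v_tot, v_slope / v_tot, v_res / v_tot


def compute_icc(draws: PosteriorDraws, rel_times) -> IccReport:
    """Posterior mean and SD of intercept and slope ICCs."""
    for k in ("sd_pid_intercept", "sd_pid_slope", "rho_intercept_slope",
              "sigma_resid"):
        if k not in draws.params:
            raise KeyError(f"missing variance component {k!r}")
    icc_i, icc_s, _ = icc_components(
        draws.stacked("sd_pid_intercept"), draws.stacked("sd_pid_slope"),
        draws.stacked("rho_intercept_slope"), draws.stacked("sigma_resid"),
        rel_times)
    return IccReport(
        icc_intercept_mean=float(icc_i.mean()),
        icc_intercept_sd=float(icc_i.std()),
        icc_slope_mean=float(icc_s.mean()),
        icc_slope_sd=float(icc_s.std()),
    )


def _fixed_effect_mu(draws: PosteriorDraws, covariates: dict, t: np.ndarray):
    """Linear predictor draws (ndraw, nt) at given covariates (no latents)."""
    age = float(covariates.get("age_z", 0.0))
    woman = float(covariates.get("woman", 0.0))
    comm = str(covariates.get("community", "reference"))
    mu = (draws.stacked("mu0")[:, None]
          + np.outer(draws.stacked("beta_time"), t)
          + draws.stacked("beta_age_z")[:, None] * age
          + draws.stacked("beta_woman")[:, None] * woman
          + np.outer(draws.stacked("beta_time_age_z"), t) * age
          + np.outer(draws.stacked("beta_time_woman"), t) * woman
          + draws.stacked("beta_age_z_woman")[:, None] * age * woman
          + np.outer(draws.stacked("beta_time_age_z_woman"), t) * age * woman)
    if comm not in ("reference", "1"):
        key = f"beta_community_{comm}"
        if key not in draws.params:
            raise KeyError(f"unknown community {comm!r}")
        mu += draws.stacked(key)[:, None]
    return mu


def predict_diurnal_curve(draws: PosteriorDraws, covariates: dict,
                          time_grid, level: str = "population",
                          data: ModelData | None = None) -> pd.DataFrame:
    """Posterior median and 89% band of expected cortisol over the day.

    ``level="population"`` sets latent deviations to zero;
    ``level="individual"`` (with ``covariates["participant_id"]`` and
    ``data``) adds that individual's latent intercept/slope draws. Values
    are back-transformed to pg/mL.
    """
    t = np.asarray(time_grid, dtype=float)
    mu = _fixed_effect_mu(draws, covariates, t)
    if level == "individual":
        if data is None:
            raise ValueError("individual curves need the ModelData")
        pid = covariates.get("participant_id")
        if pid not in data.participant_ids:
            raise KeyError(f"unknown individual id {pid!r}")
        i = data.participant_ids.index(pid)
        lat = draws.latent_effects()           # (ndraw, n, k); last two dims
        b_int = lat[:, i, -1] if lat.shape[-1] > 2 else lat[:, i, 0]
        b_slope = lat[:, i, -2] if lat.shape[-1] > 2 else lat[:, i, 1]
        mu = mu + b_int[:, None] + np.outer(b_slope, t)
    elif level != "population":
        raise ValueError("level must be 'population' or 'individual'")
    y = np.exp(mu)
    lo, hi = np.quantile(y, _CI, axis=0)
    return pd.DataFrame({
        "time_h": t,
        "median": np.median(y, axis=0),
        "lower89": lo,
        "upper89": hi,
    })


def descriptive_table(data: ModelData) -> pd.DataFrame:
    """Sample sizes, means, SDs, ranges of corrected cortisol and age by gender."""
    rows = []

    def describe(label, x):
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            rows.append({"variable": label, "n": 0, "mean": np.nan,
                         "sd": np.nan, "min": np.nan, "max": np.nan})
            return
        sd = float(np.std(x, ddof=1)) if x.size > 1 else np.nan
        rows.append({"variable": label, "n": int(x.size),
                     "mean": float(x.mean()), "sd": sd,
                     "min": float(x.min()), "max": float(x.max())})

    woman_sample = data.woman[data.pid_index] == 1
    age = np.asarray(data.meta.get("age_years", data.age_z), dtype=float)
    label = "age_years" if "age_years" in data.meta else "age_z"
    describe("cortisol_pg_ml", data.y)
    describe("cortisol_pg_ml_women", data.y[woman_sample])
    describe("cortisol_pg_ml_men", data.y[~woman_sample])
    describe(label, age)
    describe(f"{label}_women", age[data.woman == 1])
    describe(f"{label}_men", age[data.woman == 0])
    df = pd.DataFrame(rows)
    return df[df["n"] > 0].reset_index(drop=True)
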