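"""Generate full synthetic studies from the joint generative process.

The real field data are access-restricted, so testing runs on synthetic
studies drawn from the Model 1 generative process with known parameters.
The default :class:`GenerativeTruth` mirrors the study design: 129
analyzable participants (57% women) across three communities of sizes
37/53/39, ages uniform on 15-83, two or three urine samples on one day
(first-morning void at relative time 0, later samples 4-10 h after
sunrise), lognormal cortisol declining about 3% per hour with
among-individual intercept SD an order of magnitude above the slope SD, and
stressor items on their questionnaire scales with translator effects.
Additional participants carry the exclusion-rule load: 8 pregnant, 3 with
missing age, 4 with incomplete questionnaires (140 enrolled in total).

Specific gravity is drawn per sample and raw cortisol back-computed from
the generative (dilution-corrected) value, so the specific-gravity
correction stage is exercised end to end.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SolarContext, StudyConfig, sunrise_hour

__all__ = ["GenerativeTruth", "ItemTruth", "default_truth",
           "default_study_config", "generate_dataset", "recovery_experiment"]

#: community id -> (latitude, longitude); lowland Bolivia, UTC-4, no DST
DEFAULT_COMMUNITIES = {
    "1": (-14.85, -66.75),
    "2": (-15.05, -66.95),
    "3": (-14.95, -66.55),
}


def default_study_config(**overrides) -> StudyConfig:
    cfg = StudyConfig(communities=dict(DEFAULT_COMMUNITIES), utc_offset_h=-4.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class ItemTruth:
    """Generative parameters of one stressor item submodel."""

    kind: str                      # "ordinal" | "binary"
    score_range: tuple             # inclusive original scale
    cutpoints: np.ndarray | None = None
    intercept: float = 0.0         # binary only
    beta_age: float = 0.0
    beta_gender: float = 0.0
    beta_community: tuple = (0.0, 0.0)
    sd_translator: float = 0.3
    sd_latent: float = 1.0
    split_items: tuple | None = None   # raw items a composite is split into


def _default_items() -> dict:
    return {
        "health": ItemTruth("ordinal", (1, 3),
                            cutpoints=np.array([-1.5, 1.0]),
                            beta_age=-0.15, beta_gender=-0.1),
        "food_insecurity": ItemTruth("ordinal", (2, 10),
                                     cutpoints=np.linspace(-2.5, 3.0, 8),
                                     beta_age=0.1, beta_gender=0.15,
                                     beta_community=(0.2, 0.4),
                                     split_items=("worry_food", "day_without_food")),
        "social_conflicts": ItemTruth("ordinal", (2, 10),
                                      cutpoints=np.linspace(-2.0, 3.5, 8),
                                      beta_age=-0.1, beta_gender=0.2,
                                      beta_community=(-0.4, -0.2),
                                      split_items=("conflict_spouse", "conflict_children")),
        "hunger": ItemTruth("ordinal", (1, 5),
                            cutpoints=np.array([-1.0, 0.8, 2.2, 3.5]),
                            beta_age=0.05, beta_gender=0.1,
                            beta_community=(0.1, 0.3)),
        "rumination": ItemTruth("ordinal", (1, 5),
                                cutpoints=np.array([-0.8, 0.6, 2.0, 3.2]),
                                beta_age=0.1, beta_gender=0.2,
                                beta_community=(-0.5, -0.8)),
        "debt": ItemTruth("binary", (0, 1), intercept=-0.5,
                          beta_age=0.0, beta_gender=-0.2,
                          beta_community=(0.3, 0.1)),
    }


#: latent residual correlations (item vs cortisol intercept / slope) that the
#: default truth encodes; signs follow the directions the analysis reports.
_DEFAULT_ITEM_CORR = {
    "health": (0.06, -0.10),
    "food_insecurity": (0.08, -0.19),
    "social_conflicts": (0.10, -0.10),
    "hunger": (-0.15, -0.15),
    "rumination": (0.10, -0.15),
    "debt": (-0.05, 0.12),
}


@dataclass
class GenerativeTruth:
    """All population-level values of the joint generative process."""

    n_participants: int = 129
    prop_women: float = 0.57
    community_props: tuple = (37 / 129, 53 / 129, 39 / 129)
    n_translators: int = 2
    age_range: tuple = (15.0, 83.0)
    p_three_samples: float = 45 / 129          # 303 samples from 129 people
    afternoon_window: tuple = (4.0, 10.0)
    # cortisol submodel (log pg/mL scale)
    mu0: float = 12.66
    beta_time: float = -0.03
    beta_age: float = 0.06
    beta_gender: float = 0.13
    beta_community: tuple = (0.03, -0.21)
    beta_time_age: float = -0.00
    beta_time_gender: float = -0.04
    beta_age_gender: float = -0.06
    beta_time_age_gender: float = 0.01
    sigma_resid: float = 0.4
    sd_pid_intercept: float = 0.5
    sd_pid_slope: float = 0.05
    rho_int_slope: float = 0.22
    # items and joint latent correlation structure
    items: dict = field(default_factory=_default_items)
    corr_matrix: np.ndarray | None = None      # built from defaults when None
    # measurement layer
    sg_range: tuple = (1.005, 1.035)
    sg_target: float = 1.020
    censor_threshold: float | None = None      # corrected pg/mL
    # exclusion-rule load
    n_pregnant: int = 8
    n_missing_age: int = 3
    n_incomplete_questionnaire: int = 4
    # study window
    start_date: dt.date = dt.date(2023, 9, 15)
    n_study_days: int = 90
    seed: int = 2023

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.corr_matrix is None:
            self.corr_matrix = self.default_corr_matrix()
        d = len(self.items) + 2
        R = np.asarray(self.corr_matrix, dtype=float)
        if R.shape != (d, d) or not np.allclose(R, R.T) or \
                not np.allclose(np.diag(R), 1.0):
            raise ValueError("corr_matrix must be a symmetric correlation "
                             f"matrix of size {d}")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("corr_matrix must be positive definite")
        for it in self.items.values():
            if it.kind == "ordinal" and np.any(np.diff(it.cutpoints) <= 0):
                raise ValueError("cutpoints must be strictly increasing")

    @property
    def latent_dim_names(self):
        return list(self.items) + ["slope", "intercept"]

    def default_corr_matrix(self) -> np.ndarray:
        """Identity between items; reported-scale item-cortisol correlations."""
        names = list(self.items)
        d = len(names) + 2
        R = np.eye(d)
        i_slope, i_int = d - 2, d - 1
        R[i_slope, i_int] = R[i_int, i_slope] = self.rho_int_slope
        for m, nm in enumerate(names):
            r_int, r_slope = _DEFAULT_ITEM_CORR.get(nm, (0.0, 0.0))
            R[m, i_int] = R[i_int, m] = r_int
            R[m, i_slope] = R[i_slope, m] = r_slope
        return R

    def latent_sds(self) -> np.ndarray:
        return np.concatenate([[it.sd_latent for it in self.items.values()],
                               [self.sd_pid_slope, self.sd_pid_intercept]])

    def named_values(self) -> dict:
        """Generative truth keyed by posterior parameter names."""
        out = {
            "mu0": self.mu0, "beta_time": self.beta_time,
            "beta_age_z": self.beta_age, "beta_woman": self.beta_gender,
            "beta_community_2": self.beta_community[0],
            "beta_community_3": self.beta_community[1],
            "beta_time_age_z": self.beta_time_age,
            "beta_time_woman": self.beta_time_gender,
            "beta_age_z_woman": self.beta_age_gender,
            "beta_time_age_z_woman": self.beta_time_age_gender,
            "sigma_resid": self.sigma_resid,
            "sd_pid_intercept": self.sd_pid_intercept,
            "sd_pid_slope": self.sd_pid_slope,
            "rho_intercept_slope": self.rho_int_slope,
        }
        names = list(self.items)
        d = len(names) + 2
        R = np.asarray(self.corr_matrix)
        for m, nm in enumerate(names):
            out[f"r_{nm}_intercept"] = R[m, d - 1]
            out[f"r_{nm}_slope"] = R[m, d - 2]
        return out

    def to_record(self) -> dict:
        rec = dataclasses.asdict(self)
        rec["corr_matrix"] = np.asarray(self.corr_matrix).tolist()
        rec["items"] = {k: {f: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for f, v in dataclasses.asdict(it).items()}
                        for k, it in self.items.items()}
        rec["start_date"] = self.start_date.isoformat()
        rec["named_values"] = self.named_values()
        return rec


def default_truth(**overrides) -> GenerativeTruth:
    """The study-condition truth profile, with field overrides."""
    return GenerativeTruth(**overrides)


def _split_composite(c, lo, hi, rng):
    """Split a composite score into two items on [lo, hi] uniformly."""
    a_min = max(lo, c - hi)
    a_max = min(hi, c - lo)
    a = int(rng.integers(a_min, a_max + 1))
    return a, c - a


def generate_dataset(truth: GenerativeTruth, config: StudyConfig | None = None):
    """Draw one full synthetic study.

    Returns ``(samples, participants, questionnaire, record)`` where the
    three tables match the input CSV schemas of the preprocessing modules
    and ``record`` is a JSON-ready dict of the generative truth. Identical
    seeds give identical tables.
    """
    cfg = config or default_study_config()
    rng = np.random.default_rng(truth.seed)
    n = truth.n_participants
    names = list(truth.items)
    d = len(names) + 2

    # ---- participant frame (analyzable core) ----
    n_women = int(round(truth.prop_women * n))
    woman = np.zeros(n, dtype=int)
    woman[rng.choice(n, size=n_women, replace=False)] = 1
    sizes = np.floor(np.asarray(truth.community_props) * n).astype(int)
    while sizes.sum() < n:
        sizes[int(rng.integers(0, sizes.size))] += 1
    community = np.repeat(np.arange(sizes.size), sizes)
    rng.shuffle(community)
    translator = rng.integers(0, truth.n_translators, size=n)
    age = rng.uniform(*truth.age_range, size=n)
    age_z = (age - age.mean()) / age.std()

    # ---- joint latent effects ----
    sds = truth.latent_sds()
    L = np.linalg.cholesky(np.asarray(truth.corr_matrix, dtype=float))
    latent = (rng.standard_normal((n, d)) @ L.T) * sds
    eff_slope = latent[:, d - 2]
    eff_int = latent[:, d - 1]
    tr_effects = {nm: rng.normal(0.0, it.sd_translator, truth.n_translators)
                  for nm, it in truth.items.items()}

    pids = [f"P{i + 1:03d}" for i in range(n)]
    dates = [truth.start_date + dt.timedelta(days=int(x))
             for x in rng.integers(0, truth.n_study_days, size=n)]

    def mu_at(i, t):
        a, w = age_z[i], woman[i]
        comm = truth.beta_community[community[i] - 1] if community[i] > 0 else 0.0
        return (truth.mu0 + truth.beta_time * t + truth.beta_age * a
                + truth.beta_gender * w + comm
                + truth.beta_time_age * t * a + truth.beta_time_gender * t * w
                + truth.beta_age_gender * a * w
                + truth.beta_time_age_gender * t * a * w
                + eff_int[i] + eff_slope[i] * t)

    def emit_samples(i, pid, date, comm_id, extra_log_shift=0.0):
        n_samp = 2 + int(rng.uniform() < truth.p_three_samples)
        rel = np.concatenate([[0.0], np.sort(
            rng.uniform(*truth.afternoon_window, size=n_samp - 1))])
        rise = sunrise_hour(SolarContext(
            *cfg.communities[comm_id], cfg.utc_offset_h, date))
        rows = []
        for t in rel:
            corrected = float(np.exp(
                mu_at(i, t) + extra_log_shift + truth.sigma_resid * rng.standard_normal()))
            censored = 0
            if truth.censor_threshold is not None and corrected >= truth.censor_threshold:
                corrected = truth.censor_threshold
                censored = 1
            sg = rng.uniform(*truth.sg_range)
            raw = corrected * (sg - 1.0) / (truth.sg_target - 1.0)
            if t == 0.0:
                clock = ""
                first = 1
            else:
                total_min = int(round((rise + t) * 60.0))
                clock = f"{total_min // 60:02d}:{total_min % 60:02d}"
                first = 0
            rows.append((pid, comm_id, date.isoformat(), clock, first,
                         raw, sg, censored))
        return rows

    sample_rows = []
    part_rows = []
    quest_rows = []
    for i, pid in enumerate(pids):
        comm_id = str(community[i] + 1)
        part_rows.append((pid, "woman" if woman[i] else "man", round(age[i], 1),
                          comm_id, f"T{translator[i] + 1}", 0))
        sample_rows += emit_samples(i, pid, dates[i], comm_id)
        # questionnaire
        q = {"participant_id": pid}
        for m, nm in enumerate(names):
            it = truth.items[nm]
            phi = (it.beta_age * age_z[i] + it.beta_gender * woman[i]
                   + (it.beta_community[community[i] - 1] if community[i] > 0 else 0.0)
                   + tr_effects[nm][translator[i]] + latent[:, m][i])
            if it.kind == "binary":
                p = 1.0 / (1.0 + np.exp(-(it.intercept + phi)))
                q["in_debt"] = int(rng.uniform() < p)
            else:
                cum = 1.0 / (1.0 + np.exp(-(it.cutpoints - phi)))
                probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
                k = int(rng.choice(probs.size, p=probs / probs.sum()))
                score = it.score_range[0] + k
                if it.split_items:
                    a, b = _split_composite(score, 1, 5, rng)
                    q[it.split_items[0]], q[it.split_items[1]] = a, b
                else:
                    col = {"health": "health_vs_others", "hunger": "hunger_sleep",
                           "rumination": "rumination_sleep"}[nm]
                    q[col] = score
        quest_rows.append(q)

    # ---- excluded extras: pregnant women, missing age, incomplete items ----
    extra_idx = n
    for _ in range(truth.n_pregnant):
        extra_idx += 1
        pid = f"P{extra_idx:03d}"
        i = int(rng.integers(0, n))  # borrow covariates from a core participant
        comm_id = str(community[i] + 1)
        part_rows.append((pid, "woman", round(float(rng.uniform(18, 40)), 1),
                          comm_id, f"T{translator[i] + 1}", 1))
        date = truth.start_date + dt.timedelta(days=int(rng.integers(0, truth.n_study_days)))
        sample_rows += emit_samples(i, pid, date, comm_id, extra_log_shift=1.0)
        quest_rows.append({"participant_id": pid})
    for _ in range(truth.n_missing_age):
        extra_idx += 1
        pid = f"P{extra_idx:03d}"
        i = int(rng.integers(0, n))
        comm_id = str(community[i] + 1)
        part_rows.append((pid, "woman" if woman[i] else "man", np.nan,
                          comm_id, f"T{translator[i] + 1}", 0))
        date = truth.start_date + dt.timedelta(days=int(rng.integers(0, truth.n_study_days)))
        sample_rows += emit_samples(i, pid, date, comm_id)
        quest_rows.append({"participant_id": pid})
    incomplete = rng.choice(n, size=min(truth.n_incomplete_questionnaire, n),
                            replace=False)
    for j in incomplete:  # blank one raw item for an otherwise-complete row
        row = quest_rows[j]
        keys = [k for k in row if k != "participant_id"]
        row[keys[int(rng.integers(0, len(keys)))]] = np.nan

    samples = pd.DataFrame(sample_rows, columns=[
        "participant_id", "community_id", "date", "clock_time",
        "is_first_morning", "raw_cortisol_pg_ml", "specific_gravity",
        "censored_high"])
    participants = pd.DataFrame(part_rows, columns=[
        "participant_id", "gender", "age_years", "community_id",
        "translator_id", "pregnant"])
    from .questionnaire import VARIABLE_ITEMS
    questionnaire = pd.DataFrame(quest_rows)
    item_cols = ["participant_id"] + [
        c for nm in names
        for c in (truth.items[nm].split_items or VARIABLE_ITEMS[nm])]
    questionnaire = questionnaire.reindex(columns=item_cols)
    return samples, participants, questionnaire, truth.to_record()


def recovery_experiment(truth: GenerativeTruth, cfg, model_stage: str = "model0",
                        priors=None, config: StudyConfig | None = None):
    """Full-pipeline parameter recovery on one synthetic study.

    Generates a dataset, preprocesses it, fits the requested model, and
    reports per-parameter truth, posterior median, 89% interval and a
    coverage indicator. Returns ``(report_df, draws)``.
    """
    from .inference import fit_model
    from .model_core import PriorSpec
    from .preprocess import prepare_model_data

    study_cfg = config or default_study_config()
    samples, participants, questionnaire, record = generate_dataset(truth, study_cfg)
    data, _ = prepare_model_data(samples, participants, questionnaire,
                                 study_cfg, model_stage)
    draws = fit_model(model_stage, data, priors or PriorSpec(), cfg)

    rows = []
    for name, true_val in record["named_values"].items():
        if name not in draws.params:
            continue
        x = draws.stacked(name)
        lo, hi = np.quantile(x, [0.055, 0.945])
        rows.append({
            "parameter": name, "truth": true_val,
            "posterior_mean": float(x.mean()),
            "posterior_median": float(np.median(x)),
            "l89": float(lo), "u89": float(hi),
            "covered": bool(lo <= true_val <= hi),
        })
    return pd.DataFrame(rows), draws
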