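"""Turn raw field tables into model-ready observations.

Field measurements of urinary cortisol need three corrections before any
rhythm modelling:

* **Specific-gravity (SG) correction** — urine concentration varies with
  hydration; the analyte is rescaled by ``(SG_target - 1)/(SG_sample - 1)``
  where ``SG_target`` is the population-mean specific gravity.
* **Sunrise-anchored time** — first-morning voids rarely have a reliable
  clock time; sunrise (computed from community coordinates with the NOAA
  solar-position equations) stands in for waking, all first-morning samples
  are anchored at relative time 0, and later samples are expressed as hours
  since sunrise.
* **Exclusion filtering** — pregnancy (elevated cortisol), missing age, and
  (for the joint stressor model) incomplete questionnaires remove
  participants, with every removal logged.

Tables are plain :class:`pandas.DataFrame` objects with documented columns
(see :data:`SAMPLE_COLUMNS` and :data:`PARTICIPANT_COLUMNS`).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InvalidGravityError", "NoSunriseError", "NegativeTimeError",
    "MissingTimeError", "ReferentialIntegrityError",
    "SolarContext", "StudyConfig", "ModelData",
    "correct_specific_gravity", "compute_population_sg", "compute_sunrise",
    "assign_relative_times", "apply_exclusions", "standardize_age",
    "prepare_model_data",
]

SAMPLE_COLUMNS = [
    "participant_id", "community_id", "date", "clock_time",
    "is_first_morning", "raw_cortisol_pg_ml", "specific_gravity",
    "censored_high",
]
PARTICIPANT_COLUMNS = [
    "participant_id", "gender", "age_years", "community_id",
    "translator_id", "pregnant",
]


class InvalidGravityError(ValueError):
    """Specific gravity at or below 1.000 makes the dilution ratio degenerate."""


class NoSunriseError(ValueError):
    """Polar day/night: the sun does not cross the horizon on this date."""


class NegativeTimeError(ValueError):
    """A non-morning sample is timed before sunrise."""


class MissingTimeError(ValueError):
    """A non-morning sample lacks a clock time."""


class ReferentialIntegrityError(ValueError):
    """Samples reference a participant that is not in the participants table."""


class EmptyInputError(ValueError):
    """An operation received an empty collection."""


# ---------------------------------------------------------------------------
# specific gravity
# ---------------------------------------------------------------------------

def correct_specific_gravity(raw_cortisol, sg_sample, sg_target):
    """SG-correct a cortisol concentration (pg/mL).

    Implements ``corrected = raw * (sg_target - 1) / (sg_sample - 1)``;
    accepts scalars or arrays.
    """
    raw = np.asarray(raw_cortisol, dtype=float)
    sg_s = np.asarray(sg_sample, dtype=float)
    sg_t = np.asarray(sg_target, dtype=float)
    if np.any(raw <= 0):
        raise ValueError("raw cortisol must be positive")
    if np.any(sg_s <= 1.0) or np.any(sg_t <= 1.0):
        raise InvalidGravityError("specific gravity must exceed 1.000")
    out = raw * (sg_t - 1.0) / (sg_s - 1.0)
    return float(out) if out.ndim == 0 else out


def compute_population_sg(specific_gravity) -> float:
    """Population-mean specific gravity over included samples."""
    if isinstance(specific_gravity, pd.DataFrame):
        specific_gravity = specific_gravity["specific_gravity"]
    sg = np.asarray(specific_gravity, dtype=float)
    if sg.size == 0:
        raise EmptyInputError("no samples to average specific gravity over")
    return float(sg.mean())


# ---------------------------------------------------------------------------
# sunrise (NOAA solar-position equations)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolarContext:
    """Location/date context for the sunrise computation.

    ``utc_offset_h`` is the fixed civil offset (e.g. -4 for Bolivia, no DST);
    longitudes are east-positive.
    """

    latitude: float
    longitude: float
    utc_offset_h: float
    date: dt.date

    def __post_init__(self):
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError("coordinates out of range")


def _noaa_sunrise_hour(lat: float, lon: float, tz: float, date: dt.date) -> float:
    # NOAA spreadsheet equations, evaluated at local solar noon. Accuracy is
    # well inside the +/-5 min the rhythm model needs.
    jd = date.toordinal() + 1721424.5 + (12.0 - tz) / 24.0
    jc = (jd - 2451545.0) / 36525.0
    rad = math.radians

    ml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    ma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_ctr = (math.sin(rad(ma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
              + math.sin(rad(2 * ma)) * (0.019993 - 0.000101 * jc)
              + math.sin(rad(3 * ma)) * 0.000289)
    true_long = ml + eq_ctr
    app_long = true_long - 0.00569 - 0.00478 * math.sin(rad(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(rad(125.04 - 1934.136 * jc))
    decl = math.degrees(math.asin(math.sin(rad(obliq)) * math.sin(rad(app_long))))

    var_y = math.tan(rad(obliq / 2.0)) ** 2
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * rad(ml))
        - 2 * ecc * math.sin(rad(ma))
        + 4 * ecc * var_y * math.sin(rad(ma)) * math.cos(2 * rad(ml))
        - 0.5 * var_y * var_y * math.sin(4 * rad(ml))
        - 1.25 * ecc * ecc * math.sin(2 * rad(ma)))

    cos_ha = (math.cos(rad(90.833)) / (math.cos(rad(lat)) * math.cos(rad(decl)))
              - math.tan(rad(lat)) * math.tan(rad(decl)))
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise NoSunriseError(f"no sunrise at latitude {lat} on {date}")
    ha = math.degrees(math.acos(cos_ha))

    solar_noon_min = 720.0 - 4.0 * lon - eq_time + tz * 60.0
    return (solar_noon_min - 4.0 * ha) / 60.0  # local civil hours


def compute_sunrise(ctx: SolarContext) -> dt.time:
    """Local civil sunrise time for the given context."""
    h = _noaa_sunrise_hour(ctx.latitude, ctx.longitude, ctx.utc_offset_h, ctx.date)
    h %= 24.0
    minutes = round(h * 60.0)
    return dt.time(int(minutes // 60) % 24, int(minutes % 60))


def sunrise_hour(ctx: SolarContext) -> float:
    """Sunrise as decimal local hours (unrounded)."""
    return _noaa_sunrise_hour(ctx.latitude, ctx.longitude, ctx.utc_offset_h, ctx.date)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Study-level settings: community coordinates, timezone, SG target.

    ``communities`` maps community id to ``(latitude, longitude)``.
    ``sg_target`` overrides the population-mean specific gravity when set.
    ``censor_threshold_pg_ml`` (raw scale) derives ``censored_high`` flags
    when the assay ceiling is known; otherwise flags are taken from input.
    """

    communities: dict = field(default_factory=dict)
    utc_offset_h: float = -4.0
    sg_target: float | None = None
    censor_threshold_pg_ml: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        communities = {str(k): (float(v[0]), float(v[1]))
                       for k, v in d.get("communities", {}).items()}
        return cls(
            communities=communities,
            utc_offset_h=float(d.get("utc_offset_h", -4.0)),
            sg_target=d.get("sg_target"),
            censor_threshold_pg_ml=d.get("censor_threshold_pg_ml"),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parse_clock(v) -> float | None:
    """'HH:MM' (or missing) -> decimal hours."""
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, dt.time):
        return v.hour + v.minute / 60.0 + v.second / 3600.0
    h, m = str(v).split(":")
    return int(h) + int(m) / 60.0


def assign_relative_times(samples: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Fill ``rel_time_h``: 0 for first-morning voids, hours since sunrise after.

    Requires exactly one first-morning sample per participant-day and clock
    times on all later samples.
    """
    out = samples.copy()
    rel = np.empty(len(out), dtype=float)
    for (pid, date), idx in out.groupby(["participant_id", "date"]).groups.items():
        block = out.loc[idx]
        n_morning = int(block["is_first_morning"].astype(int).sum())
        if n_morning != 1:
            raise ValueError(
                f"participant {pid} on {date}: expected exactly one first-morning "
                f"sample, found {n_morning}")
        comm = str(block["community_id"].iloc[0])
        if comm not in config.communities:
            raise KeyError(f"no coordinates configured for community {comm}")
        lat, lon = config.communities[comm]
        d = date if isinstance(date, dt.date) else dt.date.fromisoformat(str(date))
        rise = sunrise_hour(SolarContext(lat, lon, config.utc_offset_h, d))
        for i in idx:
            if bool(int(out.at[i, "is_first_morning"])):
                rel_i = 0.0
            else:
                clock = _parse_clock(out.at[i, "clock_time"])
                if clock is None:
                    raise MissingTimeError(
                        f"participant {pid} on {date}: non-morning sample lacks clock time")
                rel_i = clock - rise
                if rel_i <= 0:
                    raise NegativeTimeError(
                        f"participant {pid} on {date}: sample at {clock:.2f} h "
                        f"precedes sunrise at {rise:.2f} h")
            rel[out.index.get_loc(i)] = rel_i
    out["rel_time_h"] = rel
    return out


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(participants: pd.DataFrame, samples: pd.DataFrame,
                     questionnaire: pd.DataFrame | None, model_stage: str):
    """Filter the study tables for a model stage; return tables + exclusion log.

    ``model_stage`` is ``"model0"`` (cortisol only: drop pregnant and
    missing-age) or ``"model1"`` (additionally drop incomplete
    questionnaires). Idempotent.
    """
    if model_stage not in ("model0", "model1"):
        raise ValueError(f"unknown model stage {model_stage!r}")
    known = set(participants["participant_id"])
    orphans = set(samples["participant_id"]) - known
    if orphans:
        raise ReferentialIntegrityError(
            f"samples reference unknown participants: {sorted(orphans)[:5]}")

    log_rows = []
    drop: set = set()
    for _, row in participants.iterrows():
        pid = row["participant_id"]
        if bool(int(row["pregnant"])) if not pd.isna(row["pregnant"]) else False:
            drop.add(pid)
            log_rows.append((pid, model_stage, "pregnant"))
        elif pd.isna(row["age_years"]):
            drop.add(pid)
            log_rows.append((pid, model_stage, "missing_age"))

    if model_stage == "model1":
        if questionnaire is None:
            raise ValueError("model1 exclusions need the questionnaire table")
        complete = set(questionnaire.dropna(how="any")["participant_id"])
        for pid in sorted(known - drop):
            if pid not in complete:
                drop.add(pid)
                log_rows.append((pid, model_stage, "incomplete_questionnaire"))

    p = participants[~participants["participant_id"].isin(drop)].reset_index(drop=True)
    s = samples[~samples["participant_id"].isin(drop)].reset_index(drop=True)
    q = None
    if questionnaire is not None:
        q = questionnaire[~questionnaire["participant_id"].isin(drop)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["participant_id", "stage", "reason"])
    return p, s, q, log


def standardize_age(age_years: np.ndarray) -> np.ndarray:
    """Z-score ages over the analysis set (ddof=0, matching a population SD)."""
    age = np.asarray(age_years, dtype=float)
    sd = age.std()
    if sd == 0:
        raise ValueError("cannot standardize constant ages")
    return (age - age.mean()) / sd


# ---------------------------------------------------------------------------
# model-ready bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Preprocessed arrays consumed by the model log-posteriors.

    Sample-level arrays are aligned with each other; ``pid_index`` maps each
    sample to a row of the participant-level arrays.
    """

    # sample level
    y: np.ndarray                  # SG-corrected cortisol, pg/mL
    rel_time_h: np.ndarray
    pid_index: np.ndarray          # int, into participant arrays
    censored_high: np.ndarray      # bool
    # participant level
    participant_ids: list
    age_z: np.ndarray
    woman: np.ndarray              # 0/1
    community: np.ndarray          # int codes, 0 = reference
    community_levels: list
    translator_index: np.ndarray | None = None
    translator_levels: list | None = None
    # stressor items (model 1): name -> dict(kind, codes, n_categories, mapping)
    items: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_samples(self) -> int:
        return self.y.size


def prepare_model_data(samples: pd.DataFrame, participants: pd.DataFrame,
                       questionnaire: pd.DataFrame | None, config: StudyConfig,
                       model_stage: str = "model0"):
    """Full preprocessing pipeline: exclusions, times, SG correction, coding.

    Returns ``(ModelData, exclusion_log)``. For ``model1`` the questionnaire
    is scored and recoded (see :mod:`cortrhythm.questionnaire`) and attached
    as ``ModelData.items``.
    """
    from . import questionnaire as q_mod

    parts, samp, quest, log = apply_exclusions(
        participants, samples, questionnaire, model_stage)
    if len(samp) == 0:
        raise EmptyInputError("no samples left after exclusions")

    samp = assign_relative_times(samp, config)

    sg_target = config.sg_target
    if sg_target is None:
        # population mean over the post-exclusion (pregnancy/age) analysis set
        sg_target = compute_population_sg(samp["specific_gravity"])
    y = correct_specific_gravity(
        samp["raw_cortisol_pg_ml"].to_numpy(float),
        samp["specific_gravity"].to_numpy(float), sg_target)

    censored = samp["censored_high"].to_numpy(int).astype(bool)
    if config.censor_threshold_pg_ml is not None:
        censored = censored | (samp["raw_cortisol_pg_ml"].to_numpy(float)
                               >= config.censor_threshold_pg_ml)

    parts = parts.sort_values("participant_id").reset_index(drop=True)
    pid_order = {pid: i for i, pid in enumerate(parts["participant_id"])}
    pid_index = samp["participant_id"].map(pid_order).to_numpy(int)

    community_levels = sorted(parts["community_id"].astype(str).unique())
    community = parts["community_id"].astype(str).map(
        {c: i for i, c in enumerate(community_levels)}).to_numpy(int)
    woman = (parts["gender"].astype(str) == "woman").to_numpy(int)
    age_z = standardize_age(parts["age_years"].to_numpy(float))

    translator_index = translator_levels = None
    items = None
    if model_stage == "model1":
        translator_levels = sorted(parts["translator_id"].astype(str).unique())
        translator_index = parts["translator_id"].astype(str).map(
            {t: i for i, t in enumerate(translator_levels)}).to_numpy(int)
        scores = q_mod.score_table(quest)
        scored_vars = [c for c in scores.columns if c != "participant_id"]
        scores = scores.set_index("participant_id").loc[parts["participant_id"]]
        items = {}
        for name in scored_vars:
            vals = scores[name].to_numpy(int)
            if name == "debt":
                items[name] = {"kind": "binary", "codes": vals,
                               "n_categories": 2, "mapping": {0: 0, 1: 1}}
            else:
                codes, mapping = q_mod.recode_observed_categories(vals)
                items[name] = {"kind": "ordinal", "codes": codes,
                               "n_categories": len(mapping), "mapping": mapping}

    data = ModelData(
        y=np.asarray(y, dtype=float),
        rel_time_h=samp["rel_time_h"].to_numpy(float),
        pid_index=pid_index,
        censored_high=censored,
        participant_ids=list(parts["participant_id"]),
        age_z=age_z, woman=woman, community=community,
        community_levels=community_levels,
        translator_index=translator_index, translator_levels=translator_levels,
        items=items,
        meta={"sg_target": float(sg_target), "model_stage": model_stage,
              "n_excluded": int(len(log)),
              "age_years": parts["age_years"].astype(float).tolist()},
    )
    return data, log
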