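"""Score raw questionnaire responses into the six stressor variables.

The stressor battery covers self-rated health (1-3), food insecurity (two
1-5 items, summed to 2-10), social conflicts (two 1-5 items, summed to
2-10), going to sleep hungry (1-5), trouble falling asleep from rumination
(1-5), and a yes/no debt item. A seventh item (conflicts with other
community members) is not scored: responses were near-constant ("never")
and carry no information for an ordinal model.

Composite sums leave gaps in the observed category set (e.g. nobody scores
a 7), and cumulative-logit cutpoints are unidentifiable for empty
categories, so observed values are recoded to contiguous indices before
fitting; the mapping is retained so summaries report original scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_RANGES", "STRESSOR_VARIABLES", "RangeError", "MissingItemError",
    "DegenerateVariableError", "score_stressors", "score_table",
    "recode_observed_categories", "decode_categories",
]

#: raw item name -> inclusive (lo, hi) response range
ITEM_RANGES = {
    "health_vs_others": (1, 3),
    "worry_food": (1, 5),
    "day_without_food": (1, 5),
    "hunger_sleep": (1, 5),
    "conflict_spouse": (1, 5),
    "conflict_children": (1, 5),
    "rumination_sleep": (1, 5),
    "in_debt": (0, 1),
}

#: the six analysis variables, in reporting order
STRESSOR_VARIABLES = [
    "health", "food_insecurity", "social_conflicts", "hunger",
    "rumination", "debt",
]

#: analysis variable -> raw items it is built from
VARIABLE_ITEMS = {
    "health": ["health_vs_others"],
    "food_insecurity": ["worry_food", "day_without_food"],
    "social_conflicts": ["conflict_spouse", "conflict_children"],
    "hunger": ["hunger_sleep"],
    "rumination": ["rumination_sleep"],
    "debt": ["in_debt"],
}


class RangeError(ValueError):
    """An item response lies outside its printed scale."""


class MissingItemError(ValueError):
    """A required item is absent (participant excluded from the joint model)."""


class DegenerateVariableError(ValueError):
    """A variable with a single observed value cannot support cutpoints."""


def score_stressors(raw: dict, variables=None) -> dict:
    """Compose stressor scores from one participant's raw items.

    Composites are item sums (food insecurity = worry + day-without-food;
    social conflicts = spouse + children); single items pass through; debt
    maps yes/no (or 1/0) to 0/1. ``variables`` restricts scoring to a
    subset (defaults to all six).
    """
    variables = list(variables) if variables is not None else STRESSOR_VARIABLES
    clean = {}
    needed = [it for v in variables for it in VARIABLE_ITEMS[v]]
    for item in needed:
        lo, hi = ITEM_RANGES[item]
        v = raw.get(item)
        if v in ("yes", "no"):
            v = 1 if v == "yes" else 0
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingItemError(f"missing item {item!r}")
        v = int(v)
        if not lo <= v <= hi:
            raise RangeError(f"item {item!r}={v} outside [{lo}, {hi}]")
        clean[item] = v
    return {v: sum(clean[it] for it in VARIABLE_ITEMS[v]) for v in variables}


def score_table(questionnaire: pd.DataFrame) -> pd.DataFrame:
    """Score a questionnaire table (one row per participant).

    Scores every analysis variable whose raw items are all present as
    columns, so reduced designs with a subset of items work unchanged.
    """
    variables = [v for v in STRESSOR_VARIABLES
                 if all(c in questionnaire.columns for c in VARIABLE_ITEMS[v])]
    if not variables:
        raise MissingItemError("no scoreable stressor variables in table")
    rows = []
    for _, row in questionnaire.iterrows():
        scores = score_stressors(row.to_dict(), variables)
        scores["participant_id"] = row["participant_id"]
        rows.append(scores)
    return pd.DataFrame(rows, columns=["participant_id", *variables])


def recode_observed_categories(values) -> tuple[np.ndarray, dict]:
    """Map observed scores to contiguous 1..K category indices.

    Returns ``(codes, mapping)`` where ``mapping[index] = original_value``.
    Strictly monotone, so order comparisons survive the recoding.
    """
    vals = np.asarray(values, dtype=int)
    observed = np.unique(vals)
    if observed.size < 2:
        raise DegenerateVariableError(
            "variable has fewer than 2 observed categories; cutpoints unidentifiable")
    lookup = {v: i + 1 for i, v in enumerate(observed)}
    codes = np.array([lookup[v] for v in vals], dtype=int)
    mapping = {i + 1: int(v) for i, v in enumerate(observed)}
    return codes, mapping


def decode_categories(codes, mapping: dict) -> np.ndarray:
    """Invert :func:`recode_observed_categories`."""
    return np.array([mapping[int(c)] for c in np.asarray(codes)], dtype=int)
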