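"""Daily records -> weekly analysis table.

Implements the aggregation rules of a weekly, Monday-restarting
computer-adaptive survey design:

* weeks run Monday-Sunday (closed intervals); partial leading/trailing
  windows are kept with their true length;
* the weekly outcome is the score of the *last* response day in the
  window; windows with fewer than 3 daily responses are invalid;
* the weekly dose is the number of prompts delivered from the window's
  first day through the day *before* the last response day (so the
  intervention precedes the outcome measurement), giving counts 0-6
  mapped to categories none (0), low (1-2), medium (3-4), high (5-6);
* weekly steps / sleep are arithmetic means of the non-missing daily
  values (at least one required, otherwise missing);
* the previous-week moderator is the immediately preceding calendar
  week's final score, and only if that week is valid.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from mrtdose.synth import OUTCOMES, WEEKDAYS

logger = logging.getLogger(__name__)

DOSE_CATEGORIES = ("none", "low", "medium", "high")
_SCORE_COLS = [f"score_{out}" for out in OUTCOMES]

#: Columns a daily-records table must provide.
DAILY_REQUIRED_COLUMNS = (
    "participant_id",
    "day_index",
    "weekday",
    "message_sent",
    "survey_responded",
    *_SCORE_COLS,
    "steps",
    "sleep_minutes",
)


def dose_category(dose_count: int) -> str:
    """Map a weekly prompt count (0-6) to its frequency category."""
    if not 0 <= dose_count <= 6:
        raise ValueError(f"dose_count must be in 0..6, got {dose_count!r}")
    if dose_count == 0:
        return "none"
    if dose_count <= 2:
        return "low"
    if dose_count <= 4:
        return "medium"
    return "high"


def category_probabilities(
    eligible_days: int, p_rand: float, *, exact: bool = False
) -> np.ndarray:
    """Randomization distribution of the dose category.

    With ``d`` eligible days and independent Bernoulli(``p_rand``) daily
    prompts, the dose count is Binomial(d, p); each category's mass is
    the sum of the binomial masses over its counts.  ``exact=True``
    returns ``Fraction`` entries (rational arithmetic), used for
    enumeration cross-checks.
    """
    d = int(eligible_days)
    if not 0 <= d <= 6:
        raise ValueError(f"eligible_days must be in 0..6, got {eligible_days!r}")
    if not 0.0 < p_rand < 1.0:
        raise ValueError(f"p_rand must lie in (0, 1), got {p_rand!r}")
    if exact:
        p = Fraction(p_rand).limit_denominator(10**6)
        pmf = [
            Fraction(comb(d, k)) * p**k * (1 - p) ** (d - k) for k in range(d + 1)
        ]
        out = [Fraction(0)] * 4
        for k in range(d + 1):
            out[0 if k == 0 else (1 if k <= 2 else (2 if k <= 4 else 3))] += pmf[k]
        return np.array(out, dtype=object)
    pmf = stats.binom.pmf(np.arange(d + 1), d, p_rand)
    out = np.zeros(4)
    for k in range(d + 1):
        out[0 if k == 0 else (1 if k <= 2 else (2 if k <= 4 else 3))] += pmf[k]
    return out


def enumerate_category_probabilities(eligible_days: int, p_rand: float) -> np.ndarray:
    """Brute-force oracle: tally all 2^d daily assignment vectors."""
    d = int(eligible_days)
    out = np.zeros(4)
    for assign in product((0, 1), repeat=d):
        k = sum(assign)
        prob = p_rand**k * (1 - p_rand) ** (d - k)
        out[DOSE_CATEGORIES.index(dose_category(k))] += prob
    return out


def partition_weeks(daily: pd.DataFrame, start_weekday: str | None = None) -> pd.DataFrame:
    """Assign Monday-anchored week windows to daily records.

    Returns a copy with ``weekday_index`` (Monday = 0) and 1-based
    ``week_index`` columns.  ``start_weekday`` overrides the weekday of
    day 1; by default it is read off the ``weekday`` column.
    """
    out = daily.copy()
    if start_weekday is not None:
        wd0 = WEEKDAYS.index(start_weekday)
        out["weekday_index"] = (wd0 + out["day_index"].to_numpy() - 1) % 7
    else:
        wd_map = {name: i for i, name in enumerate(WEEKDAYS)}
        out["weekday_index"] = out["weekday"].map(wd_map).to_numpy()
        first = out.loc[out["day_index"] == out["day_index"].min(), "weekday_index"]
        wd0 = int(first.iloc[0]) if len(first) else 0
    out["week_index"] = (wd0 + out["day_index"].to_numpy() - 1) // 7 + 1
    return out


def build_week_observation(window: pd.DataFrame) -> dict:
    """Aggregate one participant-week window of daily records.

    Scalar reference implementation of the weekly rules; the vectorized
    :func:`build_weekly_table` is cross-checked against it.
    """
    if len(window) > 7:
        raise ValueError(f"week window has {len(window)} rows; at most 7 allowed")
    window = window.sort_values("day_index")
    resp = window[window["survey_responded"] == 1]
    n_responses = len(resp)
    obs: dict = {
        "participant_id": window["participant_id"].iloc[0],
        "n_responses": n_responses,
        "last_response_day": np.nan,
        "last_response_weekday": None,
        "eligible_days": 0,
        "dose_count": 0,
        "dose_category": "none",
        "mean_steps": float(window["steps"].mean()),
        "mean_sleep": float(window["sleep_minutes"].mean()),
        "valid": 0,
    }
    for out_name in OUTCOMES:
        obs[f"score_{out_name}"] = np.nan
    if n_responses:
        last = resp.iloc[-1]
        before = window[window["day_index"] < last["day_index"]]
        obs["last_response_day"] = int(last["day_index"])
        obs["last_response_weekday"] = last["weekday"]
        obs["eligible_days"] = len(before)
        obs["dose_count"] = int(before["message_sent"].sum())
        obs["dose_category"] = dose_category(obs["dose_count"])
        for out_name in OUTCOMES:
            obs[f"score_{out_name}"] = float(last[f"score_{out_name}"])
        obs["valid"] = int(n_responses >= 3)
    return obs


def validate_daily_schema(daily: pd.DataFrame) -> None:
    missing = [c for c in DAILY_REQUIRED_COLUMNS if c not in daily.columns]
    if missing:
        raise SchemaError(f"daily records missing required column(s): {missing}")


class SchemaError(ValueError):
    """An input table does not match the documented column dictionary."""


def build_weekly_table(
    daily: pd.DataFrame, start_weekday: str | None = None
) -> pd.DataFrame:
    """Aggregate all participant-weeks (vectorized).

    One row per participant-week, satisfying the weekly-observation
    invariants: ``0 <= dose_count <= eligible_days <= 6``, validity
    requiring >= 3 responses, category consistent with the count.
    """
    validate_daily_schema(daily)
    d = partition_weeks(daily, start_weekday)
    d = d.sort_values(["participant_id", "day_index"], kind="stable")
    key = ["participant_id", "week_index"]
    resp = d["survey_responded"].to_numpy() == 1
    day = d["day_index"].to_numpy()
    d = d.assign(_resp_day=np.where(resp, day, np.nan))
    g = d.groupby(key, sort=True)
    agg = g.agg(
        n_responses=("survey_responded", "sum"),
        last_response_day=("_resp_day", "max"),
        mean_steps=("steps", "mean"),
        mean_sleep=("sleep_minutes", "mean"),
    )
    # dose and eligibility: days strictly before the last response day
    last = agg["last_response_day"].reindex(
        pd.MultiIndex.from_frame(d[key])
    ).to_numpy()
    before = day < last  # NaN last -> False
    d = d.assign(_before=before.astype(np.int64), _dosed=before * d["message_sent"].to_numpy())
    g2 = d.groupby(key, sort=True)
    agg["eligible_days"] = g2["_before"].sum()
    agg["dose_count"] = g2["_dosed"].sum()

    # final scores and weekday of the last response day
    is_last = day == last
    lastrows = d.loc[is_last, key + ["weekday", *_SCORE_COLS]].set_index(key)
    lastrows.columns = ["last_response_weekday", *_SCORE_COLS]
    agg = agg.join(lastrows)
    agg["valid"] = (agg["n_responses"] >= 3).astype(int)
    cats = np.array(DOSE_CATEGORIES)
    counts = agg["dose_count"].to_numpy(dtype=int)
    if counts.size and (counts.min() < 0 or counts.max() > 6):
        raise ValueError("dose_count out of 0..6; week windows longer than 7 days?")
    agg["dose_category"] = cats[np.where(counts == 0, 0, np.where(counts <= 2, 1, np.where(counts <= 4, 2, 3)))]
    agg = agg.reset_index()
    logger.info(
        "weekly table: %d participant-weeks, %d valid, %d invalid (<3 responses)",
        len(agg), int(agg["valid"].sum()), int((1 - agg["valid"]).sum()),
    )
    return agg


def add_lagged_and_derived(
    weekly: pd.DataFrame, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Add previous-week scores and roster covariates to the weekly table.

    ``prev_score_<outcome>`` is the immediately preceding calendar
    week's final score, present only when that week exists and is valid;
    rows with an invalid predecessor keep a missing lag (and therefore
    drop out of prev-score moderation fits, not of the primary model).
    """
    out = weekly.sort_values(["participant_id", "week_index"], kind="stable").copy()
    lag = out[["participant_id", "week_index", "valid", *_SCORE_COLS]].copy()
    lag["week_index"] = lag["week_index"] + 1
    for c in _SCORE_COLS:
        lag[c] = lag[c].where(lag["valid"] == 1)
    lag = lag.drop(columns="valid")
    lag.columns = ["participant_id", "week_index"] + [
        f"prev_{c}" for c in _SCORE_COLS
    ]
    out = out.merge(lag, on=["participant_id", "week_index"], how="left")
    if roster is not None:
        out = out.merge(
            roster[["participant_id", "group", "sex", "baseline_age"]],
            on="participant_id",
            how="left",
        )
    return out


def model_ready(
    weekly: pd.DataFrame, *, drop_zero_eligible: bool = False
) -> pd.DataFrame:
    """Rows usable for model fitting: valid weeks, optionally excluding
    weeks with no eligible days (zero randomization variance, relevant
    for centered fits)."""
    out = weekly[weekly["valid"] == 1]
    if drop_zero_eligible:
        out = out[out["eligible_days"] > 0]
    n_drop = len(weekly) - len(out)
    if n_drop:
        logger.info("model_ready: dropped %d of %d weeks", n_drop, len(weekly))
    return out.reset_index(drop=True)


class WeeklyAggregator:
    """Transformer-style wrapper: daily records -> model-ready weekly table.

    Parameters
    ----------
    start_weekday : weekday of study day 1 (default: read from data).
    drop_zero_eligible : exclude weeks whose last response fell on the
        window's first day (no randomization contrast).
    """

    def __init__(
        self, start_weekday: str | None = None, *, drop_zero_eligible: bool = False
    ) -> None:
        self.start_weekday = start_weekday
        self.drop_zero_eligible = drop_zero_eligible

    def get_params(self, deep: bool = True) -> dict:
        return {
            "start_weekday": self.start_weekday,
            "drop_zero_eligible": self.drop_zero_eligible,
        }

    def set_params(self, **params) -> "WeeklyAggregator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def transform(
        self, daily: pd.DataFrame, roster: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        weekly = build_weekly_table(daily, self.start_weekday)
        weekly = add_lagged_and_derived(weekly, roster)
        return model_ready(weekly, drop_zero_eligible=self.drop_zero_eligible)
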