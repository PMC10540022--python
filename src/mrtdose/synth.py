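"""Synthetic micro-randomized trial (MRT) generator with known ground truth.

Emulates a 90-day caregiver mobile-health trial: every participant-day a
prompt is randomized with probability ``p_rand`` (Bernoulli, independent
of history), a single survey item of a weekly, Monday-restarting
computer-adaptive test (CAT) may be answered, and wearable streams (step
count, sleep minutes) are recorded with missingness.  Health-related
quality-of-life (HRQOL) scores for three constructs — caregiver strain,
anxiety, depression — live on a T metric (population mean 50, SD 10) and
are generated on the natural-log scale, which guarantees positivity and
matches the right-skew the downstream log-linear analysis assumes.

The weekly latent log score for participant *i*, week *w* is

    z_iw = mu[outcome, group(i)] + b_i + gamma*w + beta[dose category(i,w)]
           + (dose x moderator interactions) + sigma_week * eps_iw

with b_i ~ N(0, sigma_subject^2) a participant random intercept.  The
weekly dose category (none / low / medium / high) is derived from the
realized prompt sequence with the same counting rule the analysis
applies: prompts from the week's first day through the day *before* the
last survey response of the week.  Daily provisional scores are the
weekly final score perturbed by noise that shrinks to zero at the last
response day, mimicking a CAT estimate sharpening as items accrue; only
the final response is used downstream.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

OUTCOMES = ("strain", "anxiety", "depression")
GROUPS = ("HD", "SCI", "HCT")
DOSE_LEVELS = ("low", "medium", "high")
WEEKDAYS = (
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
)

# dose count (0..6) -> index into (none, low, medium, high)
_COUNT_TO_CAT = np.array([0, 1, 1, 2, 2, 3, 3])


def _default_beta_dose() -> dict[str, tuple[float, float, float]]:
    # log-scale effects of (low, medium, high) weekly prompt frequency
    return {
        "strain": (-0.05, -0.08, -0.13),
        "anxiety": (-0.03, -0.08, -0.10),
        "depression": (-0.02, -0.04, -0.08),
    }


def _default_baseline() -> dict[str, dict[str, float]]:
    return {out: {g: math.log(50.0) for g in GROUPS} for out in OUTCOMES}


@dataclass
class SimConfig:
    """Full generative-model parameterization of a synthetic trial.

    Parameters
    ----------
    n_per_group
        Participants per caregiver group, ``{"HD": 11, "SCI": 10, "HCT": 15}``
        by default (36 total).
    n_days
        Length of home monitoring in days (default 90).
    p_rand
        Daily prompt randomization probability, in (0, 1).
    start_weekday
        Weekday of study day 1.  Weeks restart each Monday, so a
        non-Monday start creates a partial leading window.
    miss_survey, miss_steps, miss_sleep
        Independent daily missingness probabilities for the survey
        response, step count and sleep minutes.
    baseline_log_mean
        Log-scale intercept per outcome and group (default log 50); a
        scalar or per-outcome scalar is broadcast.
    sigma_subject, sigma_week, sigma_daily
        SDs on the log scale of the participant random intercept, the
        weekly noise, and the provisional daily-score perturbation.
    beta_dose
        True log-scale effects of (low, medium, high) weekly dose per
        outcome.
    gamma_week
        Linear week-in-study trend on the log scale, per outcome.
    moderator_effects
        Optional dose x moderator interaction coefficients.  Keys:
        ``"group"`` maps group -> outcome -> 3-tuple of additive effect
        shifts; ``"prev_score"`` (per T-score point above 50),
        ``"week"`` (per week), ``"steps"`` (per 1000 steps above
        ``steps_mean``) and ``"sleep"`` (per hour above
        ``sleep_mean_min``) map outcome -> 3-tuple of slopes.
    steps_mean, steps_log_sd
        Daily steps are log-normal with this mean and log-scale SD.
    sleep_mean_min, sleep_sd_min
        Daily sleep minutes are normal, truncated at 0.
    p_female, age_mean, age_sd
        Roster demographics; age is truncated below at 18 years.
    seed
        Root seed; the run is fully deterministic given it.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HD": 11, "SCI": 10, "HCT": 15}
    )
    n_days: int = 90
    p_rand: float = 0.5
    start_weekday: str = "Monday"
    miss_survey: float = 0.097
    miss_steps: float = 0.028
    miss_sleep: float = 0.142
    baseline_log_mean: dict[str, dict[str, float]] = field(
        default_factory=_default_baseline
    )
    sigma_subject: float = 0.15
    sigma_week: float = 0.12
    sigma_daily: float = 0.08
    beta_dose: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_beta_dose
    )
    gamma_week: dict[str, float] = field(
        default_factory=lambda: {out: 0.0 for out in OUTCOMES}
    )
    moderator_effects: dict | None = None
    steps_mean: float = 7802.9
    steps_log_sd: float = 0.5
    sleep_mean_min: float = 410.6
    sleep_sd_min: float = 60.0
    p_female: float = 28 / 36
    age_mean: float = 54.4
    age_sd: float = 13.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.baseline_log_mean, (int, float)):
            v = float(self.baseline_log_mean)
            self.baseline_log_mean = {out: {g: v for g in GROUPS} for out in OUTCOMES}
        else:
            norm: dict[str, dict[str, float]] = {}
            for out in OUTCOMES:
                val = self.baseline_log_mean[out]
                if isinstance(val, (int, float)):
                    norm[out] = {g: float(val) for g in GROUPS}
                else:
                    norm[out] = {g: float(val[g]) for g in GROUPS}
            self.baseline_log_mean = norm
        self.validate()

    def validate(self) -> None:
        for name in ("miss_survey", "miss_steps", "miss_sleep", "p_female"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        # p_rand = 1 is allowed for degenerate always-prompt scenarios,
        # though it leaves no randomization variance for centered fits
        if not (np.isfinite(self.p_rand) and 0.0 < self.p_rand <= 1.0):
            raise ValueError(f"p_rand must lie in (0, 1], got {self.p_rand!r}")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("n_per_group entries must be >= 0")
        if self.start_weekday not in WEEKDAYS:
            raise ValueError(f"start_weekday must be one of {WEEKDAYS}")
        for out in OUTCOMES:
            if out not in self.beta_dose or len(self.beta_dose[out]) != 3:
                raise ValueError(
                    f"beta_dose must map {out!r} to (low, medium, high) effects"
                )
            if not np.all(np.isfinite(self.beta_dose[out])):
                raise ValueError("beta_dose entries must be finite")
        for name in (
            "sigma_subject",
            "sigma_week",
            "sigma_daily",
            "steps_mean",
            "steps_log_sd",
            "sleep_mean_min",
            "sleep_sd_min",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def n_participants(self) -> int:
        return sum(self.n_per_group.values())

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def null_scenario(config: SimConfig) -> SimConfig:
    """Copy of *config* with every dose effect and interaction set to zero.

    Under the returned configuration the weekly score distribution does
    not depend on the realized dose category, which is the scenario used
    for type-I-error studies.
    """
    zero = {out: (0.0, 0.0, 0.0) for out in OUTCOMES}
    return config.replace(beta_dose=zero, moderator_effects=None)


def _dose_effect(
    config: SimConfig,
    outcome: str,
    group_idx: np.ndarray,
    cat: np.ndarray,
    week: int,
    prev_score: np.ndarray,
    mean_steps: np.ndarray,
    mean_sleep: np.ndarray,
) -> np.ndarray:
    """Per-participant treatment effect for one outcome and week.

    ``cat`` holds category indices 0..3 (0 = none); moderator values are
    centered at their configured reference points so the main ``beta``
    retains its marginal-at-reference interpretation.
    """
    beta = np.concatenate([[0.0], np.asarray(config.beta_dose[outcome], float)])
    eff = beta[cat].copy()
    mods: Mapping = config.moderator_effects or {}
    active = cat > 0
    if "group" in mods:
        for gi, g in enumerate(GROUPS):
            if g in mods["group"] and outcome in mods["group"][g]:
                delta = np.concatenate(
                    [[0.0], np.asarray(mods["group"][g][outcome], float)]
                )
                sel = group_idx == gi
                eff[sel] += delta[cat[sel]]
    for key, value, scale in (
        ("prev_score", prev_score - 50.0, 1.0),
        ("week", np.full_like(prev_score, float(week)), 1.0),
        ("steps", mean_steps - config.steps_mean, 1e-3),
        ("sleep", mean_sleep - config.sleep_mean_min, 1 / 60.0),
    ):
        if key in mods and outcome in mods[key]:
            eta = np.concatenate([[0.0], np.asarray(mods[key][outcome], float)])
            contrib = eta[cat] * np.nan_to_num(value, nan=0.0) * scale
            eff = eff + np.where(active, contrib, 0.0)
    return eff


def simulate_trial(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one trial.

    Returns
    -------
    roster : DataFrame
        One row per participant: ``participant_id``, ``group``, ``sex``,
        ``baseline_age``.
    daily : DataFrame
        One row per participant-day: ``participant_id``, ``day_index``
        (1-based), ``weekday``, ``message_sent``, ``survey_responded``,
        ``score_strain``, ``score_anxiety``, ``score_depression``
        (missing whenever no response), ``steps``, ``sleep_minutes``.
    ground_truth : dict
        Every coefficient used: dose effects, trends, intercepts,
        moderator interactions, noise SDs, subject intercepts, seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    groups = [g for g in GROUPS for _ in range(config.n_per_group.get(g, 0))]
    n = len(groups)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    group_idx = np.array([GROUPS.index(g) for g in groups], dtype=int)

    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    a = (18.0 - config.age_mean) / config.age_sd if config.age_sd > 0 else -np.inf
    ages = (
        stats.truncnorm.rvs(
            a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
        )
        if n and config.age_sd > 0
        else np.full(n, config.age_mean)
    )
    roster = pd.DataFrame(
        {
            "participant_id": ids,
            "group": groups,
            "sex": sex,
            "baseline_age": np.round(ages, 1),
        }
    )

    d = config.n_days
    ground_truth = {
        "beta_dose": {o: list(config.beta_dose[o]) for o in OUTCOMES},
        "gamma_week": dict(config.gamma_week),
        "baseline_log_mean": config.baseline_log_mean,
        "moderator_effects": config.moderator_effects,
        "sigma_subject": config.sigma_subject,
        "sigma_week": config.sigma_week,
        "sigma_daily": config.sigma_daily,
        "p_rand": config.p_rand,
        "seed": config.seed,
        "subject_intercepts": {},
    }
    empty = pd.DataFrame(
        columns=[
            "participant_id",
            "day_index",
            "weekday",
            "message_sent",
            "survey_responded",
            "score_strain",
            "score_anxiety",
            "score_depression",
            "steps",
            "sleep_minutes",
        ]
    )
    if n == 0:
        return roster, empty, ground_truth

    wd0 = WEEKDAYS.index(config.start_weekday)
    day_index = np.arange(1, d + 1)
    weekday_idx = (wd0 + day_index - 1) % 7
    week_of_day = (wd0 + day_index - 1) // 7  # 0-based week label per day

    message = (rng.random((n, d)) < config.p_rand).astype(np.int8)
    responded = (rng.random((n, d)) >= config.miss_survey).astype(np.int8)
    steps_missing = rng.random((n, d)) < config.miss_steps
    sleep_missing = rng.random((n, d)) < config.miss_sleep

    mu_steps = math.log(config.steps_mean) - config.steps_log_sd**2 / 2.0
    steps = np.round(rng.lognormal(mu_steps, config.steps_log_sd, (n, d)))
    sleep = np.maximum(
        0.0, rng.normal(config.sleep_mean_min, config.sleep_sd_min, (n, d))
    )
    steps_out = np.where(steps_missing, np.nan, steps)
    sleep_out = np.where(sleep_missing, np.nan, sleep)

    b_subj = rng.normal(0.0, config.sigma_subject, n)
    ground_truth["subject_intercepts"] = dict(zip(ids, np.round(b_subj, 6).tolist()))

    weeks = np.unique(week_of_day)
    scores = {out: np.full((n, d), np.nan) for out in OUTCOMES}
    base = {
        out: np.array([config.baseline_log_mean[out][g] for g in groups])
        for out in OUTCOMES
    }
    # previous week's latent weekly T score, per outcome (50 before week 1)
    prev_score = {out: np.full(n, 50.0) for out in OUTCOMES}

    for w in weeks:
        cols = np.where(week_of_day == w)[0]
        wlen = len(cols)
        week_label = w + 1  # 1-based week-in-study covariate
        resp = responded[:, cols].astype(bool)
        has_resp = resp.any(axis=1)
        # position (0-based within window) of the last response day
        last_pos = wlen - 1 - np.argmax(resp[:, ::-1], axis=1)
        last_pos = np.where(has_resp, last_pos, -1)
        msg_cum = np.concatenate(
            [np.zeros((n, 1), np.int64), np.cumsum(message[:, cols], axis=1)], axis=1
        )
        dose = np.where(has_resp, np.take_along_axis(
            msg_cum, np.maximum(last_pos, 0)[:, None], axis=1
        )[:, 0], 0)
        cat = _COUNT_TO_CAT[np.clip(dose, 0, 6)]
        cat = np.where(has_resp, cat, 0)

        wk_steps = np.nanmean(
            np.where(steps_missing[:, cols], np.nan, steps[:, cols]), axis=1
        ) if wlen else np.full(n, np.nan)
        wk_sleep = np.nanmean(
            np.where(sleep_missing[:, cols], np.nan, sleep[:, cols]), axis=1
        ) if wlen else np.full(n, np.nan)

        for out in OUTCOMES:
            eff = _dose_effect(
                config, out, group_idx, cat, week_label,
                prev_score[out], wk_steps, wk_sleep,
            )
            z = (
                base[out]
                + b_subj
                + config.gamma_week.get(out, 0.0) * week_label
                + eff
                + rng.normal(0.0, config.sigma_week, n)
            )
            # provisional daily scores shrink toward the final weekly score
            pos = np.arange(wlen)[None, :]
            gap = np.maximum(last_pos[:, None] - pos, 0)
            noise_sd = config.sigma_daily * gap / 7.0
            noise = rng.normal(0.0, 1.0, (n, wlen)) * noise_sd
            daily_log = z[:, None] + noise
            vals = np.where(resp, np.exp(daily_log), np.nan)
            scores[out][:, cols] = vals
            prev_score[out] = np.where(has_resp, np.exp(z), prev_score[out])

    daily = pd.DataFrame(
        {
            "participant_id": np.repeat(ids, d),
            "day_index": np.tile(day_index, n),
            "weekday": np.tile(np.array(WEEKDAYS)[weekday_idx], n),
            "message_sent": message.ravel(),
            "survey_responded": responded.ravel(),
            "score_strain": np.round(scores["strain"].ravel(), 4),
            "score_anxiety": np.round(scores["anxiety"].ravel(), 4),
            "score_depression": np.round(scores["depression"].ravel(), 4),
            "steps": steps_out.ravel(),
            "sleep_minutes": np.round(sleep_out.ravel(), 1),
        }
    )
    return roster, daily, ground_truth
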