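import numpy as np
import pandas as pd
import pytest

from mrtdose import SimConfig, WeeklyAggregator, simulate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One simulated trial at the study's own size (36 caregivers, 90 days)."""
    config = SimConfig(seed=20240901)
    roster, daily, truth = simulate_trial(config)
    return config, roster, daily, truth


@pytest.fixture(scope="session")
def weekly_table(default_trial):
    config, roster, daily, _ = default_trial
    return WeeklyAggregator(config.start_weekday).transform(daily, roster)


def make_week_window(
    responses, messages, weekdays=None, participant="P001", start_day=1
):
    """Hand-build one participant-week of daily records.

    ``responses`` and ``messages`` are sets of weekday names on which the
    survey was answered / a prompt was sent; the window runs Monday-Sunday.
    """
    names = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]
    if weekdays is None:
        weekdays = names
    rows = []
    for i, wd in enumerate(weekdays):
        responded = int(wd in responses)
        rows.append(
            {
                "participant_id": participant,
                "day_index": start_day + i,
                "weekday": wd,
                "message_sent": int(wd in messages),
                "survey_responded": responded,
                "score_strain": 50.0 + i if responded else np.nan,
                "score_anxiety": 48.0 + i if responded else np.nan,
                "score_depression": 52.0 + i if responded else np.nan,
                "steps": 8000.0,
                "sleep_minutes": 400.0,
            }
        )
    return pd.DataFrame(rows)
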