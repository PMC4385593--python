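"""Shared fixtures: simulation bundles and an independent brute-force
re-implementation of the alert rules used as a labelling oracle."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from elderwatch.config import SimulationConfig, stage_seed_int
from elderwatch.features import build_windows, prepare_dataset
from elderwatch.rules import label_windows
from elderwatch.simulate import inject_errors, simulate_all


@pytest.fixture()
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture()
def tiny_config() -> SimulationConfig:
    """12 users, ~3 months: quick but structurally complete."""
    return SimulationConfig.from_dict(
        {"n_users": 12, "start_date": "2014-03-01", "end_date": "2014-05-29", "seed": 42}
    )


@pytest.fixture(scope="session")
def sim_bundle() -> dict:
    """One full default run (50 users, 1 year): raw frames, labels, the
    initial windowed table before/after error injection, and the prepared
    modelling table.  Built once per session."""
    config = SimulationConfig()
    frames = simulate_all(config)
    labels = label_windows(
        frames["users"], frames["sessions"], frames["weather"], frames["calendar"]
    )
    windows = build_windows(
        frames["users"], frames["sessions"], frames["weather"], frames["calendar"], labels
    )
    corrupted, injection_log = inject_errors(windows, config)
    prepared = prepare_dataset(
        corrupted, seed=stage_seed_int(config.seed, "clustering")
    )
    return {
        "config": config,
        **frames,
        "labels": labels,
        "windows": windows,
        "corrupted": corrupted,
        "injection_log": injection_log,
        "prepared": prepared,
    }


# --------------------------------------------------------------------------
# brute-force labelling oracle (independent of elderwatch.rules internals)
# --------------------------------------------------------------------------


def brute_force_labels(users, sessions, weather, calendar) -> pd.DataFrame:
    """Plain-loop re-evaluation of the five alert rules over raw data.

    Written directly from the rule statements, sharing nothing with
    :func:`elderwatch.rules.label_windows` beyond the window convention
    (tumbling 3-day windows aligned to the calendar start).
    """
    cal_days = sorted(pd.Timestamp(d).date() for d in calendar["date"])
    start, end = cal_days[0], cal_days[-1]
    n_days = (end - start).days + 1
    n_win = -(-n_days // 3)
    weekendish = {
        pd.Timestamp(r["date"]).date(): bool(r["is_weekend"]) or bool(r["is_holiday"])
        for _, r in calendar.iterrows()
    }
    weekend_only = {
        pd.Timestamp(r["date"]).date(): bool(r["is_weekend"]) for _, r in calendar.iterrows()
    }
    wx = {
        pd.Timestamp(r["date"]).date(): (r["temp_max"], r["condition"])
        for _, r in weather.iterrows()
    }

    rows = []
    for _, user in users.iterrows():
        u_sessions = sessions[sessions["user_id"] == user["user_id"]]
        sess = [
            (pd.Timestamp(s["start"]), int(s["duration_min"]))
            for _, s in u_sessions.iterrows()
        ]
        alert_windows: dict[int, set[str]] = {}

        def widx_of(day: date) -> int:
            return (day - start).days // 3

        # R1: no access over a 3-day window of plain weekdays, high/average
        if user["profile"] in ("high", "average"):
            for w in range(n_win):
                days = [start + timedelta(days=3 * w + k) for k in range(3)]
                if days[-1] > end:
                    continue
                if any(weekendish[d] for d in days):
                    continue
                if any(t.date() in days for t, _ in sess):
                    continue
                alert_windows.setdefault(w, set()).add("R1")

        for t, dur in sess:
            day = t.date()
            # R2: 70-80, alone, night start, > 3 h
            if (
                70 <= user["age"] <= 80
                and user["marital_status"] in ("divorced", "widowed", "single")
                and (t.hour >= 23 or t.hour < 7)
                and dur > 180
            ):
                alert_windows.setdefault(widx_of(day), set()).add("R2")
            # R3: married, over 70 strict, > 3 h
            if user["age"] > 70 and user["marital_status"] == "married" and dur > 180:
                alert_windows.setdefault(widx_of(day), set()).add("R3")
            # R4: mild clear-ish day, > 3 h
            if day in wx:
                temp, cond = wx[day]
                if (
                    15 <= temp <= 30
                    and cond in ("Clear", "Partly Cloudy", "Scattered Clouds")
                    and dur > 180
                ):
                    alert_windows.setdefault(widx_of(day), set()).add("R4")

        # R5: >=3 consecutive accessed weekends then a miss
        saturdays = [d for d in cal_days if d.weekday() == 5]
        session_days = {t.date() for t, _ in sess}
        run = 0
        for sat in saturdays:
            sun = sat + timedelta(days=1)
            if sat in session_days or sun in session_days:
                run += 1
            else:
                if run >= 3:
                    alert_windows.setdefault(widx_of(sat), set()).add("R5")
                run = 0

        for w in range(n_win):
            fired = sorted(alert_windows.get(w, ()))
            rows.append(
                {
                    "user_id": user["user_id"],
                    "window_start": start + timedelta(days=3 * w),
                    "is_alert": bool(fired),
                    "fired_rules": ";".join(fired),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def label_oracle():
    return brute_force_labels
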