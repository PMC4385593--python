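"""Ground-truth alert rules and window labelling.

Five hand-crafted distress rules define what counts as an alert in the
synthetic study; the data-mining stages later try to rediscover them:

* **R1** — a high- or average-profile user makes no access during a 3-day
  window none of whose days is a weekend or holiday.
* **R2** — a divorced/widowed/single user aged 70–80 (inclusive) has a
  night access (start in 23:00–07:00) longer than 3 hours.
* **R3** — a married user older than 70 (strict) has an access longer than
  3 hours.
* **R4** — an access longer than 3 hours on a pleasant day: daily maximum
  temperature in [15, 30] °C and sky clear, partly cloudy or with
  scattered clouds.
* **R5** — a user accesses the platform on three or more consecutive
  weekends and then misses the next one.

Labels are attached to tumbling (non-overlapping) 3-day windows aligned to
the simulation start date; a window is an alert iff at least one rule event
falls inside it.  R1's no-access gap is identified with the tumbling window
itself, so one user-year of 363 days yields exactly 121 labelled windows.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

NIGHT_MARITAL = frozenset({"divorced", "widowed", "single"})
NICE_CONDITIONS = frozenset({"Clear", "Partly Cloudy", "Scattered Clouds"})
MARATHON_MINUTES = 180  # "over 3 hours", strict
RULE_CODES = ("R1", "R2", "R3", "R4", "R5")


def _start_hour(session: Mapping) -> int:
    return pd.Timestamp(session["start"]).hour


def rule1_no_access(user: Mapping, window_days: pd.DataFrame, sessions: pd.DataFrame) -> bool:
    """R1: zero sessions over 3 consecutive ordinary weekdays, for a user
    whose usage profile is high or average.

    ``window_days`` must be a 3-row calendar slice (columns ``date,
    is_weekend, is_holiday``); ``sessions`` the user's sessions starting in
    the window.
    """
    if len(window_days) != 3:
        raise ValueError("rule 1 window must have exactly 3 consecutive days")
    days = sorted(pd.Timestamp(d).date() for d in window_days["date"])
    if days[1] - days[0] != timedelta(days=1) or days[2] - days[1] != timedelta(days=1):
        raise ValueError("rule 1 window days must be consecutive")
    if user["profile"] not in ("high", "average"):
        return False
    if bool(window_days["is_weekend"].any()) or bool(window_days["is_holiday"].any()):
        return False
    return len(sessions) == 0


def rule2_night_marathon(user: Mapping, session: Mapping) -> bool:
    """R2: long night access by a 70–80 year-old living alone."""
    if not (70 <= user["age"] <= 80):
        return False
    if user["marital_status"] not in NIGHT_MARITAL:
        return False
    hour = _start_hour(session)
    if not (hour >= 23 or hour < 7):
        return False
    return session["duration_min"] > MARATHON_MINUTES


def rule3_married_marathon(user: Mapping, session: Mapping) -> bool:
    """R3: long access by a married user strictly older than 70."""
    return (
        user["age"] > 70
        and user["marital_status"] == "married"
        and session["duration_min"] > MARATHON_MINUTES
    )


def rule4_nice_day_marathon(weather: Mapping | None, session: Mapping) -> bool:
    """R4: long access on a mild, clear-ish day.

    The day's temperature is taken as its maximum (the afternoon shell
    value).  If the day's weather is unavailable the rule abstains.
    """
    if weather is None:
        return False
    temp = weather["temp_max"]
    if pd.isna(temp) or not (15 <= temp <= 30):
        return False
    if weather["condition"] not in NICE_CONDITIONS:
        return False
    return session["duration_min"] > MARATHON_MINUTES


def rule5_missed_weekend(sessions: pd.DataFrame, calendar: pd.DataFrame) -> set[date]:
    """R5: alert dates (the missed weekend's Saturday) for every run of >=3
    consecutive accessed weekends followed by one with zero sessions.

    A weekend counts as accessed iff at least one session starts on its
    Saturday or Sunday.
    """
    cal_dates = sorted(pd.Timestamp(d).date() for d in calendar["date"])
    saturdays = [d for d in cal_dates if d.weekday() == 5]
    if not saturdays:
        return set()
    session_days = set()
    if len(sessions):
        session_days = {pd.Timestamp(t).date() for t in sessions["start"]}

    alerts: set[date] = set()
    run = 0
    for sat in saturdays:
        accessed = sat in session_days or (sat + timedelta(days=1)) in session_days
        if accessed:
            run += 1
        else:
            if run >= 3:
                alerts.add(sat)
            run = 0
    return alerts


def window_index(day: date, start: date) -> int:
    """Tumbling 3-day window index of a day relative to the range start."""
    return (day - start).days // 3


def window_starts(start: date, end: date) -> list[date]:
    n_days = (end - start).days + 1
    n_win = -(-n_days // 3)
    return [start + timedelta(days=3 * i) for i in range(n_win)]


def label_windows(
    users: pd.DataFrame,
    sessions: pd.DataFrame,
    weather: pd.DataFrame,
    calendar: pd.DataFrame,
) -> pd.DataFrame:
    """Label every user x tumbling 3-day window with the five alert rules.

    Returns columns ``user_id, window_start, is_alert, fired_rules`` (the
    fired rule codes semicolon-joined, empty when none).  The date range is
    taken from the calendar, which must cover the sessions.
    """
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"]).dt.date
    start, end = min(cal["date"]), max(cal["date"])
    starts = window_starts(start, end)
    n_win = len(starts)

    if len(sessions):
        s_days = pd.to_datetime(sessions["start"]).dt.date
        if s_days.min() < start or s_days.max() > end:
            raise ValueError("calendar does not cover the session date range")

    # per-window R1 eligibility: exactly 3 in-range days, none weekend/holiday
    cal_by_date = cal.set_index("date")
    window_plain = np.zeros(n_win, dtype=bool)
    for i, ws in enumerate(starts):
        days = [ws + timedelta(days=k) for k in range(3)]
        if days[-1] > end:
            continue
        rows = cal_by_date.loc[days]
        window_plain[i] = not (rows["is_weekend"].any() or rows["is_holiday"].any())

    # session-level predicates, vectorised
    if len(sessions):
        sess = sessions.merge(
            users[["user_id", "age", "marital_status", "profile"]], on="user_id", how="left"
        )
        sess["day"] = pd.to_datetime(sess["start"]).dt.date
        wx = weather.copy()
        wx["day"] = pd.to_datetime(wx["date"]).dt.date
        sess = sess.merge(
            wx[["day", "temp_max", "condition"]], on="day", how="left"
        )
        hour = pd.to_datetime(sess["start"]).dt.hour
        dur = sess["duration_min"]
        night = (hour >= 23) | (hour < 7)
        sess["r2"] = (
            sess["age"].between(70, 80)
            & sess["marital_status"].isin(NIGHT_MARITAL)
            & night
            & (dur > MARATHON_MINUTES)
        )
        sess["r3"] = (
            (sess["age"] > 70)
            & (sess["marital_status"] == "married")
            & (dur > MARATHON_MINUTES)
        )
        sess["r4"] = (
            sess["temp_max"].between(15, 30)
            & sess["condition"].isin(NICE_CONDITIONS)
            & (dur > MARATHON_MINUTES)
        )
        sess["widx"] = [(d - start).days // 3 for d in sess["day"]]
    else:
        sess = pd.DataFrame(
            columns=["user_id", "widx", "r2", "r3", "r4", "day", "start", "duration_min"]
        )

    records: list[dict] = []
    sess_by_user = dict(tuple(sess.groupby("user_id"))) if len(sess) else {}
    for user in users.itertuples(index=False):
        u_sess = sess_by_user.get(user.user_id)
        fired_by_window: dict[int, set[str]] = {}

        if u_sess is not None and len(u_sess):
            grouped = u_sess.groupby("widx")[["r2", "r3", "r4"]].any()
            counts = u_sess.groupby("widx").size()
            for widx, row in grouped.iterrows():
                fired = fired_by_window.setdefault(int(widx), set())
                for code, flag in (("R2", row["r2"]), ("R3", row["r3"]), ("R4", row["r4"])):
                    if flag:
                        fired.add(code)
        else:
            counts = pd.Series(dtype=int)

        if user.profile in ("high", "average"):
            for i in range(n_win):
                if window_plain[i] and counts.get(i, 0) == 0:
                    fired_by_window.setdefault(i, set()).add("R1")

        u_sess_frame = u_sess if u_sess is not None else sess.iloc[0:0]
        for sat in rule5_missed_weekend(u_sess_frame, cal):
            widx = (sat - start).days // 3
            fired_by_window.setdefault(widx, set()).add("R5")

        for i, ws in enumerate(starts):
            fired = sorted(fired_by_window.get(i, ()))
            records.append(
                {
                    "user_id": user.user_id,
                    "window_start": ws,
                    "is_alert": bool(fired),
                    "fired_rules": ";".join(fired),
                }
            )

    return pd.DataFrame.from_records(
        records, columns=["user_id", "window_start", "is_alert", "fired_rules"]
    )
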