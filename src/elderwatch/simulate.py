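"""Synthetic cohort, session, weather and calendar generation.

The simulator emulates one year of platform use by an elderly cohort:

* **users** — ages normal around 75 (sd 10, truncated at 18, integer
  years), marital status drawn from the five-category mixture
  (30/50/10/8/2 %), a residence district, and one of three usage profiles
  (low/average/high) allocated by exact quota (20/50/30 %).
* **sessions** — per-day Poisson counts with a profile-specific rate;
  log-normal durations with an occasional uniform "marathon" tail; start
  hours from a daytime weight vector with a small night (23:00–07:00)
  component.  Sessions of one user never overlap.
* **weather** — one observation per day: seasonal daily maximum
  temperature, a diurnal minimum, bounded humidity, and a directly
  simulated sky-condition category.
* **calendar** — weekend flags by weekday arithmetic plus an injectable
  holiday list.
* **inject_errors** — sprinkles sentinel outliers (-9999 temperature,
  100 humidity) into the windowed table, mimicking the corrupted fields a
  real feed would deliver.

All functions are pure given a :class:`~elderwatch.config.SimulationConfig`
(the master seed fully determines every output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .config import (
    MARITAL_CATEGORIES,
    PROFILE_CATEGORIES,
    ConfigurationError,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

USER_COLUMNS = ["user_id", "age", "marital_status", "district", "profile"]
SESSION_COLUMNS = ["user_id", "start", "duration_min"]
WEATHER_COLUMNS = ["date", "temp_min", "temp_max", "humidity_min", "humidity_max", "condition"]
CALENDAR_COLUMNS = ["date", "is_weekend", "is_holiday"]


def _quota_allocate(n: int, fractions: dict[str, float], order: tuple[str, ...]) -> list[str]:
    """Largest-remainder allocation of n items to categories (deterministic)."""
    exact = {k: n * fractions[k] for k in order}
    counts = {k: int(np.floor(exact[k])) for k in order}
    short = n - sum(counts.values())
    by_rem = sorted(order, key=lambda k: (-(exact[k] - counts[k]), order.index(k)))
    for k in by_rem[:short]:
        counts[k] += 1
    out: list[str] = []
    for k in order:
        out.extend([k] * counts[k])
    return out


def generate_users(config: SimulationConfig) -> pd.DataFrame:
    """Generate the user cohort.

    Returns a frame with columns ``user_id, age, marital_status, district,
    profile``.  Ages are integer years >= ``age_min``; marital status and
    district are sampled; profiles are allocated by exact quota and then
    shuffled over users so profile is independent of age and marital status.
    """
    config.validate()
    n = config.n_users
    rng = config.rng("users")
    demo = config.demographics

    ages = np.rint(rng.normal(demo.age_mean, demo.age_sd, size=n)).astype(int)
    ages = np.clip(ages, demo.age_min, None)

    marital = rng.choice(
        MARITAL_CATEGORIES,
        size=n,
        p=[demo.marital_fractions[k] for k in MARITAL_CATEGORIES],
    )
    district = rng.choice(demo.districts, size=n)

    profiles = np.array(_quota_allocate(n, dict(config.profiles.fractions), PROFILE_CATEGORIES))
    rng.shuffle(profiles)

    width = max(3, len(str(max(n, 1))))
    return pd.DataFrame(
        {
            "user_id": [f"u{i:0{width}d}" for i in range(1, n + 1)],
            "age": ages,
            "marital_status": marital,
            "district": district,
            "profile": profiles,
        }
    )


def generate_sessions(users: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Generate non-overlapping access sessions for every user.

    Columns: ``user_id, start, duration_min`` with minute-resolution starts
    inside the configured date range and integer durations >= 1.
    """
    config.validate()
    if config.end_date < config.start_date:
        raise ConfigurationError("end_date must not precede start_date")
    rng = config.rng("sessions")
    prof = config.profiles
    n_days = config.n_days
    range_start = datetime.combine(config.start_date, datetime.min.time())
    range_end = range_start + timedelta(days=n_days)

    day_hours = np.arange(7, 23)
    day_w = np.asarray(prof.day_hour_weights, dtype=float)
    day_w = day_w / day_w.sum()
    night_hours = np.array([23, 0, 1, 2, 3, 4, 5, 6])

    frames: list[pd.DataFrame] = []
    # users iterated in frame order; per-user draws come from one stage rng,
    # so output is deterministic for a given cohort + seed
    for row in users.itertuples(index=False):
        p = row.profile
        rate = prof.session_rate[p]
        counts = rng.poisson(rate, size=n_days)
        total = int(counts.sum())
        if total == 0:
            continue
        day_idx = np.repeat(np.arange(n_days), counts)

        is_night = rng.random(total) < prof.night_prob[p]
        hours = np.where(
            is_night,
            rng.choice(night_hours, size=total),
            rng.choice(day_hours, size=total, p=day_w),
        )
        minutes = rng.integers(0, 60, size=total)

        is_marathon = rng.random(total) < prof.marathon_prob[p]
        base = rng.lognormal(np.log(prof.duration_median[p]), prof.duration_sigma, size=total)
        marathon = rng.uniform(prof.marathon_min, prof.marathon_max, size=total)
        durations = np.where(is_marathon, marathon, base)
        durations = np.maximum(1, np.rint(durations)).astype(int)

        starts = np.array(
            [
                range_start + timedelta(days=int(d), hours=int(h), minutes=int(m))
                for d, h, m in zip(day_idx, hours, minutes)
            ]
        )
        order = np.argsort(starts, kind="stable")
        starts, durations = starts[order], durations[order]

        # resolve overlaps by pushing a session to one minute past the
        # previous session's end; drop anything pushed out of the range
        keep_start: list[datetime] = []
        keep_dur: list[int] = []
        prev_end: datetime | None = None
        for s, dur in zip(starts, durations):
            if prev_end is not None and s <= prev_end:
                s = prev_end + timedelta(minutes=1)
            if s >= range_end:
                continue
            keep_start.append(s)
            keep_dur.append(int(dur))
            prev_end = s + timedelta(minutes=int(dur))
        if keep_start:
            frames.append(
                pd.DataFrame(
                    {
                        "user_id": row.user_id,
                        "start": pd.to_datetime(keep_start),
                        "duration_min": keep_dur,
                    }
                )
            )

    if not frames:
        return pd.DataFrame(columns=SESSION_COLUMNS).astype(
            {"user_id": object, "start": "datetime64[ns]", "duration_min": int}
        )
    return pd.concat(frames, ignore_index=True)


def generate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Generate one weather observation per day of the configured range."""
    config.validate()
    rng = config.rng("weather")
    w = config.weather
    dates = pd.to_datetime(config.dates())
    n = len(dates)

    doy = dates.dayofyear.to_numpy()
    seasonal = w.temp_base + w.temp_amplitude * np.sin(
        2 * np.pi * (doy - (w.peak_doy - 91)) / 365.25
    )
    temp_max = seasonal + rng.normal(0.0, w.temp_sd, size=n)
    temp_min = temp_max - rng.uniform(*w.diurnal_range, size=n)

    humidity_min = rng.uniform(*w.humidity_min_range, size=n)
    humidity_max = humidity_min + rng.uniform(*w.humidity_spread, size=n)

    labels = list(w.condition_probs)
    condition = rng.choice(labels, size=n, p=[w.condition_probs[k] for k in labels])

    return pd.DataFrame(
        {
            "date": dates.date,
            "temp_min": np.round(temp_min, 1),
            "temp_max": np.round(temp_max, 1),
            "humidity_min": np.round(humidity_min, 1),
            "humidity_max": np.round(humidity_max, 1),
            "condition": condition,
        }
    )


def build_calendar(config: SimulationConfig) -> pd.DataFrame:
    """Weekend/holiday flags for every day of the configured range."""
    config.validate()
    dates = config.dates()
    holidays = set(config.holidays)
    return pd.DataFrame(
        {
            "date": dates,
            "is_weekend": [d.weekday() >= 5 for d in dates],
            "is_holiday": [d in holidays for d in dates],
        }
    )


@dataclass
class InjectionLog:
    """Provenance record of sentinel-outlier injection."""

    temperature_injected: int = 0
    humidity_injected: int = 0

    @property
    def total(self) -> int:
        return self.temperature_injected + self.humidity_injected


TEMPERATURE_FIELDS = ("temperature_max", "temperature_min")
HUMIDITY_FIELDS = ("humidity_max", "humidity_min")


def inject_errors(
    windows: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, InjectionLog]:
    """Replace a configured fraction of weather fields with sentinel outliers.

    Operates on the windowed table (columns ``temperature_max/min``,
    ``humidity_max/min``); each field of each record is independently hit
    with the configured rate.  Returns a copy plus an :class:`InjectionLog`.
    """
    err = config.errors
    err.validate()
    rng = config.rng("errors")
    out = windows.copy()
    log = InjectionLog()
    for col in TEMPERATURE_FIELDS:
        if col in out.columns and len(out):
            mask = rng.random(len(out)) < err.temperature_rate
            out.loc[mask, col] = err.temperature_sentinel
            log.temperature_injected += int(mask.sum())
    for col in HUMIDITY_FIELDS:
        if col in out.columns and len(out):
            mask = rng.random(len(out)) < err.humidity_rate
            out.loc[mask, col] = err.humidity_sentinel
            log.humidity_injected += int(mask.sum())
    logger.info(
        "inject_errors: %d temperature and %d humidity fields replaced",
        log.temperature_injected,
        log.humidity_injected,
    )
    return out, log


def simulate_all(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run the full simulation stage; returns users/sessions/weather/calendar."""
    users = generate_users(config)
    return {
        "users": users,
        "sessions": generate_sessions(users, config),
        "weather": generate_weather(config),
        "calendar": build_calendar(config),
    }
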