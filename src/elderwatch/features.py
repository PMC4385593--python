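"""Windowed feature construction, cleaning, derivation and discretisation.

``build_windows`` aggregates sessions and weather into one record per user
per tumbling 3-day window (the *initial* dataset).  The preparation steps
then mirror a conventional data-preparation phase:

* ``clean_outliers`` blanks the sentinel outliers (-9999 temperature,
  100 humidity) rather than imputing them;
* ``derive_atmospheric_conditions`` combines a temperature band (rt) and a
  sky-condition band (rh) into the ordinal score ac = rt + rh in {0..4};
* ``assign_profiles`` clusters users into low/average/high usage by their
  mean offline time (seeded k-means, k=3, clusters ordered by centre);
* ``discretize`` bins session times into 30-minute bands, offline times
  into 12-hour bands and age into the empirical bands
  (-inf,65], (65,80], (80,90], (90,inf), drops the identifier-like columns
  (surrogate key, district, alert date) and emits the *prepared* dataset.

Raw ``age`` and ``time_session_max`` are kept alongside their bands so
that threshold rules such as ``time_session_max >= 180 & age > 70`` remain
exactly expressible.
"""

from __future__ import annotations

import logging
from datetime import date, timedelta
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .rules import window_starts

logger = logging.getLogger(__name__)

TEMPERATURE_SENTINEL = -9999.0
HUMIDITY_SENTINEL = 100.0

INITIAL_COLUMNS = [
    "surrogate_key",
    "user_id",
    "window_start",
    "age",
    "district",
    "marital_status",
    "alert_date",
    "num_accesses",
    "num_accesses_holidays_weekends",
    "num_accesses_morning",
    "time_session_max",
    "time_session_min",
    "time_offline_max",
    "time_offline_min",
    "temperature_max",
    "temperature_min",
    "humidity_max",
    "humidity_min",
    "condition",
    "is_alert",
]

PREPARED_COLUMNS = [
    "age",
    "age_band",
    "marital_status",
    "num_accesses",
    "num_accesses_holidays_weekends",
    "num_accesses_morning",
    "time_session_max",
    "time_session_max_band",
    "time_session_min_band",
    "time_offline_max_band",
    "time_offline_min_band",
    "atmospheric_conditions",
    "profile",
    "profile_code",
    "is_alert",
]

PROFILE_CODES = {"low": 0, "average": 1, "high": 2}

AGE_EDGES = (65, 80, 90)
SESSION_BAND_MINUTES = 30
OFFLINE_BAND_MINUTES = 720


class DegenerateClusteringError(ValueError):
    """Raised when profile clustering cannot form k distinct clusters."""


def build_windows(
    users: pd.DataFrame,
    sessions: pd.DataFrame,
    weather: pd.DataFrame,
    calendar: pd.DataFrame,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate raw simulation outputs into the initial windowed dataset.

    One record per user per tumbling 3-day window, with session aggregates
    computed over sessions *starting* in the window, weather extrema over
    the window's days, and the alert label joined from ``labels``.
    Offline times are the gaps between the window edges and its session
    intervals (a session running past the window end is clipped); a window
    with no sessions is fully offline.
    """
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"]).dt.date
    start, end = min(cal["date"]), max(cal["date"])
    starts = window_starts(start, end)
    label_key = {
        (row.user_id, pd.Timestamp(row.window_start).date()): (row.is_alert, row.fired_rules)
        for row in labels.itertuples(index=False)
    }

    holiday_or_weekend = {
        d: (we or ho)
        for d, we, ho in zip(cal["date"], cal["is_weekend"], cal["is_holiday"])
    }

    wx = weather.copy()
    wx["day"] = pd.to_datetime(wx["date"]).dt.date
    wx_by_day = wx.set_index("day")

    if len(sessions):
        sess = sessions.copy()
        sess["start"] = pd.to_datetime(sess["start"])
        sess["day"] = sess["start"].dt.date
        sess["widx"] = [(d - start).days // 3 for d in sess["day"]]
        sess_groups = dict(tuple(sess.groupby(["user_id", "widx"])))
    else:
        sess_groups = {}

    records = []
    for user in users.itertuples(index=False):
        for widx, ws in enumerate(starts):
            w_end_date = min(ws + timedelta(days=3), end + timedelta(days=1))
            w_days = [ws + timedelta(days=k) for k in range((w_end_date - ws).days)]
            span_min = len(w_days) * 1440
            w_start_ts = pd.Timestamp(ws)
            w_end_ts = pd.Timestamp(w_end_date)

            g = sess_groups.get((user.user_id, widx))
            if g is not None and len(g):
                durs = g["duration_min"]
                n_acc = len(g)
                n_hw = int(sum(holiday_or_weekend.get(d, False) for d in g["day"]))
                hours = g["start"].dt.hour
                n_morning = int(((hours >= 7) & (hours < 12)).sum())
                ts_max, ts_min = int(durs.max()), int(durs.min())
                iv = sorted(
                    (s, min(s + pd.Timedelta(minutes=int(d)), w_end_ts))
                    for s, d in zip(g["start"], durs)
                )
                gaps = []
                cursor = w_start_ts
                for s, e in iv:
                    gaps.append((s - cursor).total_seconds() / 60.0)
                    cursor = max(cursor, e)
                gaps.append(max(0.0, (w_end_ts - cursor).total_seconds() / 60.0))
                gaps = [g_ for g_ in gaps if g_ >= 0]
                off_max, off_min = float(max(gaps)), float(min(gaps))
            else:
                n_acc = n_hw = n_morning = 0
                ts_max = ts_min = np.nan
                off_max = off_min = float(span_min)

            w_wx = wx_by_day.loc[[d for d in w_days if d in wx_by_day.index]]
            if len(w_wx):
                t_max = float(w_wx["temp_max"].max())
                t_min = float(w_wx["temp_min"].min())
                h_max = float(w_wx["humidity_max"].max())
                h_min = float(w_wx["humidity_min"].min())
                condition = w_wx.loc[w_wx["temp_max"].idxmax(), "condition"]
            else:
                t_max = t_min = h_max = h_min = np.nan
                condition = None

            try:
                is_alert, fired = label_key[(user.user_id, ws)]
            except KeyError:
                raise ValueError(
                    f"missing label for user {user.user_id} window {ws}"
                ) from None

            records.append(
                {
                    "surrogate_key": f"{user.user_id}-w{widx:03d}",
                    "user_id": user.user_id,
                    "window_start": ws,
                    "age": int(user.age),
                    "district": user.district,
                    "marital_status": user.marital_status,
                    "alert_date": ws if is_alert else None,
                    "num_accesses": n_acc,
                    "num_accesses_holidays_weekends": n_hw,
                    "num_accesses_morning": n_morning,
                    "time_session_max": ts_max,
                    "time_session_min": ts_min,
                    "time_offline_max": off_max,
                    "time_offline_min": off_min,
                    "temperature_max": t_max,
                    "temperature_min": t_min,
                    "humidity_max": h_max,
                    "humidity_min": h_min,
                    "condition": condition,
                    "is_alert": int(bool(is_alert)),
                }
            )

    return pd.DataFrame.from_records(records, columns=INITIAL_COLUMNS)


def clean_outliers(records: pd.DataFrame) -> pd.DataFrame:
    """Replace sentinel outliers with missing values (idempotent).

    Temperature fields equal to -9999 and humidity fields equal to 100 are
    blanked; everything else is untouched.  Replacement counts are logged
    and stored in ``df.attrs['cleaned_counts']``.
    """
    out = records.copy()
    counts: dict[str, int] = {}
    for col in ("temperature_max", "temperature_min"):
        if col in out.columns:
            mask = out[col] == TEMPERATURE_SENTINEL
            counts[col] = int(mask.sum())
            out.loc[mask, col] = np.nan
    for col in ("humidity_max", "humidity_min"):
        if col in out.columns:
            mask = out[col] == HUMIDITY_SENTINEL
            counts[col] = int(mask.sum())
            out.loc[mask, col] = np.nan
    out.attrs["cleaned_counts"] = counts
    logger.info("clean_outliers: replaced %s", counts)
    return out


def derive_atmospheric_conditions(temp, condition):
    """ac = rt + rh, an ordinal 0–4 weather-pleasantness score.

    rt: 0 below 15 °C, 1 in [15, 30], 2 above 30.  rh: 0 for rainy
    conditions, 2 for clear-ish ones, 1 otherwise.  Missing temperature or
    condition propagates to a missing ac.  Accepts scalars or Series.
    """
    scalar = np.isscalar(temp) or temp is None or isinstance(temp, float)
    t = pd.Series([temp]) if scalar else pd.Series(temp).astype(float)
    c = pd.Series([condition]) if scalar else pd.Series(condition)

    rt = pd.Series(np.select([t < 15, t <= 30, t > 30], [0, 1, 2], default=np.nan), index=t.index)
    rt[t.isna()] = np.nan
    rainy = c.isin(["Rain", "Light Rain Showers"])
    nice = c.isin(["Partly Cloudy", "Scattered Clouds", "Clear"])
    rh = pd.Series(np.where(rainy, 0.0, np.where(nice, 2.0, 1.0)), index=c.index)
    rh[c.isna()] = np.nan

    ac = rt + rh
    if scalar:
        v = ac.iloc[0]
        return float(v) if pd.notna(v) else np.nan
    return ac


def assign_profiles(records: pd.DataFrame, k: int = 3, seed: int = 0) -> pd.Series:
    """Cluster users into usage profiles by mean offline time.

    Fits seeded k-means (k=3, multiple restarts) to the per-user mean of
    ``time_offline_max``; clusters are ordered by centre so the *lowest*
    offline time is labelled ``high`` usage, then ``average``, then
    ``low``.  Fitting on sorted values makes assignments invariant to
    record order.  Returns a Series indexed by user_id.
    """
    per_user = records.groupby("user_id")["time_offline_max"].mean().sort_index()
    values = per_user.to_numpy(dtype=float).reshape(-1, 1)
    if np.unique(values).size < k:
        raise DegenerateClusteringError(
            f"need at least {k} distinct per-user offline means, got {np.unique(values).size}"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    km.fit(np.sort(values, axis=0))
    assignment = km.predict(values)
    order = np.argsort(km.cluster_centers_.ravel())  # ascending offline time
    if k == 3:
        names = ["high", "average", "low"]
    else:
        names = [f"cluster{i}" for i in range(k)]
    label_of = {int(cluster): names[rank] for rank, cluster in enumerate(order)}
    return pd.Series(
        [label_of[int(a)] for a in assignment], index=per_user.index, name="profile"
    )


def _band_label(x: float, width: int) -> str:
    lo = int(width * np.floor(x / width))
    return f"[{lo},{lo + width})"


def _band_series(values: pd.Series, width: int) -> pd.Series:
    """Half-open fixed-width bands as an ordered categorical."""
    out = values.map(lambda x: _band_label(float(x), width) if pd.notna(x) else np.nan)
    observed = sorted(
        {v for v in out.dropna()}, key=lambda s: int(s[1:].split(",")[0])
    )
    return pd.Series(
        pd.Categorical(out, categories=observed, ordered=True), index=values.index
    )


def age_band(age) -> str:
    """Empirical age bands (-inf,65], (65,80], (80,90], (90,inf)."""
    a, b, c = AGE_EDGES
    if age <= a:
        return f"<={a}"
    if age <= b:
        return f"({a},{b}]"
    if age <= c:
        return f"({b},{c}]"
    return f">{c}"


AGE_BAND_ORDER = ("<=65", "(65,80]", "(80,90]", ">90")


def discretize(records: pd.DataFrame, profiles: pd.Series) -> pd.DataFrame:
    """Produce the prepared modelling table from cleaned windowed records.

    Drops surrogate key, user id, window start, district, alert date and
    raw weather columns; bins times and age; attaches ac, the clustered
    profile (with a numeric code low=0/average=1/high=2) and the 0/1 alert
    flag.
    """
    df = records.copy()
    ac = derive_atmospheric_conditions(df["temperature_max"], df["condition"])
    prof = df["user_id"].map(profiles)
    if prof.isna().any():
        missing = sorted(df.loc[prof.isna(), "user_id"].unique())
        raise ValueError(f"no profile assignment for users {missing}")

    out = pd.DataFrame(
        {
            "age": df["age"].astype(int),
            "age_band": pd.Categorical(
                df["age"].map(age_band), categories=list(AGE_BAND_ORDER), ordered=True
            ),
            "marital_status": df["marital_status"],
            "num_accesses": df["num_accesses"].astype(int),
            "num_accesses_holidays_weekends": df["num_accesses_holidays_weekends"].astype(int),
            "num_accesses_morning": df["num_accesses_morning"].astype(int),
            "time_session_max": df["time_session_max"].astype(float),
            "time_session_max_band": _band_series(df["time_session_max"], SESSION_BAND_MINUTES),
            "time_session_min_band": _band_series(df["time_session_min"], SESSION_BAND_MINUTES),
            "time_offline_max_band": _band_series(df["time_offline_max"], OFFLINE_BAND_MINUTES),
            "time_offline_min_band": _band_series(df["time_offline_min"], OFFLINE_BAND_MINUTES),
            "atmospheric_conditions": ac.astype(float),
            "profile": prof.to_numpy(),
            "profile_code": prof.map(PROFILE_CODES).astype(int).to_numpy(),
            "is_alert": df["is_alert"].astype(int),
        },
        index=df.index,
    )
    return out[PREPARED_COLUMNS]


def data_dictionary() -> dict:
    """Band-edge documentation for the prepared table (JSON-serialisable)."""
    return {
        "age_band": {
            "kind": "explicit", "edges": list(AGE_EDGES),
            "bands": list(AGE_BAND_ORDER), "closure": "open-left, closed-right",
        },
        "time_session_bands": {
            "kind": "fixed-width", "width_minutes": SESSION_BAND_MINUTES,
            "closure": "closed-left, open-right",
        },
        "time_offline_bands": {
            "kind": "fixed-width", "width_minutes": OFFLINE_BAND_MINUTES,
            "closure": "closed-left, open-right",
        },
        "atmospheric_conditions": {
            "kind": "derived", "formula": "ac = rt + rh",
            "rt": {"<15": 0, "[15,30]": 1, ">30": 2},
            "rh": {"Rain|Light Rain Showers": 0, "Partly Cloudy|Scattered Clouds|Clear": 2,
                   "other": 1},
        },
        "profile_code": PROFILE_CODES,
        "dropped": ["surrogate_key", "user_id", "window_start", "district", "alert_date",
                    "temperature_max", "temperature_min", "humidity_max", "humidity_min",
                    "condition"],
    }


def prepare_dataset(initial: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Clean, derive, cluster and discretise in one call."""
    cleaned = clean_outliers(initial)
    profiles = assign_profiles(cleaned, seed=seed)
    return discretize(cleaned, profiles)
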