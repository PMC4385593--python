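"""Simulation configuration and seed bookkeeping.

A single :class:`SimulationConfig` drives every stochastic stage of the
pipeline.  The defaults describe the study conditions the package is built
around: a 50-user cohort observed for one year (363 days, i.e. 121 tumbling
3-day windows per user), ages normal around 75 (sd 10), the five marital
categories with fractions 30/50/10/8/2 %, and three usage profiles
(low/average/high) mixed 20/50/30 %.

Each stage draws from its own :class:`numpy.random.Generator` derived from
the master seed and a stage name, so stages are independently reproducible
and inserting a new stage does not reshuffle the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


#: Portuguese-style national holiday fixture for the default 2014 run.
#: Injectable: pass any iterable of dates via ``SimulationConfig.holidays``.
DEFAULT_HOLIDAYS: tuple[date, ...] = (
    date(2014, 1, 1),    # New Year
    date(2014, 4, 18),   # Good Friday
    date(2014, 4, 20),   # Easter Sunday
    date(2014, 4, 25),   # Freedom Day
    date(2014, 5, 1),    # Labour Day
    date(2014, 6, 10),   # National Day
    date(2014, 8, 15),   # Assumption
    date(2014, 12, 8),   # Immaculate Conception
    date(2014, 12, 25),  # Christmas
)

MARITAL_CATEGORIES = ("married", "widowed", "single", "divorced", "cohabitation")
PROFILE_CATEGORIES = ("low", "average", "high")

#: Sky-condition labels used by the atmospheric-conditions mapping.
CONDITION_CATEGORIES = (
    "Rain",
    "Light Rain Showers",
    "Partly Cloudy",
    "Scattered Clouds",
    "Clear",
    "Other",
)


def _check_fractions(name: str, fractions: Mapping[str, float], keys: Sequence[str]) -> None:
    if set(fractions) != set(keys):
        raise ConfigurationError(f"{name} must have exactly the keys {sorted(keys)}")
    total = float(sum(fractions.values()))
    if any(v < 0 for v in fractions.values()):
        raise ConfigurationError(f"{name} fractions must be nonnegative")
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} fractions must sum to 1 (got {total})")


@dataclass(frozen=True)
class DemographicsConfig:
    """Cohort demographics: age distribution and marital mixture."""

    age_mean: float = 75.0
    age_sd: float = 10.0
    age_min: int = 18
    marital_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "married": 0.30,
            "widowed": 0.50,
            "single": 0.10,
            "divorced": 0.08,
            "cohabitation": 0.02,
        }
    )
    districts: tuple[str, ...] = ("Leiria", "Lisboa", "Coimbra", "Porto", "Santarem")

    def validate(self) -> None:
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        _check_fractions("marital_fractions", self.marital_fractions, MARITAL_CATEGORIES)
        if not self.districts:
            raise ConfigurationError("districts must be non-empty")


@dataclass(frozen=True)
class ProfileConfig:
    """Per-profile session process.

    Sessions arrive per day as Poisson counts with a profile-specific rate.
    Most durations are log-normal (median ``duration_median``, log-sd
    ``duration_sigma``); with probability ``marathon_prob`` a session is
    instead a "marathon" drawn uniformly on [marathon_min, marathon_max]
    minutes — the long accesses the alert rules key on.  A fraction
    ``night_prob`` of sessions start in the 23:00–07:00 band.
    """

    fractions: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.20, "average": 0.50, "high": 0.30}
    )
    session_rate: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.35, "average": 1.2, "high": 3.0}
    )
    duration_median: Mapping[str, float] = field(
        default_factory=lambda: {"low": 55.0, "average": 40.0, "high": 30.0}
    )
    duration_sigma: float = 0.55
    marathon_prob: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.10, "average": 0.07, "high": 0.05}
    )
    marathon_min: float = 130.0
    marathon_max: float = 420.0
    night_prob: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.08, "average": 0.06, "high": 0.04}
    )
    #: Relative weights of start hours 07:00..22:00 for daytime sessions
    #: (mild morning and evening bumps).
    day_hour_weights: tuple[float, ...] = (
        3, 4, 4, 3, 2, 2, 2, 2, 2, 2, 3, 4, 4, 3, 2, 1,
    )

    def validate(self) -> None:
        _check_fractions("profile fractions", self.fractions, PROFILE_CATEGORIES)
        for name, m in (
            ("session_rate", self.session_rate),
            ("duration_median", self.duration_median),
            ("marathon_prob", self.marathon_prob),
            ("night_prob", self.night_prob),
        ):
            if set(m) != set(PROFILE_CATEGORIES):
                raise ConfigurationError(f"{name} must have keys {PROFILE_CATEGORIES}")
            if any(v < 0 for v in m.values()):
                raise ConfigurationError(f"{name} values must be nonnegative")
        for name in ("marathon_prob", "night_prob"):
            if any(v > 1 for v in getattr(self, name).values()):
                raise ConfigurationError(f"{name} values must be in [0, 1]")
        if self.duration_sigma <= 0:
            raise ConfigurationError("duration_sigma must be positive")
        if not (0 < self.marathon_min <= self.marathon_max):
            raise ConfigurationError("need 0 < marathon_min <= marathon_max")
        if len(self.day_hour_weights) != 16 or sum(self.day_hour_weights) <= 0:
            raise ConfigurationError("day_hour_weights must give 16 nonneg weights (hours 7..22)")


@dataclass(frozen=True)
class WeatherConfig:
    """Single-series daily weather: seasonal temperature, humidity, and a
    directly simulated sky-condition category."""

    temp_base: float = 20.0       # annual mean of the daily maximum, °C
    temp_amplitude: float = 8.0   # seasonal half-range, °C
    temp_sd: float = 3.0          # day-to-day noise, °C
    peak_doy: int = 196           # mid-July peak
    diurnal_range: tuple[float, float] = (5.0, 12.0)   # temp_max - temp_min
    humidity_min_range: tuple[float, float] = (35.0, 70.0)
    humidity_spread: tuple[float, float] = (10.0, 29.0)
    condition_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Rain": 0.12,
            "Light Rain Showers": 0.08,
            "Partly Cloudy": 0.22,
            "Scattered Clouds": 0.18,
            "Clear": 0.28,
            "Other": 0.12,
        }
    )

    def validate(self) -> None:
        _check_fractions("condition_probs", self.condition_probs, CONDITION_CATEGORIES)
        if self.temp_sd < 0:
            raise ConfigurationError("temp_sd must be nonnegative")
        lo, hi = self.diurnal_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("diurnal_range must satisfy 0 <= lo <= hi")
        lo, hi = self.humidity_min_range
        slo, shi = self.humidity_spread
        if not (0 <= lo <= hi <= 100 and 0 <= slo <= shi):
            raise ConfigurationError("humidity ranges out of bounds")
        if hi + shi >= 100:
            # keep natural humidity below the 100 sentinel used for injected errors
            raise ConfigurationError("humidity_min_range + humidity_spread must stay below 100")


@dataclass(frozen=True)
class ErrorConfig:
    """Sentinel-outlier injection into the windowed table: temperature
    fields become -9999, humidity fields become 100."""

    temperature_rate: float = 0.02
    humidity_rate: float = 0.02
    temperature_sentinel: float = -9999.0
    humidity_sentinel: float = 100.0

    def validate(self) -> None:
        for name in ("temperature_rate", "humidity_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_users: int = 50
    start_date: date = date(2014, 1, 1)
    end_date: date = date(2014, 12, 29)   # inclusive; 363 days = 121 windows
    holidays: tuple[date, ...] = DEFAULT_HOLIDAYS
    demographics: DemographicsConfig = field(default_factory=DemographicsConfig)
    profiles: ProfileConfig = field(default_factory=ProfileConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    errors: ErrorConfig = field(default_factory=ErrorConfig)
    seed: int = 12345

    def validate(self) -> None:
        if self.n_users < 0:
            raise ConfigurationError("n_users must be nonnegative")
        if self.end_date < self.start_date:
            raise ConfigurationError("end_date must not precede start_date")
        self.demographics.validate()
        self.profiles.validate()
        self.weather.validate()
        self.errors.validate()

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def n_windows(self) -> int:
        """Number of tumbling 3-day windows covering the date range."""
        return -(-self.n_days // 3)

    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(stage_seed(self.seed, stage))

    # ---- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["end_date"] = self.end_date.isoformat()
        d["holidays"] = [h.isoformat() for h in self.holidays]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        try:
            for key in ("start_date", "end_date"):
                if isinstance(d.get(key), str):
                    d[key] = date.fromisoformat(d[key])
            if "holidays" in d:
                d["holidays"] = tuple(
                    h if isinstance(h, date) else date.fromisoformat(h) for h in d["holidays"]
                )
            for key, sub in (
                ("demographics", DemographicsConfig),
                ("profiles", ProfileConfig),
                ("weather", WeatherConfig),
                ("errors", ErrorConfig),
            ):
                if isinstance(d.get(key), Mapping):
                    subd = dict(d[key])
                    for tup_key in (
                        "districts", "day_hour_weights", "diurnal_range",
                        "humidity_min_range", "humidity_spread",
                    ):
                        if tup_key in subd and isinstance(subd[tup_key], list):
                            subd[tup_key] = tuple(subd[tup_key])
                    d[key] = sub(**subd)
            cfg = cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigurationError(f"malformed YAML: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigurationError("config document must be a mapping")
        return cls.from_dict(raw)


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive an independent seed sequence for a named pipeline stage."""
    return np.random.SeedSequence(entropy=(int(master_seed), zlib.crc32(stage.encode())))


def stage_seed_int(master_seed: int, stage: str) -> int:
    """A plain integer stage seed (< 2^31) for libraries wanting one."""
    return int(stage_seed(master_seed, stage).generate_state(1)[0] % (2**31))
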