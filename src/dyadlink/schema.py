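"""Canonical mother-infant dyad table schema.

One row per dyad: eight maternal fields (demographics, obstetric history and
the CBTS / EPDS / HADS psychological screening scores) and six infant fields
(behavioral class, gender, age, and the three sleep indicators).  All other
modules read and write this column set; categorical codes are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "COLUMNS",
    "MATERNAL_FEATURES",
    "SLEEP_FEATURES",
    "CATEGORICAL_LEVELS",
    "PLAUSIBILITY",
    "ROUNDING",
    "BEHAVIOR_LABELS",
    "SLEEP_QUALITY_LABELS",
    "DyadRecord",
    "DyadlinkError",
    "ConfigError",
    "SchemaError",
]


class DyadlinkError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(DyadlinkError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(DyadlinkError, ValueError):
    """A table does not conform to the canonical dyad column set."""


#: Canonical column order of the dyad CSV.
COLUMNS = (
    "dyad_id",
    "maternal_age",
    "marital_status",
    "education",
    "gestation_weeks",
    "delivery_mode",
    "cbts",
    "epds",
    "hads",
    "behavior_class",
    "infant_gender",
    "infant_age",
    "sleep_time",
    "wake_times",
    "sleep_mode",
)

#: The eight maternal indicators used as model inputs.
MATERNAL_FEATURES = (
    "maternal_age",
    "marital_status",
    "education",
    "gestation_weeks",
    "delivery_mode",
    "cbts",
    "epds",
    "hads",
)

#: The three infant sleep-quality indicators clustered by FCM.
SLEEP_FEATURES = ("sleep_time", "wake_times", "sleep_mode")

#: Enumerated levels of each categorical column (0-based codes).
CATEGORICAL_LEVELS = {
    "marital_status": (0, 1),          # unmarried / married
    "education": (0, 1, 2, 3, 4),      # elementary ... graduate school
    "delivery_mode": (0, 1),           # natural / cesarean
    "behavior_class": (0, 1, 2),       # quiet / moderate / contradictory
    "infant_gender": (0, 1),           # male / female
    "sleep_mode": (0, 1, 2, 3, 4),     # coax / touch / pacifier / environment / timing
}

#: Closed plausibility windows for the numeric columns.  These double as the
#: truncation bounds of the synthetic generator and the default outlier rules.
PLAUSIBILITY = {
    "maternal_age": (16.0, 50.0),
    "gestation_weeks": (28.0, 43.0),
    "cbts": (0.0, 30.0),
    "epds": (0.0, 30.0),
    "hads": (0.0, 21.0),
    "infant_age": (0.0, 12.0),
    "sleep_time": (0.0, 24.0),
    "wake_times": (0.0, 12.0),
}

#: Recording granularity of each continuous column (instrument resolution):
#: questionnaire scores and wake counts are integers, times to 0.1 h,
#: ages to 0.1 year / 0.1 month.
ROUNDING = {
    "maternal_age": 0.1,
    "gestation_weeks": 0.1,
    "cbts": 1.0,
    "epds": 1.0,
    "hads": 1.0,
    "infant_age": 0.1,
    "sleep_time": 0.1,
    "wake_times": 1.0,
}

#: Display names for the behavior classes (codes 0/1/2; reports show 1/2/3).
BEHAVIOR_LABELS = ("quiet", "moderate", "contradictory")

#: Ordinal sleep-quality labels, best first.
SLEEP_QUALITY_LABELS = ("good", "moderate", "poor")


@dataclass(frozen=True)
class DyadRecord:
    """One mother-infant pair; field order mirrors :data:`COLUMNS`."""

    dyad_id: int
    maternal_age: float
    marital_status: int
    education: int
    gestation_weeks: float
    delivery_mode: int
    cbts: int
    epds: int
    hads: int
    behavior_class: int
    infant_gender: int
    infant_age: float
    sleep_time: float
    wake_times: int
    sleep_mode: int
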