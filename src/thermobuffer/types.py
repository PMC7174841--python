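"""Shared domain types for the microclimate / thermal-tolerance pipeline.

Hourly logger series are held as a small metadata dataclass plus a pandas
DataFrame; assay trials are plain records.  All temperatures are degrees
Celsius, humidities percent, vapour pressures hPa, knockdown times minutes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

AREAS = ("west-high", "west-low", "east-high", "east-low")

#: plausibility bounds for logger temperatures (°C); outside = sensor fault
TEMP_MIN_C = -10.0
TEMP_MAX_C = 55.0

#: right-censoring horizon of the knockdown assay (minutes)
CENSOR_MIN = 60.0


class Stratum(str, Enum):
    """Forest layer where a logger hangs (~1 m vs ~10 m above ground)."""

    UNDERSTOREY = "understorey"
    SUBCANOPY = "subcanopy"


class AltitudeBand(str, Enum):
    HIGH = "high"
    LOW = "low"


def area_altitude(area: str) -> str:
    """Altitude band ('high'/'low') of a study area like 'west-high'."""
    if area not in AREAS:
        raise ValueError(f"unknown area {area!r}; expected one of {AREAS}")
    return area.split("-")[1]


@dataclass(frozen=True)
class LoggerMeta:
    """Identity and placement of one data logger."""

    logger_id: str
    area: str
    site_id: str
    stratum: str
    height_m: float
    elevation_masl: float
    has_humidity: bool = False

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"area {self.area!r} not in {AREAS}")
        if self.stratum not in (Stratum.UNDERSTOREY.value, Stratum.SUBCANOPY.value):
            raise ValueError(f"stratum {self.stratum!r} invalid")
        if not 0 <= self.height_m < 40:
            raise ValueError(f"height_m {self.height_m} outside [0, 40)")
        if not 0 <= self.elevation_masl <= 4000:
            raise ValueError(f"elevation_masl {self.elevation_masl} outside [0, 4000]")

    @property
    def altitude_band(self) -> str:
        return area_altitude(self.area)


@dataclass
class LoggerSeries:
    """Hourly records of one logger.

    ``records`` has columns ``timestamp`` (naive local time), ``temp_c`` and,
    when :attr:`LoggerMeta.has_humidity`, ``rh_pct``.  Timestamps are strictly
    increasing at nominal one-hour spacing; gaps are allowed and counted by
    :meth:`n_gap_hours`.
    """

    meta: LoggerMeta
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"timestamp", "temp_c"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {req}")
        if self.meta.has_humidity and "rh_pct" not in self.records.columns:
            raise ValueError("humidity logger series lacks 'rh_pct' column")
        ts = self.records["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.records)

    def n_gap_hours(self) -> int:
        """Number of whole hours missing between first and last record."""
        ts = self.records["timestamp"]
        if len(ts) < 2:
            return 0
        span = int((ts.iloc[-1] - ts.iloc[0]) / pd.Timedelta(hours=1))
        return span + 1 - len(ts)


@dataclass
class AssayRecord:
    """One heat-knockdown trial of one butterfly.

    ``knockdown_min`` is the minutes until loss of locomotor performance in
    the 39–41 °C chamber, right-censored at 60 (``censored=True`` means the
    individual was still standing at the horizon and the sentinel value 60 is
    recorded).  ``pre39_knockdown`` marks individuals knocked down while the
    chamber was still heating up (below 39 °C).
    """

    individual_id: str
    group: str
    group_kind: str  # "species" | "brood"
    altitude_band: str
    sex: str
    wing_area_mm2: float
    heating_up_min: float
    knockdown_min: float
    censored: bool
    temp_at_ko_c: float
    below_range: bool = False  # chamber fell below 39 °C during the assay
    development_days: Optional[float] = None
    egg_number: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.knockdown_min <= CENSOR_MIN:
            raise ValueError(
                f"knockdown_min {self.knockdown_min} outside (0, {CENSOR_MIN}]"
            )
        if self.censored and self.knockdown_min != CENSOR_MIN:
            raise ValueError("censored records must carry the 60-min sentinel")
        if self.heating_up_min < 0:
            raise ValueError("heating_up_min must be >= 0")

    @property
    def pre39_knockdown(self) -> bool:
        return self.temp_at_ko_c < 39.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pre39_knockdown"] = self.pre39_knockdown
        return d


def assays_to_frame(records: list[AssayRecord]) -> pd.DataFrame:
    """Tabulate assay records (one row per trial)."""
    return pd.DataFrame([r.to_dict() for r in records])


@dataclass
class RunConfig:
    """Pipeline configuration: paths, thresholds and the random seed."""

    outdir: str = "thermobuffer_out"
    loggers_csv: Optional[str] = None
    meta_csv: Optional[str] = None
    interp_csv: Optional[str] = None
    assays_csv: Optional[str] = None
    min_hours: int = 20
    temp_thresholds: tuple = (30.0, 39.0)
    vpd_threshold_hpa: float = 12.0
    overheat_limit_c: float = 41.9
    min_group_n: int = 5
    n_boot: int = 1000
    seed: int = 1
    stages: tuple = ("simulate", "summarize", "vpd", "bioclim", "compare", "tolerance")
    # synthetic-data scale (used only when the simulate stage is enabled)
    sim_n_days: int = 365
    sim_sites_per_area: int = 7
    sim_humidity_sites: int = 2
    sim_n_groups: int = 10
    sim_n_per_group_band: int = 14
    sim_interp_bias_tmax_high_c: float = 2.01

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.min_hours < 1 or self.min_hours > 24:
            raise ValueError("min_hours must be in [1, 24]")
        self.temp_thresholds = tuple(float(t) for t in self.temp_thresholds)
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["temp_thresholds"] = list(self.temp_thresholds)
        d["stages"] = list(self.stages)
        return d
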