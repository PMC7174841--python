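import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thermobuffer.types import AssayRecord, LoggerMeta, LoggerSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_meta(logger_id="L1", area="west-low", site_id="s1",
              stratum="subcanopy", height_m=10.7, elevation_masl=495.0,
              has_humidity=False):
    return LoggerMeta(logger_id=logger_id, area=area, site_id=site_id,
                      stratum=stratum, height_m=height_m,
                      elevation_masl=elevation_masl,
                      has_humidity=has_humidity)


def make_series(temps, start="2017-02-01 00:00", rh=None, **meta_kw):
    """Hourly LoggerSeries from a temperature array (and optional RH)."""
    temps = np.asarray(temps, dtype=float)
    meta = make_meta(has_humidity=rh is not None, **meta_kw)
    rec = pd.DataFrame({
        "timestamp": pd.date_range(start, periods=len(temps), freq="h"),
        "temp_c": temps,
    })
    if rh is not None:
        rec["rh_pct"] = np.asarray(rh, dtype=float)
    return LoggerSeries(meta=meta, records=rec)


def make_assay(individual_id="i1", group="sp01", altitude_band="low",
               knockdown_min=15.0, censored=False, temp_at_ko_c=40.0,
               heating_up_min=12.0, wing_area_mm2=400.0, sex="F",
               group_kind="species", **kw):
    return AssayRecord(individual_id=individual_id, group=group,
                       group_kind=group_kind, altitude_band=altitude_band,
                       sex=sex, wing_area_mm2=wing_area_mm2,
                       heating_up_min=heating_up_min,
                       knockdown_min=knockdown_min, censored=censored,
                       temp_at_ko_c=temp_at_ko_c, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
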