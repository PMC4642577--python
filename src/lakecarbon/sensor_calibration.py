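"""In-situ infrared pCO2 sensor correction and calibration.

Raw IRGA mixing-ratio output depends on the gas density in the optical
path, so it is compensated to reference temperature and pressure with the
ideal-gas relation; the compensated readings are then mapped to true
mixing ratios with a standard-gas calibration line.  Sensors drift over a
field season, so a pre-season and a post-season calibration are combined
— by default the gain and offset are interpolated linearly in time across
the deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

P_REF_HPA = 1013.25
T_REF_C = 25.0

DriftPolicy = Literal["interpolate", "pre_only", "mean"]


@dataclass
class SensorSeries:
    """Hourly raft pCO2 sensor record for one lake."""

    lake_id: str
    frame: pd.DataFrame  # columns: timestamp, raw_ppm, water_temp_c, pressure_hpa

    def __post_init__(self) -> None:
        ts = pd.to_datetime(self.frame["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        if (self.frame["raw_ppm"] < 0).any():
            raise ValueError("raw_ppm must be >= 0")
        self.frame = self.frame.assign(timestamp=ts)

    @classmethod
    def from_csv(cls, path) -> "SensorSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        (lake_id,) = df["lake_id"].unique()
        return cls(lake_id=lake_id, frame=df.drop(columns=["lake_id"]))


@dataclass
class CalibrationRecord:
    """One standard-gas calibration session (reading -> truth line)."""

    session: str  # "pre" | "post"
    when: pd.Timestamp
    gain: float
    offset: float
    r_squared: float
    standards: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("calibration gain must be positive")

    def apply(self, reading):
        return self.gain * np.asarray(reading, dtype=float) + self.offset


def correct_temperature_pressure(raw_ppm, temperature_c, pressure_hpa):
    """Ideal-gas density compensation of a raw IRGA reading.

    ``corrected = raw * (P_ref / P) * (T_K / T_ref_K)`` with
    P_ref = 1013.25 hPa and T_ref = 25 C; identity at reference conditions.

    Returns ``(corrected_ppm, ok_flag)`` where the flag marks readings taken
    inside the trusted envelope (pressure 800-1100 hPa, temperature
    -5 to 45 C).  Out-of-envelope values are passed through, flagged False.
    """
    raw = np.asarray(raw_ppm, dtype=float)
    t = np.asarray(temperature_c, dtype=float)
    p = np.asarray(pressure_hpa, dtype=float)
    ok = (p >= 800.0) & (p <= 1100.0) & (t >= -5.0) & (t <= 45.0)
    corrected = raw * (P_REF_HPA / p) * ((t + 273.15) / (T_REF_C + 273.15))
    if corrected.ndim == 0:
        return float(corrected), bool(ok)
    return corrected, ok


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    session: str = "pre",
    when=None,
) -> CalibrationRecord:
    """Least-squares reading->truth line from ``(true_ppm, reading)`` pairs."""
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    truth = np.array([s[0] for s in standards], dtype=float)
    readings = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(readings) == 0:
        raise ValueError("standards have zero variance in readings")
    res = stats.linregress(readings, truth)
    return CalibrationRecord(
        session=session,
        when=pd.Timestamp(when) if when is not None else pd.Timestamp.now(),
        gain=float(res.slope),
        offset=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=list(standards),
    )


def apply_calibration(
    series: SensorSeries,
    pre: CalibrationRecord,
    post: CalibrationRecord,
    drift_policy: DriftPolicy = "interpolate",
) -> pd.DataFrame:
    """Density-correct and calibrate a sensor series to pCO2 in uatm.

    Under the default ``interpolate`` policy the gain and offset at each
    timestamp are interpolated linearly between the pre- and post-season
    sessions (clamped outside them).  ``pre_only`` applies the pre-season
    line throughout; ``mean`` applies the session-averaged line.

    Returns a frame with columns ``timestamp, pco2_uatm, quality_ok``;
    negative calibrated values are floored at zero and flagged.
    """
    df = series.frame
    corrected, ok = correct_temperature_pressure(
        df["raw_ppm"].to_numpy(), df["water_temp_c"].to_numpy(), df["pressure_hpa"].to_numpy()
    )
    if drift_policy == "pre_only":
        gain, offset = pre.gain, pre.offset
    elif drift_policy == "mean":
        gain = 0.5 * (pre.gain + post.gain)
        offset = 0.5 * (pre.offset + post.offset)
    elif drift_policy == "interpolate":
        t = df["timestamp"].astype("int64").to_numpy(dtype=float)
        t0 = float(pd.Timestamp(pre.when).value)
        t1 = float(pd.Timestamp(post.when).value)
        frac = np.zeros_like(t) if t1 == t0 else np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        gain = pre.gain + frac * (post.gain - pre.gain)
        offset = pre.offset + frac * (post.offset - pre.offset)
    else:
        raise ValueError(f"unknown drift policy {drift_policy!r}")
    pco2 = gain * corrected + offset
    negative = pco2 < 0
    return pd.DataFrame(
        {
            "timestamp": df["timestamp"].to_numpy(),
            "pco2_uatm": np.where(negative, 0.0, pco2),
            "quality_ok": ok & ~negative,
        }
    )
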