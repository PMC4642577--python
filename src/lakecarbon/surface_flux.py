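"""Diffusive air-water gas flux from a wind-parameterized piston velocity.

The flux across the interface follows Fick's law,
``F = k * (C_water - C_eq)``, with the gas transfer (piston) velocity k
taken from the Cole-Caraco wind relation ``k600 = 2.07 + 0.215 * U10^1.7``
(cm h-1) and rescaled to the gas and temperature of interest through the
Schmidt number.  Positive flux is water -> atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lakecarbon.gas_physics import GasSpecies, dissolved_concentration, schmidt_number

K600_INTERCEPT = 2.07  # cm h-1
K600_SLOPE = 0.215  # cm h-1 per (m s-1)^1.7
K600_EXPONENT = 1.7
DEFAULT_Z0_M = 0.0002  # open-water aerodynamic roughness length
DEFAULT_ATM_PCO2_UATM = 390.0  # circa-2010 atmospheric baseline
CM_PER_H_TO_M_PER_D = 24.0 / 100.0


@dataclass
class WindSeries:
    """Anemometer record; height is the measurement height above ground."""

    frame: pd.DataFrame  # columns: timestamp, wind_ms
    height_m: float = 10.0

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError("measurement height must be positive")
        if (self.frame["wind_ms"] < 0).any():
            raise ValueError("wind speeds must be >= 0")
        self.frame = self.frame.assign(timestamp=pd.to_datetime(self.frame["timestamp"]))

    @classmethod
    def from_csv(cls, path) -> "WindSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        height = float(df["height_m"].iloc[0]) if "height_m" in df else 10.0
        return cls(frame=df[["timestamp", "wind_ms"]], height_m=height)


def wind_to_u10(speed_ms, height_m: float, z0_m: float = DEFAULT_Z0_M):
    """Scale wind to 10 m height with a neutral logarithmic profile.

    ``u10 = u_z * ln(10/z0) / ln(z/z0)``; identity at 10 m.
    """
    if height_m <= z0_m:
        raise ValueError("measurement height must exceed roughness length")
    u = np.asarray(speed_ms, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    out = u * np.log(10.0 / z0_m) / np.log(height_m / z0_m)
    return out if out.ndim else float(out)


def k600_cole_caraco(u10_ms):
    """Piston velocity normalized to Sc=600, cm h-1, from 10-m wind speed."""
    u = np.asarray(u10_ms, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    out = K600_INTERCEPT + K600_SLOPE * u**K600_EXPONENT
    return out if out.ndim else float(out)


def k_for_species(
    k600_cm_h,
    species: GasSpecies,
    temperature_c,
    exponent: float = 0.5,
):
    """Rescale k600 to a gas at in-situ temperature; returns k in m d-1.

    ``k = k600 * (Sc(T)/600)^(-n)`` with n = 0.5 by default (0.67 is the
    conventional choice for smooth surfaces, u10 < 3 m s-1).
    """
    k600 = np.asarray(k600_cm_h, dtype=float)
    if np.any(k600 <= 0):
        raise ValueError("k600 must be positive")
    sc = schmidt_number(species, temperature_c)
    out = k600 * (np.asarray(sc) / 600.0) ** (-exponent) * CM_PER_H_TO_M_PER_D
    return out if out.ndim else float(out)


def diffusive_flux(c_water_mol_m3, c_equilibrium_mol_m3, k_m_d):
    """Fick's-law interface flux in mmol m-2 d-1 (positive = outgassing)."""
    k = np.asarray(k_m_d, dtype=float)
    if np.any(k < 0):
        raise ValueError("piston velocity must be >= 0")
    out = k * (np.asarray(c_water_mol_m3, float) - np.asarray(c_equilibrium_mol_m3, float)) * 1e3
    return out if out.ndim else float(out)


def flux_series(
    pco2: pd.DataFrame,
    wind: WindSeries,
    water_temperature: pd.DataFrame | None = None,
    species: GasSpecies | None = None,
    atmospheric_pco2_uatm: float = DEFAULT_ATM_PCO2_UATM,
    join_tolerance: str = "30min",
    schmidt_exponent: float = 0.5,
) -> pd.DataFrame:
    """Per-timestamp diffusive flux series for a calibrated pCO2 record.

    ``pco2`` carries columns ``timestamp, pco2_uatm`` and (unless a separate
    ``water_temperature`` frame with ``timestamp, water_temp_c`` is given)
    ``water_temp_c``.  Wind is joined nearest-in-time within
    ``join_tolerance``; timestamps without wind are kept but flagged
    (``quality_ok`` False, flux NaN) — gaps are never silently filled.

    Returns columns ``timestamp, flux_mmol_m2_d, k600_cm_h, k_m_d,
    quality_ok``.
    """
    from lakecarbon.gas_physics import CO2

    species = species if species is not None else CO2
    left = pco2.copy()
    left["timestamp"] = pd.to_datetime(left["timestamp"])
    if water_temperature is not None:
        wt = water_temperature.copy()
        wt["timestamp"] = pd.to_datetime(wt["timestamp"])
        left = pd.merge_asof(
            left.sort_values("timestamp"),
            wt.sort_values("timestamp"),
            on="timestamp",
            direction="nearest",
            tolerance=pd.Timedelta(join_tolerance),
        )
    if "water_temp_c" not in left:
        raise ValueError("no water temperature available for flux computation")
    wind_df = wind.frame.sort_values("timestamp")
    merged = pd.merge_asof(
        left.sort_values("timestamp"),
        wind_df,
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(join_tolerance),
    )
    if merged["wind_ms"].notna().sum() == 0:
        raise ValueError("no temporal overlap between pCO2 and wind series")

    have = merged["wind_ms"].notna() & merged["water_temp_c"].notna()
    n = len(merged)
    k600 = np.full(n, np.nan)
    k = np.full(n, np.nan)
    flux = np.full(n, np.nan)
    if have.any():
        u10 = wind_to_u10(merged.loc[have, "wind_ms"].to_numpy(), wind.height_m)
        k600_h = k600_cole_caraco(u10)
        temp = merged.loc[have, "water_temp_c"].to_numpy()
        k_h = k_for_species(k600_h, species, temp, exponent=schmidt_exponent)
        c_w = dissolved_concentration(species, merged.loc[have, "pco2_uatm"].to_numpy(), temp)
        c_eq = dissolved_concentration(species, atmospheric_pco2_uatm, temp)
        k600[have.to_numpy()] = k600_h
        k[have.to_numpy()] = k_h
        flux[have.to_numpy()] = diffusive_flux(c_w, c_eq, k_h)

    quality = have.to_numpy()
    if "quality_ok" in merged:
        quality = quality & merged["quality_ok"].fillna(False).to_numpy(dtype=bool)
    return pd.DataFrame(
        {
            "timestamp": merged["timestamp"],
            "species": species.name,
            "flux_mmol_m2_d": flux,
            "k600_cm_h": k600,
            "k_m_d": k,
            "quality_ok": quality,
        }
    )
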