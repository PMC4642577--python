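"""Floating-chamber CH4 fluxes with ebullition/diffusion partitioning.

Two chamber types are deployed together: plain chambers collect the total
CH4 flux (diffusion + bubbles), while chambers fitted with an underwater
shield exclude rising bubbles and collect diffusion only.  The ebullitive
flux of a lake-period is the excess of the total-chamber mean over the
shielded-chamber mean.

Headspace mixing ratios are converted to molar content with the ideal gas
law; the flux estimate is the least-squares slope of chamber content over
time, except when the chamber headspace has been driven above equilibrium
with the water (e.g. by a bubble) so that the late-deployment gradient
reverses — there the endpoint mass balance is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from lakecarbon.gas_physics import CH4, GasSpecies, equilibrium_partial_pressure

R_J = 8.314462618  # J mol-1 K-1

Weighting = Literal["area", "arithmetic"]


@dataclass
class ChamberDeployment:
    """One floating-chamber deployment (nominally 48 h)."""

    lake_id: str
    chamber_id: str
    chamber_type: str  # "total" | "shielded"
    volume_m3: float
    area_m2: float
    elapsed_h: np.ndarray
    ch4_ppm: np.ndarray
    zone: str = "whole"
    period: str = ""  # deployment-period label (e.g. its start date)
    air_temp_c: float = 15.0
    pressure_hpa: float = 1013.25
    species: GasSpecies = field(default=CH4)

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0 or self.area_m2 <= 0:
            raise ValueError("chamber volume and area must be positive")
        self.elapsed_h = np.asarray(self.elapsed_h, dtype=float)
        self.ch4_ppm = np.asarray(self.ch4_ppm, dtype=float)
        if len(self.elapsed_h) < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(self.elapsed_h) <= 0):
            raise ValueError("elapsed times must be increasing")
        if self.chamber_type not in ("total", "shielded"):
            raise ValueError("chamber_type must be 'total' or 'shielded'")

    def moles(self) -> np.ndarray:
        """Headspace gas content per time point, mol (ideal gas)."""
        p_pa = self.pressure_hpa * 100.0
        t_k = self.air_temp_c + 273.15
        return self.ch4_ppm * 1e-6 * p_pa * self.volume_m3 / (R_J * t_k)


def chamber_flux_regression(dep: ChamberDeployment) -> float:
    """Flux (mmol m-2 d-1) from the OLS slope of chamber content vs time.

    Falls back to the endpoint mass balance when fewer than three time
    points are available.
    """
    if len(dep.elapsed_h) < 3:
        return chamber_flux_mass_balance(dep)
    n = dep.moles()
    slope = stats.linregress(dep.elapsed_h, n).slope  # mol h-1
    return float(slope * 24.0 / dep.area_m2 * 1e3)


def chamber_flux_mass_balance(dep: ChamberDeployment) -> float:
    """Flux (mmol m-2 d-1) from the first-to-last content difference."""
    n = dep.moles()
    dt_h = dep.elapsed_h[-1] - dep.elapsed_h[0]
    if dt_h <= 0:
        raise ValueError("zero elapsed time")
    return float((n[-1] - n[0]) / (dep.area_m2 * dt_h) * 24.0 * 1e3)


def select_estimator(
    dep: ChamberDeployment,
    water_concentration_mol_m3: float,
    water_temperature_c: float | None = None,
) -> tuple[float, str]:
    """Choose the flux estimator and return ``(flux, method)``.

    If the final chamber headspace exceeds the mixing ratio that would be
    in equilibrium with the water — so the end-of-deployment gradient
    drives gas back into the water — the endpoint mass balance is used;
    otherwise the regression.  Exact equality keeps the regression path.
    """
    t = water_temperature_c if water_temperature_c is not None else dep.air_temp_c
    p_eq_uatm = equilibrium_partial_pressure(dep.species, water_concentration_mol_m3, t)
    final_uatm = dep.ch4_ppm[-1] * dep.pressure_hpa / 1013.25
    if final_uatm > p_eq_uatm:
        return chamber_flux_mass_balance(dep), "mass_balance"
    return chamber_flux_regression(dep), "regression"


def partition_ebullition(
    total_fluxes: Sequence[float],
    shielded_fluxes: Sequence[float],
) -> dict:
    """Split a lake-period's chamber fluxes into diffusive and ebullitive parts.

    diffusive = mean(shielded); ebullitive = max(0, mean(total) - diffusive).
    A negative difference is floored at zero and flagged.  Without shielded
    chambers the partition is undefined: the total mean is reported as-is
    with ``ebullition_defined=False``.
    """
    total = np.asarray(list(total_fluxes), dtype=float)
    shielded = np.asarray(list(shielded_fluxes), dtype=float)
    if len(shielded) == 0:
        return {
            "diffusive": float(np.mean(total)) if len(total) else np.nan,
            "ebullitive": np.nan,
            "ebullition_defined": False,
            "floored": False,
        }
    diffusive = float(np.mean(shielded))
    raw = float(np.mean(total)) - diffusive if len(total) else 0.0
    return {
        "diffusive": diffusive,
        "ebullitive": max(0.0, raw),
        "ebullition_defined": True,
        "floored": raw < 0,
    }


def lake_period_mean_flux(
    zone_fluxes: dict[str, Sequence[float]],
    zone_area_weights: dict[str, float] | None = None,
    weighting: Weighting = "area",
) -> float:
    """Spatial mean flux (mmol m-2 d-1) over a lake's depth zones.

    ``zone_fluxes`` maps depth-zone labels to per-chamber flux estimates.
    Under ``area`` weighting each zone mean is weighted by its planar area
    fraction (weights are renormalized to sum to 1); a zone with area
    weight but no chamber is an error.  ``arithmetic`` pools all chambers
    equally.
    """
    all_fluxes = [f for fs in zone_fluxes.values() for f in fs]
    if not all_fluxes:
        raise ValueError("need at least one chamber flux estimate")
    if weighting == "arithmetic" or zone_area_weights is None:
        return float(np.mean(all_fluxes))
    if weighting != "area":
        raise ValueError(f"unknown weighting {weighting!r}")
    total_w = sum(zone_area_weights.values())
    if total_w <= 0:
        raise ValueError("zone area weights must sum to a positive value")
    mean = 0.0
    for zone, w in zone_area_weights.items():
        if w == 0:
            continue
        if zone not in zone_fluxes or len(zone_fluxes[zone]) == 0:
            raise ValueError(f"zone {zone!r} has area weight but no chamber estimate")
        mean += (w / total_w) * float(np.mean(zone_fluxes[zone]))
    return mean
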