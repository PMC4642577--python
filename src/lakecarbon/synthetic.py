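"""Synthetic lake datasets with known ground truth.

Generates every input stream the pipeline consumes — depth soundings,
hourly pCO2 sensor output (with calibration drift and density effects
baked in), wind, floating-chamber headspace series (with bubble events in
the unshielded chambers), under-ice and open-water grab profiles, and
1-cm-sliced sediment cores following the CF:CS exponential — for a lake
whose true annual emissions, storage release and burial rate are known in
closed form.  Every recovery test in the package runs against these
truths.

Randomness comes from one seeded generator per lake with independent
substreams per data type, so adding a stream never perturbs the others
and a fixed seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lakecarbon.bathymetry import DepthPointSet
from lakecarbon.chamber_flux import ChamberDeployment
from lakecarbon.gas_physics import CO2, MOLAR_MASS_C
from lakecarbon.sediment_burial import PB210_LAMBDA, CoreProfile
from lakecarbon.sensor_calibration import P_REF_HPA, SensorSeries, T_REF_C
from lakecarbon.surface_flux import (
    DEFAULT_Z0_M,
    K600_EXPONENT,
    K600_INTERCEPT,
    K600_SLOPE,
    WindSeries,
)

R_J = 8.314462618
ATM_CH4_PPM = 1.9


@dataclass
class LakeScenario:
    """All parameters of one synthetic lake; defaults emulate a small,
    CO2-supersaturated subarctic lake with a 154-day ice-free season."""

    lake_id: str = "synthetic-1"
    seed: int = 0

    # geometry
    shape: str = "cone"  # cone | paraboloid
    surface_area_m2: float = 1.0e5
    max_depth_m: float = 6.0
    n_soundings: int = 300
    n_shoreline: int = 100

    # season
    ice_off: str = "2010-05-21"
    ice_on: str = "2010-10-22"
    ice_thickness_m: float = 0.8

    # CO2 sensor
    pco2_mean_uatm: float = 800.0
    pco2_diel_amp_uatm: float = 80.0
    pco2_trend_uatm_d: float = -1.0
    sensor_noise_ppm: float = 5.0
    gain_pre: float = 1.05
    offset_pre: float = -10.0
    gain_post: float = 1.15
    offset_post: float = 5.0
    temp_mean_c: float = 10.0
    temp_amp_c: float = 5.0
    pressure_mean_hpa: float = 990.0
    atmospheric_pco2_uatm: float = 390.0

    # wind (Weibull at anemometer height)
    wind_scale_ms: float = 4.0
    wind_shape: float = 2.0
    anemometer_height_m: float = 7.5

    # CH4 chambers
    zone_edge_depth_m: float = 2.0
    ch4_diffusive_mmol_m2_d: dict = field(
        default_factory=lambda: {"shallow": 0.8, "deep": 0.3}
    )
    ebullition_events_per_day: float = 0.5  # per unshielded chamber
    bubble_moles: float = 3.0e-4  # ~7 mL CH4 per bubble event
    n_total_chambers: int = 10
    n_shielded_chambers: int = 2
    chamber_volume_m3: float = 0.01
    chamber_area_m2: float = 0.07
    deployment_h: float = 48.0
    samples_per_deployment: int = 5
    ch4_ppm_noise: float = 2.0
    ch4_water_conc_mol_m3: float = 8.0e-4

    # winter storage (uniform water-column concentrations, mol m-3)
    co2_under_ice_mol_m3: float = 0.30
    co2_open_mol_m3: float = 0.05
    ch4_under_ice_mol_m3: float = 0.020
    ch4_open_mol_m3: float = 0.001

    # sediment core
    n_cores: int = 2
    core_slices: int = 30
    dry_mass_g_cm2_per_slice: float = 0.15
    w_true_g_cm2_yr: float = 0.02
    supported_bq_kg: float = 30.0
    surface_excess_bq_kg: float = 300.0
    c_fraction: float = 0.10
    counting_cv: float = 0.07  # injected measurement noise
    reported_cv: float = 0.07  # stated counting uncertainty (never zero)

    def noiseless(self) -> "LakeScenario":
        """Copy with all measurement noise off and deterministic bubbles."""
        return dataclasses.replace(
            self, sensor_noise_ppm=0.0, ch4_ppm_noise=0.0, counting_cv=0.0
        )

    @property
    def noise_free(self) -> bool:
        return self.sensor_noise_ppm == 0 and self.ch4_ppm_noise == 0 and self.counting_cv == 0


@dataclass
class TruthRecord:
    """Closed-form ground truth for one synthetic lake."""

    lake_id: str
    co2_seasonal_gc_m2: float
    ch4_seasonal_gc_m2: float
    iceout_co2_gc_m2: float
    iceout_ch4_gc_m2: float
    burial_gc_m2_yr: float

    @property
    def iceout_gc_m2(self) -> float:
        return self.iceout_co2_gc_m2 + self.iceout_ch4_gc_m2

    @property
    def total_gc_m2_yr(self) -> float:
        return self.co2_seasonal_gc_m2 + self.ch4_seasonal_gc_m2 + self.iceout_gc_m2

    @property
    def ratio(self) -> float:
        return self.total_gc_m2_yr / self.burial_gc_m2_yr

    def to_dict(self) -> dict:
        return {
            "lake_id": self.lake_id,
            "co2_seasonal_gc_m2": self.co2_seasonal_gc_m2,
            "ch4_seasonal_gc_m2": self.ch4_seasonal_gc_m2,
            "iceout_co2_gc_m2": self.iceout_co2_gc_m2,
            "iceout_ch4_gc_m2": self.iceout_ch4_gc_m2,
            "iceout_gc_m2": self.iceout_gc_m2,
            "total_gc_m2_yr": self.total_gc_m2_yr,
            "burial_gc_m2_yr": self.burial_gc_m2_yr,
            "ratio": self.ratio,
        }


@dataclass
class LakeDataset:
    """All raw input streams for one lake, as the pipeline expects them."""

    lake_id: str
    surface_area_m2: float
    max_depth_m: float
    ice_thickness_m: float
    ice_off: pd.Timestamp
    ice_on: pd.Timestamp
    zone_edge_depth_m: float
    atmospheric_pco2_uatm: float
    ch4_water_conc_mol_m3: float
    soundings: DepthPointSet
    sensor: SensorSeries
    calibration_standards: dict  # {"pre"/"post": {"when": ts, "standards": [(truth, reading)]}}
    wind: WindSeries
    chambers: list[ChamberDeployment]
    grabs: pd.DataFrame  # lake_id, date, season, depth_m, species, concentration_mol_m3
    cores: list[CoreProfile]


# ---------------------------------------------------------------------------
# analytic basin geometry (closed-form truth path)

def basin_depth_at_radius(shape: str, r: np.ndarray, radius_m: float, zmax: float) -> np.ndarray:
    if shape == "cone":
        return zmax * (1.0 - r / radius_m)
    if shape == "paraboloid":
        return zmax * (1.0 - (r / radius_m) ** 2)
    raise ValueError(f"unknown basin shape {shape!r}")


def basin_volume_below(shape: str, area_m2: float, zmax: float, z: float) -> float:
    """Analytic water volume below depth ``z`` for the ideal basin."""
    z = min(max(z, 0.0), zmax)
    f = 1.0 - z / zmax
    if shape == "cone":
        return area_m2 * zmax / 3.0 * f**3
    if shape == "paraboloid":
        return area_m2 * zmax / 2.0 * f**2
    raise ValueError(f"unknown basin shape {shape!r}")


def basin_area_at_depth(shape: str, area_m2: float, zmax: float, z: float) -> float:
    z = min(max(z, 0.0), zmax)
    f = 1.0 - z / zmax
    if shape == "cone":
        return area_m2 * f**2
    if shape == "paraboloid":
        return area_m2 * f
    raise ValueError(f"unknown basin shape {shape!r}")


# ---------------------------------------------------------------------------
# stream generators

def _soundings(sc: LakeScenario, rng: np.random.Generator) -> DepthPointSet:
    radius = np.sqrt(sc.surface_area_m2 / np.pi)
    # sunflower layout + jitter: even coverage without gridding artifacts
    i = np.arange(sc.n_soundings, dtype=float) + 0.5
    r = radius * np.sqrt(i / sc.n_soundings) * 0.995
    theta = i * (np.pi * (3.0 - np.sqrt(5.0))) + rng.uniform(0, 2 * np.pi)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    depth = basin_depth_at_radius(sc.shape, r, radius, sc.max_depth_m)
    phi = np.linspace(0, 2 * np.pi, sc.n_shoreline, endpoint=False)
    return DepthPointSet(
        lake_id=sc.lake_id,
        x=np.concatenate([x, radius * np.cos(phi)]),
        y=np.concatenate([y, radius * np.sin(phi)]),
        depth=np.concatenate([depth, np.zeros(sc.n_shoreline)]),
        is_shoreline=np.concatenate(
            [np.zeros(sc.n_soundings, bool), np.ones(sc.n_shoreline, bool)]
        ),
    )


def _season_hours(sc: LakeScenario) -> pd.DatetimeIndex:
    return pd.date_range(pd.Timestamp(sc.ice_off), pd.Timestamp(sc.ice_on), freq="h")


def _true_environment(sc: LakeScenario, hours: pd.DatetimeIndex) -> dict:
    """True hourly pCO2, water temperature and pressure over the season."""
    t_d = (hours - hours[0]).total_seconds().to_numpy() / 86400.0
    hod = hours.hour.to_numpy(dtype=float)
    pco2 = (
        sc.pco2_mean_uatm
        + sc.pco2_diel_amp_uatm * np.sin(2 * np.pi * (hod - 16.0) / 24.0)
        + sc.pco2_trend_uatm_d * (t_d - t_d[-1] / 2.0)
    )
    season_frac = t_d / max(t_d[-1], 1.0)
    temp = sc.temp_mean_c + sc.temp_amp_c * np.sin(np.pi * season_frac)
    pressure = np.full_like(t_d, sc.pressure_mean_hpa)
    return {"t_days": t_d, "pco2_uatm": pco2, "temp_c": temp, "pressure_hpa": pressure}


def _sensor_series(
    sc: LakeScenario, env: dict, hours: pd.DatetimeIndex, rng: np.random.Generator
) -> tuple[SensorSeries, dict]:
    """Distort the true pCO2 into raw sensor output plus calibration sessions.

    The true value maps to the density-corrected reading through the
    drifting calibration line (truth = gain(t) * corrected + offset(t)),
    and the raw output re-applies the temperature/pressure density effect.
    """
    frac = env["t_days"] / env["t_days"][-1]
    gain = sc.gain_pre + frac * (sc.gain_post - sc.gain_pre)
    offset = sc.offset_pre + frac * (sc.offset_post - sc.offset_pre)
    corrected = (env["pco2_uatm"] - offset) / gain
    t_k = env["temp_c"] + 273.15
    raw = corrected * (env["pressure_hpa"] / P_REF_HPA) * ((T_REF_C + 273.15) / t_k)
    raw = raw + rng.normal(0.0, sc.sensor_noise_ppm, size=raw.shape)
    series = SensorSeries(
        lake_id=sc.lake_id,
        frame=pd.DataFrame(
            {
                "timestamp": hours,
                "raw_ppm": np.maximum(raw, 0.0),
                "water_temp_c": env["temp_c"],
                "pressure_hpa": env["pressure_hpa"],
            }
        ),
    )
    standards = [400.0, 800.0, 1500.0, 3000.0]
    sessions = {
        "pre": {
            "when": hours[0],
            "standards": [(s, (s - sc.offset_pre) / sc.gain_pre) for s in standards],
        },
        "post": {
            "when": hours[-1],
            "standards": [(s, (s - sc.offset_post) / sc.gain_post) for s in standards],
        },
    }
    return series, sessions


def _wind_series(sc: LakeScenario, hours: pd.DatetimeIndex, rng: np.random.Generator) -> WindSeries:
    if sc.noise_free:
        speeds = np.full(len(hours), sc.wind_scale_ms)
    else:
        speeds = sc.wind_scale_ms * rng.weibull(sc.wind_shape, size=len(hours))
    return WindSeries(
        frame=pd.DataFrame({"timestamp": hours, "wind_ms": speeds}),
        height_m=sc.anemometer_height_m,
    )


def _deployment_periods(sc: LakeScenario) -> list[pd.Timestamp]:
    """Two 48-h deployment periods per month, June through August."""
    year = pd.Timestamp(sc.ice_off).year
    return [
        pd.Timestamp(year=year, month=m, day=d) for m in (6, 7, 8) for d in (5, 19)
    ]


def _temp_at(sc: LakeScenario, env: dict, hours: pd.DatetimeIndex, when: pd.Timestamp) -> float:
    i = int(np.argmin(np.abs((hours - when).total_seconds().to_numpy())))
    return float(env["temp_c"][i])


def _chambers(
    sc: LakeScenario, env: dict, hours: pd.DatetimeIndex, rng: np.random.Generator
) -> tuple[list[ChamberDeployment], dict]:
    """Generate all chamber deployments; returns (deployments, truth fluxes).

    Truth per chamber is the endpoint mass balance of the noise-free
    headspace content: the injected diffusive rate plus the actually
    injected bubble load.  ``truth`` maps period label -> zone ->
    list of true total-chamber fluxes (mmol m-2 d-1).
    """
    deployments: list[ChamberDeployment] = []
    truth: dict[str, dict[str, list[float]]] = {}
    sample_t = np.linspace(0.0, sc.deployment_h, sc.samples_per_deployment)
    n_half = sc.n_total_chambers // 2
    for when in _deployment_periods(sc):
        label = when.strftime("%Y-%m-%d")
        truth[label] = {"shallow": [], "deep": []}
        temp = _temp_at(sc, env, hours, when)
        t_k = temp + 273.15
        p_pa = sc.pressure_mean_hpa * 100.0
        total_moles_hs = p_pa * sc.chamber_volume_m3 / (R_J * t_k)
        n0 = ATM_CH4_PPM * 1e-6 * total_moles_hs
        for i in range(sc.n_total_chambers + sc.n_shielded_chambers):
            shielded = i >= sc.n_total_chambers
            if shielded:
                zone = "deep" if (i - sc.n_total_chambers) % 2 else "shallow"
            else:
                zone = "shallow" if i < n_half else "deep"
            rate_mol_h = (
                sc.ch4_diffusive_mmol_m2_d[zone] * 1e-3 * sc.chamber_area_m2 / 24.0
            )
            n_t = n0 + rate_mol_h * sample_t
            if not shielded and sc.ebullition_events_per_day > 0:
                expected = sc.ebullition_events_per_day * sc.deployment_h / 24.0
                if sc.noise_free:
                    n_events = int(round(expected))
                    times = np.linspace(0, sc.deployment_h, n_events + 2)[1:-1]
                else:
                    n_events = int(rng.poisson(expected))
                    times = np.sort(rng.uniform(0, sc.deployment_h, n_events))
                for bt in times:
                    n_t = n_t + np.where(sample_t >= bt, sc.bubble_moles, 0.0)
            ppm = n_t / total_moles_hs / 1e-6
            noisy = ppm + rng.normal(0.0, sc.ch4_ppm_noise, size=ppm.shape)
            dep = ChamberDeployment(
                lake_id=sc.lake_id,
                chamber_id=f"{label}-c{i:02d}",
                chamber_type="shielded" if shielded else "total",
                volume_m3=sc.chamber_volume_m3,
                area_m2=sc.chamber_area_m2,
                elapsed_h=sample_t,
                ch4_ppm=np.maximum(noisy, 0.0),
                zone=zone,
                period=label,
                air_temp_c=temp,
                pressure_hpa=sc.pressure_mean_hpa,
            )
            deployments.append(dep)
            if not shielded:
                true_flux = (
                    (n_t[-1] - n_t[0]) / (sc.chamber_area_m2 * sc.deployment_h) * 24.0 * 1e3
                )
                truth[label][zone].append(float(true_flux))
    return deployments, truth


def _grab_samples(sc: LakeScenario) -> pd.DataFrame:
    """Under-ice and first-open-water grab profiles (uniform water column).

    Depths follow the winter sampling scheme: 0.5 m below the ice, 0.5 m
    above the sediment, and half way down when the column is deep enough.
    """
    rows = []
    under_date = pd.Timestamp(sc.ice_off) - pd.Timedelta(days=30)
    open_date = pd.Timestamp(sc.ice_off) + pd.Timedelta(days=7)
    depths = [sc.ice_thickness_m + 0.5]
    if sc.max_depth_m > 3.0:
        depths.append(sc.max_depth_m - 0.5)
    if sc.max_depth_m > 4.5:
        depths.append(sc.max_depth_m / 2.0)
    conc = {
        ("under_ice", "CO2"): sc.co2_under_ice_mol_m3,
        ("under_ice", "CH4"): sc.ch4_under_ice_mol_m3,
        ("open_water", "CO2"): sc.co2_open_mol_m3,
        ("open_water", "CH4"): sc.ch4_open_mol_m3,
    }
    for season, date in (("under_ice", under_date), ("open_water", open_date)):
        for species in ("CO2", "CH4"):
            for d in depths:
                rows.append(
                    {
                        "lake_id": sc.lake_id,
                        "date": date,
                        "season": season,
                        "depth_m": round(d, 2),
                        "species": species,
                        "concentration_mol_m3": conc[(season, species)],
                    }
                )
    return pd.DataFrame(rows)


def _cores(sc: LakeScenario, rng: np.random.Generator) -> list[CoreProfile]:
    cores = []
    for c in range(sc.n_cores):
        tops = np.arange(sc.core_slices, dtype=float)
        dry = np.full(sc.core_slices, sc.dry_mass_g_cm2_per_slice)
        cum_mid = np.cumsum(dry) - dry / 2.0
        excess = sc.surface_excess_bq_kg * np.exp(-PB210_LAMBDA * cum_mid / sc.w_true_g_cm2_yr)
        total = sc.supported_bq_kg + excess
        noisy = total + rng.normal(0.0, 1.0, size=total.shape) * (sc.counting_cv * total)
        cores.append(
            CoreProfile(
                lake_id=sc.lake_id,
                core_id=f"{sc.lake_id}-core{c + 1}",
                slices=pd.DataFrame(
                    {
                        "depth_top_cm": tops,
                        "depth_bottom_cm": tops + 1.0,
                        "dry_mass_g_cm2": dry,
                        "pb210_bq_kg": np.maximum(noisy, 0.0),
                        "pb210_sd": sc.reported_cv * total,
                        "c_fraction": np.full(sc.core_slices, sc.c_fraction),
                        "fumigation_loss_fraction": np.zeros(sc.core_slices),
                    }
                ),
            )
        )
    return cores


# ---------------------------------------------------------------------------
# closed-form truth bookkeeping (independent of the pipeline modules)

def _truth_co2_seasonal(sc: LakeScenario, env: dict, wind: WindSeries) -> float:
    """Trapezoid of the true hourly diffusive CO2 flux over the season."""
    u = wind.frame["wind_ms"].to_numpy()
    u10 = u * np.log(10.0 / DEFAULT_Z0_M) / np.log(sc.anemometer_height_m / DEFAULT_Z0_M)
    k600 = K600_INTERCEPT + K600_SLOPE * u10**K600_EXPONENT  # cm h-1
    t = env["temp_c"]
    a, b, c, d = CO2.schmidt_coeffs
    sc_num = a + b * t + c * t**2 + d * t**3
    k = k600 * np.sqrt(600.0 / sc_num) * 24.0 / 100.0  # m d-1
    kh = CO2.henry_ref * np.exp(CO2.henry_vant_hoff * (1.0 / (t + 273.15) - 1.0 / 298.15))
    c_w = kh * env["pco2_uatm"] * 1e-3
    c_eq = kh * sc.atmospheric_pco2_uatm * 1e-3
    flux = k * (c_w - c_eq) * 1e3  # mmol m-2 d-1
    mmol = float(np.trapezoid(flux, env["t_days"]))
    return mmol * MOLAR_MASS_C / 1000.0


def _truth_ch4_seasonal(sc: LakeScenario, chamber_truth: dict) -> float:
    """Step integration of true area-weighted period means over the season."""
    a_edge = basin_area_at_depth(sc.shape, sc.surface_area_m2, sc.max_depth_m, sc.zone_edge_depth_m)
    w_deep = a_edge / sc.surface_area_m2
    weights = {"shallow": 1.0 - w_deep, "deep": w_deep}
    period_means = {}
    for label, zones in chamber_truth.items():
        period_means[label] = sum(
            weights[z] * float(np.mean(f)) for z, f in zones.items() if f
        )
    start, end = pd.Timestamp(sc.ice_off), pd.Timestamp(sc.ice_on)
    dates = sorted(pd.Timestamp(d) for d in period_means)
    cuts = [start]
    for p, q in zip(dates[:-1], dates[1:]):
        cuts.append(p + (q - p) / 2)
    cuts.append(end)
    total = 0.0
    for (lo, hi), dt in zip(zip(cuts[:-1], cuts[1:]), dates):
        total += period_means[dt.strftime("%Y-%m-%d")] * (hi - lo).total_seconds() / 86400.0
    return total * MOLAR_MASS_C / 1000.0


def _truth_iceout(sc: LakeScenario) -> tuple[float, float]:
    if sc.max_depth_m <= 1.5:
        return 0.0, 0.0
    v_full = basin_volume_below(sc.shape, sc.surface_area_m2, sc.max_depth_m, 0.0)
    v_winter = basin_volume_below(sc.shape, sc.surface_area_m2, sc.max_depth_m, sc.ice_thickness_m)
    out = []
    for c_ui, c_ow in (
        (sc.co2_under_ice_mol_m3, sc.co2_open_mol_m3),
        (sc.ch4_under_ice_mol_m3, sc.ch4_open_mol_m3),
    ):
        diff = c_ui * v_winter - c_ow * v_full
        out.append(max(diff, 0.0) * MOLAR_MASS_C / sc.surface_area_m2)
    return out[0], out[1]


# ---------------------------------------------------------------------------

def generate_lake(scenario: LakeScenario) -> tuple[LakeDataset, TruthRecord]:
    """Emit the full synthetic dataset plus its closed-form truth record."""
    root = np.random.SeedSequence(scenario.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("soundings", "sensor", "wind", "chambers", "cores"), root.spawn(5)
        )
    }
    hours = _season_hours(scenario)
    env = _true_environment(scenario, hours)

    soundings = _soundings(scenario, streams["soundings"])
    sensor, sessions = _sensor_series(scenario, env, hours, streams["sensor"])
    wind = _wind_series(scenario, hours, streams["wind"])
    chambers, chamber_truth = _chambers(scenario, env, hours, streams["chambers"])
    grabs = _grab_samples(scenario)
    cores = _cores(scenario, streams["cores"])

    dataset = LakeDataset(
        lake_id=scenario.lake_id,
        surface_area_m2=scenario.surface_area_m2,
        max_depth_m=scenario.max_depth_m,
        ice_thickness_m=scenario.ice_thickness_m,
        ice_off=pd.Timestamp(scenario.ice_off),
        ice_on=pd.Timestamp(scenario.ice_on),
        zone_edge_depth_m=scenario.zone_edge_depth_m,
        atmospheric_pco2_uatm=scenario.atmospheric_pco2_uatm,
        ch4_water_conc_mol_m3=scenario.ch4_water_conc_mol_m3,
        soundings=soundings,
        sensor=sensor,
        calibration_standards=sessions,
        wind=wind,
        chambers=chambers,
        grabs=grabs,
        cores=cores,
    )
    iceout_co2, iceout_ch4 = _truth_iceout(scenario)
    truth = TruthRecord(
        lake_id=scenario.lake_id,
        co2_seasonal_gc_m2=_truth_co2_seasonal(scenario, env, wind),
        ch4_seasonal_gc_m2=_truth_ch4_seasonal(scenario, chamber_truth),
        iceout_co2_gc_m2=iceout_co2,
        iceout_ch4_gc_m2=iceout_ch4,
        burial_gc_m2_yr=scenario.w_true_g_cm2_yr * scenario.c_fraction * 1e4,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# synthetic biome table

DEFAULT_TARGET_RATIOS = {"boreal": 34.0, "subarctic_arctic": 2.4}
DEFAULT_RATIO_SDS = {"boreal": 37.0, "subarctic_arctic": 1.7}
DEFAULT_BURIAL_MEAN = 9.0  # g C m-2 yr-1, similar across biomes
DEFAULT_BURIAL_SD = 6.0


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("lognormal mean must be positive, sd nonnegative")
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_biome_table(
    n_boreal: int = 89,
    n_arctic: int = 10,
    target_ratios: dict | None = None,
    ratio_sds: dict | None = None,
    burial_mean: float = DEFAULT_BURIAL_MEAN,
    burial_sd: float = DEFAULT_BURIAL_SD,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Paired emission/burial table with lognormal ratios per biome.

    Burial is lognormal with the same parameters in both biomes (burial
    rates are comparable across biomes); the per-lake emission:burial
    ratio is lognormal around the biome target; emission = ratio x
    burial.  Defaults target mean +/- SD ratios of 34 +/- 37 (boreal) and
    2.4 +/- 1.7 (subarctic-arctic).

    Returns ``(table, truth)`` where truth records the target moments.
    """
    if n_boreal < 2 or n_arctic < 2:
        raise ValueError("need n >= 2 lakes per biome")
    ratios = dict(DEFAULT_TARGET_RATIOS, **(target_ratios or {}))
    sds = dict(DEFAULT_RATIO_SDS, **(ratio_sds or {}))
    rng = np.random.default_rng(seed)
    rows = []
    for biome, n in (("boreal", n_boreal), ("subarctic_arctic", n_arctic)):
        mu_b, sig_b = _lognormal_params(burial_mean, burial_sd)
        burial = rng.lognormal(mu_b, sig_b, size=n) if sig_b > 0 else np.full(n, burial_mean)
        if sds[biome] > 0:
            mu_r, sig_r = _lognormal_params(ratios[biome], sds[biome])
            ratio = rng.lognormal(mu_r, sig_r, size=n)
        else:
            ratio = np.full(n, ratios[biome])
        for i in range(n):
            rows.append(
                {
                    "lake_id": f"{biome}-{i:03d}",
                    "biome": biome,
                    "emission_gc_m2_yr": ratio[i] * burial[i],
                    "burial_gc_m2_yr": burial[i],
                    "paired": True,
                    "area_m2": float(np.exp(rng.normal(11.5, 1.5))),
                    "doc_mg_l": float(rng.lognormal(1.5, 0.5)),
                    "source": "synthetic",
                }
            )
    truth = {
        "target_ratio_mean": ratios,
        "target_ratio_sd": sds,
        "burial_mean": burial_mean,
        "burial_sd": burial_sd,
    }
    return pd.DataFrame(rows), truth
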