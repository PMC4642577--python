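"""End-to-end orchestration: raw input streams -> per-lake annual budget.

Ties the stage modules together in the order the data dictate:
bathymetry -> sensor calibration -> diffusive CO2 flux -> chamber CH4
fluxes -> under-ice storage -> seasonal integration -> budget.  Also owns
the CSV serialization of a :class:`~lakecarbon.synthetic.LakeDataset`
directory so the command-line interface can run stage by stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lakecarbon import annual_budget, chamber_flux, storage_emission, surface_flux
from lakecarbon.bathymetry import (
    DepthPointSet,
    Hypsometry,
    hypsometry_from_raster,
    interpolate_depth_grid,
    winter_volume,
)
from lakecarbon.chamber_flux import ChamberDeployment
from lakecarbon.gas_physics import CH4, CO2, WaterSample
from lakecarbon.sediment_burial import CoreProfile, date_core, lake_burial_rate
from lakecarbon.sensor_calibration import SensorSeries, apply_calibration, fit_calibration
from lakecarbon.surface_flux import WindSeries
from lakecarbon.synthetic import LakeDataset


# ---------------------------------------------------------------------------
# dataset directory round trip

def write_dataset(ds: LakeDataset, outdir) -> Path:
    """Write all input streams of one lake as plain CSVs plus metadata.yaml."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sdf = pd.DataFrame(
        {
            "lake_id": ds.lake_id,
            "x_m": ds.soundings.x,
            "y_m": ds.soundings.y,
            "depth_m": ds.soundings.depth,
            "is_shoreline": ds.soundings.is_shoreline,
        }
    )
    sdf.to_csv(out / "soundings.csv", index=False)
    ds.sensor.frame.assign(lake_id=ds.lake_id).to_csv(out / "sensor.csv", index=False)
    cal_rows = [
        {"session": s, "when": str(v["when"]), "true_ppm": t, "reading": r}
        for s, v in ds.calibration_standards.items()
        for t, r in v["standards"]
    ]
    pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)
    ds.wind.frame.assign(height_m=ds.wind.height_m).to_csv(out / "wind.csv", index=False)
    ch_rows = []
    for dep in ds.chambers:
        for t, ppm in zip(dep.elapsed_h, dep.ch4_ppm):
            ch_rows.append(
                {
                    "lake_id": dep.lake_id,
                    "chamber_id": dep.chamber_id,
                    "type": dep.chamber_type,
                    "zone": dep.zone,
                    "period": dep.period,
                    "volume_m3": dep.volume_m3,
                    "area_m2": dep.area_m2,
                    "elapsed_h": t,
                    "ch4_ppm": ppm,
                    "temp_c": dep.air_temp_c,
                    "pressure_hpa": dep.pressure_hpa,
                }
            )
    pd.DataFrame(ch_rows).to_csv(out / "chambers.csv", index=False)
    ds.grabs.to_csv(out / "grabs.csv", index=False)
    core_rows = []
    for core in ds.cores:
        core_rows.append(core.slices.assign(lake_id=core.lake_id, core_id=core.core_id))
    pd.concat(core_rows).to_csv(out / "cores.csv", index=False)
    meta = {
        "lake_id": ds.lake_id,
        "surface_area_m2": ds.surface_area_m2,
        "max_depth_m": ds.max_depth_m,
        "ice_thickness_m": ds.ice_thickness_m,
        "ice_off": str(ds.ice_off.date()),
        "ice_on": str(ds.ice_on.date()),
        "zone_edge_depth_m": ds.zone_edge_depth_m,
        "atmospheric_pco2_uatm": ds.atmospheric_pco2_uatm,
        "ch4_water_conc_mol_m3": ds.ch4_water_conc_mol_m3,
    }
    (out / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_dataset(indir) -> LakeDataset:
    """Inverse of :func:`write_dataset`."""
    d = Path(indir)
    meta = yaml.safe_load((d / "metadata.yaml").read_text())
    soundings = DepthPointSet.from_csv(d / "soundings.csv")
    sensor = SensorSeries.from_csv(d / "sensor.csv")
    cal = pd.read_csv(d / "calibration.csv")
    sessions = {}
    for s, g in cal.groupby("session"):
        sessions[s] = {
            "when": pd.Timestamp(g["when"].iloc[0]),
            "standards": list(zip(g["true_ppm"], g["reading"])),
        }
    wind = WindSeries.from_csv(d / "wind.csv")
    ch = pd.read_csv(d / "chambers.csv")
    chambers = []
    for cid, g in ch.groupby("chamber_id", sort=False):
        g = g.sort_values("elapsed_h")
        chambers.append(
            ChamberDeployment(
                lake_id=g["lake_id"].iloc[0],
                chamber_id=cid,
                chamber_type=g["type"].iloc[0],
                volume_m3=float(g["volume_m3"].iloc[0]),
                area_m2=float(g["area_m2"].iloc[0]),
                elapsed_h=g["elapsed_h"].to_numpy(),
                ch4_ppm=g["ch4_ppm"].to_numpy(),
                zone=g["zone"].iloc[0],
                period=str(g["period"].iloc[0]),
                air_temp_c=float(g["temp_c"].iloc[0]),
                pressure_hpa=float(g["pressure_hpa"].iloc[0]),
            )
        )
    grabs = pd.read_csv(d / "grabs.csv", parse_dates=["date"])
    cores = CoreProfile.from_csv(d / "cores.csv")
    return LakeDataset(
        lake_id=meta["lake_id"],
        surface_area_m2=float(meta["surface_area_m2"]),
        max_depth_m=float(meta["max_depth_m"]),
        ice_thickness_m=float(meta["ice_thickness_m"]),
        ice_off=pd.Timestamp(meta["ice_off"]),
        ice_on=pd.Timestamp(meta["ice_on"]),
        zone_edge_depth_m=float(meta["zone_edge_depth_m"]),
        atmospheric_pco2_uatm=float(meta["atmospheric_pco2_uatm"]),
        ch4_water_conc_mol_m3=float(meta["ch4_water_conc_mol_m3"]),
        soundings=soundings,
        sensor=sensor,
        calibration_standards=sessions,
        wind=wind,
        chambers=chambers,
        grabs=grabs,
        cores=cores,
    )


# ---------------------------------------------------------------------------
# stage runners

def lake_hypsometry(ds: LakeDataset, stratum_thickness_m: float = 0.5) -> Hypsometry:
    raster = interpolate_depth_grid(ds.soundings)
    return hypsometry_from_raster(raster, stratum_thickness_m)


def co2_flux_series(ds: LakeDataset) -> pd.DataFrame:
    pre = fit_calibration(
        ds.calibration_standards["pre"]["standards"],
        session="pre",
        when=ds.calibration_standards["pre"]["when"],
    )
    post = fit_calibration(
        ds.calibration_standards["post"]["standards"],
        session="post",
        when=ds.calibration_standards["post"]["when"],
    )
    calibrated = apply_calibration(ds.sensor, pre, post)
    calibrated = calibrated.merge(
        ds.sensor.frame[["timestamp", "water_temp_c"]], on="timestamp"
    )
    return surface_flux.flux_series(
        calibrated, ds.wind, species=CO2, atmospheric_pco2_uatm=ds.atmospheric_pco2_uatm
    )


def ch4_period_means(ds: LakeDataset, hyps: Hypsometry) -> tuple[dict, pd.DataFrame]:
    """Per-period spatial mean total CH4 flux plus a partition report.

    Total-type chambers carry the emission estimate (they see diffusion and
    bubbles alike); shielded chambers supply the diffusive baseline for the
    ebullition partition, reported per period.
    """
    a_deep = hyps.area_at_depth(ds.zone_edge_depth_m)
    w_deep = a_deep / hyps.surface_area_m2
    weights = {"shallow": 1.0 - w_deep, "deep": w_deep}
    period_means: dict[str, float] = {}
    partition_rows = []
    by_period: dict[str, list[ChamberDeployment]] = {}
    for dep in ds.chambers:
        by_period.setdefault(dep.period, []).append(dep)
    for period, deps in sorted(by_period.items()):
        zone_fluxes: dict[str, list[float]] = {}
        totals, shields = [], []
        for dep in deps:
            temp = dep.air_temp_c
            flux, method = chamber_flux.select_estimator(
                dep, ds.ch4_water_conc_mol_m3, water_temperature_c=temp
            )
            if dep.chamber_type == "total":
                zone_fluxes.setdefault(dep.zone, []).append(flux)
                totals.append(flux)
            else:
                shields.append(flux)
        period_means[period] = chamber_flux.lake_period_mean_flux(
            zone_fluxes, weights, weighting="area"
        )
        part = chamber_flux.partition_ebullition(totals, shields)
        partition_rows.append({"period": period, **part})
    return period_means, pd.DataFrame(partition_rows)


def iceout_emissions(ds: LakeDataset, hyps: Hypsometry) -> dict[str, dict]:
    """Ice break-up emission per species, g C m-2, from the grab profiles."""
    winter = winter_volume(hyps, ds.ice_thickness_m)
    out = {}
    for species_name, species in (("CO2", CO2), ("CH4", CH4)):
        snaps = {}
        for season, season_hyps in (("under_ice", winter), ("open_water", hyps)):
            sub = ds.grabs[(ds.grabs["season"] == season) & (ds.grabs["species"] == species_name)]
            if sub.empty or season_hyps.frozen_solid:
                snaps = None
                break
            samples = [
                WaterSample(
                    lake_id=ds.lake_id,
                    depth_m=row["depth_m"],
                    temperature_c=4.0,
                    concentration_mol_m3=row["concentration_mol_m3"],
                    species=species,
                )
                for _, row in sub.iterrows()
            ]
            profile = storage_emission.profile_to_strata(samples, season_hyps)
            snaps[season] = storage_emission.inventory(
                profile, season_hyps, lake_id=ds.lake_id, species=species_name,
                season=season,
            )
        if snaps is None:
            out[species_name] = {"emission_gc_m2": 0.0, "frozen_solid": True,
                                 "negative_storage": False}
            continue
        out[species_name] = storage_emission.iceout_emission(
            snaps["under_ice"], snaps["open_water"], ds.surface_area_m2, ds.max_depth_m
        )
    return out


def run_lake_pipeline(ds: LakeDataset) -> dict:
    """Full per-lake run; returns the budget and stage diagnostics."""
    hyps = lake_hypsometry(ds)
    flux = co2_flux_series(ds)
    co2_seasonal = annual_budget.integrate_flux_series(flux, ds.ice_off, ds.ice_on)
    means, partition = ch4_period_means(ds, hyps)
    ch4_seasonal = annual_budget.integrate_chamber_periods(means, ds.ice_off, ds.ice_on)
    iceout = iceout_emissions(ds, hyps)
    budget = annual_budget.assemble_budget(
        ds.lake_id,
        co2_seasonal["emission_gc_m2"],
        ch4_seasonal,
        iceout_co2_gc_m2=iceout["CO2"]["emission_gc_m2"],
        iceout_ch4_gc_m2=iceout["CH4"]["emission_gc_m2"],
    )
    burial = np.nan
    if ds.cores:
        burial = lake_burial_rate([date_core(c) for c in ds.cores])
    return {
        "budget": budget,
        "burial_gc_m2_yr": burial,
        "ratio": budget.total_gc_m2_yr / burial if burial and burial > 0 else np.nan,
        "hypsometry": hyps,
        "co2_seasonal": co2_seasonal,
        "ch4_period_means": means,
        "partition": partition,
        "iceout": iceout,
    }


# ---------------------------------------------------------------------------

def run_manifest(config: dict, inputs: list[Path]) -> dict:
    """Reproducibility manifest: config hash + input file hashes."""
    h = hashlib.sha256()
    for p in sorted(Path(p) for p in inputs):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    from lakecarbon import __version__

    return {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs_sha256": h.hexdigest(),
    }
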