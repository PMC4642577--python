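"""Gas solubility, Schmidt numbers and headspace-equilibration chemistry.

Shared physical chemistry for every flux computation: Henry's-law
solubility with van 't Hoff temperature dependence, freshwater Schmidt
number polynomials, and the two-compartment mass balance used to back out
a dissolved gas concentration from a headspace-equilibrated sample.

Unit conventions
----------------
* dissolved concentrations: mol m-3
* partial pressures at interfaces: uatm
* Henry solubility: mol L-1 atm-1
* temperatures: degrees Celsius at interfaces, Kelvin internally

Carbonate speciation is deliberately ignored: fluxes act on free CO2
only, and the lakes of interest are soft-water systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

T_REF_K = 298.15  #: reference temperature for Henry constants, K
R_L_ATM = 0.082057366  #: gas constant, L atm mol-1 K-1
MOLAR_MASS_C = 12.011  #: g C per mol of C atoms (one C per CO2 or CH4)

#: uatm -> (mol L-1 atm-1 solubility) -> mol m-3: 1e-6 atm/uatm * 1e3 L/m3
_UATM_TO_MOLM3 = 1e-3


@dataclass(frozen=True)
class GasSpecies:
    """Physical-constant bundle for one gas.

    Parameters
    ----------
    name
        ``"CO2"`` or ``"CH4"``.
    molar_mass_c
        Grams of carbon per mole of gas (12.011 for both: one C atom each).
    henry_ref
        Solubility at 298.15 K, mol L-1 atm-1.
    henry_vant_hoff
        van 't Hoff temperature-dependence constant, K.
    schmidt_coeffs
        Cubic polynomial coefficients ``(a, b, c, d)`` so that
        ``Sc(T) = a + b*T + c*T**2 + d*T**3`` with T in degrees Celsius
        (freshwater parameterization).
    """

    name: str
    henry_ref: float
    henry_vant_hoff: float
    schmidt_coeffs: tuple[float, float, float, float]
    molar_mass_c: float = MOLAR_MASS_C

    def __post_init__(self) -> None:
        if self.henry_ref <= 0:
            raise ValueError("henry_ref must be positive")
        if self.henry_vant_hoff <= 0:
            raise ValueError("henry_vant_hoff must be positive")
        t = np.linspace(0.0, 30.0, 61)
        a, b, c, d = self.schmidt_coeffs
        if np.any(a + b * t + c * t**2 + d * t**3 <= 0):
            raise ValueError("Schmidt polynomial must be positive on 0-30 C")


def _load_default_constants() -> dict:
    with resources.files("lakecarbon").joinpath("gas_constants.yaml").open() as fh:
        return yaml.safe_load(fh)


def species_from_config(name: str, config: dict | None = None) -> GasSpecies:
    """Build a :class:`GasSpecies` from the shipped (or a user) constants table."""
    cfg = config if config is not None else _load_default_constants()
    entry = cfg[name]
    return GasSpecies(
        name=name,
        henry_ref=float(entry["henry_ref"]),
        henry_vant_hoff=float(entry["henry_vant_hoff"]),
        schmidt_coeffs=tuple(float(v) for v in entry["schmidt_coeffs"]),
    )


CO2 = species_from_config("CO2")
CH4 = species_from_config("CH4")


@dataclass
class WaterSample:
    """One discrete water grab sample."""

    lake_id: str
    depth_m: float
    temperature_c: float
    partial_pressure_uatm: float | None = None
    concentration_mol_m3: float | None = None
    species: GasSpecies = field(default=CO2)
    timestamp: object = None

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError("depth must be >= 0 (downward positive)")
        if self.concentration_mol_m3 is None and self.partial_pressure_uatm is not None:
            self.concentration_mol_m3 = dissolved_concentration(
                self.species, self.partial_pressure_uatm, self.temperature_c
            )
        if self.concentration_mol_m3 is not None and self.concentration_mol_m3 < 0:
            raise ValueError("concentration must be >= 0")


def henry_constant(species: GasSpecies, temperature_c):
    """Henry solubility K_h(T) in mol L-1 atm-1.

    ``K_h(T) = henry_ref * exp(henry_vant_hoff * (1/T_K - 1/298.15))`` —
    strictly decreasing in temperature (gases are less soluble warm).

    Raises ``ValueError`` outside the liquid-water field range [-2, 40] C.
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        raise ValueError("temperature outside [-2, 40] C")
    t_k = t + 273.15
    out = species.henry_ref * np.exp(species.henry_vant_hoff * (1.0 / t_k - 1.0 / T_REF_K))
    return out if out.ndim else float(out)


def dissolved_concentration(species: GasSpecies, partial_pressure_uatm, temperature_c):
    """Dissolved concentration (mol m-3) from partial pressure via Henry's law."""
    p = np.asarray(partial_pressure_uatm, dtype=float)
    if np.any(p < 0):
        raise ValueError("partial pressure must be >= 0")
    kh = henry_constant(species, temperature_c)
    out = np.asarray(kh) * p * 1e3 * 1e-6  # uatm -> atm, mol/L -> mol/m3
    return out if out.ndim else float(out)


def equilibrium_partial_pressure(species: GasSpecies, concentration_mol_m3, temperature_c):
    """Partial pressure (uatm) in equilibrium with a dissolved concentration."""
    c = np.asarray(concentration_mol_m3, dtype=float)
    kh = henry_constant(species, temperature_c)
    out = c / (np.asarray(kh) * _UATM_TO_MOLM3)
    return out if out.ndim else float(out)


def schmidt_number(species: GasSpecies, temperature_c):
    """Schmidt number Sc = nu/D from the freshwater cubic polynomial in T (C).

    Valid on [0, 30] C where the polynomial is positive and decreasing.
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t < 0.0) or np.any(t > 30.0):
        raise ValueError("temperature outside [0, 30] C")
    a, b, c, d = species.schmidt_coeffs
    out = a + b * t + c * t**2 + d * t**3
    return out if out.ndim else float(out)


def headspace_to_source_concentration(
    species: GasSpecies,
    headspace_ppm: float,
    equilibration_temperature_c: float,
    water_volume_ml: float,
    headspace_volume_ml: float,
    pressure_atm: float = 1.0,
    initial_headspace_ppm: float = 400.0,
) -> float:
    """Original dissolved concentration (mol m-3) from a headspace equilibration.

    A water sample of volume ``water_volume_ml`` is shaken to equilibrium
    against ``headspace_volume_ml`` of gas (initially at
    ``initial_headspace_ppm``); the headspace ends at ``headspace_ppm``.
    Mass balance: the original dissolved amount equals the
    post-equilibration dissolved amount plus whatever was transferred to
    the headspace above its initial content:

        n_orig = K_h(T) * p_eq * V_w  +  (x_f - x_i) * P * V_g / (R * T_K)

    and the returned concentration is ``n_orig / V_w``.
    """
    if water_volume_ml <= 0 or headspace_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    if headspace_ppm < 0 or initial_headspace_ppm < 0:
        raise ValueError("mixing ratios must be >= 0")
    t_k = equilibration_temperature_c + 273.15
    v_w = water_volume_ml / 1000.0  # L
    v_g = headspace_volume_ml / 1000.0  # L
    p_eq_atm = headspace_ppm * 1e-6 * pressure_atm
    kh = henry_constant(species, equilibration_temperature_c)
    n_aq = kh * p_eq_atm * v_w  # mol dissolved at equilibrium
    dn_gas = (headspace_ppm - initial_headspace_ppm) * 1e-6 * pressure_atm * v_g / (
        R_L_ATM * t_k
    )
    return (n_aq + dn_gas) / v_w * 1e3  # mol/L -> mol/m3
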