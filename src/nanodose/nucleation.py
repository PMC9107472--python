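"""Superheat and homogeneous-nucleation physics of perfluorocarbon cores.

Superheated perfluorocarbon (PFC) nanodroplets behave as miniature
superheated-drop detectors: a charged particle whose linear energy transfer
(LET) is high enough deposits, within a thermal spike along its track, the
energy needed to nucleate a critical vapor embryo, vaporizing the droplet.
This module computes the degree of superheat, the critical embryo radius,
the nucleation energy, and the resulting LET threshold for any PFC in the
shipped property table (perfluorobutane by default).

Thermophysics is evaluated in SI internally; temperatures cross the public
interface in degrees Celsius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PerfluorocarbonProperties",
    "NucleationResult",
    "load_pfc_table",
    "get_pfc",
    "degree_of_superheat",
    "critical_radius",
    "nucleation_energy",
    "let_threshold",
]

R_GAS = 8.314462618  # J/(mol K)
ATM = 101325.0  # Pa
KEV = 1.602176634e-16  # J per keV


class InvalidPropertyError(ValueError):
    """Raised for degenerate thermophysical property sets (e.g. T_b >= T_c)."""


class NotSuperheatedError(ValueError):
    """Raised when the requested state is not superheated (p_v(T) <= p0)."""


def _celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass(frozen=True)
class PerfluorocarbonProperties:
    """Thermophysical constants and correlations of a PFC liquid core.

    Correlations used (all standard engineering closures):

    * surface tension: ``sigma(T) = sigma0 * (1 - T/T_c)**n`` (van der Waals /
      Guggenheim-Katayama form), anchored at a reference point;
    * saturated vapor pressure: two-point log-linear Antoine form
      ``log10(p/bar) = A - B/T`` anchored at the boiling point (1 atm) and at
      the critical point (p_c);
    * latent heat: Watson correlation anchored at the boiling point;
    * vapor density: ideal gas at the requested (T, p).
    """

    name: str
    M: float  # molar mass, g/mol
    T_b: float  # boiling temperature, degC
    T_c: float  # critical temperature, degC
    p_c: float  # critical pressure, Pa
    rho_liquid: float  # liquid density, kg/m^3
    sigma_ref: float  # surface tension at sigma_ref_T, N/m
    sigma_ref_T: float  # degC
    sigma_exponent: float
    h_fg_tb: float  # latent heat at T_b, J/kg
    watson_exponent: float

    def __post_init__(self) -> None:
        if not (self.T_b < self.T_c):
            raise InvalidPropertyError(
                f"{self.name}: T_b ({self.T_b} degC) must lie below "
                f"T_c ({self.T_c} degC)"
            )
        if self.M <= 0 or self.rho_liquid <= 0 or self.sigma_ref <= 0:
            raise InvalidPropertyError(f"{self.name}: non-positive constants")

    # --- correlations -----------------------------------------------------

    def sigma(self, T: float) -> float:
        """Surface tension (N/m) at temperature ``T`` (degC)."""
        Tk = _celsius_to_kelvin(T)
        Tck = _celsius_to_kelvin(self.T_c)
        if Tk >= Tck:
            return 0.0
        ref = 1.0 - _celsius_to_kelvin(self.sigma_ref_T) / Tck
        return self.sigma_ref * ((1.0 - Tk / Tck) / ref) ** self.sigma_exponent

    def _antoine_coefficients(self) -> tuple[float, float]:
        # log10(p/bar) = A - B/T_K through (T_b, 1 atm) and (T_c, p_c)
        tb = _celsius_to_kelvin(self.T_b)
        tc = _celsius_to_kelvin(self.T_c)
        lo = math.log10(ATM / 1e5)
        hi = math.log10(self.p_c / 1e5)
        B = (hi - lo) / (1.0 / tb - 1.0 / tc)
        A = lo + B / tb
        return A, B

    def p_v(self, T: float) -> float:
        """Saturated vapor pressure (Pa) at ``T`` (degC)."""
        A, B = self._antoine_coefficients()
        return 1e5 * 10.0 ** (A - B / _celsius_to_kelvin(T))

    def h_fg(self, T: float) -> float:
        """Latent heat of vaporization (J/kg) at ``T`` (degC), Watson-scaled."""
        Tk = _celsius_to_kelvin(T)
        Tck = _celsius_to_kelvin(self.T_c)
        if Tk >= Tck:
            return 0.0
        tr = Tk / Tck
        tr_b = _celsius_to_kelvin(self.T_b) / Tck
        return self.h_fg_tb * ((1.0 - tr) / (1.0 - tr_b)) ** self.watson_exponent

    def rho_vapor(self, T: float, p: float) -> float:
        """Ideal-gas vapor density (kg/m^3) at ``T`` (degC) and ``p`` (Pa)."""
        return p * (self.M * 1e-3) / (R_GAS * _celsius_to_kelvin(T))


@dataclass(frozen=True)
class NucleationResult:
    """Critical-embryo quantities and LET threshold at one (T, p0) state."""

    R_c: float  # m
    W_tot: float  # J
    LET_threshold: float  # keV/um
    temperature: float  # degC
    ambient_pressure: float  # Pa

    def __post_init__(self) -> None:
        if not (self.R_c > 0 and self.W_tot > 0 and self.LET_threshold > 0):
            raise ValueError("nucleation quantities must be positive")


def load_pfc_table() -> pd.DataFrame:
    """Return the built-in PFC property table as a DataFrame."""
    with resources.files("nanodose.data").joinpath("pfc_properties.csv").open() as fh:
        return pd.read_csv(fh)


def get_pfc(name: str = "perfluorobutane") -> PerfluorocarbonProperties:
    """Look up a PFC from the built-in table by name or formula."""
    table = load_pfc_table()
    mask = (table["name"].str.lower() == name.lower()) | (
        table["formula"].str.lower() == name.lower()
    )
    if not mask.any():
        raise KeyError(f"unknown PFC {name!r}; known: {list(table['name'])}")
    row = table[mask].iloc[0]
    return PerfluorocarbonProperties(
        name=row["name"],
        M=row["M_g_mol"],
        T_b=row["T_b_C"],
        T_c=row["T_c_C"],
        p_c=row["p_c_bar"] * 1e5,
        rho_liquid=row["rho_liquid_kg_m3"],
        sigma_ref=row["sigma_ref_N_m"],
        sigma_ref_T=row["sigma_ref_T_C"],
        sigma_exponent=row["sigma_exponent"],
        h_fg_tb=row["h_fg_tb_J_kg"],
        watson_exponent=row["watson_exponent"],
    )


def degree_of_superheat(T: float, props: PerfluorocarbonProperties) -> float:
    """Degree of superheat s = (T - T_b)/(T_c - T_b), all in degC.

    May fall outside [0, 1] when T lies outside [T_b, T_c]; callers that
    care can check the returned value.
    """
    if not np.isfinite(T):
        raise ValueError("temperature must be finite")
    return (T - props.T_b) / (props.T_c - props.T_b)


def critical_radius(T: float, p0: float, props: PerfluorocarbonProperties) -> float:
    """Critical vapor-embryo radius R_c = 2 sigma / (p_v - p0), in metres.

    The Laplace balance of a vapor embryo in the superheated liquid: embryos
    smaller than R_c collapse, larger ones grow into a bubble.
    """
    dp = props.p_v(T) - p0
    if dp <= 0:
        raise NotSuperheatedError(
            f"{props.name} at {T} degC, {p0:.0f} Pa is not superheated "
            f"(p_v - p0 = {dp:.1f} Pa)"
        )
    return 2.0 * props.sigma(T) / dp


def nucleation_energy(
    R_c: float,
    T: float,
    props: PerfluorocarbonProperties,
    *,
    include_expansion_work: bool = False,
    p0: float = ATM,
) -> float:
    """Energy W_tot (J) to create a critical embryo of radius ``R_c``.

    Sum of the surface-formation term ``4 pi R_c^2 sigma`` and the
    vaporization term ``(4/3) pi R_c^3 rho_vapor h_fg``. The reversible
    expansion-work term ``(4/3) pi R_c^3 (p_v - p0)`` can be switched on;
    it is off by default.
    """
    if R_c < 0:
        raise ValueError("R_c must be non-negative")
    sigma = props.sigma(T)
    p_v = props.p_v(T)
    vol = (4.0 / 3.0) * math.pi * R_c**3
    w = 4.0 * math.pi * R_c**2 * sigma + vol * props.rho_vapor(T, p_v) * props.h_fg(T)
    if include_expansion_work:
        w += vol * (p_v - p0)
    return w


def let_threshold(
    T: float,
    p0: float = ATM,
    props: PerfluorocarbonProperties | None = None,
    *,
    include_expansion_work: bool = False,
) -> NucleationResult:
    """Thermal-spike LET threshold W_tot / (2 R_c) in keV/um.

    A particle crossing the droplet must deposit at least the critical
    nucleation energy over a track segment of one critical diameter; the
    required stopping power is therefore W_tot / (2 R_c).
    """
    if props is None:
        props = get_pfc("perfluorobutane")
    r_c = critical_radius(T, p0, props)
    w_tot = nucleation_energy(
        r_c, T, props, include_expansion_work=include_expansion_work, p0=p0
    )
    let_j_per_m = w_tot / (2.0 * r_c)
    let_kev_per_um = let_j_per_m * 1e-6 / KEV
    return NucleationResult(
        R_c=r_c,
        W_tot=w_tot,
        LET_threshold=let_kev_per_um,
        temperature=T,
        ambient_pressure=p0,
    )
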