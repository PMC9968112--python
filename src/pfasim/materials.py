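"""Constitutive laws for the ablation model.

Electrical and thermal constants for the four materials (electrode,
plastic catheter, blood, myocardium), the field-dependent sigmoid
electrical conductivity of electroporated myocardium, its exponential
thermal growth and desiccation collapse, the linearly growing myocardial
thermal conductivity, and the enthalpy-method effective volumetric heat
capacity that represents the latent heat of water vaporisation as a very
large capacity over the 99-100 degC band.

All temperatures in this module are in degrees Celsius, fields in V/m,
conductivities in S/m unless noted otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RegionProperties",
    "MaterialSet",
    "default_materials",
]


@dataclass(frozen=True)
class RegionProperties:
    """Constant bulk properties of one material region."""

    density: float  # kg/m^3
    specific_heat: float  # J/kg/K
    thermal_conductivity: float  # W/m/K
    electrical_conductivity: float  # S/m

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c in J/m^3/K."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class MaterialSet:
    """Full material description of the tissue-blood-catheter system.

    Defaults are the ablation-model property table: platinum-iridium
    electrodes, an insulating plastic catheter body, blood, and
    myocardium with liquid/gas phases around the vaporisation point.
    The myocardium carries the nonlinear laws; blood, electrode and
    insulator are temperature-independent.
    """

    electrode: RegionProperties = field(
        default_factory=lambda: RegionProperties(21500.0, 132.0, 71.0, 4.6e6)
    )
    insulator: RegionProperties = field(
        default_factory=lambda: RegionProperties(70.0, 1045.0, 0.026, 1e-5)
    )
    blood: RegionProperties = field(
        default_factory=lambda: RegionProperties(1000.0, 4180.0, 0.541, 0.667)
    )
    # myocardium, liquid phase (below vaporisation)
    myocardium: RegionProperties = field(
        default_factory=lambda: RegionProperties(1060.0, 3111.0, 0.531, 0.0537)
    )
    # myocardium, gas phase (above vaporisation)
    rho_gas: float = 370.44  # kg/m^3
    c_gas: float = 2155.92  # J/kg/K

    # electroporation sigmoid: sigma rises from sigma0 to sigma1 around E_c
    sigma0: float = 0.0537  # S/m, pre-electroporation (10 Hz value)
    sigma1: float = 0.281  # S/m, post-electroporation (500 kHz value)
    e_center: float = 58000.0  # V/m, sigmoid centre
    e_width: float = 3000.0  # V/m, sigmoid width

    # thermal growth / desiccation of myocardial electrical conductivity
    sigma_growth_per_degc: float = 0.015  # 1.5 %/degC exponential growth
    desic_intercept: float = 1.371  # S/m at 100 degC on the desiccation ramp
    desic_slope: float = 0.274  # S/m per degC, 100-105 degC
    sigma_desiccated: float = 1.371e-4  # S/m above 105 degC

    # myocardial thermal conductivity law
    k37: float = 0.531  # W/m/K at 37 degC
    k_growth_per_degc: float = 0.0012  # 0.12 %/degC linear growth
    k_plateau: float = 0.606  # W/m/K above 100 degC

    # enthalpy method (water vaporisation)
    latent_heat_volumetric: float = 2.162e9  # J/m^3 = 2257 kJ/kg * 958 kg/m^3
    water_content: float = 0.75  # tissue water fraction
    phase_band: tuple[float, float] = (99.0, 100.0)  # degC
    # optional smoothing half-width for the capacity band edges (degC);
    # 0 keeps the half-open piecewise definition exactly
    capacity_smoothing: float = 0.0
    # continuity_mode rescales the desiccation ramp so it starts at the
    # growth-branch limit at 100 degC instead of the printed intercept
    continuity_mode: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.water_content <= 1.0):
            raise ValueError("water content must be in (0, 1]")
        if self.sigma0 >= self.sigma1:
            raise ValueError("sigma0 must be below sigma1")
        for name in ("sigma0", "sigma1", "e_center", "e_width",
                     "latent_heat_volumetric", "rho_gas", "c_gas", "k37"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- electrical conductivity laws (myocardium) -------------------------

    def sigma_field(self, e_mag):
        """Field-dependent myocardial conductivity sigma(E).

        Sigmoid between the pre- and post-electroporation values:
        sigma(E) = sigma0 + (sigma1 - sigma0) / (1 + 10 e^{-(|E|-Ec)/Ew}).
        """
        e_mag = np.asarray(e_mag, dtype=float)
        if np.any(e_mag < 0):
            raise ValueError("field magnitude must be nonnegative")
        z = -(e_mag - self.e_center) / self.e_width
        # clip to avoid overflow in exp; sigmoid saturates anyway
        z = np.clip(z, -700.0, 700.0)
        out = self.sigma0 + (self.sigma1 - self.sigma0) / (1.0 + 10.0 * np.exp(z))
        return out if out.ndim else float(out)

    def sigma_field_temp(self, e_mag, temp_c):
        """Field- and temperature-dependent myocardial conductivity.

        Exponential growth of 1.5 %/degC on sigma(E) up to 100 degC, a
        linear desiccation ramp on (100, 105], and a desiccated floor
        above 105 degC.  At and below 37 degC sigma(E) is used unchanged
        (the pulse train never cools tissue below its 37 degC start).
        """
        e_mag = np.asarray(e_mag, dtype=float)
        temp_c = np.asarray(temp_c, dtype=float)
        if np.any(temp_c < 0):
            raise ValueError("temperature must be >= 0 degC")
        sig_e = np.asarray(self.sigma_field(e_mag), dtype=float)
        sig_e, temp_c = np.broadcast_arrays(sig_e, temp_c)

        grown = sig_e * np.exp(self.sigma_growth_per_degc * (np.minimum(temp_c, 100.0) - 37.0))
        intercept = self.desic_intercept
        if self.continuity_mode:
            intercept = sig_e * np.exp(self.sigma_growth_per_degc * 63.0)
        ramp = intercept - self.desic_slope * (temp_c - 100.0)

        out = np.where(temp_c <= 37.0, sig_e, grown)
        out = np.where(temp_c > 100.0, ramp, out)
        out = np.where(temp_c > 105.0, self.sigma_desiccated, out)
        out = np.maximum(out, self.sigma_desiccated)
        return out if out.ndim else float(out)

    # -- thermal laws (myocardium) -----------------------------------------

    def k_temp(self, temp_c):
        """Temperature-dependent myocardial thermal conductivity k(T)."""
        temp_c = np.asarray(temp_c, dtype=float)
        if np.any(temp_c < 0):
            raise ValueError("temperature must be >= 0 degC")
        out = np.where(
            temp_c <= 100.0,
            self.k37 + self.k_growth_per_degc * (temp_c - 37.0),
            self.k_plateau,
        )
        return out if out.ndim else float(out)

    def effective_volumetric_heat_capacity(self, temp_c):
        """Enthalpy-method effective rho*c of myocardium in J/m^3/K.

        Liquid-phase rho_l c_l up to 99 degC, the latent-heat band
        Hfg * C on (99, 100], and gas-phase rho_g c_g above 100 degC.
        With ``capacity_smoothing`` > 0 the band edges are linearly
        blended over that half-width for solver robustness.
        """
        temp_c = np.asarray(temp_c, dtype=float)
        if np.any(temp_c < 0):
            raise ValueError("temperature must be >= 0 degC")
        lo, hi = self.phase_band
        c_liq = self.myocardium.volumetric_heat_capacity
        c_band = self.latent_heat_volumetric * self.water_content / (hi - lo)
        c_gas = self.rho_gas * self.c_gas
        eps = self.capacity_smoothing
        if eps <= 0.0:
            out = np.where(temp_c <= lo, c_liq, np.where(temp_c <= hi, c_band, c_gas))
        else:
            out = np.full_like(temp_c, c_band)
            out = np.where(temp_c <= lo - eps, c_liq, out)
            out = np.where(temp_c > hi + eps, c_gas, out)
            lo_blend = (temp_c > lo - eps) & (temp_c <= lo + eps)
            w = (temp_c - (lo - eps)) / (2 * eps)
            out = np.where(lo_blend, c_liq + (c_band - c_liq) * w, out)
            hi_blend = (temp_c > hi - eps) & (temp_c <= hi + eps)
            w = (temp_c - (hi - eps)) / (2 * eps)
            out = np.where(hi_blend, c_band + (c_gas - c_band) * w, out)
        return out if out.ndim else float(out)

    def myocardium_enthalpy(self, temp_c):
        """Volumetric enthalpy H(T) of myocardium in J/m^3, H(0 degC) = 0.

        Piecewise-linear integral of the effective capacity; its exact
        inverse is what makes the phase-change plateau traverse correctly
        under implicit time stepping (chord-capacity Picard iteration).
        """
        temp_c = np.asarray(temp_c, dtype=float)
        lo, hi = self.phase_band
        c_liq = self.myocardium.volumetric_heat_capacity
        c_band = self.latent_heat_volumetric * self.water_content / (hi - lo)
        c_gas = self.rho_gas * self.c_gas
        h_lo = c_liq * lo
        h_hi = h_lo + c_band * (hi - lo)
        out = np.where(
            temp_c <= lo,
            c_liq * temp_c,
            np.where(temp_c <= hi, h_lo + c_band * (temp_c - lo), h_hi + c_gas * (temp_c - hi)),
        )
        return out if out.ndim else float(out)

    def myocardium_temperature(self, enthalpy):
        """Exact inverse of :meth:`myocardium_enthalpy` (degC from J/m^3)."""
        h = np.asarray(enthalpy, dtype=float)
        lo, hi = self.phase_band
        c_liq = self.myocardium.volumetric_heat_capacity
        c_band = self.latent_heat_volumetric * self.water_content / (hi - lo)
        c_gas = self.rho_gas * self.c_gas
        h_lo = c_liq * lo
        h_hi = h_lo + c_band * (hi - lo)
        out = np.where(
            h <= h_lo,
            h / c_liq,
            np.where(h <= h_hi, lo + (h - h_lo) / c_band, hi + (h - h_hi) / c_gas),
        )
        return out if out.ndim else float(out)

    def with_overrides(self, **kwargs) -> "MaterialSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_materials() -> MaterialSet:
    """The default property set of the ablation model."""
    return MaterialSet()
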