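"""Formulation characterization arithmetic.

Entrapment efficiency and drug loading from free-drug ultrafiltration
measurements, DSC endotherm integration, and the crystallinity index of
the solid-lipid matrix relative to the bulk lipid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormulationRecord",
    "Thermogram",
    "CrystallinityInputs",
    "entrapment_efficiency",
    "free_drug_fraction",
    "drug_loading",
    "integrate_endotherm",
    "crystallinity_index",
]

#: density used to convert the liquid-oil volume to mass in the lipid-matrix
#: denominator of %DL (sesame-oil literature value, g/mL)
DEFAULT_OIL_DENSITY = 0.92


@dataclass(frozen=True)
class FormulationRecord:
    """Masses, volumes and concentrations behind one %EE / %DL calculation.

    Parameters
    ----------
    drug
        Drug name (label only).
    w0_mg
        Initial drug mass loaded into the formulation (mg).
    cfd_mg_per_ml
        Free (non-encapsulated) drug concentration in the filtrate (mg/mL).
    vf_ml
        Final formulation volume (mL).
    solid_lipid_mg
        Solid lipid mass (mg).
    oil_volume_ul
        Liquid oil volume (µL); its mass (µL x g/mL = mg) joins the solid
        lipid in the %DL denominator.
    oil_density_g_per_ml
        Oil density (g/mL).
    """

    drug: str
    w0_mg: float
    cfd_mg_per_ml: float
    vf_ml: float
    solid_lipid_mg: float = 0.0
    oil_volume_ul: float = 0.0
    oil_density_g_per_ml: float = DEFAULT_OIL_DENSITY

    def __post_init__(self) -> None:
        for name in ("w0_mg", "cfd_mg_per_ml", "solid_lipid_mg",
                     "oil_volume_ul", "oil_density_g_per_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.vf_ml <= 0:
            raise ValueError("vf_ml must be positive")

    @property
    def free_drug_mg(self) -> float:
        return self.cfd_mg_per_ml * self.vf_ml

    @property
    def lipid_mass_mg(self) -> float:
        return self.solid_lipid_mg + self.oil_volume_ul * self.oil_density_g_per_ml


def entrapment_efficiency(rec: FormulationRecord) -> float:
    """Percent of the loaded drug not found free in the external phase."""
    if rec.w0_mg <= 0:
        raise ValueError("initial drug mass must be positive")
    if rec.free_drug_mg > rec.w0_mg * (1 + 1e-12):
        raise ValueError(
            f"free drug ({rec.free_drug_mg:.4g} mg) exceeds the loaded mass "
            f"({rec.w0_mg:.4g} mg): inconsistent record")
    return (rec.w0_mg - rec.free_drug_mg) / rec.w0_mg * 100.0


def free_drug_fraction(rec: FormulationRecord) -> float:
    """Percent of the loaded drug found free; complements %EE to 100."""
    return 100.0 - entrapment_efficiency(rec)


def drug_loading(rec: FormulationRecord) -> float:
    """Entrapped drug mass per unit lipid-matrix mass, as percent."""
    if rec.lipid_mass_mg <= 0:
        raise ValueError("lipid mass must be positive")
    entrapped = rec.w0_mg - rec.free_drug_mg
    return entrapped / rec.lipid_mass_mg * 100.0


@dataclass
class Thermogram:
    """A mass-normalized DSC trace at constant heating rate.

    Heat flow is in mW/mg so integration over time in seconds yields
    mJ/mg = J/g directly.
    """

    time_s: np.ndarray
    temperature_c: np.ndarray
    heat_flow_mw_per_mg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.heat_flow_mw_per_mg = np.asarray(self.heat_flow_mw_per_mg, dtype=float)
        n = len(self.time_s)
        if not (len(self.temperature_c) == n == len(self.heat_flow_mw_per_mg)):
            raise ValueError("time, temperature and heat-flow arrays must match")
        if n < 2:
            raise ValueError("thermogram needs at least 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        rates = np.diff(self.temperature_c) / dt
        mean_rate = rates.mean()
        if mean_rate <= 0:
            raise ValueError("expected a heating (temperature-increasing) scan")
        if np.max(np.abs(rates - mean_rate)) > 0.01 * abs(mean_rate):
            raise ValueError("heating rate varies by more than 1%")

    @property
    def heating_rate_c_per_s(self) -> float:
        return float((self.temperature_c[-1] - self.temperature_c[0])
                     / (self.time_s[-1] - self.time_s[0]))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_s": self.time_s,
            "temperature_c": self.temperature_c,
            "heat_flow_mw_per_mg": self.heat_flow_mw_per_mg,
        }).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "Thermogram":
        df = pd.read_csv(path)
        cols = list(df.columns)
        if {"time_s", "temperature_c", "heat_flow_mw_per_mg"} <= set(cols):
            return cls(df["time_s"], df["temperature_c"], df["heat_flow_mw_per_mg"])
        if len(cols) == 3:  # positional: time, temperature, heat flow
            return cls(df[cols[0]], df[cols[1]], df[cols[2]])
        raise ValueError(
            "thermogram CSV needs columns time_s, temperature_c, heat_flow_mw_per_mg")


def integrate_endotherm(tg: Thermogram, window: tuple[float, float]) -> float:
    """Enthalpy (J/g) of an endothermic peak over a temperature window.

    A straight baseline joining the signal at the two window endpoints is
    subtracted; the baseline-corrected heat flow is integrated over *time*
    by the trapezoidal rule (at constant heating rate this is equivalent to
    integrating over temperature).  Endpoint values are obtained by linear
    interpolation so windows need not land on sample points.
    """
    t_lo, t_hi = sorted(window)
    temp = tg.temperature_c
    if t_lo < temp[0] or t_hi > temp[-1]:
        raise ValueError(
            f"window ({t_lo}, {t_hi}) °C outside thermogram range "
            f"({temp[0]}, {temp[-1]}) °C")
    # temperature is strictly monotone at constant positive heating rate
    time_lo = float(np.interp(t_lo, temp, tg.time_s))
    time_hi = float(np.interp(t_hi, temp, tg.time_s))
    hf_lo = float(np.interp(t_lo, temp, tg.heat_flow_mw_per_mg))
    hf_hi = float(np.interp(t_hi, temp, tg.heat_flow_mw_per_mg))

    inside = (tg.time_s > time_lo) & (tg.time_s < time_hi)
    times = np.concatenate(([time_lo], tg.time_s[inside], [time_hi]))
    signal = np.concatenate(([hf_lo], tg.heat_flow_mw_per_mg[inside], [hf_hi]))
    if time_hi > time_lo:
        baseline = hf_lo + (hf_hi - hf_lo) * (times - time_lo) / (time_hi - time_lo)
    else:
        baseline = signal
    area_mj_per_mg = float(np.trapezoid(signal - baseline, times)) / 1000.0
    return area_mj_per_mg  # mJ/mg = J/g


@dataclass(frozen=True)
class CrystallinityInputs:
    """Inputs to the crystallinity index of the lipid matrix.

    ``c_lipid_phase`` is the lipid-phase mass fraction of the dispersion
    expressed as a fraction (e.g. 0.0268 for 2.68%).
    """

    dh_dispersion_j_per_g: float
    dh_reference_j_per_g: float
    c_lipid_phase: float

    def __post_init__(self) -> None:
        if self.dh_reference_j_per_g <= 0:
            raise ValueError("reference melting enthalpy must be positive")
        if not (0 < self.c_lipid_phase <= 1):
            raise ValueError("lipid-phase fraction must lie in (0, 1]")
        if self.dh_dispersion_j_per_g < 0:
            raise ValueError("dispersion enthalpy must be nonnegative")


def crystallinity_index(ci: CrystallinityInputs) -> float:
    """Dispersion melting enthalpy over the lipid-fraction-scaled reference, %."""
    return (ci.dh_dispersion_j_per_g
            / (ci.dh_reference_j_per_g * ci.c_lipid_phase) * 100.0)
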