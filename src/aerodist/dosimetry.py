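"""Nebulizer-run accounting: deposition efficiency, nebulization rate,
radionuclide decay correction and capnoperitoneal residence time.

All operations are simple, dimensionally explicit arithmetic on declared
quantities:

* residence time of an aerosol parcel in a CO2-inflated cavity under a
  well-mixed single-compartment model, tau = V / Q;
* deposition efficiency as a weight percentage of the loaded liquid,
  assuming unit density (aqueous 0.9% saline) so that volume and weight
  fractions coincide;
* radioactive decay correction A_ref = A * 2^((t - t_ref) / T_half),
  defaulting to the Tc-99m half-life of 6.0067 h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "TC99M_HALF_LIFE_H",
    "F18_HALF_LIFE_H",
    "NebulizerRun",
    "ActivityMeasurement",
    "FlowRegime",
    "residence_time",
    "deposition_fraction",
    "activity_deposition_fraction",
    "nebulization_rate",
    "decay_correct",
]

TC99M_HALF_LIFE_H = 6.0067
F18_HALF_LIFE_H = 1.8288


@dataclass(frozen=True)
class NebulizerRun:
    """One nebulization experiment.

    Volumes in mL, time in minutes, CO2 flow in L/min, activities in MBq.
    ``deposited_volume`` is the liquid mass (as volume at unit density)
    recovered intraperitoneally.
    """

    loaded_volume: float
    nebulization_time: float
    co2_flow: float
    deposited_volume: float
    loaded_activity: Optional[float] = None
    deposited_activity: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("loaded_volume", "nebulization_time", "co2_flow", "deposited_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.deposited_volume > self.loaded_volume:
            raise ValueError("deposited_volume cannot exceed loaded_volume")
        for name in ("loaded_activity", "deposited_activity"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ActivityMeasurement:
    """A radioactivity reading (MBq) at a point in time (elapsed hours),
    tied to an isotope half-life (hours; Tc-99m by default)."""

    activity: float
    time: float
    half_life: float = TC99M_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be >= 0")
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")


@dataclass(frozen=True)
class FlowRegime:
    """Steady gas regime of the capnoperitoneum: cavity volume (mL), CO2
    flow (L/min), and the informational pressure range (mmHg)."""

    capno_volume: float
    gas_flow: float
    pressure_range: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.capno_volume <= 0:
            raise ValueError("capno_volume must be positive")
        if self.gas_flow <= 0:
            raise ValueError("gas_flow must be positive")


def residence_time(regime: FlowRegime) -> float:
    """Mean residence time (s) of aerosol in the capnoperitoneum.

    Well-mixed single-compartment model: tau = V / Q.  With V in mL and
    Q in L/min the conversion factor is exactly 60/1000:
    tau_s = (V_mL / 1000) / Q_Lpm * 60.
    """
    return regime.capno_volume / 1000.0 / regime.gas_flow * 60.0


def deposition_fraction(run: NebulizerRun) -> float:
    """Deposited fraction of the loaded liquid in wt.-% (unit-density
    aqueous assumption, so identical to the volume percentage)."""
    if run.loaded_volume == 0:
        raise ValueError("loaded_volume must be positive")
    return 100.0 * run.deposited_volume / run.loaded_volume


def activity_deposition_fraction(run: NebulizerRun) -> float:
    """Deposited fraction of the loaded *activity* in percent.

    Reported alongside the volume-based fraction; the two need not agree
    (decay timing and device dead volume affect them differently), so no
    reconciliation is forced.
    """
    if run.loaded_activity is None or run.deposited_activity is None:
        raise ValueError("both loaded_activity and deposited_activity are required")
    if run.loaded_activity == 0:
        raise ValueError("loaded_activity must be positive")
    return 100.0 * run.deposited_activity / run.loaded_activity


def nebulization_rate(run: NebulizerRun) -> float:
    """Liquid aerosolization rate in mL/min."""
    if run.nebulization_time == 0:
        raise ValueError("nebulization_time must be positive")
    return run.loaded_volume / run.nebulization_time


def decay_correct(measurement: ActivityMeasurement, reference_time: float) -> ActivityMeasurement:
    """Refer an activity reading to another time point.

    A_ref = A * 2^((t - t_ref) / T_half): a reading taken one half-life
    *after* the reference doubles when referred back.  Correcting to t'
    and back to t recovers the original activity (group property).
    """
    exponent = (measurement.time - reference_time) / measurement.half_life
    return replace(measurement, activity=measurement.activity * 2.0**exponent, time=reference_time)
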