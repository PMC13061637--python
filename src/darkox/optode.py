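"""Optode calibration, drift and Winkler cross-validation.

Optical oxygen sensors (optodes) deployed on benthic chamber landers are
calibrated against 0% and 100% air-saturation solutions at several
temperatures before deployment.  This module converts raw sensor readings to
dissolved-O2 concentrations via a per-temperature affine map with linear
interpolation of the coefficients in temperature and a multiplicative
hydrostatic-pressure correction, estimates sensor drift from repeated
calibrations, and summarises duplicate Winkler titrations used to
cross-validate the optodes.

The affine raw-signal model is an abstraction: commercial optodes report a
luminescence phase that is converted through a Stern-Volmer-type transfer
function, but a two-point calibration pins any monotone transfer function at
the two anchors, so an affine map that is exact at the calibration points
preserves the calibration contract without proprietary sensor constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_PRESSURE_COEFF,
    GG92_A,
    GG92_B,
    GG92_C0,
    ML_PER_L_TO_UMOL_PER_L,
)

__all__ = [
    "OptodeSeries",
    "CalibrationPoint",
    "CalibrationModel",
    "WinklerSample",
    "WinklerSummary",
    "o2_saturation_concentration",
    "fit_two_point",
    "apply_calibration",
    "estimate_drift",
    "winkler_summary",
    "winkler_vs_optode",
]


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------


@dataclass
class OptodeSeries:
    """A timestamped dissolved-O2 trace for one chamber.

    Parameters
    ----------
    time_s : array
        Seconds since experiment start, strictly increasing.
    o2 : array
        Dissolved O2 in µmol l-1, finite and non-negative.
    temperature : array or float
        In situ temperature, degC.
    pressure : array or float, optional
        In situ pressure, dbar.
    events : dict
        Maps an event label (``"injection"``, ``"stir_on"``, ``"stir_off"``,
        ``"syringe"``, ``"chamber_close"``) to a list of event times in
        seconds.
    """

    time_s: np.ndarray
    o2: np.ndarray
    temperature: np.ndarray | float = 1.6
    pressure: np.ndarray | float | None = None
    events: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time_s.shape != self.o2.shape:
            raise ValueError("time_s and o2 must have the same shape")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.o2)):
            raise ValueError("O2 concentrations must be finite")
        if np.any(self.o2 < 0):
            raise ValueError("O2 concentrations must be non-negative")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def time_h(self) -> np.ndarray:
        return self.time_s / 3600.0

    def copy(self) -> "OptodeSeries":
        return OptodeSeries(
            self.time_s.copy(),
            self.o2.copy(),
            np.array(self.temperature, copy=True)
            if isinstance(self.temperature, np.ndarray)
            else self.temperature,
            np.array(self.pressure, copy=True)
            if isinstance(self.pressure, np.ndarray)
            else self.pressure,
            {k: list(v) for k, v in self.events.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s, "o2_umol_l": self.o2})
        df["temp_c"] = self.temperature
        if self.pressure is not None:
            df["pressure_dbar"] = self.pressure
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, events: dict | None = None) -> "OptodeSeries":
        return cls(
            df["time_s"].to_numpy(float),
            df["o2_umol_l"].to_numpy(float),
            df["temp_c"].to_numpy(float) if "temp_c" in df else 1.6,
            df["pressure_dbar"].to_numpy(float) if "pressure_dbar" in df else None,
            events or {},
        )


# ---------------------------------------------------------------------------
# solubility
# ---------------------------------------------------------------------------


def o2_saturation_concentration(temperature: float, salinity: float = 35.0) -> float:
    """Dissolved-O2 concentration (µmol l-1) at 100% air saturation, 1 atm.

    Uses the Garcia & Gordon (1992) refit of the Benson & Krause data
    (combined-fit coefficients, ml l-1 set, converted to µmol l-1).
    Monotone decreasing in both temperature and salinity over the valid
    range.

    Parameters
    ----------
    temperature : float
        Water temperature in degC, within [-2, 40].
    salinity : float
        Practical salinity, within [0, 42].
    """
    if not (-2.0 <= temperature <= 40.0):
        raise ValueError(f"temperature {temperature} degC outside [-2, 40]")
    if not (0.0 <= salinity <= 42.0):
        raise ValueError(f"salinity {salinity} outside [0, 42]")
    ts = math.log((298.15 - temperature) / (273.15 + temperature))
    a = sum(c * ts**i for i, c in enumerate(GG92_A))
    b = sum(c * ts**i for i, c in enumerate(GG92_B))
    ln_c = a + salinity * b + GG92_C0 * salinity**2
    return math.exp(ln_c) * ML_PER_L_TO_UMOL_PER_L


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration measurement at a known saturation level.

    ``reference_o2`` is the assigned true concentration: 0 for the 0%
    solution, the solubility value (or a Winkler-confirmed value) for 100%.
    """

    temperature: float
    saturation_level: float  # 0.0 or 1.0
    raw_reading: float
    reference_o2: float

    def __post_init__(self) -> None:
        if self.saturation_level not in (0.0, 1.0):
            raise ValueError("saturation_level must be 0 or 1")
        if (self.saturation_level == 0.0) != (self.reference_o2 == 0.0):
            raise ValueError("reference_o2 must be 0 iff saturation_level is 0")


@dataclass
class CalibrationModel:
    """Per-temperature affine calibration with linear T-interpolation.

    concentration = gain(T) * (raw - offset(T)) * (1 + pressure_coeff*P/1000)

    ``offset`` is the raw reading of the 0% solution; ``gain`` maps the raw
    span between the anchors onto the reference concentration, so the model
    is exact at its own calibration points.
    """

    temperatures: np.ndarray
    offsets: np.ndarray
    gains: np.ndarray
    pressure_coeff: float = DEFAULT_PRESSURE_COEFF
    drift_rate: float = 0.0  # µmol l-1 d-1, positive = reads high over time
    calibration_epoch_day: float = 0.0
    interpolation: str = "linear"
    version: int = 1

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        if np.any(self.gains <= 0):
            raise ValueError("gains must be strictly positive")
        order = np.argsort(self.temperatures)
        self.temperatures = self.temperatures[order]
        self.offsets = self.offsets[order]
        self.gains = self.gains[order]

    def coefficients_at(self, temperature):
        """Linearly interpolated (offset, gain) at the given temperature(s)."""
        t = np.asarray(temperature, dtype=float)
        lo, hi = self.temperatures[0], self.temperatures[-1]
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"temperature outside calibrated range [{lo}, {hi}] degC"
            )
        return (
            np.interp(t, self.temperatures, self.offsets),
            np.interp(t, self.temperatures, self.gains),
        )

    def concentration(self, raw, temperature, pressure=0.0):
        """Apply the calibration to raw readings (no drift term)."""
        offset, gain = self.coefficients_at(temperature)
        p = 0.0 if pressure is None else np.asarray(pressure, dtype=float)
        if self.pressure_coeff != 0.0 and pressure is None:
            raise ValueError("pressure required when pressure_coeff != 0")
        return gain * (np.asarray(raw, float) - offset) * (
            1.0 + self.pressure_coeff * p / 1000.0
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "interpolation": self.interpolation,
            "temperatures_c": self.temperatures.tolist(),
            "offsets_raw": self.offsets.tolist(),
            "gains_umol_l_per_raw": self.gains.tolist(),
            "pressure_coeff_per_1000dbar": self.pressure_coeff,
            "drift_rate_umol_l_d": self.drift_rate,
            "calibration_epoch_day": self.calibration_epoch_day,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        if d.get("version") != 1:
            raise ValueError("unsupported calibration model version")
        return cls(
            np.asarray(d["temperatures_c"], float),
            np.asarray(d["offsets_raw"], float),
            np.asarray(d["gains_umol_l_per_raw"], float),
            pressure_coeff=float(d["pressure_coeff_per_1000dbar"]),
            drift_rate=float(d.get("drift_rate_umol_l_d", 0.0)),
            calibration_epoch_day=float(d.get("calibration_epoch_day", 0.0)),
            interpolation=d.get("interpolation", "linear"),
        )


def fit_two_point(points: list[CalibrationPoint]) -> CalibrationModel:
    """Fit the two-point multi-temperature calibration.

    Requires a 0% and a 100% point at each of at least two temperatures.
    The fitted map sends the 0% raw reading to 0 and the 100% raw reading to
    its reference concentration exactly.
    """
    by_temp: dict[float, dict[float, CalibrationPoint]] = {}
    for p in points:
        slot = by_temp.setdefault(p.temperature, {})
        if p.saturation_level in slot:
            prev = slot[p.saturation_level]
            if (prev.raw_reading, prev.reference_o2) != (p.raw_reading, p.reference_o2):
                raise ValueError(
                    f"conflicting duplicate calibration point at "
                    f"T={p.temperature}, level={p.saturation_level}"
                )
            continue
        slot[p.saturation_level] = p
    if len(by_temp) < 2:
        raise ValueError("calibration requires at least two temperatures")
    temps, offsets, gains = [], [], []
    for t in sorted(by_temp):
        slot = by_temp[t]
        if 0.0 not in slot or 1.0 not in slot:
            raise ValueError(f"missing 0% or 100% point at T={t} degC")
        zero, full = slot[0.0], slot[1.0]
        span = full.raw_reading - zero.raw_reading
        if span == 0:
            raise ValueError(f"zero raw span at T={t} degC")
        temps.append(t)
        offsets.append(zero.raw_reading)
        gains.append(full.reference_o2 / span)
    return CalibrationModel(np.array(temps), np.array(offsets), np.array(gains))


def apply_calibration(
    time_s,
    raw,
    model: CalibrationModel,
    temperature,
    pressure=None,
    drift_correction: bool = False,
    events: dict | None = None,
) -> OptodeSeries:
    """Convert a raw optode series to a calibrated :class:`OptodeSeries`.

    Drift correction (off by default; lander-scale drift is typically
    negligible) subtracts ``drift_rate * days_since_epoch`` where the epoch
    is the model's calibration time and time_s is measured from it.
    """
    o2 = model.concentration(raw, temperature, pressure)
    if drift_correction:
        days = (np.asarray(time_s, float) / 86400.0) - model.calibration_epoch_day
        o2 = o2 - model.drift_rate * days
    o2 = np.asarray(o2, dtype=float)
    # clip tiny negative values from sensor noise near anoxia
    o2[(o2 < 0) & (o2 > -1e-9)] = 0.0
    return OptodeSeries(np.asarray(time_s, float), o2, temperature, pressure,
                        events or {})


def estimate_drift(
    pre_cal: CalibrationModel,
    post_cal: CalibrationModel,
    elapsed_days: float,
    reference_raw=None,
) -> float:
    """Sensor drift (µmol l-1 d-1) between two calibrations.

    Evaluates both models at reference conditions — by default the
    pre-calibration 100%-saturation raw readings at each temperature shared
    by both models — and divides the mean concentration discrepancy by the
    elapsed time.  Positive drift means the sensor reads higher at the later
    calibration.
    """
    if elapsed_days <= 0:
        raise ValueError("elapsed_days must be positive")
    temps = np.intersect1d(pre_cal.temperatures, post_cal.temperatures)
    if temps.size == 0:
        raise ValueError("calibrations share no temperatures")
    if reference_raw is None:
        off, gain = pre_cal.coefficients_at(temps)
        # raw reading corresponding to the pre-calibration 100% anchor
        ref_c = np.array(
            [o2_saturation_concentration(t) for t in temps]
        )
        reference_raw = off + ref_c / gain
    pre_c = pre_cal.concentration(reference_raw, temps, 0.0)
    post_c = post_cal.concentration(reference_raw, temps, 0.0)
    return float(np.mean(post_c - pre_c) / elapsed_days)


# ---------------------------------------------------------------------------
# Winkler titrations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WinklerSample:
    """Duplicate Winkler titrations of one syringe sample."""

    experiment_id: str
    syringe_time_h: float
    titrations: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.titrations) != 2:
            raise ValueError("each Winkler sample must have exactly two titrations")


@dataclass
class WinklerSummary:
    """Per-sample means and the duplicate-error statistics."""

    table: pd.DataFrame  # experiment_id, syringe_time_h, mean_o2, abs_error
    mean_error: float
    se_error: float
    n: int

    def format(self, digits: int = 1) -> str:
        return (
            f"{self.mean_error:.{digits}f} ± {self.se_error:.{digits}f} "
            f"(n={self.n})"
        )


def winkler_summary(samples: list[WinklerSample]) -> WinklerSummary:
    """Mean of duplicates per sample plus duplicate-error mean ± SE."""
    if not samples:
        raise ValueError("no Winkler samples")
    rows = [
        {
            "experiment_id": s.experiment_id,
            "syringe_time_h": s.syringe_time_h,
            "mean_o2": (s.titrations[0] + s.titrations[1]) / 2.0,
            "abs_error": abs(s.titrations[0] - s.titrations[1]),
        }
        for s in samples
    ]
    table = pd.DataFrame(rows)
    errors = table["abs_error"].to_numpy()
    n = errors.size
    se = float(errors.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return WinklerSummary(table, float(errors.mean()), se, n)


def winkler_vs_optode(
    summary: WinklerSummary,
    series: OptodeSeries,
    window_s: float = 60.0,
) -> tuple[float, float, int, pd.DataFrame]:
    """Percent difference of Winkler values from optode values.

    Each Winkler syringe time is matched to the nearest optode sample within
    ``window_s``; the per-pair difference is ``100*(optode - winkler)/optode``
    so a positive value means the Winkler value is lower.  Returns
    ``(mean, se, n, pair_table)``.
    """
    diffs = []
    rows = []
    for _, row in summary.table.iterrows():
        t = row["syringe_time_h"] * 3600.0
        i = int(np.argmin(np.abs(series.time_s - t)))
        if abs(series.time_s[i] - t) > window_s:
            raise ValueError(
                f"no optode sample within {window_s} s of syringe time "
                f"{row['syringe_time_h']} h"
            )
        opt = series.o2[i]
        pct = 100.0 * (opt - row["mean_o2"]) / opt
        diffs.append(pct)
        rows.append(
            {
                "syringe_time_h": row["syringe_time_h"],
                "winkler_o2": row["mean_o2"],
                "optode_o2": opt,
                "percent_diff": pct,
            }
        )
    d = np.array(diffs)
    n = d.size
    se = float(d.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(d.mean()), se, n, pd.DataFrame(rows)
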