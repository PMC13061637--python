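"""Synthetic benthic-chamber, microprofile, voltage and taxon data.

Every downstream estimator in this package is exercised against data from
this module.  The chamber generator emulates the phenomenology of abyssal
nodule-field incubations: chambers seal ~185 µmol l-1 bottom water, dissolved
O2 then rises (net dark oxygen production) along a monotone,
exponentially-saturating trajectory over ~47 h, with a flat initial segment
while the stirrer is off, step dilution dips when a syringe sampler entrains
50 ml of ambient water, slow linear sensor drift, i.i.d. Gaussian sensor
noise and optional logging gaps.  Each generator returns the data together
with a truth record carrying every generating parameter, so parameter
recovery can be tested exactly.

Randomness: each generator derives independent child streams from the single
root seed via ``numpy.random.SeedSequence(seed).spawn`` in a fixed,
documented order, so identical seed + config give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .electrochem import VoltageSurvey
from .microprofile import Microprofile
from .optode import OptodeSeries

__all__ = [
    "ConfigInfeasibleError",
    "ChamberSimConfig",
    "ChamberTruth",
    "ProfileSimConfig",
    "ProfileTruth",
    "simulate_chamber_series",
    "simulate_ambient_series",
    "simulate_microprofile",
    "simulate_voltage_survey",
    "simulate_taxon_table",
]


class ConfigInfeasibleError(ValueError):
    """The requested configuration produces non-physical concentrations."""


# ---------------------------------------------------------------------------
# benthic chamber series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChamberSimConfig:
    """Generating parameters for one synthetic chamber incubation.

    Defaults are the study conditions of an abyssal nodule-field deployment:
    initial O2 185.2 ± 2.9 µmol l-1, SCOC 0.7 mmol m-2 d-1, mean net dark O2
    production 3.5 mmol m-2 d-1 (so gross production 4.2), a 484 cm2 square
    chamber, syringe sampling at 28, 38 and 47 h entraining 50 ml of ambient
    water, 10-s logging, 0.5 µmol l-1 sensor noise and 0.27 µmol l-1 d-1
    drift.
    """

    initial_o2_mean: float = 185.2   # µmol l-1
    initial_o2_sd: float = 2.9       # µmol l-1
    scoc_true: float = 0.7           # mmol m-2 d-1, consumption >= 0
    dop_true: float = 4.2            # mmol m-2 d-1, production >= 0
    saturation_shape: float = 1.0    # 0 = linear; larger = earlier plateau
    chamber_area: float = 484.0      # cm2
    water_depth: float = 10.0        # cm
    stir_off_interval: float = 1.0   # h, reading flat from t=0
    syringe_times: tuple[float, ...] = (28.0, 38.0, 47.0)  # h
    syringe_volume: float = 50.0     # ml entrained per event
    ambient_o2: float = 185.2        # µmol l-1
    noise_sd: float = 0.5            # µmol l-1
    drift_rate: float = 0.27         # µmol l-1 d-1
    log_interval: float = 10.0       # s
    gap_intervals: tuple[tuple[float, float], ...] = ()  # (start h, end h)
    duration_h: float = 47.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chamber_area <= 0 or self.water_depth <= 0:
            raise ValueError("chamber_area and water_depth must be positive")
        if self.syringe_volume >= self.water_volume_l * 1000.0:
            raise ValueError("syringe_volume must be below the water volume")
        if self.noise_sd < 0 or self.initial_o2_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.scoc_true < 0 or self.dop_true < 0:
            raise ValueError("rates are magnitudes and must be non-negative")
        if self.log_interval <= 0 or self.duration_h <= 0:
            raise ValueError("log_interval and duration_h must be positive")

    @property
    def water_volume_l(self) -> float:
        return self.chamber_area * self.water_depth / 1000.0

    @property
    def net_rate(self) -> float:
        """Generating net areal rate, mmol m-2 d-1 (production positive)."""
        return self.dop_true - self.scoc_true

    @property
    def slope_umol_l_d(self) -> float:
        """Undamped concentration trend: rate * 100 / water_depth."""
        return self.net_rate * 100.0 / self.water_depth


@dataclass
class ChamberTruth:
    """Everything the chamber generator actually did."""

    config: ChamberSimConfig
    initial_o2: float
    net_rate: float
    slope_umol_l_d: float
    tau_d: float | None           # damping timescale, None when linear
    dilution_steps: list[float]   # µmol l-1 removed at each syringe event

    def expected_delta(self, t_h: float) -> float:
        """Cumulative produced concentration (µmol l-1) at time t, before
        dilution, drift and noise."""
        t_d = t_h / 24.0
        if self.tau_d is None:
            return self.slope_umol_l_d * t_d
        return self.slope_umol_l_d * self.tau_d * (1.0 - math.exp(-t_d / self.tau_d))

    def to_record(self) -> dict:
        rec = {f"cfg_{k}": v for k, v in vars(self.config).items()}
        rec.update(
            initial_o2=self.initial_o2,
            net_rate=self.net_rate,
            slope_umol_l_d=self.slope_umol_l_d,
            tau_d=self.tau_d,
            dilution_steps=list(self.dilution_steps),
        )
        return rec


def _chamber_streams(seed: int) -> list[np.random.Generator]:
    """Child RNG streams, fixed order: [initial, noise, ambient]."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]


def simulate_chamber_series(
    config: ChamberSimConfig,
) -> tuple[OptodeSeries, ChamberTruth]:
    """Generate one chamber optode series plus its truth record.

    Construction order: saturating production curve -> flat stirrer-off
    reading -> cumulative mass-balance dilution steps at syringe events ->
    linear drift -> Gaussian noise -> gap removal.  Dilution magnitudes are
    computed from the series value at the last sample before each event,
    exactly as the mass balance C_after = (C(V-v) + C_amb v)/V prescribes.
    """
    rng_init, rng_noise, _ = _chamber_streams(config.seed)
    initial = config.initial_o2_mean + config.initial_o2_sd * rng_init.standard_normal()

    t_s = np.arange(0.0, config.duration_h * 3600.0 + config.log_interval / 2,
                    config.log_interval)
    t_d = t_s / 86400.0

    m0 = config.slope_umol_l_d
    if config.saturation_shape > 0:
        tau = (config.duration_h / 24.0) / config.saturation_shape
        delta = m0 * tau * (1.0 - np.exp(-t_d / tau))
    else:
        tau = None
        delta = m0 * t_d
    c = initial + delta

    # optode reads the unmixed near-lid water until the stirrer starts
    c[t_s < config.stir_off_interval * 3600.0] = initial

    v = config.syringe_volume / 1000.0  # l
    V = config.water_volume_l
    steps: list[float] = []
    for te in sorted(config.syringe_times):
        te_s = te * 3600.0
        before = np.nonzero(t_s < te_s)[0]
        if before.size == 0:
            continue
        c_before = c[before[-1]]
        step = (c_before - config.ambient_o2) * v / V
        c[t_s >= te_s] -= step
        steps.append(float(step))

    c = c + config.drift_rate * t_d
    if config.noise_sd > 0:
        c = c + rng_noise.normal(0.0, config.noise_sd, size=c.size)

    keep = np.ones(t_s.size, dtype=bool)
    for start_h, end_h in config.gap_intervals:
        keep &= ~((t_s >= start_h * 3600.0) & (t_s < end_h * 3600.0))
    t_s, c = t_s[keep], c[keep]

    if not np.all(np.isfinite(c)) or np.any(c < 0):
        raise ConfigInfeasibleError(
            "configuration produced non-finite or negative concentrations"
        )

    events = {
        "stir_off": [0.0],
        "stir_on": [config.stir_off_interval * 3600.0],
        "syringe": [te * 3600.0 for te in sorted(config.syringe_times)],
        "chamber_close": [0.0],
    }
    series = OptodeSeries(t_s, c, temperature=1.6, events=events)
    truth = ChamberTruth(config, float(initial), config.net_rate, m0,
                         tau, steps)
    return series, truth


def simulate_ambient_series(config: ChamberSimConfig) -> OptodeSeries:
    """Constant ambient control trace outside the chamber (noise only)."""
    _, _, rng_amb = _chamber_streams(config.seed)
    t_s = np.arange(0.0, config.duration_h * 3600.0 + config.log_interval / 2,
                    config.log_interval)
    c = np.full(t_s.size, config.ambient_o2)
    if config.noise_sd > 0:
        c = c + rng_amb.normal(0.0, config.noise_sd, size=c.size)
    if np.any(c < 0):
        raise ConfigInfeasibleError("ambient configuration infeasible")
    return OptodeSeries(t_s, c, temperature=1.6)


# ---------------------------------------------------------------------------
# porewater microprofiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSimConfig:
    """Generating parameters for one synthetic porewater microprofile.

    The profile is constant (overlying water) above the interface, declines
    linearly with gradient ``true_flux / (porosity * diffusivity)`` over the
    upper half of ``penetration_depth_mm``, then relaxes along a
    slope-matched exponential tail.  ``diffusivity`` is the effective
    (tortuosity-corrected) Ds used in the construction.  ``noise_sd`` is the
    per-replicate sensor noise; ``n_replicates`` readings are taken per
    depth and averaged, as the profiler does.
    """

    true_flux: float = 0.7            # mmol m-2 d-1 into sediment
    porosity: float = 0.8
    diffusivity: float = 8.159e-6     # cm2 s-1 (effective Ds)
    overlying_o2: float = 185.2       # µmol l-1
    penetration_depth_mm: float = 4.0  # profiled sediment thickness
    surface_depth_offset_mm: float = 2.0
    step_mm: float = 0.05
    noise_sd: float = 0.5             # µmol l-1 per replicate reading
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step must be positive")
        if not (0.0 < self.porosity < 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_flux < 0:
            raise ValueError("true_flux is a consumption magnitude")

    @property
    def gradient(self) -> float:
        """Near-surface dC/dz magnitude, µmol l-1 mm-1."""
        from .constants import FICK_UNIT

        return self.true_flux / (self.porosity * self.diffusivity * FICK_UNIT)


@dataclass
class ProfileTruth:
    config: ProfileSimConfig
    surface_index: int
    gradient: float  # µmol l-1 mm-1, magnitude


def simulate_microprofile(
    config: ProfileSimConfig,
) -> tuple[Microprofile, ProfileTruth]:
    """Generate a microprofile plus truth record.

    The sediment surface is snapped onto the depth grid so the true
    interface index is exact.  Replicate noise is added after construction;
    the returned profile holds the replicate means (and SDs for QC).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n_surf = round(config.surface_depth_offset_mm / config.step_mm)
    z0 = n_surf * config.step_mm
    depths = np.arange(
        0.0,
        z0 + config.penetration_depth_mm + config.step_mm / 2,
        config.step_mm,
    )
    g = config.gradient
    lin_thickness = config.penetration_depth_mm / 2.0
    c = np.full(depths.size, config.overlying_o2)
    below = depths > z0
    dz = depths[below] - z0
    lin = config.overlying_o2 - g * np.minimum(dz, lin_thickness)
    c_t = config.overlying_o2 - g * lin_thickness
    if c_t <= 0:
        raise ConfigInfeasibleError(
            "gradient depletes O2 within the linear zone; reduce true_flux "
            "or penetration depth"
        )
    tail = dz > lin_thickness
    vals = lin.copy()
    if g > 0:
        vals[tail] = c_t * np.exp(-g * (dz[tail] - lin_thickness) / c_t)
    c[below] = vals

    reps = c[:, None] + rng.normal(
        0.0, config.noise_sd, size=(depths.size, config.n_replicates)
    )
    profile = Microprofile(
        depths,
        reps.mean(axis=1),
        reps.std(axis=1, ddof=1),
        np.full(depths.size, config.n_replicates),
    )
    return profile, ProfileTruth(config, int(n_surf), g)


# ---------------------------------------------------------------------------
# voltage surveys and taxon tables
# ---------------------------------------------------------------------------


def simulate_voltage_survey(
    n_sites: int,
    mean_v: float = 0.2,
    sd_v: float = 0.1,
    background_v: float = 0.003,
    seed: int = 0,
    specimen: str = "nodule",
    temperature: float = 21.0,
) -> VoltageSurvey:
    """Replicate open-circuit potentials across one specimen's surface."""
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    raw = mean_v + sd_v * rng.standard_normal(n_sites)
    return VoltageSurvey(
        specimen=specimen,
        license_area="synthetic",
        temperature=temperature,
        potentials=raw,
        background=background_v,
    )


def simulate_taxon_table(
    n_samples: int,
    n_taxa: int,
    correlated_taxon_rho: float,
    dop_values,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative-abundance table with one taxon rank-linked to DOP.

    Rows (samples) sum to 1.  The first taxon's values are assigned to
    samples by the rank of a Gaussian blend ``rho*z(dop) + sqrt(1-rho^2)*e``,
    giving a target rank correlation with ``dop_values`` by construction
    (exact monotone coupling at |rho| = 1); the remaining taxa are
    independent log-normal abundances.
    """
    dop_values = np.asarray(dop_values, dtype=float)
    if dop_values.size != n_samples:
        raise ValueError("dop_values length must equal n_samples")
    if not (-1.0 <= correlated_taxon_rho <= 1.0):
        raise ValueError("correlated_taxon_rho must lie in [-1, 1]")
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    abund = rng.lognormal(mean=0.0, sigma=1.0, size=(n_samples, n_taxa))

    from scipy import stats

    rho = correlated_taxon_rho
    z_dop = stats.zscore(stats.rankdata(dop_values)) if n_samples > 1 else np.zeros(1)
    z = rho * z_dop + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n_samples)
    order = np.argsort(np.argsort(z))  # rank of z per sample
    # the designated taxon's *relative* abundance is assigned directly (so
    # the rank coupling survives row normalisation); the remaining taxa
    # share the residual fraction
    frac0 = np.sort(abund[:, 0] / (1.0 + abund[:, 0]))[order]
    rest = abund[:, 1:]
    rest = rest / rest.sum(axis=1, keepdims=True) * (1.0 - frac0)[:, None]
    abund = np.column_stack([frac0, rest])
    return pd.DataFrame(
        abund,
        index=[f"sample_{i + 1:02d}" for i in range(n_samples)],
        columns=[f"taxon_{j + 1:02d}" for j in range(n_taxa)],
    )
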