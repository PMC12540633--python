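"""Thermal-index computation for transect records.

Each meteorological record is enriched to a :class:`ThermalRecord` carrying
vapour pressure, mean radiant temperature (Tmrt), the Universal Thermal
Climate Index (UTCI) and a heat/cold stress category.

Tmrt comes from the globe-thermometer energy balance by default: a small grey
globe equilibrates between radiant gain and forced-convective exchange, so

    Tmrt = [ (Tg + 273.15)^4 + h_cg * (Tg - Ta) ]^(1/4) - 273.15,
    h_cg = 1.1e8 * va^0.6 / (eps * D^0.4)

with globe temperature Tg, air temperature Ta, air speed va [m/s], globe
diameter D [m] and emissivity eps. An alternative irradiance-based Tmrt
estimate is available behind a switch and is explicitly approximate.

Wind was not measured on the transects (hand-carried device, calm summer
conditions), so a fixed assumed 10-m speed is used — by default 0.5 m/s, the
lower validity bound of the UTCI polynomial — and every record is flagged
``wind_assumed``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._utci_poly import utci_offset
from .transect_io import Lap

__all__ = [
    "GlobeSpec",
    "WindConfig",
    "StressCategory",
    "ThermalRecord",
    "LapSummary",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "tmrt_from_globe",
    "tmrt_from_irradiance",
    "utci",
    "utci_vector",
    "classify_stress",
    "enrich_lap",
]

# Magnus saturation vapour pressure over water (WMO form):
#   es(T) = 6.112 hPa * exp(17.62 T / (243.12 + T)),  T in degC
_MAGNUS_ES0 = 6.112
_MAGNUS_A = 17.62
_MAGNUS_B = 243.12

SIGMA_SB = 5.670374419e-8  # W m-2 K-4


@dataclass(frozen=True)
class GlobeSpec:
    """Geometry of the globe thermometer (small grey globe by default)."""

    diameter: float = 0.04   # m
    emissivity: float = 0.95

    def __post_init__(self) -> None:
        if not (0.01 < self.diameter <= 0.2):
            raise ValueError(f"globe diameter {self.diameter} m outside (0.01, 0.2]")
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError(f"globe emissivity {self.emissivity} outside (0, 1]")


@dataclass(frozen=True)
class WindConfig:
    """Assumed constant 10-m wind speed [m/s] (wind was not measured)."""

    assumed_speed_10m: float = 0.5

    def __post_init__(self) -> None:
        if not (0.5 <= self.assumed_speed_10m <= 17.0):
            raise ValueError(
                f"assumed wind {self.assumed_speed_10m} m/s outside UTCI validity [0.5, 17]"
            )


class StressCategory(Enum):
    """UTCI heat/cold stress classes on half-open [lower, upper) intervals."""

    EXTREME_COLD = (-np.inf, -40.0)
    VERY_STRONG_COLD = (-40.0, -27.0)
    STRONG_COLD = (-27.0, -13.0)
    MODERATE_COLD = (-13.0, 0.0)
    SLIGHT_COLD = (0.0, 9.0)
    NO_THERMAL_STRESS = (9.0, 26.0)
    MODERATE_HEAT = (26.0, 32.0)
    STRONG_HEAT = (32.0, 38.0)
    VERY_STRONG_HEAT = (38.0, 46.0)
    EXTREME_HEAT = (46.0, np.inf)

    @property
    def lower(self) -> float:
        return self.value[0]

    @property
    def upper(self) -> float:
        return self.value[1]


def classify_stress(utci_c: float) -> StressCategory:
    """Deterministic half-open interval lookup of the UTCI stress class."""
    if not np.isfinite(utci_c):
        raise ValueError(f"non-finite UTCI value {utci_c}")
    for cat in StressCategory:
        if cat.lower <= utci_c < cat.upper:
            return cat
    raise AssertionError("stress categories must partition the real line")


def saturation_vapour_pressure(air_temp):
    """Magnus saturation vapour pressure over water [hPa].

    Outside the sensible meteorological range [-50, 60] degC the value is
    still returned (the formula extrapolates smoothly); callers flag rather
    than reject such inputs.
    """
    t = np.asarray(air_temp, dtype=float)
    return _MAGNUS_ES0 * np.exp(_MAGNUS_A * t / (_MAGNUS_B + t))


def vapour_pressure(air_temp, rel_humidity):
    """Actual water vapour pressure [hPa] from temperature and RH [%]."""
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity outside [0, 100] %")
    return rh / 100.0 * saturation_vapour_pressure(air_temp)


def tmrt_from_globe(globe_temp, air_temp, wind: WindConfig = WindConfig(),
                    spec: GlobeSpec = GlobeSpec()):
    """Mean radiant temperature [degC] from the globe energy balance.

    When ``globe_temp == air_temp`` the convective term vanishes and
    Tmrt equals the globe temperature. A negative radicand (possible only
    for extreme ``Tg < Ta``) is resolved by the signed fourth-root magnitude
    so that a value is always returned; callers should treat such records as
    flagged.
    """
    tg = np.asarray(globe_temp, dtype=float)
    ta = np.asarray(air_temp, dtype=float)
    h = 1.1e8 * wind.assumed_speed_10m ** 0.6 / (spec.emissivity * spec.diameter ** 0.4)
    radicand = (tg + 273.15) ** 4 + h * (tg - ta)
    tmrt_k = np.sign(radicand) * np.abs(radicand) ** 0.25
    return tmrt_k - 273.15


def tmrt_from_irradiance(air_temp, global_irradiance, absorptivity: float = 0.7,
                         projected_area_factor: float = 0.25,
                         emissivity_person: float = 0.97):
    """Approximate Tmrt [degC] from global irradiance alone.

    A deliberately simple estimate for devices without a globe channel: the
    short-wave gain of a standing person is added to an assumed long-wave
    field at air temperature. It ignores reflected and diffuse anisotropy and
    is labelled approximate; the globe-based path is preferred when a globe
    temperature exists.
    """
    ta_k = np.asarray(air_temp, dtype=float) + 273.15
    s = np.clip(np.asarray(global_irradiance, dtype=float), 0.0, None)
    gain = projected_area_factor * absorptivity * s / (emissivity_person * SIGMA_SB)
    return (ta_k ** 4 + gain) ** 0.25 - 273.15


def utci_vector(air_temp, tmrt, wind_10m, vapour_pressure_hpa):
    """Vectorised UTCI [degC] with clamping flags.

    Inputs are clamped into the validity box of the polynomial approximation
    (Ta in [-50, 50] degC, Tmrt - Ta in [-30, 70] K, wind in [0.5, 17] m/s,
    vapour pressure at most saturation and 50 hPa); the returned boolean
    arrays record which records were touched by which clamp.
    """
    ta = np.asarray(air_temp, dtype=float)
    tr = np.asarray(tmrt, dtype=float)
    va = np.asarray(wind_10m, dtype=float)
    pa = np.asarray(vapour_pressure_hpa, dtype=float)
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(tr))
            and np.all(np.isfinite(va)) and np.all(np.isfinite(pa))):
        raise ValueError("non-finite input to UTCI")

    ta_c = np.clip(ta, -50.0, 50.0)
    d = np.clip(tr - ta_c, -30.0, 70.0)
    va_c = np.clip(va, 0.5, 17.0)
    pa_cap = np.minimum(saturation_vapour_pressure(ta_c), 50.0)
    pa_c = np.clip(pa, 0.0, pa_cap)

    value = ta_c + utci_offset(ta_c, va_c, d, pa_c / 10.0)  # polynomial takes kPa
    shape = np.shape(value)
    flags = {
        "ta_clamped": np.broadcast_to(ta_c != ta, shape),
        "tmrt_clamped": np.broadcast_to(d != (tr - ta_c), shape),
        "wind_clamped": np.broadcast_to(va_c != va, shape),
        "humidity_clamped": np.broadcast_to(pa_c != pa, shape),
    }
    return value, flags


def utci(air_temp: float, tmrt: float, wind_10m: float,
         vapour_pressure_hpa: float) -> tuple[float, frozenset[str]]:
    """Scalar UTCI [degC] plus the set of clamping flags that fired."""
    value, flags = utci_vector(air_temp, tmrt, wind_10m, vapour_pressure_hpa)
    fired = frozenset(name for name, mask in flags.items() if bool(np.asarray(mask)))
    return float(value), fired


@dataclass(frozen=True)
class ThermalRecord:
    """A meteorological record enriched with derived thermal quantities."""

    timestamp: dt.datetime
    lat: float
    lon: float
    air_temp: float
    rel_humidity: float
    pressure: float
    surface_temp: float
    globe_temp: float
    global_irradiance: float
    vapour_pressure: float  # hPa
    tmrt: float             # degC
    utci: float             # degC
    stress_category: StressCategory
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class LapSummary:
    lap_id: str
    n_records: int
    utci_min: float
    utci_max: float
    utci_mean: float


def enrich_lap(lap: Lap, wind: WindConfig = WindConfig(),
               spec: GlobeSpec = GlobeSpec(),
               tmrt_method: str = "globe") -> tuple[list[ThermalRecord], LapSummary]:
    """Compute vapour pressure, Tmrt, UTCI and stress class for every record.

    ``tmrt_method`` is ``"globe"`` (default, energy-balance inversion of the
    globe channel) or ``"irradiance"`` (approximate, for logs without a globe
    thermometer). Returns one :class:`ThermalRecord` per input record plus a
    lap-level UTCI summary.
    """
    if not lap.records:
        raise ValueError(f"lap {lap.lap_id} has no valid records to enrich")
    recs = lap.records
    ta = np.array([r.air_temp for r in recs])
    rh = np.array([r.rel_humidity for r in recs])
    tg = np.array([r.globe_temp for r in recs])
    s = np.array([r.global_irradiance for r in recs])

    vp = vapour_pressure(ta, rh)
    if tmrt_method == "globe":
        tmrt = tmrt_from_globe(tg, ta, wind, spec)
        neg_radicand = tmrt + 273.15 < 0
    elif tmrt_method == "irradiance":
        tmrt = tmrt_from_irradiance(ta, s)
        neg_radicand = np.zeros(len(recs), dtype=bool)
    else:
        raise ValueError(f"unknown tmrt_method {tmrt_method!r}")

    values, clamp_flags = utci_vector(ta, tmrt, wind.assumed_speed_10m, vp)

    enriched: list[ThermalRecord] = []
    for i, r in enumerate(recs):
        fl = {"wind_assumed"}
        if tmrt_method == "irradiance":
            fl.add("tmrt_approximate")
        if neg_radicand[i]:
            fl.add("globe_radicand_negative")
        for name, mask in clamp_flags.items():
            if mask[i]:
                fl.add(name)
        enriched.append(ThermalRecord(
            timestamp=r.timestamp, lat=r.lat, lon=r.lon, air_temp=r.air_temp,
            rel_humidity=r.rel_humidity, pressure=r.pressure,
            surface_temp=r.surface_temp, globe_temp=r.globe_temp,
            global_irradiance=r.global_irradiance,
            vapour_pressure=float(vp[i]), tmrt=float(tmrt[i]),
            utci=float(values[i]), stress_category=classify_stress(float(values[i])),
            flags=frozenset(fl),
        ))
    summary = LapSummary(
        lap_id=lap.lap_id, n_records=len(enriched),
        utci_min=float(values.min()), utci_max=float(values.max()),
        utci_mean=float(values.mean()),
    )
    return enriched, summary
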