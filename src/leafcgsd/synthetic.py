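"""Synthetic weather series and canopy images with planted structure.

The field studies this pipeline targets (camera above a crop canopy, hourly
weather station alongside) rarely deposit their raw data, so every stage here
is exercised against a generator that emulates the statistical structure the
analysis assumes:

* weather — diurnal temperature cycles with optional cold-wave depressions;
  relative humidity anti-coupled to temperature; dew point and vapor pressure
  derived through the Magnus formulas so the five factors are physically
  consistent; slowly drifting pressure;
* images — foreground pixels drawn per channel from a scaled Beta
  distribution on [0, 255] whose location is a *planted linear function of
  the weather factors*.  Bounded support matches 8-bit gradation and the
  Beta shape gives skewed histograms like real leaf images.

Because the planted coefficients are emitted alongside the images, parameter
recovery of the full pipeline (images -> CGSD -> stepwise models) can be
checked against ground truth.  All randomness flows from a single scenario
seed through named substreams, so the weather and each image are
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import CanopyImage
from .meteorology import (
    MeteoRecord,
    MeteoTable,
    dew_point_from_T_RH,
    vapor_pressure_from_TD,
    write_meteo_csv,
)

__all__ = [
    "ColdWave",
    "WeatherConfig",
    "ChannelResponse",
    "ResponseConfig",
    "SyntheticScenario",
    "SyntheticStudy",
    "PlantedMapDomainError",
    "generate_weather",
    "generate_canopy_image",
    "generate_study",
    "save_study",
    "greenhouse_scenario",
    "coldwave_scenario",
]


class PlantedMapDomainError(ValueError):
    """Planted linear map left the Beta family's valid domain."""


@dataclass(frozen=True)
class ColdWave:
    """A cold-air outbreak: temperatures drop by ``depth`` degC for some days."""

    onset_day: int
    depth: float  # degC
    duration_days: int


@dataclass(frozen=True)
class WeatherConfig:
    t_mean: float = 26.0  # degC
    diurnal_amplitude: float = 6.0  # degC, half peak-to-trough
    t_noise_sd: float = 0.4
    cold_waves: tuple[ColdWave, ...] = ()
    rh_base: float = 70.0  # % at T = t_mean
    rh_t_slope: float = -2.0  # % per degC anomaly (anti-coupling)
    rh_noise_sd: float = 3.0
    ap_base: float = 1005.0  # hPa
    ap_drift_amplitude: float = 2.0
    ap_drift_period_days: float = 6.0
    ap_noise_sd: float = 0.3


@dataclass(frozen=True)
class ChannelResponse:
    """Planted map for one channel: location = base + sum(coef * factor).

    Location is the Beta mean in intensity units (0-255); ``concentration``
    is alpha + beta of the Beta (larger = tighter).  ``concentration = inf``
    degenerates to a point mass at the location.
    """

    base: float
    coeffs: dict[str, float] = field(default_factory=dict)
    concentration: float = 25.0

    def location(self, record: MeteoRecord) -> float:
        loc = self.base
        for factor, slope in self.coeffs.items():
            loc += slope * getattr(record, factor)
        return loc


@dataclass(frozen=True)
class ResponseConfig:
    channels: dict[str, ChannelResponse] = field(default_factory=dict)
    pixel_noise_sd: float = 2.0  # additive Gaussian, intensity units


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int
    days: int = 7
    hours: tuple[int, ...] = (7, 9, 12, 15, 18)
    start: datetime = datetime(2021, 6, 1)
    weather: WeatherConfig = WeatherConfig()
    response: ResponseConfig = field(default_factory=lambda: ResponseConfig(
        channels={
            "R": ChannelResponse(base=30.0, coeffs={"VP_h": 1.2}),
            "G": ChannelResponse(base=60.0, coeffs={"RH_h": 0.35, "VP_h": 0.8}),
            "B": ChannelResponse(base=55.0, coeffs={}),
        }
    ))
    image_size: tuple[int, int] = (128, 128)  # (H, W)
    mask_axes_fraction: float = 0.44  # ellipse semi-axes as a fraction of H, W

    @property
    def n_samples(self) -> int:
        return self.days * len(self.hours)


@dataclass
class SyntheticStudy:
    images: list[CanopyImage]
    meteo: MeteoTable
    truth: pd.DataFrame  # channel, parameter, factor, coefficient
    image_truths: list[dict[str, dict[str, float]]]
    sample_ids: list[str]
    scenario: SyntheticScenario


def _substreams(seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    weather_ss, images_ss = np.random.SeedSequence(seed).spawn(2)
    return weather_ss, images_ss


def generate_weather(scenario: SyntheticScenario) -> MeteoTable:
    """Hourly factors at the scenario's observation hours, seed-reproducible.

    T peaks mid-afternoon (sinusoid with maximum at 15:00); cold waves
    subtract their full depth on the days they cover.  TD and VP are derived
    from (T, RH) via the Magnus forms, so every record satisfies the hard
    physical invariants by construction.
    """
    cfg = scenario.weather
    weather_ss, _ = _substreams(scenario.seed)
    rng = np.random.default_rng(weather_ss)
    records = []
    for day in range(scenario.days):
        deficit = 0.0
        for wave in cfg.cold_waves:
            if wave.onset_day <= day < wave.onset_day + wave.duration_days:
                deficit += wave.depth
        for hour in scenario.hours:
            diurnal = cfg.diurnal_amplitude * math.sin(2 * math.pi * (hour - 9) / 24)
            T = cfg.t_mean + diurnal - deficit + rng.normal(0, cfg.t_noise_sd)
            RH = cfg.rh_base + cfg.rh_t_slope * (T - cfg.t_mean) \
                + rng.normal(0, cfg.rh_noise_sd)
            RH = float(np.clip(RH, 5.0, 100.0))
            TD = dew_point_from_T_RH(T, RH)
            VP = vapor_pressure_from_TD(TD)
            AP = cfg.ap_base + cfg.ap_drift_amplitude * math.sin(
                2 * math.pi * (day + hour / 24) / cfg.ap_drift_period_days
            ) + rng.normal(0, cfg.ap_noise_sd)
            records.append(MeteoRecord(
                timestamp=scenario.start + timedelta(days=day, hours=hour),
                T_h=float(T), RH_h=RH, AP_h=float(AP), TD_h=TD, VP_h=VP,
            ))
    table = MeteoTable(records=records, source="synthetic")
    return table.validate(strict_dew_point=True)


def _ellipse_mask(scenario: SyntheticScenario) -> np.ndarray:
    h, w = scenario.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ay, ax = scenario.mask_axes_fraction * h, scenario.mask_axes_fraction * w
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _beta_params(loc: float, concentration: float,
                 record: MeteoRecord) -> tuple[float, float]:
    mu = loc / 255.0
    if not 0.0 < mu < 1.0:
        raise PlantedMapDomainError(
            f"planted location {loc:.2f} outside (0, 255) at factors "
            f"T_h={record.T_h:.2f}, RH_h={record.RH_h:.2f}, "
            f"VP_h={record.VP_h:.2f}, TD_h={record.TD_h:.2f}, "
            f"AP_h={record.AP_h:.2f}"
        )
    return mu * concentration, (1.0 - mu) * concentration


def generate_canopy_image(
    record: MeteoRecord,
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> tuple[CanopyImage, dict[str, dict[str, float]]]:
    """One canopy image whose channel distributions follow the planted maps.

    Returns the image and the true per-channel distribution parameters
    (location, alpha, beta) used to draw it.
    """
    if rng is None:
        _, images_ss = _substreams(scenario.seed)
        rng = np.random.default_rng(images_ss)
    mask = _ellipse_mask(scenario)
    n_fg = int(mask.sum())
    h, w = scenario.image_size
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    truth: dict[str, dict[str, float]] = {}
    for ci, channel in enumerate("RGB"):
        resp = scenario.response.channels[channel]
        loc = resp.location(record)
        if math.isinf(resp.concentration):
            if not 0.0 <= loc <= 255.0:
                raise PlantedMapDomainError(
                    f"point-mass location {loc:.2f} outside [0, 255]")
            values = np.full(n_fg, loc, dtype=np.float64)
            truth[channel] = {"location": loc, "alpha": math.inf, "beta": math.inf}
        else:
            a, b = _beta_params(loc, resp.concentration, record)
            values = 255.0 * rng.beta(a, b, size=n_fg)
            truth[channel] = {"location": loc, "alpha": a, "beta": b}
        if scenario.response.pixel_noise_sd > 0:
            values = values + rng.normal(0, scenario.response.pixel_noise_sd, n_fg)
        values = np.clip(values, 0.0, 255.0)
        plane = np.zeros((h, w), dtype=np.uint8)
        plane[mask] = np.floor(values + 0.5).astype(np.uint8)
        rgb[:, :, ci] = plane
    return CanopyImage(rgb=rgb, mask=mask), truth


def _truth_table(scenario: SyntheticScenario) -> pd.DataFrame:
    rows = []
    for channel, resp in scenario.response.channels.items():
        rows.append({"channel": channel, "parameter": "location",
                     "factor": "intercept", "coefficient": resp.base})
        for factor, slope in resp.coeffs.items():
            rows.append({"channel": channel, "parameter": "location",
                         "factor": factor, "coefficient": slope})
        rows.append({"channel": channel, "parameter": "concentration",
                     "factor": "intercept", "coefficient": resp.concentration})
    return pd.DataFrame(rows)


def generate_study(scenario: SyntheticScenario) -> SyntheticStudy:
    """Full synthetic campaign: one image per observation hour plus ground truth."""
    meteo = generate_weather(scenario)
    _, images_ss = _substreams(scenario.seed)
    children = images_ss.spawn(len(meteo))
    images, truths, ids = [], [], []
    for i, (record, child) in enumerate(zip(meteo, children)):
        rng = np.random.default_rng(child)
        img, truth = generate_canopy_image(record, scenario, rng=rng)
        img.path = None
        images.append(img)
        truths.append(truth)
        ids.append(record.timestamp.strftime("img_%Y%m%d_%H%M"))
    return SyntheticStudy(
        images=images, meteo=meteo, truth=_truth_table(scenario),
        image_truths=truths, sample_ids=ids, scenario=scenario,
    )


def save_study(study: SyntheticStudy, out_dir) -> None:
    """Write the study as RGBA PNGs + meteorology CSV + planted-truth CSV."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for img, sid in zip(study.images, study.sample_ids):
        rgba = np.dstack([img.rgb, (img.mask * 255).astype(np.uint8)])
        Image.fromarray(rgba, mode="RGBA").save(img_dir / f"{sid}.png")
    write_meteo_csv(study.meteo, out / "meteo.csv")
    study.truth.to_csv(out / "truth.csv", index=False)


def greenhouse_scenario(seed: int, **overrides) -> SyntheticScenario:
    """Summer greenhouse campaign: 7 days x 5 observation hours, stable pressure.

    These defaults are the package's reference study conditions: ~10^4
    foreground pixels per image, G channel responding to RH_h and VP_h,
    R channel to VP_h, B channel flat.
    """
    return replace(SyntheticScenario(seed=seed), **overrides)


def coldwave_scenario(seed: int, **overrides) -> SyntheticScenario:
    """Winter open-air campaign with a cold wave: bimodal temperatures.

    12 days x 4 hours around a 6 degC mean with a 7 degC cold wave on days
    5-7; image channel maps are re-based so planted locations stay in domain
    at winter humidity and vapor-pressure levels.
    """
    base = SyntheticScenario(
        seed=seed,
        days=12,
        hours=(8, 9, 10, 16),
        start=datetime(2018, 12, 1),
        weather=WeatherConfig(
            t_mean=6.0, diurnal_amplitude=3.0, t_noise_sd=0.5,
            cold_waves=(ColdWave(onset_day=5, depth=7.0, duration_days=3),),
            rh_base=75.0, rh_t_slope=-3.0, rh_noise_sd=3.0,
            ap_base=1020.0, ap_drift_amplitude=3.0, ap_drift_period_days=8.0,
        ),
        response=ResponseConfig(channels={
            "R": ChannelResponse(base=45.0, coeffs={"VP_h": 2.0}),
            "G": ChannelResponse(base=70.0, coeffs={"RH_h": 0.4, "VP_h": 1.5}),
            "B": ChannelResponse(base=60.0, coeffs={}),
        }),
    )
    return replace(base, **overrides)
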