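"""Hourly meteorological records: data model, CSV I/O, and moisture physics.

The pipeline relates canopy color statistics to five hourly meteorological
factors: air temperature ``T_h`` (degC), relative humidity ``RH_h`` (%),
atmospheric pressure ``AP_h`` (hPa), dew-point temperature ``TD_h`` (degC)
and vapor pressure ``VP_h`` (hPa).  Observed records are taken as-is; the
Magnus-form helpers below exist so *synthetic* weather keeps TD/VP physically
consistent with T/RH, and are never applied to observed CSV columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METEO_COLUMNS",
    "FACTOR_NAMES",
    "MeteoRecord",
    "MeteoTable",
    "MeteoFormatError",
    "MeteoValidationError",
    "MatchReport",
    "read_meteo_csv",
    "write_meteo_csv",
    "dew_point_from_T_RH",
    "vapor_pressure_from_TD",
    "match_images_to_hours",
]

#: CSV column order (fixed dialect).
METEO_COLUMNS = ["timestamp", "T_h", "RH_h", "AP_h", "TD_h", "VP_h"]

#: Candidate order for regression model building (deterministic tie-break).
FACTOR_NAMES = ["T_h", "RH_h", "AP_h", "VP_h", "TD_h"]

# Magnus formula constants (over water), saturation pressure in hPa.
MAGNUS_BETA = 17.62
MAGNUS_LAMBDA = 243.12  # degC
MAGNUS_E0 = 6.112  # hPa


class MeteoFormatError(ValueError):
    """Malformed meteorology CSV (missing column, bad timestamp...)."""


class MeteoValidationError(ValueError):
    """A record violates a hard physical invariant (e.g. RH outside [0,100])."""


@dataclass(frozen=True)
class MeteoRecord:
    """One timestamped set of the five hourly factors."""

    timestamp: datetime
    T_h: float
    RH_h: float
    AP_h: float
    TD_h: float
    VP_h: float

    def validate(self, *, strict_dew_point: bool = False) -> None:
        """Check physical invariants.

        Hard failures: RH outside [0, 100], non-positive vapor pressure.
        Soft (warning): implausible pressure, dew point above air temperature
        in observed data (sensor noise).  With ``strict_dew_point`` the dew
        point check is a hard failure (used for synthetic data).
        """
        if not 0.0 <= self.RH_h <= 100.0:
            raise MeteoValidationError(
                f"RH_h={self.RH_h} outside [0, 100] at {self.timestamp}"
            )
        if not self.VP_h > 0.0:
            raise MeteoValidationError(
                f"VP_h={self.VP_h} must be positive at {self.timestamp}"
            )
        if self.TD_h > self.T_h + 1e-9:
            msg = f"TD_h={self.TD_h} exceeds T_h={self.T_h} at {self.timestamp}"
            if strict_dew_point:
                raise MeteoValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        if not 800.0 <= self.AP_h <= 1100.0:
            warnings.warn(
                f"AP_h={self.AP_h} outside plausibility bound [800, 1100] hPa "
                f"at {self.timestamp}",
                stacklevel=2,
            )


@dataclass
class MeteoTable:
    """Ordered collection of :class:`MeteoRecord` with a provenance label."""

    records: list[MeteoRecord]
    source: str = "station"

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.timestamp)
        stamps = [r.timestamp for r in self.records]
        if len(set(stamps)) != len(stamps):
            dupes = {t for t in stamps if stamps.count(t) > 1}
            raise MeteoValidationError(f"duplicate timestamps: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self, *, strict_dew_point: bool = False) -> "MeteoTable":
        for rec in self.records:
            rec.validate(strict_dew_point=strict_dew_point)
        return self

    @property
    def timestamps(self) -> list[datetime]:
        return [r.timestamp for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame in the fixed CSV column order."""
        return pd.DataFrame(
            {
                "timestamp": [r.timestamp for r in self.records],
                "T_h": [r.T_h for r in self.records],
                "RH_h": [r.RH_h for r in self.records],
                "AP_h": [r.AP_h for r in self.records],
                "TD_h": [r.TD_h for r in self.records],
                "VP_h": [r.VP_h for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str = "station") -> "MeteoTable":
        records = [
            MeteoRecord(
                timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
                T_h=float(row.T_h),
                RH_h=float(row.RH_h),
                AP_h=float(row.AP_h),
                TD_h=float(row.TD_h),
                VP_h=float(row.VP_h),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records=records, source=source)


def read_meteo_csv(path, source: str = "station") -> MeteoTable:
    """Read and validate an hourly meteorology CSV.

    The dialect is fixed: comma-separated, UTF-8, header columns exactly
    ``timestamp,T_h,RH_h,AP_h,TD_h,VP_h`` with ISO-8601 timestamps.
    """
    frame = pd.read_csv(path)
    for col in METEO_COLUMNS:
        if col not in frame.columns:
            raise MeteoFormatError(f"missing required column {col!r} in {path}")
    stamps = []
    for i, raw in enumerate(frame["timestamp"]):
        try:
            stamps.append(datetime.fromisoformat(str(raw)))
        except ValueError as exc:
            raise MeteoFormatError(
                f"unparseable timestamp {raw!r} on data line {i + 1} of {path}"
            ) from exc
    frame = frame.assign(timestamp=stamps)
    table = MeteoTable.from_frame(frame[METEO_COLUMNS], source=source)
    return table.validate()


def write_meteo_csv(table: MeteoTable, path) -> None:
    frame = table.to_frame()
    frame["timestamp"] = [t.isoformat() for t in frame["timestamp"]]
    frame.to_csv(path, index=False)


def dew_point_from_T_RH(T: float, RH: float) -> float:
    """Dew-point temperature (degC) from air temperature and relative humidity.

    Magnus inversion with beta=17.62, lambda=243.12 degC:
    ``f = ln(RH/100) + beta*T/(lambda+T)``; ``TD = lambda*f/(beta - f)``.
    Always <= T; equality at saturation (RH = 100).
    """
    if not RH > 0.0:
        raise ValueError(f"RH={RH} must be positive")
    if RH > 100.0:
        raise ValueError(f"RH={RH} exceeds 100%")
    f = np.log(RH / 100.0) + MAGNUS_BETA * T / (MAGNUS_LAMBDA + T)
    return float(MAGNUS_LAMBDA * f / (MAGNUS_BETA - f))


def vapor_pressure_from_TD(TD: float) -> float:
    """Saturation vapor pressure (hPa) at the dew point: Magnus closed form."""
    if not -60.0 <= TD <= 60.0:
        raise ValueError(f"TD={TD} outside supported range [-60, 60] degC")
    return float(MAGNUS_E0 * np.exp(MAGNUS_BETA * TD / (MAGNUS_LAMBDA + TD)))


@dataclass
class MatchReport:
    """Image-to-record pairing: index pairs plus explicitly listed orphans."""

    pairs: list[tuple[int, int]] = field(default_factory=list)  # (image idx, record idx)
    unmatched: list[int] = field(default_factory=list)  # image indices
    max_gap_minutes: float = 30.0

    def record_for(self, image_index: int) -> int | None:
        for i, j in self.pairs:
            if i == image_index:
                return j
        return None


def match_images_to_hours(
    image_timestamps: Sequence[datetime] | Iterable[datetime],
    table: MeteoTable,
    max_gap_minutes: float = 30.0,
) -> MatchReport:
    """Pair each image with the nearest-in-time record within ``max_gap_minutes``.

    Cameras shoot just after the punctual hour (07:04 pairs with 07:00), so the
    nearest record is the natural rule; equidistant ties go to the *earlier*
    record.  Images with no record inside the gap are reported, never dropped
    silently.
    """
    if max_gap_minutes < 0:
        raise ValueError("max_gap_minutes must be >= 0")
    if len(table) == 0:
        raise ValueError("cannot match against an empty MeteoTable")
    image_timestamps = list(image_timestamps)
    rec_times = table.timestamps
    report = MatchReport(max_gap_minutes=max_gap_minutes)
    for i, ts in enumerate(image_timestamps):
        gaps = [abs((ts - rt).total_seconds()) for rt in rec_times]
        best = int(np.argmin(gaps))  # argmin returns first minimum: earlier record wins ties
        if gaps[best] <= max_gap_minutes * 60.0:
            report.pairs.append((i, best))
        else:
            report.unmatched.append(i)
    return report
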