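"""The 20 CGSD parameters and normality testing of gradation distributions.

For each canopy image and each channel c in {R, G, B, Y} the color gradation
skewness-distribution (CGSD) parameters are the mean, median, mode, skewness
and kurtosis of the foreground intensity multiset — 20 numbers per image.
Conventions are fixed to the MATLAB defaults the parameter system was built
with: biased (population) central moments, non-excess kurtosis (a normal
distribution has kurtosis 3), mode ties broken toward the smallest level.

Leaf gradation distributions are strongly non-normal; the Lilliefors and
Jarque-Bera tests quantify that.  Lilliefors p-values come from a seeded
Monte-Carlo null (honest at image-scale n where lookup tables end), the
Jarque-Bera p from its asymptotic chi-square(2) tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging import CHANNELS, CanopyImage, GradationArray, gradation_array

__all__ = [
    "PARAM_NAMES",
    "STAT_NAMES",
    "ChannelStats",
    "CGSDRecord",
    "NormalityResult",
    "compute_cgsd",
    "cgsd_from_gradation",
    "channel_stats_from_values",
    "lilliefors_statistic",
    "lilliefors_null_table",
    "lilliefors_test",
    "jarque_bera_test",
    "cgsd_table",
    "write_cgsd_csv",
    "read_cgsd_csv",
]

STAT_NAMES = ("Mean", "Median", "Mode", "Skewness", "Kurtosis")

#: The 20 parameter names in canonical (R, G, B, Y) x (Mean..Kurtosis) order.
PARAM_NAMES = tuple(f"{c}_{s}" for c in CHANNELS for s in STAT_NAMES)


@dataclass(frozen=True)
class ChannelStats:
    """The five distribution statistics of one channel of one image.

    ``skewness``/``kurtosis`` are NaN with ``moments_defined=False`` when the
    channel is constant (zero variance).
    """

    channel: str
    mean: float
    median: float
    mode: int
    skewness: float
    kurtosis: float
    moments_defined: bool = True


@dataclass
class CGSDRecord:
    """The 20 CGSD parameters of one image."""

    sample_id: str
    timestamp: datetime | None = None
    channels: dict[str, ChannelStats] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in CHANNELS:
            st = self.channels[c]
            out[f"{c}_Mean"] = st.mean
            out[f"{c}_Median"] = st.median
            out[f"{c}_Mode"] = float(st.mode)
            out[f"{c}_Skewness"] = st.skewness
            out[f"{c}_Kurtosis"] = st.kurtosis
        return out


@dataclass(frozen=True)
class NormalityResult:
    test: str  # "lilliefors" | "jarque_bera"
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    n: int


def _weighted_stats(counts: np.ndarray, channel: str) -> ChannelStats:
    """Frequency-weighted mean/median/mode/skewness/kurtosis from a histogram."""
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n < 1:
        raise ValueError("empty histogram")
    levels = np.arange(256, dtype=np.float64)
    mean = float((counts * levels).sum() / n)

    # Median via order statistics on the cumulative counts: average of the
    # ceil(n/2)-th and (n/2+1)-th smallest values when n is even.
    cum = np.cumsum(counts)
    if n % 2 == 1:
        k = (n + 1) // 2
        median = float(np.searchsorted(cum, k))
    else:
        lo = float(np.searchsorted(cum, n // 2))
        hi = float(np.searchsorted(cum, n // 2 + 1))
        median = (lo + hi) / 2.0

    mode = int(np.argmax(counts))  # argmax -> first max: smallest level wins ties

    dev = levels - mean
    m2 = float((counts * dev**2).sum() / n)
    if m2 == 0.0:
        return ChannelStats(channel, mean, median, mode, float("nan"),
                            float("nan"), moments_defined=False)
    m3 = float((counts * dev**3).sum() / n)
    m4 = float((counts * dev**4).sum() / n)
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    return ChannelStats(channel, mean, median, mode, skew, kurt)


def cgsd_from_gradation(g: GradationArray) -> ChannelStats:
    """The five statistics of one channel from its gradation array.

    Exactly equivalent to computing on the expanded pixel multiset, but O(256)
    instead of O(n) per statistic.
    """
    return _weighted_stats(g.counts, g.channel)


def channel_stats_from_values(values: Sequence[float] | np.ndarray,
                              channel: str = "") -> ChannelStats:
    """Per-pixel route: statistics computed directly on the value array."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 1:
        raise ValueError("empty value array")
    mean = float(x.mean())
    median = float(np.median(x))
    ints = np.asarray(values)
    mode = int(np.bincount(ints.astype(np.int64), minlength=256).argmax())
    m2 = float(((x - mean) ** 2).mean())
    if m2 == 0.0:
        return ChannelStats(channel, mean, median, mode, float("nan"),
                            float("nan"), moments_defined=False)
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    return ChannelStats(channel, mean, median, mode, m3 / m2**1.5, m4 / m2**2)


def compute_cgsd(image: CanopyImage, sample_id: str = "",
                 timestamp: datetime | None = None) -> CGSDRecord:
    """All 20 CGSD parameters of one background-removed image.

    Statistics are taken over foreground pixels only.  Needs at least two
    foreground pixels for the moment statistics to be attempted; a constant
    channel yields NaN skewness/kurtosis flagged as undefined.
    """
    if image.n_foreground < 2:
        raise ValueError("need >= 2 foreground pixels for CGSD moments")
    rec = CGSDRecord(sample_id=sample_id, timestamp=timestamp)
    for c in CHANNELS:
        rec.channels[c] = cgsd_from_gradation(gradation_array(image, c))
    return rec


# ---------------------------------------------------------------------------
# Normality tests
# ---------------------------------------------------------------------------

def lilliefors_statistic(values: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to the normal fitted by (mean, sd).

    D = sup_x |F_hat(x) - Phi((x - xbar)/s)| with s the unbiased sample SD.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    s = x.std(ddof=1)
    if s == 0.0:
        raise ValueError("constant sample: Lilliefors statistic undefined")
    z = sps.norm.cdf((x - x.mean()) / s)
    up = np.arange(1, n + 1) / n - z
    down = z - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors_null_table(n: int, n_reps: int = 10_000, seed: int = 0) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the Lilliefors D for sample size n.

    The statistic is location-scale invariant, so one table per n serves every
    test at that n.
    """
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((n_reps, n))
    samples.sort(axis=1)
    means = samples.mean(axis=1, keepdims=True)
    sds = samples.std(axis=1, ddof=1, keepdims=True)
    z = sps.norm.cdf((samples - means) / sds)
    grid_up = np.arange(1, n + 1) / n
    grid_down = np.arange(0, n) / n
    d = np.maximum((grid_up - z).max(axis=1), (z - grid_down).max(axis=1))
    d.sort()
    return d


def lilliefors_test(
    values: Iterable[float],
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
    null_table: np.ndarray | None = None,
) -> NormalityResult:
    """Lilliefors test of composite normality with a Monte-Carlo p-value.

    ``p = (1 + #{D_null >= D_obs}) / (n_reps + 1)`` — a valid (slightly
    conservative) Monte-Carlo p.  Pass a precomputed ``null_table`` (from
    :func:`lilliefors_null_table`) to amortize the null simulation across
    many tests at the same n.
    """
    x = np.asarray(list(values), dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError(f"Lilliefors test needs n >= 4, got {n}")
    d = lilliefors_statistic(x)
    if null_table is None:
        null_table = lilliefors_null_table(n, n_reps=n_reps, seed=seed)
    exceed = null_table.size - int(np.searchsorted(null_table, d, side="left"))
    p = (1 + exceed) / (null_table.size + 1)
    return NormalityResult("lilliefors", d, float(p), alpha, p < alpha, n)


def jarque_bera_test(values: Iterable[float], alpha: float = 0.05) -> NormalityResult:
    """Jarque-Bera test: JB = n/6 * (S^2 + (K-3)^2/4), p from chi-square(2).

    S and K are the biased sample skewness and (non-excess) kurtosis — the
    same moment convention as the CGSD parameters.
    """
    x = np.asarray(list(values), dtype=np.float64)
    n = x.size
    if n < 8:
        raise ValueError(f"Jarque-Bera test needs n >= 8, got {n}")
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    if m2 == 0.0:
        raise ValueError("constant sample: Jarque-Bera statistic undefined")
    s = ((x - mean) ** 3).mean() / m2**1.5
    k = ((x - mean) ** 4).mean() / m2**2
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    p = float(sps.chi2.sf(jb, df=2))
    return NormalityResult("jarque_bera", float(jb), p, alpha, p < alpha, n)


# ---------------------------------------------------------------------------
# Table assembly / I/O
# ---------------------------------------------------------------------------

def cgsd_table(records: Iterable[CGSDRecord]) -> pd.DataFrame:
    """One row per image: sample_id, timestamp, then the 20 parameter columns."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"sample_id": rec.sample_id,
                                  "timestamp": rec.timestamp}
        row.update(rec.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "timestamp", *PARAM_NAMES])


def write_cgsd_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = [
            t.isoformat() if isinstance(t, datetime) else t for t in out["timestamp"]
        ]
    out.to_csv(path, index=False)


def read_cgsd_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "timestamp" in frame.columns:
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame
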