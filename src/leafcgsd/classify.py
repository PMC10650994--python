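"""Temperature-regime classification of samples and bubble-chart data export.

Samples are split into a normal-temperature group T1 and a low-temperature
group T2 by 2-means clustering on the hourly air temperature.  In one
dimension the optimal k-means partition is contiguous in sorted order, so the
exact optimum is found by scanning all n-1 contiguous splits of the sorted
values — deterministic, no initialization, provably no worse than any Lloyd
run.  T0 denotes the unsplit sample set in downstream per-group modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateClusteringError",
    "TemperatureClassification",
    "classify_by_temperature",
    "bubble_chart_data",
]


class DegenerateClusteringError(ValueError):
    """All values identical: no meaningful 2-partition exists."""


@dataclass
class TemperatureClassification:
    """Result of the exact 1-D 2-means split on air temperature."""

    labels: list[str]  # per-sample, input order: "T1" (warm) or "T2" (cold)
    centers: dict[str, float]  # cluster mean temperature, degC
    ranges: dict[str, tuple[float, float]]  # (min, max) per cluster
    counts: dict[str, int]
    within_ss: float

    @property
    def boundary(self) -> tuple[float, float]:
        """(upper limit of T2, lower limit of T1) — the gap the split sits in."""
        return (self.ranges["T2"][1], self.ranges["T1"][0])

    def to_frame(self, temperatures, sample_ids=None) -> pd.DataFrame:
        ids = sample_ids if sample_ids is not None else range(len(self.labels))
        return pd.DataFrame({"sample_id": list(ids),
                             "T_h": list(temperatures),
                             "label": self.labels})


def classify_by_temperature(temperatures, k: int = 2) -> TemperatureClassification:
    """Exact 1-D k-means (k=2) on air temperatures.

    Sorts the values, evaluates the within-cluster sum of squares of every
    contiguous 2-partition, and takes the minimum.  The higher-mean cluster is
    labelled T1 (normal temperature), the lower T2 (low temperature).
    """
    if k != 2:
        raise NotImplementedError("only k=2 regimes are supported")
    x = np.asarray(list(temperatures), dtype=float)
    n = x.size
    if not np.isfinite(x).all():
        raise ValueError("temperatures must be finite")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateClusteringError("all temperatures identical")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs**2)])

    def wcss(lo: int, hi: int) -> float:  # [lo, hi) half-open on sorted values
        m = hi - lo
        s = csum[hi] - csum[lo]
        return (csq[hi] - csq[lo]) - s * s / m

    splits = [(wcss(0, i) + wcss(i, n), i) for i in range(1, n)]
    best_ss, best_i = min(splits)  # ties -> smallest split index

    cold = xs[:best_i]
    warm = xs[best_i:]
    labels_sorted = ["T2"] * best_i + ["T1"] * (n - best_i)
    labels = [""] * n
    for pos, orig in enumerate(order):
        labels[orig] = labels_sorted[pos]
    return TemperatureClassification(
        labels=labels,
        centers={"T1": float(warm.mean()), "T2": float(cold.mean())},
        ranges={"T1": (float(warm.min()), float(warm.max())),
                "T2": (float(cold.min()), float(cold.max()))},
        counts={"T1": int(warm.size), "T2": int(cold.size)},
        within_ss=float(best_ss),
    )


def bubble_chart_data(classification: TemperatureClassification,
                      meteo: pd.DataFrame) -> pd.DataFrame:
    """Plot table for the regime bubble chart: TD_h (x), RH_h (y), T_h (size), label.

    Values are carried verbatim; rows with a missing factor are flagged rather
    than dropped.
    """
    if len(meteo) != len(classification.labels):
        raise ValueError("classification does not cover all samples")
    out = pd.DataFrame({
        "TD_h": np.asarray(meteo["TD_h"], dtype=float),
        "RH_h": np.asarray(meteo["RH_h"], dtype=float),
        "T_h": np.asarray(meteo["T_h"], dtype=float),
        "label": classification.labels,
    })
    out["flagged"] = ~np.isfinite(out[["TD_h", "RH_h", "T_h"]]).all(axis=1)
    return out
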