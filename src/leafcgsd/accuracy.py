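"""Prediction-accuracy scoring and holdout validation reports.

The accuracy statistic for a single prediction is

    accuracy = (1 - |predicted - measured| / |measured|) * 100  [%]

It equals 100 only for an exact prediction, is 0 at 100% relative error, and
goes negative beyond that.  A holdout sample whose accuracy falls below the
outlier threshold (default 0, i.e. relative error above 100%) is flagged as
an outlier; the headline mean accuracy is taken over the non-flagged samples
(responses that hover near zero, like skewness, otherwise dominate the mean
through exploding relative errors).  The all-sample mean is reported too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import LinearModel, evaluate_model

__all__ = [
    "NearZeroMeasuredError",
    "AccuracyReport",
    "prediction_accuracy",
    "validate",
    "summary_table",
]


class NearZeroMeasuredError(ZeroDivisionError):
    """Measured value too close to zero for a relative-error statistic."""


def prediction_accuracy(predicted: float, measured: float, eps: float = 1e-9) -> float:
    """Percent accuracy of one prediction; see the module docstring.

    Scale invariant: multiplying both values by any c != 0 leaves it unchanged.
    """
    if abs(measured) <= eps:
        raise NearZeroMeasuredError(
            f"measured value {measured} within {eps} of zero"
        )
    return (1.0 - abs(predicted - measured) / abs(measured)) * 100.0


@dataclass
class AccuracyReport:
    """Per-sample accuracies of one model on a holdout set."""

    model_name: str
    samples: pd.DataFrame  # sample_id, predicted, measured, accuracy, outlier
    n_outliers: int
    mean_accuracy: float  # over non-outlier, computable samples
    mean_accuracy_all: float  # over all computable samples
    n: int
    n_non_computable: int = 0
    outlier_threshold: float = 0.0
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def validate(
    model: LinearModel,
    holdout: pd.DataFrame,
    outlier_threshold: float = 0.0,
    eps: float = 1e-9,
) -> AccuracyReport:
    """Score a fitted model on holdout samples.

    ``holdout`` carries one column per model predictor plus a column named
    after the model response with the measured values (and optionally a
    ``sample_id`` column).  Samples whose measured value is within ``eps`` of
    zero are counted as non-computable rather than scored.
    """
    if model.status != "fitted":
        raise ValueError(f"cannot validate unfitted model {model.response}")
    if len(holdout) == 0:
        raise ValueError("empty holdout set")
    if model.response not in holdout.columns:
        raise KeyError(f"holdout lacks measured column {model.response!r}")

    rows = []
    n_nc = 0
    for idx, row in holdout.iterrows():
        sid = row["sample_id"] if "sample_id" in holdout.columns else idx
        pred = evaluate_model(model, row)
        meas = float(row[model.response])
        try:
            acc = prediction_accuracy(pred, meas, eps=eps)
        except NearZeroMeasuredError:
            n_nc += 1
            rows.append({"sample_id": sid, "predicted": pred, "measured": meas,
                         "accuracy": np.nan, "outlier": False,
                         "computable": False})
            continue
        rows.append({"sample_id": sid, "predicted": pred, "measured": meas,
                     "accuracy": acc, "outlier": acc < outlier_threshold,
                     "computable": True})
    frame = pd.DataFrame(rows)
    scored = frame[frame["computable"]]
    kept = scored[~scored["outlier"]]
    return AccuracyReport(
        model_name=model.response,
        samples=frame,
        n_outliers=int(scored["outlier"].sum()),
        mean_accuracy=float(kept["accuracy"].mean()) if len(kept) else float("nan"),
        mean_accuracy_all=float(scored["accuracy"].mean()) if len(scored) else float("nan"),
        n=len(frame),
        n_non_computable=n_nc,
        outlier_threshold=outlier_threshold,
        metadata={"outlier_rule": f"accuracy < {outlier_threshold}",
                  "mean_excludes_outliers": True},
    )


def summary_table(reports: dict[str, AccuracyReport]) -> pd.DataFrame:
    """Wide summary shaped like a published validation table: one row per model."""
    rows = []
    for name, rep in reports.items():
        rows.append({
            "model": name,
            "n": rep.n,
            "n_outliers": rep.n_outliers,
            "mean_accuracy_pct": rep.mean_accuracy,
            "mean_accuracy_all_pct": rep.mean_accuracy_all,
            "n_non_computable": rep.n_non_computable,
        })
    return pd.DataFrame(rows)
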