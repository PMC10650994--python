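"""Correlation screening and stepwise least-squares models in both directions.

Two families of linear models are built:

* response models — each of the 20 CGSD parameters regressed on the five
  hourly meteorological factors;
* inversion models — each meteorological factor regressed on the 20 CGSD
  parameters.

Selection follows the SPSS stepwise convention: at each step the excluded
candidate with the smallest partial-F p-value enters if p < ``p_enter``
(default 0.05); after every entry any included predictor with partial-F
p > ``p_remove`` (default 0.10) is removed.  When no candidate ever enters
the model the outcome is the explicit ``unable_to_model`` status rather
than an error — with weakly coupled data that is a legitimate result.

Fit statistics mirror the SPSS summary: R^2, adjusted R^2, RMSE (the
regression standard error sqrt(SSE/(n-p-1))), the overall F and its p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cgsd import PARAM_NAMES
from .meteorology import FACTOR_NAMES

__all__ = [
    "CorrelationMatrix",
    "LinearModel",
    "StepwiseConfig",
    "DegenerateDesignError",
    "correlation_screen",
    "stepwise_fit",
    "fit_statistics",
    "evaluate_model",
    "fit_all_response_models",
    "fit_all_inversion_models",
    "save_models",
    "load_models",
]


class DegenerateDesignError(ValueError):
    """Selected design matrix is rank deficient (collinear predictors)."""


@dataclass
class CorrelationMatrix:
    """Pearson r and two-tailed p for every (row variable, column variable) pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame  # pairwise complete-case counts

    def to_csv(self, path) -> None:
        out = pd.concat({"r": self.r, "p": self.p, "n": self.n}, axis=1)
        out.to_csv(path)


@dataclass
class StepwiseConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    forced_entry: bool = False  # fit all candidates, no selection

    def __post_init__(self) -> None:
        if not self.forced_entry and not self.p_enter < self.p_remove:
            raise ValueError("p_enter must be < p_remove")


@dataclass
class LinearModel:
    """A fitted stepwise model, or the explicit unable-to-model outcome."""

    response: str
    status: str = "fitted"  # "fitted" | "unable_to_model"
    intercept: float | None = None
    terms: list[tuple[str, float]] = field(default_factory=list)
    n: int = 0
    r2: float | None = None
    adj_r2: float | None = None
    rmse: float | None = None
    f: float | None = None
    sig_f: float | None = None

    @property
    def predictors(self) -> list[str]:
        return [name for name, _ in self.terms]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "status": self.status,
            "intercept": self.intercept,
            "terms": [{"name": n, "coef": c} for n, c in self.terms],
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "f": self.f,
            "sig_f": self.sig_f,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            response=d["response"],
            status=d["status"],
            intercept=d["intercept"],
            terms=[(t["name"], t["coef"]) for t in d["terms"]],
            n=d["n"],
            r2=d["r2"],
            adj_r2=d["adj_r2"],
            rmse=d["rmse"],
            f=d["f"],
            sig_f=d["sig_f"],
        )


def correlation_screen(left: pd.DataFrame, right: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation of every column of ``left`` with every column of ``right``.

    Rows must already be paired one-to-one (same order).  p-values are
    two-tailed from the t distribution with n-2 degrees of freedom.  Cells
    with a constant column or fewer than 3 complete pairs are NaN.
    """
    if len(left) != len(right):
        raise ValueError("left and right tables must have equal length")
    if len(left) < 3:
        raise ValueError("need at least 3 paired samples")
    r = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    p = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    n = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    for a in left.columns:
        xa = np.asarray(left[a], dtype=float)
        for b in right.columns:
            xb = np.asarray(right[b], dtype=float)
            ok = np.isfinite(xa) & np.isfinite(xb)
            n.loc[a, b] = int(ok.sum())
            if ok.sum() < 3 or np.std(xa[ok]) == 0 or np.std(xb[ok]) == 0:
                r.loc[a, b] = np.nan
                p.loc[a, b] = np.nan
                continue
            res = sps.pearsonr(xa[ok], xb[ok])
            r.loc[a, b] = res.statistic
            p.loc[a, b] = res.pvalue
    return CorrelationMatrix(r=r, p=p, n=n)


def _ols_sse(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and SSE for a design X (with intercept column)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDesignError("rank-deficient design")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _design(data: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(data))] + [np.asarray(data[c], dtype=float) for c in names]
    return np.column_stack(cols)


def _partial_f_p(y: np.ndarray, data: pd.DataFrame, base: list[str],
                 extra: str) -> float:
    """p-value of the partial F test for adding ``extra`` to ``base``."""
    n = y.size
    X_r = _design(data, base)
    X_f = _design(data, base + [extra])
    _, sse_r = _ols_sse(y, X_r)
    try:
        _, sse_f = _ols_sse(y, X_f)
    except DegenerateDesignError:
        return 1.0  # candidate adds nothing new
    df_f = n - X_f.shape[1]
    if df_f <= 0:
        return 1.0
    if sse_f <= 0.0:
        return 0.0 if sse_r > sse_f else 1.0
    f = (sse_r - sse_f) / (sse_f / df_f)
    return float(sps.f.sf(max(f, 0.0), 1, df_f))


def stepwise_fit(
    y: Sequence[float] | np.ndarray,
    candidates: pd.DataFrame,
    config: StepwiseConfig | None = None,
    response_name: str = "y",
) -> LinearModel:
    """SPSS-style stepwise least squares over named candidate predictors.

    Candidate order in the DataFrame is the deterministic tie-break.  Returns
    a model with ``status="unable_to_model"`` when no candidate ever enters.
    """
    config = config or StepwiseConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    if len(candidates) != n:
        raise ValueError("y and candidates must have equal length")
    names = list(candidates.columns)
    if not config.forced_entry and n <= len(names) + 1:
        # selection can still proceed as long as each augmented fit has df;
        # the classical guard protects the full design
        pass

    if config.forced_entry:
        selected = names
    else:
        selected: list[str] = []
        max_steps = 4 * len(names) + 10  # guards against enter/remove cycling
        steps = 0
        while steps < max_steps:
            steps += 1
            changed = False
            # entry: smallest partial-F p among the excluded, if < p_enter
            best_name, best_p = None, np.inf
            for name in names:
                if name in selected:
                    continue
                pval = _partial_f_p(y, candidates, selected, name)
                if pval < best_p - 1e-15:
                    best_name, best_p = name, pval
            if best_name is not None and best_p < config.p_enter:
                selected.append(best_name)
                changed = True
                # removal sweep after every entry
                while True:
                    worst_name, worst_p = None, -np.inf
                    for name in selected:
                        rest = [s for s in selected if s != name]
                        pval = _partial_f_p(y, candidates, rest, name)
                        if pval > worst_p:
                            worst_name, worst_p = name, pval
                    if worst_name is not None and worst_p > config.p_remove:
                        selected.remove(worst_name)
                    else:
                        break
            if not changed:
                break

    if not selected:
        return LinearModel(response=response_name, status="unable_to_model", n=n)

    X = _design(candidates, selected)
    try:
        coef, _ = _ols_sse(y, X)
    except DegenerateDesignError:
        raise DegenerateDesignError(
            f"collinear predictors among {selected} for response {response_name}"
        ) from None
    model = LinearModel(
        response=response_name,
        intercept=float(coef[0]),
        terms=[(name, float(c)) for name, c in zip(selected, coef[1:])],
        n=n,
    )
    return fit_statistics(model, y, candidates)


def fit_statistics(model: LinearModel, y: Sequence[float] | np.ndarray,
                   data: pd.DataFrame) -> LinearModel:
    """Attach R^2, adjusted R^2, RMSE, F and Significance F to a fitted model.

    RMSE is the regression standard error sqrt(SSE/(n-p-1)), the "Std. Error
    of the Estimate" of an SPSS model summary.
    """
    if model.status != "fitted":
        raise ValueError("fit_statistics requires a fitted model")
    y = np.asarray(y, dtype=float)
    n = y.size
    p = len(model.terms)
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    X = _design(data, model.predictors)
    coef = np.concatenate([[model.intercept], [c for _, c in model.terms]])
    resid = y - X @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = sst - sse
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    model.r2 = r2
    model.adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    model.rmse = float(np.sqrt(sse / (n - p - 1)))
    if sse > 0:
        model.f = float((ssr / p) / (sse / (n - p - 1)))
        model.sig_f = float(sps.f.sf(model.f, p, n - p - 1))
    else:
        model.f = float("inf")
        model.sig_f = 0.0
    model.n = n
    return model


def evaluate_model(model: LinearModel, inputs: Mapping[str, float]) -> float:
    """Evaluate a fitted model equation: intercept + sum(coef * input)."""
    if model.status != "fitted":
        raise ValueError(f"model for {model.response} has no equation "
                         f"(status={model.status})")
    total = float(model.intercept)
    for name, coef in model.terms:
        if name not in inputs:
            raise KeyError(f"missing predictor {name!r} for model {model.response}")
        total += coef * float(inputs[name])
    return total


def _drop_incomplete(y: pd.Series, X: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, int]:
    ok = np.isfinite(np.asarray(y, dtype=float))
    for c in X.columns:
        ok &= np.isfinite(np.asarray(X[c], dtype=float))
    dropped = int((~ok).sum())
    return np.asarray(y, dtype=float)[ok], X.loc[ok].reset_index(drop=True), dropped


def fit_all_response_models(
    cgsd: pd.DataFrame,
    meteo: pd.DataFrame,
    config: StepwiseConfig | None = None,
) -> dict[str, LinearModel]:
    """One stepwise model per CGSD parameter, factors as candidates.

    Tables must be row-paired.  Samples with undefined moments (NaN skewness or
    kurtosis) are dropped per response, with the count recorded on the model
    via its ``n``.
    """
    factors = meteo[[f for f in FACTOR_NAMES if f in meteo.columns]]
    models: dict[str, LinearModel] = {}
    for param in PARAM_NAMES:
        if param not in cgsd.columns:
            continue
        y, X, _ = _drop_incomplete(cgsd[param], factors)
        models[param] = stepwise_fit(y, X, config, response_name=param)
    return models


def fit_all_inversion_models(
    meteo: pd.DataFrame,
    cgsd: pd.DataFrame,
    config: StepwiseConfig | None = None,
) -> dict[str, LinearModel]:
    """One stepwise model per meteorological factor, CGSD parameters as candidates."""
    params = cgsd[[p for p in PARAM_NAMES if p in cgsd.columns]]
    models: dict[str, LinearModel] = {}
    for factor in FACTOR_NAMES:
        if factor not in meteo.columns:
            continue
        y, X, _ = _drop_incomplete(meteo[factor], params)
        # drop candidate columns that became constant after pairwise deletion
        keep = [c for c in X.columns if np.std(np.asarray(X[c], float)) > 0]
        models[factor] = stepwise_fit(y, X[keep], config, response_name=factor)
    return models


def save_models(models: Mapping[str, LinearModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=2)


def load_models(path) -> dict[str, LinearModel]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {k: LinearModel.from_dict(d) for k, d in raw.items()}
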