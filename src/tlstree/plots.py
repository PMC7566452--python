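"""Plot-level statistics: model-vs-TLS regressions and biomass density.

Two outputs mirror the standard reporting of a TLS biomass campaign:

* per-model ordinary least squares of model AGB (y) against TLS AGB (x) in
  arithmetic tons, with r^2, residual RMSE, and CV% = 100*RMSE/mean(x),
  fitted both with and without the single largest-reference tree to expose
  the leverage of a giant individual;
* per-plot above-ground biomass density, AGBD = sum(tree AGB)/area, with a
  standard error combining per-tree uncertainties in quadrature
  (independent-tree assumption).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, PairingError, ParameterError

__all__ = [
    "ComparisonFit",
    "PlotSummary",
    "compare_regression",
    "plot_agbd",
    "table1_report",
    "table2_report",
]


@dataclass(frozen=True)
class ComparisonFit:
    model_id: str
    slope: float
    intercept_t: float
    r2: float
    rmse_t: float
    cv_percent: float
    includes_largest: bool
    n: int

    def __post_init__(self):
        assert -1e-9 <= self.r2 <= 1 + 1e-9
        assert self.rmse_t >= 0 and self.cv_percent >= 0


@dataclass(frozen=True)
class PlotSummary:
    plot_id: str
    area_ha: float
    method_id: str
    agbd_t_ha: float
    agbd_se_t_ha: float


def _pair(reference, candidate) -> tuple[np.ndarray, np.ndarray]:
    """Pair two per-tree series by tree_id (dict / Series) or positionally."""
    if hasattr(reference, "keys") and hasattr(candidate, "keys"):
        ref_ids, cand_ids = set(reference.keys()), set(candidate.keys())
        if ref_ids != cand_ids:
            raise PairingError(
                f"unmatched tree ids: {sorted(ref_ids ^ cand_ids)[:5]} ..."
            )
        ids = sorted(ref_ids)
        return (np.array([reference[i] for i in ids], float),
                np.array([candidate[i] for i in ids], float))
    x = np.asarray(reference, dtype=float)
    y = np.asarray(candidate, dtype=float)
    if len(x) != len(y):
        raise PairingError(f"length mismatch: {len(x)} vs {len(y)}")
    return x, y


def compare_regression(
    reference,
    candidate,
    model_id: str = "model",
    include_largest: bool = True,
    log_space: bool = False,
) -> ComparisonFit:
    """OLS of candidate AGB on reference (TLS) AGB in arithmetic tons.

    ``include_largest=False`` drops the single largest-reference tree before
    fitting (the leverage sensitivity).  ``log_space=True`` fits in ln-ln
    space instead (a sensitivity option; RMSE/CV are then computed on the
    back-transformed predictions).
    """
    x, y = _pair(reference, candidate)
    if not include_largest:
        keep = np.arange(len(x)) != int(np.argmax(x))
        x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ParameterError(f"need >= 10 paired trees, got {len(x)}")

    if log_space:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ParameterError("log-space regression requires positive AGB")
        lx, ly = np.log(x), np.log(y)
        slope, intercept, r2 = _ols(lx, ly)
        pred = np.exp(intercept + slope * lx)
    else:
        slope, intercept, r2 = _ols(x, y)
        pred = intercept + slope * x
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    cv = 100.0 * rmse / float(np.mean(x))
    return ComparisonFit(
        model_id=model_id, slope=slope, intercept_t=intercept, r2=r2,
        rmse_t=rmse, cv_percent=cv, includes_largest=include_largest, n=len(x),
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, r^2."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ParameterError("zero variance in reference")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = float(np.sum((y - ym) ** 2))
    r2 = 0.0 if syy == 0 else min(max(sxy**2 / (sxx * syy), 0.0), 1.0)
    return float(slope), float(intercept), float(r2)


def plot_agbd(
    agb_t,
    area_ha: float,
    agb_sd_t=None,
    plot_id: str = "plot",
    method_id: str = "tls",
) -> PlotSummary:
    """AGBD = sum(tree AGB) / area; SE = sqrt(sum sd^2) / area."""
    agb = np.asarray(agb_t, dtype=float)
    if area_ha <= 0:
        raise ParameterError("area_ha must be > 0")
    if len(agb) == 0:
        raise EmptyInputError("no trees in plot")
    sd = np.zeros_like(agb) if agb_sd_t is None else np.asarray(agb_sd_t, dtype=float)
    return PlotSummary(
        plot_id=plot_id,
        area_ha=area_ha,
        method_id=method_id,
        agbd_t_ha=float(agb.sum()) / area_ha,
        agbd_se_t_ha=math.sqrt(float(np.sum(sd**2))) / area_ha,
    )


def table1_report(agb_table: pd.DataFrame, reference_col: str = "tls") -> pd.DataFrame:
    """Model-vs-reference regression summary for every model column.

    ``agb_table`` is one row per tree with a reference column and one column
    per model; the result has one row per model and subset (with / without
    the largest-reference tree), in a bit-stable column order.
    """
    models = [c for c in agb_table.columns if c not in (reference_col, "tree_id", "plot_id")]
    rows = []
    for include in (True, False):
        for mid in models:
            fit = compare_regression(
                agb_table[reference_col].to_numpy(),
                agb_table[mid].to_numpy(),
                model_id=mid,
                include_largest=include,
            )
            rows.append(
                dict(model_id=mid, slope=fit.slope, intercept_t=fit.intercept_t,
                     r2=fit.r2, rmse_t=fit.rmse_t, cv_percent=fit.cv_percent,
                     includes_largest=include)
            )
    return pd.DataFrame(rows, columns=[
        "model_id", "slope", "intercept_t", "r2", "rmse_t", "cv_percent",
        "includes_largest",
    ])


def table2_report(
    per_tree: pd.DataFrame,
    area_ha: float = 0.25,
    plot_col: str = "plot_id",
    method_cols: tuple[str, ...] | None = None,
    sd_suffix: str = "_sd",
) -> pd.DataFrame:
    """Per-plot AGBD summary for every method column.

    ``per_tree`` has one row per tree with a plot id and per-method AGB
    columns (optionally ``<method>_sd`` uncertainty columns).
    """
    if method_cols is None:
        method_cols = tuple(
            c for c in per_tree.columns
            if c not in (plot_col, "tree_id") and not c.endswith(sd_suffix)
        )
    rows = []
    for plot_id, grp in per_tree.groupby(plot_col, sort=True):
        for mid in method_cols:
            sd = grp[mid + sd_suffix] if mid + sd_suffix in grp.columns else None
            s = plot_agbd(grp[mid].to_numpy(), area_ha,
                          None if sd is None else sd.to_numpy(),
                          plot_id=str(plot_id), method_id=mid)
            rows.append(dict(plot_id=s.plot_id, method_id=s.method_id,
                             agbd_t_ha=s.agbd_t_ha, agbd_se_t_ha=s.agbd_se_t_ha))
    return pd.DataFrame(rows, columns=["plot_id", "method_id", "agbd_t_ha", "agbd_se_t_ha"])
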