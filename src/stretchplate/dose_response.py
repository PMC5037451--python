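"""Generalized-logistic dose-response fitting of injury metrics vs strain.

Each injury metric y is modeled as a four-parameter logistic in the well
strain E:

    y(E) = yf + (y0 - yf) / (1 + exp(k (E - E_t)))

where y0 is the zero-strain plateau, yf the high-strain asymptote, k a
rate constant governing the sharpness of the transition, and E_t the
transition strain at which y is halfway between y0 and yf. The curve is
fit by Levenberg-Marquardt least squares; 95% confidence intervals come
from the asymptotic parameter covariance with a t quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the four-parameter logistic injury model."""

    y0: float
    yf: float
    k: float
    E_t: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant k must be > 0")
        if self.E_t <= 0:
            raise ValueError("transition strain E_t must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.y0, self.yf, self.k, self.E_t], dtype=float)


@dataclass(frozen=True)
class LogisticFit:
    """Fit result: estimates, 95% CIs per parameter, R^2, diagnostics."""

    params: LogisticParams
    ci: Mapping[str, tuple[float, float]]
    r_squared: float
    converged: bool
    n: int
    message: str = ""
    cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def E_t(self) -> float:
        return self.params.E_t


PARAM_NAMES = ("y0", "yf", "k", "E_t")


def logistic_eval(params: LogisticParams | Sequence[float], E) -> np.ndarray | float:
    """Evaluate the four-parameter logistic at strain(s) ``E``."""
    if isinstance(params, LogisticParams):
        y0, yf, k, e_t = params.as_array()
    else:
        y0, yf, k, e_t = (float(p) for p in params)
    E = np.asarray(E, dtype=float)
    # guard exp overflow for extreme k*(E - E_t); the limit values are exact
    z = np.clip(k * (E - e_t), -700.0, 700.0)
    out = yf + (y0 - yf) / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def _model(E, y0, yf, k, e_t):
    z = np.clip(k * (E - e_t), -700.0, 700.0)
    return yf + (y0 - yf) / (1.0 + np.exp(z))


def auto_initial_params(strain: np.ndarray, value: np.ndarray) -> np.ndarray:
    """Heuristic starting point standing in for by-eye initialization.

    y0 from the lowest-strain tertile mean, yf from the highest-strain
    tertile mean, E_t from the strain whose value is closest to the
    midpoint, and a moderately sharp default rate constant.
    """
    order = np.argsort(strain)
    s, v = strain[order], value[order]
    n = len(s)
    third = max(1, n // 3)
    y0 = float(v[:third].mean())
    yf = float(v[-third:].mean())
    mid = 0.5 * (y0 + yf)
    e_t = float(s[np.argmin(np.abs(v - mid))])
    if e_t <= 0:
        e_t = max(float(np.median(s)), 1e-3)
    return np.array([y0, yf, 15.0, e_t])


def fit_logistic(
    strain: Sequence[float],
    value: Sequence[float],
    init: LogisticParams | Sequence[float] | None = None,
) -> LogisticFit:
    """Levenberg-Marquardt fit of the four-parameter logistic.

    Non-convergence and degenerate data produce a flagged fit (``converged
    = False``) rather than an exception, so batch fitting over many
    metrics can proceed.
    """
    strain = np.asarray(strain, dtype=float)
    value = np.asarray(value, dtype=float)
    if strain.shape != value.shape or strain.ndim != 1:
        raise ValueError("strain and value must be 1-D arrays of equal length")
    n = len(strain)
    if n < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")

    if np.ptp(value) == 0:
        params = LogisticParams(float(value[0]), float(value[0]), 15.0, max(float(np.median(strain)), 1e-3))
        ci = {p: (np.nan, np.nan) for p in PARAM_NAMES}
        return LogisticFit(params, ci, np.nan, False, n, "degenerate: constant response")

    if init is None:
        p0 = auto_initial_params(strain, value)
    elif isinstance(init, LogisticParams):
        p0 = init.as_array()
    else:
        p0 = np.asarray(init, dtype=float)

    try:
        popt, pcov = optimize.curve_fit(
            _model, strain, value, p0=p0, method="lm", maxfev=20000
        )
    except RuntimeError as exc:  # LM did not converge
        params = LogisticParams(p0[0], p0[1], max(p0[2], 1e-6), max(p0[3], 1e-6))
        ci = {p: (np.nan, np.nan) for p in PARAM_NAMES}
        return LogisticFit(params, ci, np.nan, False, n, f"no convergence: {exc}")

    resid = value - _model(strain, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((value - value.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    tq = stats.t.ppf(0.975, df=max(n - 4, 1))
    ci = {
        name: (float(popt[i] - tq * perr[i]), float(popt[i] + tq * perr[i]))
        for i, name in enumerate(PARAM_NAMES)
    }

    ok = np.all(np.isfinite(popt)) and popt[2] > 0 and popt[3] > 0
    if not ok:
        ci = {p: (np.nan, np.nan) for p in PARAM_NAMES}
        params = LogisticParams(p0[0], p0[1], max(p0[2], 1e-6), max(p0[3], 1e-6))
        return LogisticFit(params, ci, r2, False, n, "implausible estimates (k or E_t <= 0)")

    params = LogisticParams(*[float(p) for p in popt])
    return LogisticFit(params, ci, r2, True, n, "", cov=pcov)


#: The nine injury metrics reported per well, in canonical column order.
METRIC_COLUMNS = (
    "neurite_length_per_cell",
    "cell_viability",
    "processes_per_cell",
    "total_neurite_length",
    "branches_per_cell",
    "total_processes",
    "viable_cells_per_image",
    "total_branches",
    "dead_cells_per_image",
)


def fit_all_metrics(
    table: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    strain_column: str = "strain",
) -> pd.DataFrame:
    """Fit every metric column against strain; one row per metric.

    ``table`` must hold a strain column plus one column per metric
    (control wells enter as strain-0 rows). Failed or degenerate fits are
    reported in place with ``converged = False`` and are excluded from
    the E_t range summary attached as ``DataFrame.attrs['E_t_range']``.
    """
    if strain_column not in table.columns:
        raise ValueError(f"table lacks strain column {strain_column!r}")
    if metrics is None:
        metrics = [c for c in METRIC_COLUMNS if c in table.columns]
    if not metrics:
        raise ValueError("no metric columns found")

    rows = []
    for metric in metrics:
        sub = table[[strain_column, metric]].dropna()
        fit = fit_logistic(sub[strain_column].to_numpy(), sub[metric].to_numpy())
        rows.append(
            {
                "metric": metric,
                "y0": fit.params.y0,
                "yf": fit.params.yf,
                "k": fit.params.k,
                "E_t": fit.params.E_t,
                **{
                    f"{p}_ci_low": fit.ci[p][0] for p in PARAM_NAMES
                },
                **{
                    f"{p}_ci_high": fit.ci[p][1] for p in PARAM_NAMES
                },
                "r_squared": fit.r_squared,
                "converged": fit.converged,
                "n": fit.n,
                "message": fit.message,
            }
        )
    report = pd.DataFrame(rows).set_index("metric")
    good = report.loc[report["converged"]]
    report.attrs["E_t_range"] = (
        (float(good["E_t"].min()), float(good["E_t"].max()))
        if len(good)
        else (np.nan, np.nan)
    )
    return report
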