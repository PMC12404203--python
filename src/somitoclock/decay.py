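"""Exponential-with-background decay fitting and half-life estimation.

Protein time courses (e.g. NICD after gamma-secretase inhibition) rarely
decay to zero on a Western blot: a non-degrading background fraction ``b``
remains.  The model fitted here is::

    y(t) = (1 - b) * exp(-k * t) + b

on intensities normalised to the t=0 value of each replicate, pooling all
replicates into one least-squares fit.  The half-life of the decaying
component is ``t_half = ln(2) / k``; its standard error follows by the delta
method, ``se(t_half) = ln(2) * se(k) / k**2``.  Condition comparisons use
Welch t-tests on log2 intensities per timepoint with Benjamini-Hochberg
adjustment across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))


@dataclass
class DecayFit:
    """Result of fitting ``y(t) = (1-b) exp(-k t) + b``."""

    k: float  # decay rate, per hour
    b: float  # background fraction
    se_k: float
    se_b: float
    t_half: float  # hours
    se_t_half: float
    converged: bool
    n_iterations: int
    message: str = ""


def normalize_to_t0(series: pd.DataFrame) -> pd.DataFrame:
    """Divide each replicate's intensities by its own t=0 intensity."""
    out = series.copy()
    keys = [c for c in ("condition", "replicate") if c in series.columns]
    for name, grp in series.groupby(keys):
        t0 = grp.loc[grp["time_h"] == 0, "intensity"]
        if t0.empty or float(t0.iloc[0]) <= 0:
            raise ValueError(f"replicate {name} lacks a positive t=0 intensity")
        out.loc[grp.index, "intensity"] = grp["intensity"] / float(t0.iloc[0])
    return out


def _model(t: np.ndarray, k: float, b: float) -> np.ndarray:
    return (1.0 - b) * np.exp(-k * t) + b


def fit_decay(series: pd.DataFrame, max_iter: int = 200) -> DecayFit:
    """Least-squares fit of the decay model, pooling all replicates.

    Initialisation: ``b0`` is the mean intensity at the latest timepoint
    (reset to 0 if it is not below the maximum intensity), ``k0`` the slope
    of ``-ln((y - b0)/(1 - b0))`` over the early timepoints with a 0.5/h
    fallback.  ``b`` is bounded to [0, 1); standard errors come from the
    Jacobian-based covariance at the solution.
    """
    t = series["time_h"].to_numpy(dtype=float)
    y = series["intensity"].to_numpy(dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct timepoints")

    t_max = t.max()
    b0 = float(y[t == t_max].mean())
    if b0 >= y.max() or not (0 <= b0 < 1):
        b0 = 0.0
    k0 = _initial_rate(t, y, b0)

    res = optimize.least_squares(
        lambda p: _model(t, p[0], p[1]) - y,
        x0=[k0, b0],
        bounds=([1e-12, 0.0], [np.inf, 1.0 - 1e-9]),
        xtol=1e-12, ftol=1e-14, gtol=1e-14,
        max_nfev=max_iter * 4,
    )
    k_hat, b_hat = res.x
    dof = t.size - 2
    resid = res.fun
    converged = bool(res.success) and dof > 0
    if dof > 0:
        s2 = float(resid @ resid) / dof
        jtj = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            se_k = float(np.sqrt(max(cov[0, 0], 0.0)))
            se_b = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            se_k = se_b = float("nan")
            converged = False
    else:
        se_k = se_b = float("nan")

    # an essentially flat series leaves k unidentifiable
    if np.ptp(y) < 1e-12 or not np.isfinite(se_k) or (se_k > 0 and se_k / max(k_hat, 1e-12) > 1e3):
        converged = False

    if k_hat > 0 and converged:
        t_half, se_t_half = _half_life_from(k_hat, se_k)
    else:
        t_half = se_t_half = float("nan")
    return DecayFit(
        k=float(k_hat), b=float(b_hat), se_k=se_k, se_b=se_b,
        t_half=t_half, se_t_half=se_t_half,
        converged=converged, n_iterations=int(res.nfev), message=res.message,
    )


def _initial_rate(t: np.ndarray, y: np.ndarray, b0: float) -> float:
    early = t <= np.median(t)
    tt, yy = t[early], y[early]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log((yy - b0) / (1.0 - b0))
    ok = np.isfinite(z)
    if ok.sum() >= 2 and np.ptp(tt[ok]) > 0:
        slope = np.polyfit(tt[ok], z[ok], 1)[0]
        if slope < 0:
            return float(-slope)
    return 0.5


def _half_life_from(k: float, se_k: float) -> tuple[float, float]:
    return LN2 / k, LN2 * se_k / k**2


def half_life(fit: DecayFit | float, se_k: float | None = None) -> tuple[float, float]:
    """Half-life and its delta-method standard error.

    Accepts either a :class:`DecayFit` or a bare ``(k, se_k)`` pair:
    ``t_half = ln(2)/k``, ``se = ln(2) * se_k / k**2``.
    """
    if isinstance(fit, DecayFit):
        k, se = fit.k, fit.se_k
    else:
        k, se = float(fit), float(se_k if se_k is not None else np.nan)
    if k <= 0:
        raise ValueError("k must be positive")
    return _half_life_from(k, se)


def compare_conditions(series_a: pd.DataFrame, series_b: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint Welch t-test on log2 intensities, BH-adjusted.

    Tests every shared timepoint strictly after t=0 (the normalisation
    anchor); returns a table of (time_h, t, df, p, p_adj).
    """
    ta = set(series_a["time_h"]) & set(series_b["time_h"])
    shared = sorted(x for x in ta if x > 0)
    if not shared:
        raise ValueError("conditions share no timepoints after t=0")
    rows = []
    for tp in shared:
        xa = np.log2(series_a.loc[series_a["time_h"] == tp, "intensity"].to_numpy())
        xb = np.log2(series_b.loc[series_b["time_h"] == tp, "intensity"].to_numpy())
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"need >= 2 replicates per condition at t={tp}")
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"time_h": tp, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
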