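"""Growth-curve quality control.

Every strain in the screen is grown in the same plate format as the
vesiculation assay and its OD600 trajectory is fit with the modified
(Zwietering) Gompertz model,

    od(t) = y0 + A * exp(-exp((mu_max * e / A) * (lag - t) + 1)),

whose slope parameter ``mu_max`` is the maximum growth rate in OD600/h and
``lag`` the lag time in hours.  Trials with a poor fit (R^2 at or below a
threshold, default 0.7) are discarded; strains whose mean rate falls more
than one standard deviation from the collection mean are flagged as
growth-defective and excluded from phenotype calling, so that apparent
vesiculation phenotypes cannot be driven by poor growth or lysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

_E = float(np.e)

#: Perturbation factors for the single restart after an optimizer failure.
_RESTART_FACTORS = np.array([1.2, 0.8, 1.5, 1.1])


def gompertz(t, y0: float, A: float, mu_max: float, lag: float):
    """Modified Gompertz growth curve evaluated at times ``t`` (hours).

    Parameters are the baseline OD ``y0``, amplitude ``A`` (OD units above
    baseline), maximum growth rate ``mu_max`` (OD/h) and lag time ``lag`` (h).
    """
    t = np.asarray(t, dtype=float)
    return y0 + A * np.exp(-np.exp((mu_max * _E / A) * (lag - t) + 1.0))


@dataclass(frozen=True)
class GompertzFit:
    """Fitted growth parameters for one trial of one strain."""

    y0: float
    A: float
    mu_max: float
    lag: float
    r_squared: float
    converged: bool


def _validate_curve(times: np.ndarray, od: np.ndarray) -> None:
    if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
        raise ValueError("times and od must be 1-D arrays of equal length")
    if len(times) < 6:
        raise ValueError("growth curve needs at least 6 time points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times[-1] - times[0] <= 2.0:
        raise ValueError("growth curve must span more than 2 hours")
    if np.any(od < 0):
        raise ValueError("OD600 readings must be nonnegative")


def _initial_guess(times: np.ndarray, y: np.ndarray) -> np.ndarray:
    y0 = float(y.min())
    A = float(y.max() - y.min())
    slopes = np.diff(y) / np.diff(times)
    i = int(np.argmax(slopes))
    mu = float(slopes[i])
    if mu <= 0:
        mu = 1e-3
    t_mid = 0.5 * (times[i] + times[i + 1])
    lag = max(0.0, float(t_mid - A / (2.0 * mu))) if A > 0 else 0.0
    return np.array([y0, max(A, 1e-6), mu, lag])


def fit_gompertz(times, od, log_od: bool = False) -> GompertzFit:
    """Fit the modified Gompertz model to one OD600 time series.

    By default the model is fit to raw OD readings; with ``log_od=True`` the
    same functional form is fit to ln(OD) instead (useful when curves span a
    large dynamic range).  R^2 is computed on the fitted scale.  A flat curve
    (zero total sum of squares) cannot be scored and is returned with
    ``converged=False`` and ``r_squared`` of NaN.  Optimizer failures are
    retried once from perturbed initial values; a persistent failure is
    reported as data (``converged=False``), not raised.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    _validate_curve(times, od)

    if log_od:
        y = np.log(np.maximum(od, 1e-6))
    else:
        y = od

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or np.ptp(y) == 0.0:
        logger.debug("flat curve: SS_tot = 0, cannot fit")
        return GompertzFit(float(y[0]), 0.0, 0.0, 0.0, float("nan"), False)

    def resid(p: np.ndarray) -> np.ndarray:
        return gompertz(times, *p) - y

    lower = np.array([0.0 if not log_od else -np.inf, 1e-8, 0.0, 0.0])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])
    x0 = np.clip(_initial_guess(times, y), lower, upper)

    best = None
    for attempt, start in enumerate((x0, np.clip(x0 * _RESTART_FACTORS, lower, upper))):
        try:
            res = least_squares(
                resid, start, bounds=(lower, upper),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:  # numerical blow-up inside the optimizer
            logger.debug("least_squares raised on attempt %d", attempt)
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            break

    if best is None:
        return GompertzFit(*x0, float("nan"), False)

    y0, A, mu, lag = (float(v) for v in best.x)
    ss_res = float(np.sum(resid(best.x) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    converged = bool(best.success) and np.all(np.isfinite(best.x))
    return GompertzFit(y0, A, mu, lag, r2, converged)


def fit_growth_table(curves: pd.DataFrame, log_od: bool = False) -> pd.DataFrame:
    """Fit every (strain, trial) curve in a long-format growth table.

    ``curves`` needs columns strain, trial, time_h, od600.  Returns one row
    per trial with the fitted parameters, R^2 and convergence flag.
    """
    required = {"strain", "trial", "time_h", "od600"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    rows = []
    for (strain, trial), grp in curves.groupby(["strain", "trial"], sort=True):
        grp = grp.sort_values("time_h")
        fit = fit_gompertz(grp["time_h"].to_numpy(), grp["od600"].to_numpy(),
                           log_od=log_od)
        rows.append({"strain": strain, "trial": trial, "y0": fit.y0, "A": fit.A,
                     "mu_max": fit.mu_max, "lag": fit.lag,
                     "r_squared": fit.r_squared, "converged": fit.converged})
    return pd.DataFrame(rows)


def classify_growth(fits: pd.DataFrame, r2_min: float = 0.7,
                    n_sd: float = 1.0, pooled: bool = False) -> pd.DataFrame:
    """Flag strains with unusable fits or outlying growth rates.

    Trials with ``r_squared <= r2_min`` (the boundary itself is filtered) or
    that failed to converge are discarded.  A strain with no usable trial is
    excluded with reason ``poor_fit_all_trials``.  The remaining strains'
    mean rates are compared against the collection: strains more than
    ``n_sd`` sample standard deviations from the mean (strictly, two-sided)
    are excluded with reason ``rate_outlier``.  With ``pooled=True`` the
    collection mean/sd are computed over all usable per-trial rates rather
    than per-strain means.

    Returns columns strain, mean_rate, n_usable_trials, passed, reason.
    """
    required = {"strain", "trial", "mu_max", "r_squared", "converged"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fit table missing columns: {sorted(missing)}")

    usable = fits[fits["converged"] & (fits["r_squared"] > r2_min)]
    per_strain = usable.groupby("strain")["mu_max"].agg(["mean", "size"])

    if len(per_strain) < 3:
        raise ValueError(
            "fewer than 3 strains with usable growth fits; collection "
            "statistics are undefined")

    pool = usable["mu_max"].to_numpy() if pooled else per_strain["mean"].to_numpy()
    m = float(np.mean(pool))
    s = float(np.std(pool, ddof=1))

    rows = []
    for strain in sorted(fits["strain"].unique()):
        if strain not in per_strain.index:
            rows.append({"strain": strain, "mean_rate": float("nan"),
                         "n_usable_trials": 0, "passed": False,
                         "reason": "poor_fit_all_trials"})
            continue
        rate = float(per_strain.loc[strain, "mean"])
        n_use = int(per_strain.loc[strain, "size"])
        if abs(rate - m) > n_sd * s:
            rows.append({"strain": strain, "mean_rate": rate,
                         "n_usable_trials": n_use, "passed": False,
                         "reason": "rate_outlier"})
        else:
            rows.append({"strain": strain, "mean_rate": rate,
                         "n_usable_trials": n_use, "passed": True,
                         "reason": "ok"})
    out = pd.DataFrame(rows)
    logger.info("growth QC: %d strains, %d excluded (%d poor fit, %d rate outliers)",
                len(out), int((~out["passed"]).sum()),
                int((out["reason"] == "poor_fit_all_trials").sum()),
                int((out["reason"] == "rate_outlier").sum()))
    return out
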