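"""Behavioural-economic demand curves from progressive-ratio consumption.

The PR1 record gives, for each mouse, the number of pellets earned at each
fixed-ratio requirement (the *price* C).  Consumption is modelled with the
exponential demand form

    log10 Q = log10 Q0 + k * (exp(-a * Q0 * C) - 1)

where Q0 is the theoretical consumption at zero cost, k the curve's range
and ``a`` the native elasticity parameter.  Reported indices follow the
operational definitions used for the study data:

* **alpha** -- the price at which fitted consumption falls to Q0 / 2, solved
  from the fitted curve (not the native ``a``):
  ``alpha = -ln(1 - log10(2) / k) / (a * Q0)``, defined only for
  ``k > log10 2``; otherwise the curve never halves (inelastic flag).
* **beta** -- the slope of Q0-normalized consumption with respect to log10
  price, evaluated at alpha (cost sensitivity across the dynamic range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG10_2 = float(np.log10(2.0))


@dataclass
class DemandCurve:
    prices: np.ndarray       # strictly increasing positive integers
    consumption: np.ndarray  # pellets earned at each price

    def __post_init__(self) -> None:
        self.prices = np.asarray(self.prices, dtype=float)
        self.consumption = np.asarray(self.consumption, dtype=float)
        if np.any(np.diff(self.prices) <= 0):
            raise ValueError("prices must be strictly increasing")
        if np.any(self.consumption < 0):
            raise ValueError("consumption must be non-negative")

    def normalized(self, q0: float) -> np.ndarray:
        return self.consumption / q0


@dataclass
class DemandFit:
    q0: float
    k: float
    a: float          # native exponential-demand elasticity (kept internal)
    alpha: float      # price at half-maximal fitted consumption
    beta: float       # d(Q/Q0) / d(log10 C) at alpha
    rss: float
    flags: list


def tabulate_demand(pr_metrics) -> DemandCurve:
    """Price-consumption curve from pooled PR1 run metrics.

    Prices beyond the largest attained ratio are censoring (the animal never
    faced them), not zero demand, and are simply absent from the table.
    """
    table = pr_metrics.demand_table
    if not len(table):
        raise ValueError("degenerate demand curve: no pellets earned")
    return DemandCurve(
        prices=table["price"].to_numpy(float),
        consumption=table["pellets"].to_numpy(float),
    )


def _model_log10q(C, q0, k, a):
    return np.log10(q0) + k * (np.exp(-a * q0 * C) - 1.0)


def alpha_from_params(q0: float, k: float, a: float) -> float:
    """Price at which the fitted curve crosses Q0/2 (nan if it never does)."""
    if k <= LOG10_2:
        return np.nan
    return float(-np.log(1.0 - LOG10_2 / k) / (a * q0))


def beta_at_alpha(q0: float, k: float, a: float) -> float:
    """Slope of normalized consumption vs log10 price at alpha.

    With u = log10 C and Qn = Q/Q0 = 10^(k (e^(-aQ0C) - 1)):
    dQn/du = Qn * ln10 * (-k * aQ0 * C * ln10 * e^(-aQ0C)), evaluated at C = alpha
    where Qn = 1/2.
    """
    alpha = alpha_from_params(q0, k, a)
    if not np.isfinite(alpha):
        return np.nan
    b = a * q0
    ln10 = np.log(10.0)
    dlog10qn_du = -k * b * alpha * ln10 * np.exp(-b * alpha)
    return float(0.5 * ln10 * dlog10qn_du)


def fit_demand(curve: DemandCurve, drop_zero: bool = True) -> DemandFit:
    """Fit the exponential demand form by nonlinear least squares on log10 Q.

    Requires at least 4 distinct prices with nonzero consumption.  Flags:
    ``inelastic`` when the fitted curve never reaches half-maximum (alpha is
    then reported at the maximum observed price), ``non-converged`` when the
    optimizer fails (parameters are still the best found, with diagnostics in
    the residual sum of squares).
    """
    mask = curve.consumption > 0 if drop_zero else np.ones(len(curve.prices), bool)
    C = curve.prices[mask]
    Q = curve.consumption[mask]
    if len(np.unique(C)) < 4:
        raise ValueError("need >= 4 distinct prices with nonzero consumption")
    y = np.log10(Q)
    q0_init = float(Q.max())
    p0 = (q0_init, 1.0, 1.0 / (q0_init * max(C.mean(), 1.0)))
    flags = []
    try:
        popt, _ = optimize.curve_fit(
            _model_log10q, C, y, p0=p0,
            bounds=([1e-6, 1e-6, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        q0, k, a = (float(v) for v in popt)
    except RuntimeError:
        q0, k, a = p0
        flags.append("non-converged")
    rss = float(((_model_log10q(C, q0, k, a) - y) ** 2).sum())
    alpha = alpha_from_params(q0, k, a)
    # inelastic when consumption never halves: either the fitted curve has no
    # half-maximum (k <= log10 2) or the observed consumption never drops to
    # half its own maximum within the observed price range (flat or rising
    # demand; Q0 and a are then unidentifiable)
    if not np.isfinite(alpha) or Q.min() > 0.5 * Q.max():
        flags.append("inelastic")
        alpha = float(C.max())
        beta = np.nan
    else:
        beta = beta_at_alpha(q0, k, a)
    return DemandFit(q0=q0, k=k, a=a, alpha=alpha, beta=beta, rss=rss, flags=flags)


def fits_table(fits: dict, sexes: dict) -> pd.DataFrame:
    """Tidy per-mouse fit table: mouse_id, sex, Q0, alpha, beta, RSS, flags."""
    rows = []
    for mouse_id, fit in fits.items():
        rows.append(
            {
                "mouse_id": mouse_id,
                "sex": sexes[mouse_id],
                "q0": fit.q0,
                "k": fit.k,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "rss": fit.rss,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(fit_table: pd.DataFrame, params=("alpha", "beta")) -> pd.DataFrame:
    """Per-sex mean +/- SE and unpaired two-tailed t-tests for fit parameters.

    P-values are Bonferroni-corrected across the tested parameter family
    (capped at 1), matching the figure-level correction of the study's group
    comparisons.  Requires >= 2 mice per sex.
    """
    out = []
    m = len(params)
    for param in params:
        by_sex = {
            sex: grp[param].dropna().to_numpy()
            for sex, grp in fit_table.groupby("sex")
        }
        if set(by_sex) != {"F", "M"} or min(len(v) for v in by_sex.values()) < 2:
            raise ValueError("need >= 2 mice of each sex")
        t, p = stats.ttest_ind(by_sex["M"], by_sex["F"])
        out.append(
            {
                "param": param,
                "mean_M": by_sex["M"].mean(),
                "se_M": stats.sem(by_sex["M"]),
                "mean_F": by_sex["F"].mean(),
                "se_F": stats.sem(by_sex["F"]),
                "t": float(t),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(out)
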