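"""Lagged logistic regression of choice on reward-weighted choice history.

For each trial t the current choice (left = 1) is predicted from the K = 5
previous trials.  Default coding is *signed rewarded-choice*: lag k carries
+1 if trial t-k was a rewarded left choice, -1 if a rewarded right choice,
and 0 if unrewarded.  An alternative *dual* coding with separate rewarded
and unrewarded signed histories is available.  The fit is a maximum-
likelihood logistic regression with an intercept (side bias) and a weak L2
ridge that leaves a well-conditioned fit essentially untouched but keeps the
estimate finite for quasi-separated, highly exploitative animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

#: ridge scale; perturbs a well-conditioned 10^4-trial fit by well under 1%
DEFAULT_RIDGE = 1e-3


@dataclass
class LagDesign:
    X: np.ndarray          # (n_rows, n_regressors), no intercept column
    y: np.ndarray          # (n_rows,), 1 = left choice
    lags: int
    coding: str            # "signed" or "dual"
    columns: list


@dataclass
class LagFit:
    intercept: float
    coef: np.ndarray          # per-regressor coefficients
    se: np.ndarray            # per-regressor standard errors
    odds_ratio: np.ndarray    # exp(coef)
    columns: list
    converged: bool
    separation_flag: bool

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.columns,
                "coef": self.coef,
                "odds_ratio": self.odds_ratio,
                "se": self.se,
            }
        )


def build_lag_design(trials: pd.DataFrame, K: int = 5, coding: str = "signed") -> LagDesign:
    """Build the lag-K design matrix from a trial table.

    Rows with incomplete history (the first K trials) are excluded, so the
    design has ``n_trials - K`` rows.  Raises ``ValueError`` when fewer than
    ``K + 1`` trials are available.
    """
    n = len(trials)
    if n < K + 1:
        raise ValueError(f"need at least K+1={K + 1} trials, got {n}")
    left = (trials["choice"].to_numpy() == "left").astype(float)
    win = (trials["outcome"].to_numpy() == "win").astype(float)
    signed = np.where(left == 1.0, 1.0, -1.0)
    rewarded = signed * win
    unrewarded = signed * (1.0 - win)

    y = left[K:]
    cols, names = [], []
    for k in range(1, K + 1):
        cols.append(rewarded[K - k: n - k])
        names.append(f"rewarded_lag{k}")
    if coding == "dual":
        for k in range(1, K + 1):
            cols.append(unrewarded[K - k: n - k])
            names.append(f"unrewarded_lag{k}")
    elif coding != "signed":
        raise ValueError(f"unknown coding {coding!r}")
    X = np.column_stack(cols)
    return LagDesign(X=X, y=y.astype(float), lags=K, coding=coding, columns=names)


def _penalized_logistic(X: np.ndarray, y: np.ndarray, ridge: float):
    """Ridge-stabilised logistic MLE; returns (beta, H) with intercept first."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    s = 2.0 * y - 1.0  # +/-1 labels

    def nll(b):
        z = Xd @ b
        pen = 0.5 * ridge * float(b[1:] @ b[1:])  # intercept unpenalized
        return float(np.logaddexp(0.0, -s * z).sum()) + pen

    def grad(b):
        z = Xd @ b
        g = -(s * _sigmoid(-s * z)) @ Xd
        g[1:] += ridge * b[1:]
        return g

    res = optimize.minimize(nll, np.zeros(p + 1), jac=grad, method="L-BFGS-B",
                            options={"maxiter": 500, "gtol": 1e-8})
    b = res.x
    mu = _sigmoid(Xd @ b)
    W = mu * (1.0 - mu)
    H = (Xd * W[:, None]).T @ Xd
    H[1:, 1:] += ridge * np.eye(p)
    return b, H, bool(res.success)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def fit_choice_regression(design: LagDesign, ridge: float = DEFAULT_RIDGE) -> LagFit:
    """Fit the lagged logistic model and report per-lag odds ratios.

    Quasi-separation (coefficients driven extreme, e.g. a near-pure
    exploiter) is detected from the coefficient scale and flagged; the ridge
    keeps the estimate finite in that case.
    """
    if len(design.y) == 0:
        raise ValueError("empty design")
    if design.X.shape[0] != len(design.y):
        raise ValueError("design shape mismatch")
    b, H, ok = _penalized_logistic(design.X, design.y, ridge)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    coef = b[1:]
    separation = bool(np.any(np.abs(coef) > 10.0))
    return LagFit(
        intercept=float(b[0]),
        coef=coef,
        se=se[1:],
        odds_ratio=np.exp(coef),
        columns=design.columns,
        converged=ok,
        separation_flag=separation,
    )


def fit_per_mouse(trials_by_mouse: dict, sexes: dict, K: int = 5,
                  coding: str = "signed", ridge: float = DEFAULT_RIDGE) -> pd.DataFrame:
    """Fit the regression for every mouse; tidy output, one row per (mouse, lag)."""
    rows = []
    for mouse_id, trials in trials_by_mouse.items():
        try:
            fit = fit_choice_regression(build_lag_design(trials, K=K, coding=coding), ridge)
        except ValueError:
            continue
        for k, (term, c, orat, s) in enumerate(
            zip(fit.columns, fit.coef, fit.odds_ratio, fit.se), start=0
        ):
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "sex": sexes[mouse_id],
                    "term": term,
                    "lag": k % K + 1,
                    "coef": c,
                    "odds_ratio": orat,
                    "se": s,
                    "converged": fit.converged,
                    "separation_flag": fit.separation_flag,
                }
            )
    return pd.DataFrame(rows)


def summarize_by_sex(per_mouse: pd.DataFrame) -> pd.DataFrame:
    """Group summary: mean +/- SE of per-mouse odds ratios, per sex and lag."""
    g = per_mouse.groupby(["sex", "term", "lag"])["odds_ratio"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "odds_ratio_mean", "sem": "odds_ratio_se",
                               "count": "n_mice"})
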