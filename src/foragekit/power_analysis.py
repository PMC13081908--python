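"""Empirical (resampling) and analytic power for two-group comparisons.

The empirical route mirrors the study procedure: at each per-group sample
size N, draw N subjects per group from the observed per-mouse values
(without replacement within each draw), run an unpaired two-tailed t-test at
level alpha, and record the fraction of draws reaching significance over
1000 resamples.  The analytic route evaluates the noncentral-t power of the
two-sample t-test (via statsmodels), with noncentrality d * sqrt(N / 2) and
2N - 2 degrees of freedom for equal groups.  ``required_n`` then reads off
the smallest N achieving a target power (default 80%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

DEFAULT_N_GRID = tuple(range(4, 61))


@dataclass
class EffectSpec:
    """Two-group effect description; d is Cohen's d with the pooled SD."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int | None = None
    n_b: int | None = None

    def __post_init__(self) -> None:
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError("group SDs must be positive")

    @property
    def cohens_d(self) -> float:
        if self.n_a and self.n_b:
            num = (self.n_a - 1) * self.sd_a**2 + (self.n_b - 1) * self.sd_b**2
            pooled = np.sqrt(num / (self.n_a + self.n_b - 2))
        else:
            pooled = np.sqrt((self.sd_a**2 + self.sd_b**2) / 2.0)
        return float((self.mean_a - self.mean_b) / pooled)

    @classmethod
    def from_samples(cls, a, b) -> "EffectSpec":
        a, b = np.asarray(a, float), np.asarray(b, float)
        return cls(a.mean(), b.mean(), a.std(ddof=1), b.std(ddof=1), len(a), len(b))


@dataclass
class PowerCurve:
    n_grid: np.ndarray
    power: np.ndarray
    method: str               # "empirical" or "analytic"
    alpha: float
    n_resamples: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n_grid = np.asarray(self.n_grid, int)
        self.power = np.asarray(self.power, float)
        if np.any(np.diff(self.n_grid) <= 0):
            raise ValueError("n_grid must be strictly increasing")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_per_group": self.n_grid, "power": self.power, "method": self.method}
        )


def _t_pvalues(xa: np.ndarray, xb: np.ndarray, welch: bool) -> np.ndarray:
    """Row-wise unpaired two-tailed t-test p-values for (R, N) sample blocks."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full(len(ma), na + nb - 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    return 2.0 * stats.t.sf(np.abs(t), df)


def empirical_power(
    values_a,
    values_b,
    n_grid=DEFAULT_N_GRID,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
    replace: bool = False,
    welch: bool = False,
) -> PowerCurve:
    """Resampling power curve over per-group sample sizes.

    At each N, ``n_resamples`` subsets of N subjects per group are drawn
    (without replacement within a draw by default; ``replace=True`` for a
    bootstrap) and tested with an unpaired two-tailed t-test at ``alpha``.
    Raises if a grid point exceeds a group's size, naming the group.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    n_grid = np.asarray(sorted(n_grid), int)
    for name, grp in (("a", a), ("b", b)):
        if not replace and n_grid.max() > len(grp):
            raise ValueError(
                f"grid point {n_grid.max()} exceeds group {name!r} size {len(grp)}"
            )
    rng = np.random.default_rng(seed)
    power = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        if replace:
            xa = rng.choice(a, size=(n_resamples, n), replace=True)
            xb = rng.choice(b, size=(n_resamples, n), replace=True)
        else:
            keys_a = rng.random((n_resamples, len(a)))
            keys_b = rng.random((n_resamples, len(b)))
            xa = a[np.argpartition(keys_a, n - 1, axis=1)[:, :n]]
            xb = b[np.argpartition(keys_b, n - 1, axis=1)[:, :n]]
        p = _t_pvalues(xa, xb, welch)
        power[i] = np.mean(p < alpha)
    return PowerCurve(
        n_grid=n_grid, power=power, method="empirical", alpha=alpha,
        n_resamples=n_resamples, seed=seed,
    )


def analytic_power(effect, n_grid=DEFAULT_N_GRID, alpha: float = 0.05) -> PowerCurve:
    """Noncentral-t power of the two-sample t-test at equal per-group N.

    ``effect`` is an :class:`EffectSpec` or a plain Cohen's d.
    """
    d = effect.cohens_d if isinstance(effect, EffectSpec) else float(effect)
    n_grid = np.asarray(sorted(n_grid), int)
    solver = TTestIndPower()
    if d == 0.0:
        power = np.full(len(n_grid), alpha)  # test level under the null
    else:
        power = np.array(
            [solver.power(effect_size=d, nobs1=int(n), ratio=1.0, alpha=alpha)
             for n in n_grid]
        )
    return PowerCurve(n_grid=n_grid, power=power, method="analytic", alpha=alpha)


def required_n(curve: PowerCurve, target: float = 0.8) -> tuple:
    """Smallest grid N whose power (and that of all larger grid N) >= target.

    Returns ``(n, "ok")`` or ``(None, "beyond-grid")`` when the curve never
    stays above the target; the suffix rule makes the answer robust to
    Monte-Carlo wiggle near the crossing.
    """
    ok = curve.power >= target
    # suffix-and: True where every power from this N onward clears the target
    suffix = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(suffix)
    if idx.size == 0:
        return None, "beyond-grid"
    return int(curve.n_grid[idx[0]]), "ok"
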