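"""Model-performance statistics and regression-based global sensitivity.

Goodness of fit uses the two statistics standard in watershed modeling:
the Nash-Sutcliffe efficiency NS = 1 - SSE/SST (1 is perfect, 0 matches
the observed-mean predictor) and percent bias
P_bias = 100*(O_avg - P_avg)/O_avg, positive when the model
underestimates.

Global sensitivity regresses an objective value (NS by default) from an
ensemble of model runs on the sampled parameter values,
g = alpha + sum_i beta_i * b_i, and flags a parameter as sensitive when
the two-sided t-test on its coefficient gives p < alpha_level.  Ranks are
by ascending p-value.  Parameter ensembles come from Latin-hypercube
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import qmc

__all__ = [
    "PairedSeries",
    "nash_sutcliffe",
    "pbias",
    "monthly_totals",
    "global_sensitivity",
    "sample_parameters",
]


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed/predicted vectors of equal length >= 2."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.observed, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if o.ndim != 1 or p.ndim != 1 or o.size != p.size or o.size < 2:
            raise ValueError("need two aligned 1-D series of length >= 2")
        if np.isnan(o).any() or np.isnan(p).any():
            raise ValueError("series must not contain missing values")
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "predicted", p)


def nash_sutcliffe(series: PairedSeries) -> float:
    """Nash-Sutcliffe efficiency: 1 - sum(O-P)^2 / sum(O-O_avg)^2."""
    o, p = series.observed, series.predicted
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed series is constant; NS undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


def pbias(series: PairedSeries) -> float:
    """Percent bias 100*(O_avg - P_avg)/O_avg; positive = underestimation."""
    o, p = series.observed, series.predicted
    o_avg = float(o.mean())
    if o_avg == 0.0:
        raise ValueError("observed mean is zero; P_bias undefined")
    return 100.0 * (o_avg - float(p.mean())) / o_avg


def monthly_totals(daily: pd.Series) -> pd.Series:
    """Calendar-month sums of a daily series with a DatetimeIndex."""
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise TypeError("daily series needs a DatetimeIndex")
    return daily.resample("MS").sum()


def sample_parameters(
    ranges: dict[str, tuple[float, float]], k: int, seed: int
) -> pd.DataFrame:
    """Latin-hypercube sample of k parameter sets within the given ranges."""
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(ranges)
    lows = np.array([ranges[n][0] for n in names], dtype=float)
    highs = np.array([ranges[n][1] for n in names], dtype=float)
    if np.any(lows >= highs):
        bad = [n for n in names if ranges[n][0] >= ranges[n][1]]
        raise ValueError(f"degenerate ranges for: {', '.join(bad)}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=k)
    return pd.DataFrame(qmc.scale(unit, lows, highs), columns=names)


def global_sensitivity(
    b: pd.DataFrame, g: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Multiple-regression sensitivity of objective g to parameter matrix b.

    Fits g = alpha + sum beta_i b_i by OLS and tests each coefficient with
    a two-sided t-test.  Returns a DataFrame indexed by parameter with
    columns coefficient, t_stat, p_value, rank (1 = most sensitive) and
    sensitive (p < alpha).  A constant objective carries no information,
    so every p-value is reported as 1.  A rank-deficient design raises,
    naming the collinear columns.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or len(g) != len(b):
        raise ValueError("g must be 1-D with one entry per run")
    m = b.shape[1]
    if len(g) <= m + 1:
        raise ValueError("need more runs than parameters + 1")
    for col in b.columns:
        if np.ptp(b[col].to_numpy()) == 0:
            raise ValueError(f"parameter column {col!r} is constant")
    x = sm.add_constant(b.to_numpy(dtype=float))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = np.corrcoef(b.to_numpy(dtype=float), rowvar=False)
        pairs = [
            f"{b.columns[i]}~{b.columns[j]}"
            for i in range(m)
            for j in range(i + 1, m)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient (collinear: {pairs})")

    if np.ptp(g) == 0.0:
        out = pd.DataFrame(
            {
                "coefficient": np.zeros(m),
                "t_stat": np.zeros(m),
                "p_value": np.ones(m),
            },
            index=b.columns,
        )
    else:
        fit = sm.OLS(g, x).fit()
        pvals = np.nan_to_num(fit.pvalues[1:], nan=1.0)
        tvals = fit.tvalues[1:]
        sst = float(np.sum((g - g.mean()) ** 2))
        if fit.ssr <= 1e-18 * sst:
            # numerically exact fit: the residual t-test operates on rounding
            # noise, so judge coefficients by their contribution to g instead
            contrib = np.abs(fit.params[1:]) * b.to_numpy(dtype=float).std(axis=0)
            active = contrib > 1e-9 * np.sqrt(sst / len(g))
            pvals = np.where(active, 0.0, 1.0)
            tvals = np.where(active, np.inf, 0.0)
        out = pd.DataFrame(
            {
                "coefficient": fit.params[1:],
                "t_stat": tvals,
                "p_value": pvals,
            },
            index=b.columns,
        )
    out["rank"] = out["p_value"].rank(method="first").astype(int)
    out["sensitive"] = out["p_value"] < alpha
    return out.sort_values("rank")
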