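"""Watershed-area-normalized annual carbon budgets and derived ratios.

Daily whole-watershed carbon masses (kgC day^-1) are summed to average
annual fluxes per hectare (kgC ha^-1 yr^-1; 1 kgC ha^-1 = 0.1 gC m^-2).
From the budget two summary products follow: the flux-ratio table
(outlet/watershed, net-deposition shares, resuspension/deposition, burial
shares) and the benthic budget, which expresses resuspension, burial,
inorganic release (CH4 + CO2) and the accumulated remainder as
percentages of total organic carbon deposited on the riverbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AnnualBudget",
    "RatioTable",
    "BenthicBudget",
    "accumulate_annual",
    "ratio_table",
    "benthic_budget",
    "KG_PER_HA_TO_G_PER_M2",
]

#: 1 kgC ha^-1 = 1000 gC / 10000 m^2 = 0.1 gC m^-2
KG_PER_HA_TO_G_PER_M2 = 0.1

#: daily mass columns (kgC day^-1) accepted by accumulate_annual
FLUX_COLUMNS = (
    "watershed_contribution",
    "riverine_contribution",
    "outlet_outflow",
    "deposition",
    "resuspension",
    "burial",
    "inorganic_release",
)


@dataclass(frozen=True)
class AnnualBudget:
    """Average annual fluxes for one constituent (kgC ha^-1 yr^-1).

    net_deposition = deposition - resuspension and accumulated_sediment_c
    = deposition - resuspension - burial - inorganic_release are derived;
    the latter may be negative in net-erosion years.
    """

    watershed_contribution: float = 0.0
    riverine_contribution: float = 0.0
    outlet_outflow: float = 0.0
    deposition: float = 0.0
    resuspension: float = 0.0
    burial: float = 0.0
    inorganic_release: float = 0.0
    watershed_area: float = 1.0  # ha

    def __post_init__(self) -> None:
        if self.watershed_area <= 0:
            raise ValueError("watershed_area must be positive")
        for name in FLUX_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def net_deposition(self) -> float:
        return self.deposition - self.resuspension

    @property
    def accumulated_sediment_c(self) -> float:
        return (
            self.deposition
            - self.resuspension
            - self.burial
            - self.inorganic_release
        )


@dataclass(frozen=True)
class RatioTable:
    """Unitless flux ratios; NaN marks an undefined (zero-denominator) entry."""

    out_over_wc: float
    ndep_over_wc: float
    ndep_over_out: float
    res_over_dep: float
    bury_over_wc: float
    bury_over_out: float
    bury_over_ndep: float

    def rounded(self, ndigits: int = 3) -> "RatioTable":
        """Reporting copy at printed precision; full precision kept internally."""
        return RatioTable(
            *(v if math.isnan(v) else round(v, ndigits) for v in self.__dict__.values())
        )

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class BenthicBudget:
    """Fate of deposited organic C as percentages of total deposition."""

    resuspension_pct: float
    burial_pct: float
    inorganic_pct: float
    accumulated_pct: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _complete_calendar_years(dates: pd.DatetimeIndex) -> pd.Series:
    """Boolean mask selecting days belonging to complete calendar years."""
    years = dates.year
    counts = pd.Series(1, index=dates).groupby(years).transform("size")
    expected = pd.Series(dates.is_leap_year, index=dates).map({True: 366, False: 365})
    return counts.to_numpy() == expected.to_numpy()


def accumulate_annual(
    daily: pd.DataFrame,
    watershed_area: float,
    calendar_complete: bool = True,
) -> AnnualBudget:
    """Aggregate daily whole-watershed masses into an average annual budget.

    `daily` needs a 'date' column (strictly daily, no gaps) and any subset
    of the flux columns in kgC day^-1; missing columns count as zero.  By
    default only complete calendar years enter the average; with
    calendar_complete=False all days are used and the year count is the
    span length / 365.25.
    """
    if watershed_area <= 0:
        raise ValueError("watershed_area must be positive")
    if "date" not in daily.columns:
        raise ValueError("daily table needs a 'date' column")
    dates = pd.DatetimeIndex(pd.to_datetime(daily["date"]))
    if len(dates) == 0:
        raise ValueError("empty daily table")
    deltas = dates[1:] - dates[:-1]
    if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
        raise ValueError("daily series must be gap-free and strictly daily")

    df = daily.copy()
    if calendar_complete:
        mask = _complete_calendar_years(dates)
        if not mask.any():
            raise ValueError("no complete calendar year in the series")
        df = df.loc[mask]
        n_years = pd.DatetimeIndex(pd.to_datetime(df["date"])).year.nunique()
    else:
        n_years = len(df) / 365.25

    values = {}
    for col in FLUX_COLUMNS:
        total = float(df[col].sum()) if col in df.columns else 0.0
        values[col] = total / watershed_area / n_years
    return AnnualBudget(watershed_area=watershed_area, **values)


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def ratio_table(budget: AnnualBudget) -> RatioTable:
    """Flux-ratio summary of an annual budget (full precision)."""
    wc = budget.watershed_contribution
    out = budget.outlet_outflow
    dep = budget.deposition
    ndep = budget.net_deposition
    bury = budget.burial
    return RatioTable(
        out_over_wc=_ratio(out, wc),
        ndep_over_wc=_ratio(ndep, wc),
        ndep_over_out=_ratio(ndep, out),
        res_over_dep=_ratio(budget.resuspension, dep),
        bury_over_wc=_ratio(bury, wc),
        bury_over_out=_ratio(bury, out),
        bury_over_ndep=_ratio(bury, ndep),
    )


def benthic_budget(budget: AnnualBudget) -> BenthicBudget:
    """Partition deposited organic C into its four fates (percent).

    The four percentages sum to 100 before rounding; deposition must be
    positive, otherwise every entry is NaN.
    """
    dep = budget.deposition
    if dep <= 0:
        return BenthicBudget(math.nan, math.nan, math.nan, math.nan)
    res = 100.0 * budget.resuspension / dep
    bury = 100.0 * budget.burial / dep
    inorg = 100.0 * budget.inorganic_release / dep
    return BenthicBudget(res, bury, inorg, 100.0 - res - bury - inorg)
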