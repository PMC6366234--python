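"""Static energy landscape: daily ODBA versus daily predicted uplift
suitability.

Per individual and UTC calendar day, the mean ODBA of flying accelerometer
bursts (height above ground > 100 m, time-matched GPS) and the mean
suitability-map probability at those burst locations form one record; days
with fewer than five contributing bursts are dropped.  A linear mixed model
with a random intercept per individual, fit by maximum likelihood so AICs of
nested fixed effects are comparable, tests whether birds spend more energy
where uplift is less available:

    sqrt(mean daily ODBA) ~ mean daily suitability + (1 | individual)

The fixed slope and the AIC difference to the interceptless-slope null model
are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .suitability import SuitabilityMap

log = logging.getLogger(__name__)


class DataError(ValueError):
    pass


@dataclass
class MixedModelFit:
    """Fixed suitability effect on sqrt daily ODBA, with model evidence."""

    slope: float
    slope_se: float
    intercept: float
    random_intercept_var: float
    aic: float
    null_aic: float
    delta_aic: float
    n_obs: int
    n_individuals: int
    result: object


def build_daily_records(bursts: pd.DataFrame, suit_map: SuitabilityMap,
                        min_height_m: float = 100.0,
                        min_obs: int = 5) -> pd.DataFrame:
    """One record per individual-day from flying, geolocated ACC bursts.

    Bursts qualify when height above ground exceeds ``min_height_m`` (which
    also implies a time-matched GPS fix).  Bursts over unclassified map
    cells are excluded from the suitability mean (count logged); days with
    fewer than ``min_obs`` qualifying bursts are dropped.
    """
    b = bursts[(bursts["height_above_ground"] > min_height_m)
               & bursts["x"].notna()].copy()
    if b.empty:
        raise DataError("no flying, geolocated bursts")
    prob = suit_map.probability.sample(b["x"].to_numpy(float),
                                       b["y"].to_numpy(float))
    n_unclassified = int(np.isnan(prob).sum())
    if n_unclassified:
        log.info("build_daily_records: %d bursts on unclassified cells "
                 "excluded from the suitability mean", n_unclassified)
    b["map_prob"] = prob
    b["date"] = pd.to_datetime(b["timestamp"], utc=True).dt.date
    rows = []
    for (ind, date), g in b.groupby(["individual_id", "date"]):
        if len(g) < min_obs:
            continue
        suit = g["map_prob"].dropna()
        if suit.empty:
            continue
        rows.append({
            "individual_id": ind, "date": date,
            "mean_daily_odba": float(g["odba_mean"].mean()),
            "mean_daily_suitability": float(suit.mean()),
            "n_obs": int(len(g)),
        })
    if not rows:
        raise DataError("no individual-day with enough qualifying bursts")
    return pd.DataFrame(rows)


def fit_energy_model(records: pd.DataFrame,
                     random_slope: bool = False) -> MixedModelFit:
    """Mixed model of sqrt daily ODBA on daily suitability (ML fit).

    The null model drops the fixed slope; ``delta_aic = aic - null_aic`` is
    negative when suitability carries information about daily energy
    expenditure.  A singular random-effect variance is retained with a
    warning.
    """
    if records["individual_id"].nunique() < 2:
        raise DataError("need at least 2 individuals")
    if len(records) < 20:
        raise DataError("need at least 20 daily records")
    d = records.copy()
    d["sqrt_odba"] = np.sqrt(d["mean_daily_odba"].astype(float))
    re_formula = "~mean_daily_suitability" if random_slope else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm("sqrt_odba ~ mean_daily_suitability", d,
                           groups=d["individual_id"],
                           re_formula=re_formula).fit(reml=False)
        null = smf.mixedlm("sqrt_odba ~ 1", d,
                           groups=d["individual_id"]).fit(reml=False)
    re_var = float(np.asarray(full.cov_re)[0, 0])
    if re_var < 1e-8:
        warnings.warn("random-intercept variance is singular (~0); "
                      "fit retained", stacklevel=2)
    aic, null_aic = float(full.aic), float(null.aic)
    return MixedModelFit(
        slope=float(full.params["mean_daily_suitability"]),
        slope_se=float(full.bse["mean_daily_suitability"]),
        intercept=float(full.params["Intercept"]),
        random_intercept_var=re_var,
        aic=aic, null_aic=null_aic, delta_aic=aic - null_aic,
        n_obs=int(len(d)),
        n_individuals=int(d["individual_id"].nunique()),
        result=full)
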