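"""Non-linear promoter responsiveness: slopes against the cross-promoter average.

Promoters integrate enhancer signals with different steepness. For every
enhancer-enhancer pair measured in all promoter libraries, boost indices
are averaged across promoters; regressing each promoter's observed boosts
on that average (both in log2 space) yields a per-promoter slope. A slope
of 1 marks an averagely responsive promoter, slopes > 1 steeper-than-
average (stronger relative amplification) and < 1 flatter. Because the
average itself is the shared x, the unweighted mean of slopes over a fixed
shared key set is exactly 1. The slope-baseline relation then asks whether
weak promoters respond more steeply: a negative Pearson correlation
between slope and log2 baseline activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boost import aggregate_boosts, ec_boost_records
from .stats import ols_fit, pearson_r

__all__ = [
    "ScalingFit",
    "ee_pair_boosts",
    "single_enhancer_boosts",
    "shared_combinations",
    "average_boost",
    "promoter_scaling_fit",
    "scaling_analysis",
    "slope_baseline_relation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalingFit:
    promoter: str
    slope: float
    intercept: float
    r: float
    n: int
    baseline: float


def ee_pair_boosts(boosted: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-promoter EE boost indices keyed by unordered fragment pair.

    Position- and orientation-resolved records are averaged (arithmetic
    mean in log2 space) per unordered enhancer pair.
    """
    ee = boosted[boosted["combo_class"] == "EE"].copy()
    if ee.empty:
        raise ValueError("no EE records")
    ee["pair"] = [tuple(sorted(p)) for p in zip(ee["frag1"], ee["frag2"])]
    tables: dict[str, pd.Series] = {}
    for prom, grp in ee.groupby("promoter", sort=True):
        agg = aggregate_boosts(grp, ["pair"])
        tables[prom] = agg.set_index("pair")["boost"]
    return tables


def single_enhancer_boosts(boosted: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-promoter single-enhancer boost indices keyed by enhancer id."""
    ec = ec_boost_records(boosted)
    if ec.empty:
        raise ValueError("no EC records")
    tables: dict[str, pd.Series] = {}
    for prom, grp in ec.groupby("promoter", sort=True):
        agg = aggregate_boosts(grp, ["enhancer"])
        tables[prom] = agg.set_index("enhancer")["boost"]
    return tables


def shared_combinations(tables: dict[str, pd.Series]) -> list:
    """Keys present in every promoter library (set intersection)."""
    if len(tables) < 2:
        raise ValueError("need at least two promoter libraries")
    keys = None
    for series in tables.values():
        keys = set(series.index) if keys is None else keys & set(series.index)
    if not keys:
        raise ValueError("no combination is shared by all promoter libraries")
    return sorted(keys)


def average_boost(shared: list, tables: dict[str, pd.Series]) -> pd.Series:
    """Arithmetic mean boost index across promoters for each shared key."""
    mat = pd.DataFrame({prom: series.reindex(shared) for prom, series in tables.items()})
    if mat.isna().any().any():
        raise ValueError("a shared key is missing from some promoter library")
    return mat.mean(axis=1)


def promoter_scaling_fit(promoter: str, boosts: pd.Series, avg: pd.Series,
                         baseline: float, with_intercept: bool = True) -> ScalingFit:
    """OLS fit of a promoter's observed boosts on the cross-promoter average."""
    y = boosts.reindex(avg.index)
    if y.isna().any():
        raise ValueError(f"promoter {promoter} lacks some shared combinations")
    fit = ols_fit(avg.to_numpy(), y.to_numpy(), with_intercept=with_intercept)
    return ScalingFit(promoter, fit.slope, fit.intercept, fit.r, fit.n, baseline)


def scaling_analysis(boosted: pd.DataFrame, baselines: pd.DataFrame,
                     kind: str = "EE", with_intercept: bool = True) -> pd.DataFrame:
    """Per-promoter scaling fits on shared EE pairs (or single enhancers).

    Promoters without a baseline are excluded with a warning. Returns one
    row per promoter with slope, intercept, Pearson R, n, baseline and
    log2 baseline.
    """
    if kind == "EE":
        tables = ee_pair_boosts(boosted)
    elif kind == "EC":
        tables = single_enhancer_boosts(boosted)
    else:
        raise ValueError(f"kind must be 'EE' or 'EC', got {kind!r}")
    base = baselines.set_index("promoter")["baseline"]
    missing = [p for p in tables if p not in base.index]
    for p in missing:
        logger.warning("promoter %s lacks a baseline; excluded from scaling", p)
        tables.pop(p)
    shared = shared_combinations(tables)
    avg = average_boost(shared, tables)
    rows = []
    for prom, series in tables.items():
        fit = promoter_scaling_fit(prom, series, avg, float(base[prom]),
                                   with_intercept=with_intercept)
        rows.append({"promoter": prom, "slope": fit.slope, "intercept": fit.intercept,
                     "pearson_r": fit.r, "n_combinations": fit.n,
                     "baseline": fit.baseline, "log2_baseline": np.log2(fit.baseline)})
    return pd.DataFrame(rows).sort_values("promoter").reset_index(drop=True)


def slope_baseline_relation(fits: pd.DataFrame) -> dict:
    """Pearson correlation between scaling slope and (log2) baseline activity."""
    if len(fits) < 3:
        raise ValueError("need at least 3 promoter fits")
    r_log = pearson_r(fits["log2_baseline"], fits["slope"])
    r_raw = pearson_r(fits["baseline"], fits["slope"])
    return {"pearson_r_log2_baseline": r_log, "pearson_r_baseline": r_raw,
            "sign": "negative" if r_log < 0 else "non-negative", "n_promoters": int(len(fits))}
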