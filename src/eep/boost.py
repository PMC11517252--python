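"""Promoter baselines, boost indices, and enhancer-activation calls.

The baseline activity of a promoter is the median combined activity across
its control-control (CC) combinations. The boost index of any combination
is log2(activity / baseline): 0 means no effect, 1 a doubling. Single
enhancers are summarised per (enhancer, promoter, position) as the median
activity across all combinations with a scrambled-control partner, and the
sample SD across that same set carries forward into the error propagation
of the additivity module.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import classify_combinations
from .stats import bh_fdr, wilcoxon_rank_sum

__all__ = [
    "promoter_baselines",
    "boost_index",
    "boost_table",
    "cc_boost_indices",
    "single_enhancer_estimates",
    "aggregate_boosts",
    "activation_test",
]

logger = logging.getLogger(__name__)

#: below this many CC combinations the baseline is flagged as poorly determined
SMALL_BASELINE_N = 30


def promoter_baselines(activities: pd.DataFrame) -> pd.DataFrame:
    """Median and sample SD of CC combined activities per promoter.

    Promoters with no CC combinations are absent from the result (and are
    excluded downstream); a log record marks them and any promoter whose
    baseline rests on few CC combinations.
    """
    cc = activities[activities["combo_class"] == "CC"]
    promoters = activities["promoter"].unique()
    rows = []
    for prom in sorted(promoters):
        vals = cc.loc[cc["promoter"] == prom, "activity"].to_numpy()
        if vals.size == 0:
            logger.error("promoter %s has no CC combinations; no baseline", prom)
            continue
        if vals.size < SMALL_BASELINE_N:
            logger.warning("promoter %s baseline rests on only %d CC combinations",
                           prom, vals.size)
        rows.append({
            "promoter": prom,
            "baseline": float(np.median(vals)),
            "sd_cc": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            "n_cc": int(vals.size),
        })
    return pd.DataFrame(rows)


def boost_index(activity: float, baseline: float) -> float:
    """log2 ratio of a combination's activity over the promoter baseline."""
    if np.any(np.asarray(activity) <= 0) or np.any(np.asarray(baseline) <= 0):
        raise ValueError("boost_index requires positive activity and baseline")
    return np.log2(np.asarray(activity) / np.asarray(baseline))


def boost_table(activities: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Per-combination boost indices (promoters without baseline are dropped)."""
    merged = activities.merge(baselines[["promoter", "baseline"]], on="promoter", how="inner")
    merged = merged[merged["activity"] > 0].copy()
    merged["boost"] = np.log2(merged["activity"] / merged["baseline"])
    return merged


def cc_boost_indices(activities: pd.DataFrame, per_promoter: bool = True) -> pd.DataFrame:
    """Boost indices of CC combinations over the median control activity.

    With ``per_promoter`` (default) each CC combination is referenced to
    the median CC activity of its own promoter, so the median CC boost is 0
    per promoter; the alternative references all CC combinations to the
    global control median.
    """
    cc = activities[activities["combo_class"] == "CC"].copy()
    if cc.empty:
        raise ValueError("no CC combinations")
    if per_promoter:
        ref = cc.groupby("promoter")["activity"].transform("median")
    else:
        ref = float(cc["activity"].median())
    cc["boost"] = np.log2(cc["activity"] / ref)
    return cc


def single_enhancer_estimates(activities: pd.DataFrame,
                              catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Median single-enhancer activity per (promoter, enhancer, position).

    Position 1 pools all EC combinations (enhancer first, control partner),
    position 2 all CE combinations; both orientations are pooled. The SD is
    the sample SD across the same combination set (NaN when only one
    combination exists, flagged ``degenerate``).
    """
    df = activities
    if "combo_class" not in df.columns:
        if catalog is None:
            raise ValueError("need combo_class column or a catalog")
        df = df.copy()
        df["combo_class"] = classify_combinations(df, catalog)
    parts = []
    for cls, frag_col, position in (("EC", "frag1", 1), ("CE", "frag2", 2)):
        sub = df[df["combo_class"] == cls]
        if sub.empty:
            continue
        grp = sub.groupby(["promoter", frag_col])["activity"]
        est = grp.agg(estimate="median", n="size",
                      sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan)
        est = est.reset_index().rename(columns={frag_col: "enhancer"})
        est["position"] = position
        parts.append(est)
    if not parts:
        return pd.DataFrame(columns=["promoter", "enhancer", "position",
                                     "estimate", "sd", "n", "degenerate"])
    out = pd.concat(parts, ignore_index=True)
    out["degenerate"] = out["n"] < 2
    return out[["promoter", "enhancer", "position", "estimate", "sd", "n", "degenerate"]]


def aggregate_boosts(boosts: pd.DataFrame, keys: Sequence[str],
                     value_col: str = "boost") -> pd.DataFrame:
    """Arithmetic mean of log2 boost indices over a grouping key.

    Averaging in log2 space makes the aggregate the log of a geometric mean
    of activity ratios; the group size is recorded. Grouping keys partition
    the records, so no record contributes twice.
    """
    keys = list(keys)
    if boosts.empty:
        raise ValueError("empty boost table")
    grouped = boosts.groupby(keys, sort=True)[value_col].agg(["mean", "size"])
    return grouped.rename(columns={"mean": value_col, "size": "n"}).reset_index()


def ec_boost_records(boosted: pd.DataFrame) -> pd.DataFrame:
    """Raw enhancer-control boost records with an ``enhancer`` column.

    Pools EC (enhancer in position 1) and CE (position 2) records; each raw
    record contributes once.
    """
    ec = boosted[boosted["combo_class"] == "EC"].copy()
    ec["enhancer"] = ec["frag1"]
    ce = boosted[boosted["combo_class"] == "CE"].copy()
    ce["enhancer"] = ce["frag2"]
    return pd.concat([ec, ce], ignore_index=True)


def activation_test(boosted: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Wilcoxon test of enhancer-control vs control-control boost indices.

    For each (enhancer, promoter) the distribution of its EC/CE boost
    indices is compared two-sidedly with the promoter's CC boost
    distribution; q-values are BH-adjusted across all tests of the run and
    an enhancer is called activating at q < ``fdr``.
    """
    ec = ec_boost_records(boosted)
    cc = boosted[boosted["combo_class"] == "CC"]
    rows = []
    for (prom, enh), grp in ec.groupby(["promoter", "enhancer"], sort=True):
        ref = cc.loc[cc["promoter"] == prom, "boost"].to_numpy()
        vals = grp["boost"].to_numpy()
        if vals.size == 0 or ref.size == 0:
            continue
        res = wilcoxon_rank_sum(vals, ref)
        rows.append({"promoter": prom, "enhancer": enh, "n_ec": int(vals.size),
                     "n_cc": int(ref.size), "median_boost": float(np.median(vals)),
                     "statistic": res.statistic, "p": res.p_value, "exact": res.exact})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = bh_fdr(table["p"])
    table["significant"] = table["q"] < fdr
    return table
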