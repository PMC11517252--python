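"""Additive vs multiplicative expectation models for enhancer pairs.

For an enhancer-enhancer combination E1-E2 on promoter P, with A_E1CP and
A_CE2P the median single-enhancer activities at positions 1 and 2 and
A_CCP the promoter baseline, the two candidate models predict (in linear
activity space)

    expected_additive        = A_E1CP + A_CE2P - A_CCP
    expected_multiplicative  = A_E1CP * A_CE2P / A_CCP

The uncertainty of the additive expectation is propagated as
sqrt(sd_E1^2 + sd_E2^2 + sd_CC^2) from the sample SDs of the combination
sets behind each median. A pair is supra-additive when its observed
activity exceeds the additive expectation by more than one propagated SD,
sub-additive when it falls more than one SD below, and within otherwise
(all comparisons in linear space, where the propagation formula lives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import wilcoxon_rank_sum

__all__ = [
    "expected_additive",
    "expected_multiplicative",
    "propagate_additive_sd",
    "classify_additivity",
    "expectation_records",
    "supra_sub_fractions",
    "model_preference",
    "enhancer_additivity_summary",
    "cluster_comparison",
    "ClusterComparison",
]

logger = logging.getLogger(__name__)


def expected_additive(a_e1c, a_ce2, a_cc):
    """Additive expectation A_E1CP + A_CE2P - A_CCP (may be <= 0 on pathological input)."""
    _check_positive(a_e1c, a_ce2, a_cc)
    return np.asarray(a_e1c) + np.asarray(a_ce2) - np.asarray(a_cc)


def expected_multiplicative(a_e1c, a_ce2, a_cc):
    """Multiplicative expectation A_E1CP * A_CE2P / A_CCP."""
    _check_positive(a_e1c, a_ce2, a_cc)
    return np.asarray(a_e1c) * np.asarray(a_ce2) / np.asarray(a_cc)


def _check_positive(*vals) -> None:
    for v in vals:
        if np.any(np.asarray(v, dtype=float) <= 0):
            raise ValueError("expectation inputs must be > 0")


def propagate_additive_sd(sd_e1, sd_e2, sd_cc):
    """sqrt of the summed variances of the three single measurements."""
    arrs = [np.asarray(s, dtype=float) for s in (sd_e1, sd_e2, sd_cc)]
    for a in arrs:
        if np.any(a < 0):
            raise ValueError("standard deviations must be >= 0")
    return np.sqrt(arrs[0] ** 2 + arrs[1] ** 2 + arrs[2] ** 2)


def classify_additivity(observed, expected, sd, sd_multiplier: float = 1.0):
    """'supra' / 'sub' / 'within' by the +-(sd_multiplier x SD) band in linear space."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    s = np.asarray(sd, dtype=float) * sd_multiplier
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValueError("sd undefined or negative; class unavailable")
    out = np.where(obs > exp + s, "supra", np.where(obs < exp - s, "sub", "within"))
    return out if out.ndim else str(out)


def expectation_records(activities: pd.DataFrame, baselines: pd.DataFrame,
                        singles: pd.DataFrame, sd_multiplier: float = 1.0,
                        include_baseline_variance: bool = True,
                        log_space_band: bool = False) -> pd.DataFrame:
    """One record per position-resolved EE combination with both expectations.

    Observed activities are first averaged (geometric mean) over
    orientation variants of the same ordered fragment pair. Records whose
    additive expectation is non-positive, or whose propagated SD is
    undefined (degenerate single-enhancer sets), are flagged invalid and
    excluded from the classified output columns but retained in the table
    for QC. ``include_baseline_variance=False`` drops the sd_CC term from
    the propagation; ``log_space_band`` applies the banding rule to
    log-activities instead (sensitivity analysis).
    """
    ee = activities[activities["combo_class"] == "EE"]
    if ee.empty:
        return pd.DataFrame()
    obs = (ee[ee["activity"] > 0]
           .groupby(["promoter", "frag1", "frag2"], sort=True)["activity"]
           .agg(lambda v: float(np.exp(np.mean(np.log(v)))))
           .rename("observed").reset_index())

    s1 = singles[singles["position"] == 1][["promoter", "enhancer", "estimate", "sd"]]
    s1 = s1.rename(columns={"enhancer": "frag1", "estimate": "a_e1c", "sd": "sd_e1"})
    s2 = singles[singles["position"] == 2][["promoter", "enhancer", "estimate", "sd"]]
    s2 = s2.rename(columns={"enhancer": "frag2", "estimate": "a_ce2", "sd": "sd_e2"})
    rec = (obs.merge(s1, on=["promoter", "frag1"], how="inner")
              .merge(s2, on=["promoter", "frag2"], how="inner")
              .merge(baselines[["promoter", "baseline", "sd_cc"]], on="promoter", how="inner"))

    rec["expected_additive"] = rec["a_e1c"] + rec["a_ce2"] - rec["baseline"]
    rec["expected_multiplicative"] = rec["a_e1c"] * rec["a_ce2"] / rec["baseline"]
    sd_cc = rec["sd_cc"].to_numpy() if include_baseline_variance else np.zeros(len(rec))
    rec["sd_additive"] = np.sqrt(rec["sd_e1"].to_numpy() ** 2
                                 + rec["sd_e2"].to_numpy() ** 2 + sd_cc**2)

    rec["valid"] = (rec["expected_additive"] > 0) & rec["sd_additive"].notna()
    n_invalid = int((~rec["valid"]).sum())
    if n_invalid:
        logger.warning("excluding %d EE records with non-positive additive "
                       "expectation or undefined SD", n_invalid)

    valid = rec["valid"]
    rec["log2_obs_over_exp_add"] = np.nan
    rec.loc[valid, "log2_obs_over_exp_add"] = np.log2(
        rec.loc[valid, "observed"] / rec.loc[valid, "expected_additive"])
    rec["log2_obs_over_exp_mult"] = np.log2(rec["observed"] / rec["expected_multiplicative"])

    rec["sd_distance"] = np.nan
    nz = valid & (rec["sd_additive"] > 0)
    rec.loc[nz, "sd_distance"] = ((rec.loc[nz, "observed"] - rec.loc[nz, "expected_additive"])
                                  / rec.loc[nz, "sd_additive"])
    rec["combo_class"] = "EE"
    rec["class"] = ""
    if log_space_band:
        lo = np.log(rec.loc[nz, "expected_additive"])
        band = rec.loc[nz, "sd_additive"] / rec.loc[nz, "expected_additive"] * sd_multiplier
        rec.loc[nz, "class"] = classify_additivity(np.log(rec.loc[nz, "observed"]), lo, band, 1.0)
    else:
        rec.loc[nz, "class"] = classify_additivity(rec.loc[nz, "observed"],
                                                   rec.loc[nz, "expected_additive"],
                                                   rec.loc[nz, "sd_additive"], sd_multiplier)
    return rec


def supra_sub_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Percentages of supra / sub / within-1SD and within-2SD records.

    One row per promoter plus a pooled row. Percentages are over valid
    records; supra + sub + within sums to 100.
    """
    valid = records[records["valid"] & records["class"].isin(["supra", "sub", "within"])]
    if valid.empty:
        raise ValueError("no valid classified records")

    def _one(df, label):
        n = len(df)
        cls = df["class"]
        within2 = np.abs(df["sd_distance"]) <= 2.0
        return {"promoter": label, "n": n,
                "pct_supra": 100.0 * (cls == "supra").mean(),
                "pct_sub": 100.0 * (cls == "sub").mean(),
                "pct_within_1sd": 100.0 * (cls == "within").mean(),
                "pct_within_2sd": 100.0 * within2.mean()}

    rows = [_one(grp, prom) for prom, grp in valid.groupby("promoter", sort=True)]
    rows.append(_one(valid, "pooled"))
    return pd.DataFrame(rows)


def model_preference(records: pd.DataFrame, min_gap: float = 0.5) -> pd.DataFrame:
    """Fraction of EE records better matched by the multiplicative model.

    Restricted to records where the two expectations differ by more than
    ``min_gap`` log2 units (limits random-noise effects); distances are
    log-space absolute deviations.
    """
    valid = records[records["valid"] & (records["expected_additive"] > 0)].copy()
    gap = np.abs(np.log2(valid["expected_multiplicative"]) - np.log2(valid["expected_additive"]))
    eligible = valid[gap > min_gap].copy()
    rows = []
    for prom, grp in eligible.groupby("promoter", sort=True):
        d_mult = np.abs(np.log2(grp["observed"]) - np.log2(grp["expected_multiplicative"]))
        d_add = np.abs(np.log2(grp["observed"]) - np.log2(grp["expected_additive"]))
        rows.append({"promoter": prom, "n_eligible": len(grp),
                     "frac_multiplicative": float((d_mult < d_add).mean())})
    pooled_n = len(eligible)
    if pooled_n:
        d_mult = np.abs(np.log2(eligible["observed"]) - np.log2(eligible["expected_multiplicative"]))
        d_add = np.abs(np.log2(eligible["observed"]) - np.log2(eligible["expected_additive"]))
        rows.append({"promoter": "pooled", "n_eligible": pooled_n,
                     "frac_multiplicative": float((d_mult < d_add).mean())})
    return pd.DataFrame(rows)


def enhancer_additivity_summary(records: pd.DataFrame,
                                threshold: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Mean log2(obs/exp_add) per enhancer x promoter, and consistency counts.

    Each valid EE record contributes to both of its enhancers (once, for
    self-pairs). An enhancer is consistently supra-additive in a promoter
    context when its mean exceeds ``threshold`` log2 units; the summary
    counts enhancers flagged in >= 1 and >= 2 promoter contexts.
    """
    valid = records[records["valid"]].copy()
    if valid.empty:
        raise ValueError("no valid records")
    long = pd.concat([
        valid.rename(columns={"frag1": "enhancer"})[["promoter", "enhancer",
                                                     "log2_obs_over_exp_add"]],
        valid[valid["frag1"] != valid["frag2"]]
            .rename(columns={"frag2": "enhancer"})[["promoter", "enhancer",
                                                    "log2_obs_over_exp_add"]],
    ], ignore_index=True)
    summary = (long.groupby(["enhancer", "promoter"], sort=True)["log2_obs_over_exp_add"]
               .agg(mean_log2_obs_over_exp="mean", n_pairs="size").reset_index())
    summary["consistent_supra"] = summary["mean_log2_obs_over_exp"] > threshold
    flagged = summary.groupby("enhancer")["consistent_supra"].sum()
    counts = {
        "n_enhancers": int(flagged.size),
        "n_flagged_ge1": int((flagged >= 1).sum()),
        "n_flagged_ge2": int((flagged >= 2).sum()),
    }
    counts["pct_flagged_ge1"] = 100.0 * counts["n_flagged_ge1"] / counts["n_enhancers"]
    counts["pct_flagged_ge2"] = 100.0 * counts["n_flagged_ge2"] / counts["n_enhancers"]
    return summary, counts


@dataclass
class ClusterComparison:
    within_median: float
    between_median: float
    n_within: int
    n_between: int
    p_value: float


def cluster_comparison(records: pd.DataFrame, catalog: pd.DataFrame) -> ClusterComparison:
    """Same-cluster vs different-cluster EE pairs, on log2(obs/exp_add).

    Position-resolved records are first averaged to unordered pairs per
    promoter (a partition: each pair lands in exactly one group), pooled
    across promoters, and the two groups compared with a two-sided Wilcoxon
    rank-sum test.
    """
    clusters = catalog.set_index("fragment_id")["cluster"]
    valid = records[records["valid"]].copy()
    if valid.empty:
        raise ValueError("no valid records")
    key = [tuple(sorted(p)) for p in zip(valid["frag1"], valid["frag2"])]
    valid["pair"] = key
    pair_level = (valid.groupby(["promoter", "pair"], sort=False)["log2_obs_over_exp_add"]
                  .mean().reset_index())
    c1 = pair_level["pair"].map(lambda p: clusters[p[0]])
    c2 = pair_level["pair"].map(lambda p: clusters[p[1]])
    if c1.isna().any() or c2.isna().any():
        raise ValueError("cluster labels missing for some enhancers")
    within = pair_level.loc[(c1 == c2).to_numpy(), "log2_obs_over_exp_add"].to_numpy()
    between = pair_level.loc[(c1 != c2).to_numpy(), "log2_obs_over_exp_add"].to_numpy()
    if within.size == 0 or between.size == 0:
        raise ValueError("one of the cluster groups is empty; p unavailable")
    res = wilcoxon_rank_sum(within, between)
    return ClusterComparison(float(np.median(within)), float(np.median(between)),
                             int(within.size), int(between.size), res.p_value)
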