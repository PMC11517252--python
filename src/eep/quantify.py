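"""Barcode count tables -> per-combination activities.

The quantification contract mirrors standard combinatorial-MPRA
post-processing: ambiguous barcodes (one barcode, several insert
identities) are discarded; counts are normalised to counts-per-million
within each table; per-barcode activity is the normalised cDNA:pDNA ratio,
kept only when the raw pDNA count reaches a minimum (default 8); activities
are averaged per combination and replicate over a minimum number of
barcodes (default 5); and replicate means are combined with a geometric
mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "IDENTITY_COLUMNS",
    "COMBINATION_KEY",
    "remove_ambiguous_barcodes",
    "normalize_counts",
    "barcode_activities",
    "combination_activity",
    "combine_replicates",
    "replicate_correlation",
    "classify_combinations",
    "quantify_counts",
]

IDENTITY_COLUMNS = ["promoter", "frag1", "orient1", "frag2", "orient2"]
COMBINATION_KEY = IDENTITY_COLUMNS  # one combination == one full identity


def remove_ambiguous_barcodes(assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop barcodes mapping to more than one insert identity.

    Duplicate rows with identical identity are collapsed first (set
    semantics); only true multi-identity barcodes are removed. Returns the
    filtered table and a report of the removed rows.
    """
    if assignments.empty:
        return assignments.copy(), assignments.copy()
    deduped = assignments.drop_duplicates(subset=["barcode"] + IDENTITY_COLUMNS)
    multiplicity = deduped["barcode"].value_counts()
    ambiguous = multiplicity.index[multiplicity > 1]
    removed = deduped[deduped["barcode"].isin(ambiguous)].copy()
    kept = deduped[~deduped["barcode"].isin(ambiguous)].reset_index(drop=True)
    return kept, removed.reset_index(drop=True)


def normalize_counts(counts) -> pd.Series | np.ndarray:
    """Counts-per-million normalisation; the scale cancels in activity ratios."""
    values = counts["count"] if isinstance(counts, pd.DataFrame) else counts
    arr = np.asarray(values, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot normalise an all-zero count table")
    norm = arr * 1e6 / total
    if isinstance(values, pd.Series):
        return pd.Series(norm, index=values.index)
    return norm


def barcode_activities(cdna: pd.DataFrame, pdna: pd.DataFrame,
                       min_pdna: int = 8, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-barcode activity for one replicate.

    activity = CPM(cDNA) / CPM(pDNA) for barcodes whose *raw* pDNA count is
    at least ``min_pdna``; other barcodes are dropped for this replicate.
    Barcodes absent from the cDNA table count as zero expression. A
    ``pseudocount`` (CPM units, default off) may be added to the cDNA side
    to keep fully silent barcodes in the geometric-mean step downstream.
    """
    for name, tab in (("cdna", cdna), ("pdna", pdna)):
        if not {"barcode", "count"}.issubset(tab.columns):
            raise ValueError(f"{name} table must have columns barcode, count")
    pd_tab = pdna.set_index("barcode")["count"]
    cd_tab = cdna.set_index("barcode")["count"]
    norm_p = pd_tab * 1e6 / pd_tab.sum()
    norm_c = cd_tab * 1e6 / cd_tab.sum() if cd_tab.sum() > 0 else cd_tab * 0.0
    keep = pd_tab[pd_tab >= min_pdna]
    if keep.empty:
        return pd.DataFrame(columns=["barcode", "activity", "pdna_raw"])
    nc = norm_c.reindex(keep.index, fill_value=0.0) + pseudocount
    np_ = norm_p.loc[keep.index]
    if (np_ <= 0).any():
        raise ValueError("pDNA count above threshold but normalised value <= 0")
    return pd.DataFrame({
        "barcode": keep.index,
        "activity": (nc / np_).to_numpy(),
        "pdna_raw": keep.to_numpy(),
    })


def classify_combinations(df: pd.DataFrame, catalog: pd.DataFrame) -> pd.Series:
    """CC/EC/CE/EE class from the fragment catalog (E = enhancer at that position)."""
    cls = catalog.set_index("fragment_id")["frag_class"]
    c1 = df["frag1"].map(cls)
    c2 = df["frag2"].map(cls)
    if c1.isna().any() or c2.isna().any():
        raise ValueError("fragment ids missing from catalog")
    out = pd.Series("CC", index=df.index)
    out[(c1 == "enhancer") & (c2 == "control")] = "EC"
    out[(c1 == "control") & (c2 == "enhancer")] = "CE"
    out[(c1 == "enhancer") & (c2 == "enhancer")] = "EE"
    return out


def combination_activity(activities: pd.DataFrame, assignments: pd.DataFrame,
                         min_barcodes: int = 5) -> pd.DataFrame:
    """Mean barcode activity per combination for one replicate.

    Combinations backed by fewer than ``min_barcodes`` barcodes in this
    replicate are dropped (from this replicate only).
    """
    merged = activities.merge(assignments, on="barcode", how="inner", sort=False)
    grouped = merged.groupby(COMBINATION_KEY, sort=True)["activity"].agg(["mean", "size"])
    grouped = grouped[grouped["size"] >= min_barcodes]
    return grouped.rename(columns={"mean": "activity", "size": "n_barcodes"}).reset_index()


def combine_replicates(values) -> float:
    """Geometric mean across replicate means; all inputs must be > 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    if np.any(arr <= 0):
        raise ValueError("geometric mean undefined for non-positive replicate means")
    return float(np.exp(np.mean(np.log(arr))))


def replicate_correlation(per_rep: pd.DataFrame, rep_a: int, rep_b: int) -> float:
    """Pearson R between two replicates on log2 activities of shared combinations."""
    a = per_rep[f"activity_r{rep_a}"]
    b = per_rep[f"activity_r{rep_b}"]
    mask = a.notna() & b.notna() & (a > 0) & (b > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 shared combinations between replicates")
    from .stats import pearson_r
    return pearson_r(np.log2(a[mask]), np.log2(b[mask]))


def quantify_counts(assignments: pd.DataFrame, counts: dict,
                    catalog: pd.DataFrame, min_barcodes: int = 5,
                    min_pdna: int = 8, pseudocount: float = 0.0) -> tuple[pd.DataFrame, dict]:
    """Full quantification: counts -> per-combination combined activities.

    ``counts`` maps replicate id -> {"cdna": table, "pdna": table}. Returns
    the activity table (one row per combination, with per-replicate means,
    barcode numbers, combined geometric-mean activity, combination class
    and QC flags) and an attrition report.
    """
    clean, removed = remove_ambiguous_barcodes(assignments)
    report = {
        "barcodes_in": int(assignments["barcode"].nunique()) if len(assignments) else 0,
        "barcodes_ambiguous": int(removed["barcode"].nunique()) if len(removed) else 0,
        "replicates": sorted(counts),
    }
    per_rep = None
    for rep in sorted(counts):
        acts = barcode_activities(counts[rep]["cdna"], counts[rep]["pdna"],
                                  min_pdna=min_pdna, pseudocount=pseudocount)
        combo = combination_activity(acts, clean, min_barcodes=min_barcodes)
        combo = combo.rename(columns={"activity": f"activity_r{rep}",
                                      "n_barcodes": f"n_barcodes_r{rep}"})
        per_rep = combo if per_rep is None else per_rep.merge(
            combo, on=COMBINATION_KEY, how="outer", sort=False)
    if per_rep is None or per_rep.empty:
        report["combinations_out"] = 0
        empty = pd.DataFrame(columns=COMBINATION_KEY + ["combo_class", "activity",
                                                        "n_replicates", "flag"])
        return empty, report

    act_cols = [c for c in per_rep.columns if c.startswith("activity_r")]
    vals = per_rep[act_cols]
    positive = vals.notna() & (vals > 0)
    n_rep = positive.sum(axis=1)
    zero_rep = (vals.notna() & (vals <= 0)).any(axis=1)

    combined = np.full(len(per_rep), np.nan)
    logs = np.log(vals.where(positive))
    with np.errstate(invalid="ignore"):
        combined = np.exp(logs.mean(axis=1, skipna=True)).to_numpy()
    per_rep["activity"] = combined
    per_rep["n_replicates"] = n_rep
    flags = np.where(zero_rep, "zero_replicate",
                     np.where(n_rep == 1, "low_replicate", ""))
    per_rep["flag"] = flags
    per_rep["combo_class"] = classify_combinations(per_rep, catalog)

    # combinations with a zero replicate mean are excluded from the
    # geometric mean step and logged, per the stated activity formula
    keep = n_rep >= 1
    report["combinations_covered"] = int(len(per_rep))
    report["combinations_zero_replicate"] = int(zero_rep.sum())
    per_rep = per_rep[keep & ~zero_rep].reset_index(drop=True)
    report["combinations_out"] = int(len(per_rep))
    return per_rep, report
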