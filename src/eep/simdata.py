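"""Synthetic three-way combinatorial reporter libraries with known ground truth.

The generator emulates the three tables a combinatorial
enhancer-enhancer-promoter (EEP) reporter experiment produces after barcode
clustering: a fragment catalog (enhancers and scrambled controls with
cluster-of-origin labels), a barcode->insert assignment table, and
per-replicate cDNA/pDNA barcode count tables. Every downstream stage of the
pipeline can therefore be tested against exact ground truth.

Ground-truth model
------------------
Each promoter P has a baseline linear activity b_P, each enhancer E a
non-negative linear contribution c_E (0 for scrambled controls). The raw
combined signal of fragments 1 and 2 on promoter P is

    additive mode:        R = b_P + c1 + c2 + 2**delta * min(c1, c2)   (delta term only if delta != 0)
    multiplicative mode:  R = b_P * (1 + c1/b_P) * (1 + c2/b_P)

where delta (log2 units) injects a supra-additive bonus for designated
fragment pairs. The promoter then transforms the signal through a power law

    A = b_P * (R / b_P) ** gamma_P

so gamma_P = 1 is a faithfully linear promoter, gamma_P < 1 compresses
(diminishing returns) and gamma_P > 1 amplifies. Control-control
combinations have R = b_P and hence A = b_P exactly, for any gamma_P.

Count model
-----------
Each barcode (clone) carries a latent log-normal representation weight w.
Per promoter library and replicate, plasmid counts are
Poisson(depth_pdna * w / sum(w)) and expression counts are
Poisson(depth_cdna * w * A * eps / sum(w * A * eps)) with a fresh
log-normal noise factor eps per barcode and replicate. Depths are per
promoter library per replicate, mirroring an assay in which every promoter
library is transfected and sequenced separately. A configurable fraction of
barcodes is made ambiguous by re-using an existing barcode string for a
second, different insert identity, giving the ambiguity filter a detectable
signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedLibrary",
    "build_catalog",
    "enumerate_design",
    "true_combination_activity",
    "draw_ground_truth",
    "generate_assignments",
    "simulate_counts",
    "simulate_library",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic EEP library.

    Defaults reproduce the scale of the assay this pipeline targets: 8
    promoter libraries x 79 fragments (59 enhancers + 20 scrambled
    controls) x 79 fragments, three biological replicates, ten barcodes per
    combination, and sequencing depths of 1e7 reads per promoter library
    and replicate.
    """

    n_promoters: int = 8
    n_enhancers: int = 59
    n_controls: int = 20
    #: per-promoter baseline linear activity; None -> geometric ladder 2^2..2^-2
    baselines: Sequence[float] | float | None = None
    #: per-enhancer linear contribution; None -> LogNormal(contribution_log_mean, contribution_log_sd)
    contributions: Sequence[float] | None = None
    contribution_log_mean: float = -0.5
    contribution_log_sd: float = 1.0
    #: per-promoter power-law exponent; scalar broadcasts
    gamma: Sequence[float] | float = 1.0
    #: supra-additive bonus (log2 units) per unordered fragment pair
    interaction_delta: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mode: str = "additive"
    barcodes_per_combination: int = 10
    replicates: int = 3
    depth_cdna: float = 1e7
    depth_pdna: float = 1e7
    barcode_weight_sigma: float = 0.5
    noise_sigma: float = 0.15
    ambiguous_fraction: float = 0.02
    barcode_length: int = 14
    n_clusters: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters < 1 or self.n_controls + self.n_enhancers < 1:
            raise ValueError("counts must be >= 1")
        if min(self.n_enhancers, self.n_controls) < 0:
            raise ValueError("negative fragment counts")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.barcodes_per_combination < 1 or self.replicates < 1:
            raise ValueError("barcodes_per_combination and replicates must be >= 1")
        if self.depth_cdna < 0 or self.depth_pdna <= 0:
            raise ValueError("depths must be positive (depth_cdna may be 0 for an empty library)")
        if not 0 <= self.ambiguous_fraction < 1:
            raise ValueError("ambiguous_fraction must lie in [0, 1)")
        if self.barcode_weight_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        b = self.resolved_baselines()
        if np.any(b <= 0):
            raise ValueError("baselines must be > 0")
        if self.contributions is not None and np.any(np.asarray(self.contributions) < 0):
            raise ValueError("contributions must be >= 0")

    def resolved_baselines(self) -> np.ndarray:
        if self.baselines is None:
            if self.n_promoters == 1:
                return np.array([1.0])
            return 2.0 ** np.linspace(2.0, -2.0, self.n_promoters)
        return np.broadcast_to(np.asarray(self.baselines, dtype=float),
                               (self.n_promoters,)).copy()

    def resolved_gamma(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.gamma, dtype=float),
                               (self.n_promoters,)).copy()


@dataclass
class GroundTruth:
    """True activities and the parameters that generated them."""

    baselines: pd.Series       # promoter -> b_P
    gamma: pd.Series           # promoter -> gamma_P
    contributions: pd.Series   # fragment -> c (0 for controls)
    deltas: dict               # unordered fragment pair -> delta (log2 units)
    activities: pd.DataFrame   # promoter, frag1, frag2, true_activity, true_boost

    def activity(self, promoter: str, frag1: str, frag2: str) -> float:
        key = (promoter, frag1, frag2)
        try:
            return float(self._lookup[key])
        except AttributeError:
            self._lookup = self.activities.set_index(
                ["promoter", "frag1", "frag2"])["true_activity"]
            return float(self._lookup[key])


@dataclass
class SimulatedLibrary:
    config: SimulationConfig
    catalog: pd.DataFrame
    promoters: list[str]
    truth: GroundTruth
    assignments: pd.DataFrame
    counts: dict  # replicate -> {"cdna": DataFrame, "pdna": DataFrame}

    def write_tsvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        self.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        self.truth.activities.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for rep, tables in self.counts.items():
            for kind in ("cdna", "pdna"):
                tables[kind].to_csv(outdir / f"counts_rep{rep}_{kind}.tsv",
                                    sep="\t", index=False)


def enumerate_design(n_promoters: int, n_fragments: int,
                     orientation_variants: int = 1) -> int:
    """Size of the combinatorial design space.

    Every promoter is combined with an ordered pair of fragments; with four
    orientation/position variants per fragment pair the space quadruples.
    """
    for name, v in (("n_promoters", n_promoters), ("n_fragments", n_fragments),
                    ("orientation_variants", orientation_variants)):
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    return int(n_promoters) * int(n_fragments) ** 2 * int(orientation_variants)


def build_catalog(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Fragment catalog (enhancers + scrambled controls) and promoter list.

    Enhancers are spread over ``n_clusters`` source-locus clusters by a
    seeded random permutation; controls carry the label 'scrambled'.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    enh_ids = [f"E{i + 1:03d}" for i in range(config.n_enhancers)]
    ctrl_ids = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    n_clusters = max(1, min(config.n_clusters, config.n_enhancers)) if config.n_enhancers else 1
    cluster_of = np.array([f"cluster{1 + i % n_clusters}" for i in range(config.n_enhancers)])
    cluster_of = cluster_of[rng.permutation(config.n_enhancers)] if config.n_enhancers else cluster_of
    catalog = pd.DataFrame({
        "fragment_id": enh_ids + ctrl_ids,
        "frag_class": ["enhancer"] * config.n_enhancers + ["control"] * config.n_controls,
        "cluster": list(cluster_of) + ["scrambled"] * config.n_controls,
    })
    promoters = [f"P{i + 1:02d}" for i in range(config.n_promoters)]
    return catalog, promoters


def true_combination_activity(baseline: float, c1: float, c2: float,
                              gamma: float = 1.0, delta: float = 0.0,
                              mode: str = "additive") -> float:
    """True linear activity of one (promoter, frag1, frag2) combination."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if c1 < 0 or c2 < 0:
        raise ValueError("contributions must be >= 0")
    if mode == "additive":
        r = baseline + c1 + c2
        if delta != 0.0:
            r += 2.0**delta * min(c1, c2)
    elif mode == "multiplicative":
        r = baseline * (1.0 + c1 / baseline) * (1.0 + c2 / baseline)
        if delta != 0.0:
            r *= 2.0**delta if min(c1, c2) > 0 else 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if r <= 0:
        raise ValueError("combined signal must remain > 0")
    return float(baseline * (r / baseline) ** gamma)


def draw_ground_truth(catalog: pd.DataFrame, promoters: Sequence[str],
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw per-element parameters and tabulate all true activities."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    baselines = pd.Series(config.resolved_baselines(), index=list(promoters), name="baseline")
    gamma = pd.Series(config.resolved_gamma(), index=list(promoters), name="gamma")

    frags = catalog["fragment_id"].to_numpy()
    is_enh = (catalog["frag_class"] == "enhancer").to_numpy()
    if config.contributions is not None:
        cvals = np.asarray(config.contributions, dtype=float)
        if cvals.size != is_enh.sum():
            raise ValueError("contributions length must equal n_enhancers")
    else:
        cvals = rng.lognormal(config.contribution_log_mean, config.contribution_log_sd,
                              size=int(is_enh.sum()))
    contributions = pd.Series(0.0, index=frags, name="contribution")
    contributions.iloc[np.flatnonzero(is_enh)] = cvals

    deltas = {}
    known = set(frags)
    for pair, d in config.interaction_delta.items():
        a, b = pair
        if a not in known or b not in known:
            raise ValueError(f"interaction pair {pair} not in catalog")
        deltas[frozenset((a, b))] = float(d)

    f1, f2 = np.meshgrid(frags, frags, indexing="ij")
    rows = []
    for prom in promoters:
        b = baselines[prom]
        g = gamma[prom]
        c1 = contributions.loc[f1.ravel()].to_numpy()
        c2 = contributions.loc[f2.ravel()].to_numpy()
        if config.mode == "additive":
            r = b + c1 + c2
        else:
            r = b * (1.0 + c1 / b) * (1.0 + c2 / b)
        if deltas:
            for (i, (fa, fb)) in enumerate(zip(f1.ravel(), f2.ravel())):
                d = deltas.get(frozenset((fa, fb)))
                if d is not None:
                    if config.mode == "additive":
                        r[i] += 2.0**d * min(c1[i], c2[i])
                    elif min(c1[i], c2[i]) > 0:
                        r[i] *= 2.0**d
        if np.any(r <= 0):
            raise ValueError("combined signal must remain > 0 for all combinations")
        a = b * (r / b) ** g
        rows.append(pd.DataFrame({
            "promoter": prom, "frag1": f1.ravel(), "frag2": f2.ravel(),
            "true_activity": a, "true_boost": np.log2(a / b),
        }))
    activities = pd.concat(rows, ignore_index=True)
    return GroundTruth(baselines=baselines, gamma=gamma, contributions=contributions,
                       deltas=deltas, activities=activities)


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """n unique random DNA barcodes."""
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(int((n - len(out)) * 1.1) + 8, length))
        for row in alphabet[draw]:
            bc = row.tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return np.array(out)


def generate_assignments(catalog: pd.DataFrame, promoters: Sequence[str],
                         config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Barcode->insert assignment table.

    Every (promoter, ordered fragment pair) combination receives
    ``barcodes_per_combination`` unique barcodes. A fraction of barcodes is
    then re-used for a second identity within the same promoter library,
    emulating barcode collisions that the ambiguity filter must remove.
    Orientations are carried as pass-through labels ('+'/'+').
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    frags = catalog["fragment_id"].to_numpy()
    n_frag = len(frags)
    nbc = config.barcodes_per_combination
    per_prom = n_frag * n_frag * nbc
    total = per_prom * len(promoters)
    barcodes = _random_barcodes(total, config.barcode_length, rng)

    f1, f2 = np.meshgrid(frags, frags, indexing="ij")
    f1 = np.repeat(f1.ravel(), nbc)
    f2 = np.repeat(f2.ravel(), nbc)
    parts = []
    for pi, prom in enumerate(promoters):
        parts.append(pd.DataFrame({
            "barcode": barcodes[pi * per_prom:(pi + 1) * per_prom],
            "promoter": prom,
            "frag1": f1, "orient1": "+",
            "frag2": f2, "orient2": "+",
        }))
    assignments = pd.concat(parts, ignore_index=True)

    n_amb = int(round(config.ambiguous_fraction * len(assignments)))
    if per_prom <= 2 * nbc:
        n_amb = 0  # too few combinations to host a conflicting identity
    if n_amb > 0:
        extra = []
        for pi, prom in enumerate(promoters):
            lo, hi = pi * per_prom, (pi + 1) * per_prom
            k = int(round(n_amb / len(promoters)))
            if k == 0:
                continue
            src = rng.choice(np.arange(lo, hi), size=k, replace=False)
            # a different row supplies the conflicting identity
            other = (src - lo + rng.integers(nbc, per_prom - nbc, size=k)) % per_prom + lo
            dup = assignments.iloc[other].copy()
            dup["barcode"] = assignments["barcode"].to_numpy()[src]
            extra.append(dup)
        if extra:
            assignments = pd.concat([assignments] + extra, ignore_index=True)
    return assignments


def simulate_counts(assignments: pd.DataFrame, truth: GroundTruth,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> dict:
    """Per-replicate cDNA and pDNA barcode count tables.

    Counts are drawn per promoter library (separate sequencing pools) and
    then concatenated; barcode strings appearing on several clones
    accumulate summed counts, as they would after barcode clustering.
    """
    if assignments.empty:
        raise ValueError("assignment table is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    joined = assignments.merge(
        truth.activities[["promoter", "frag1", "frag2", "true_activity"]],
        on=["promoter", "frag1", "frag2"], how="left", sort=False)
    if joined["true_activity"].isna().any():
        raise ValueError("assignments contain combinations without ground truth")

    weights = rng.lognormal(0.0, config.barcode_weight_sigma, size=len(joined))
    prom_codes, prom_index = pd.factorize(joined["promoter"], sort=False)
    activity = joined["true_activity"].to_numpy()

    counts: dict = {}
    for rep in range(1, config.replicates + 1):
        eps = rng.lognormal(0.0, config.noise_sigma, size=len(joined))
        lam_p = np.empty(len(joined))
        lam_c = np.empty(len(joined))
        for pi in range(len(prom_index)):
            mask = prom_codes == pi
            w = weights[mask]
            expr = w * activity[mask] * eps[mask]
            lam_p[mask] = config.depth_pdna * w / w.sum()
            lam_c[mask] = (config.depth_cdna * expr / expr.sum()
                           if expr.sum() > 0 else 0.0)
        pdna = rng.poisson(lam_p)
        cdna = rng.poisson(lam_c)
        frame = pd.DataFrame({"barcode": joined["barcode"], "cdna": cdna, "pdna": pdna})
        summed = frame.groupby("barcode", sort=True).sum().reset_index()
        counts[rep] = {
            "cdna": summed[["barcode", "cdna"]].rename(columns={"cdna": "count"}),
            "pdna": summed[["barcode", "pdna"]].rename(columns={"pdna": "count"}),
        }
    return counts


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Run the full generator: catalog, truth, assignments, counts."""
    config.validate()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)]
    catalog, promoters = build_catalog(config, streams[0])
    truth = draw_ground_truth(catalog, promoters, config, streams[1])
    assignments = generate_assignments(catalog, promoters, config, streams[2])
    counts = simulate_counts(assignments, truth, config, streams[3])
    return SimulatedLibrary(config=config, catalog=catalog, promoters=promoters,
                            truth=truth, assignments=assignments, counts=counts)
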