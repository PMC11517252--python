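"""End-to-end orchestration: simulate -> quantify -> boost -> additivity ->
selectivity -> scaling, with flat TSV interchange and a JSON run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, additivity, boost, quantify, scaling, simdata, stats

__all__ = ["PipelineConfig", "StageError", "run_all", "load_counts_dir"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for a pipeline run.

    Threshold defaults follow the assay's standard quality rules: >= 5
    barcodes per combination and replicate, >= 8 raw pDNA counts per
    barcode, 1% FDR, 0.5 log2 model-preference gap, a 1-SD
    supra/sub-additivity band.
    """

    outdir: str = "eep_run"
    seed: int = 0
    min_barcodes: int = 5
    min_pdna: int = 8
    fdr: float = 0.01
    model_gap: float = 0.5
    sd_multiplier: float = 1.0
    simulate: bool = True
    simulation: simdata.SimulationConfig = field(default_factory=simdata.SimulationConfig)
    catalog_path: str | None = None
    assignments_path: str | None = None
    counts_dir: str | None = None

    def validate(self) -> None:
        if self.min_barcodes < 1 or self.min_pdna < 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.model_gap < 0 or self.sd_multiplier <= 0:
            raise ValueError("model_gap must be >= 0 and sd_multiplier > 0")
        if not self.simulate:
            for p in (self.catalog_path, self.assignments_path, self.counts_dir):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or does not exist: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = {k: _coerce_scalar(v) for k, v in d.items()}
        sim = d.pop("simulation", {})
        cfg = cls(**d)
        if isinstance(sim, dict):
            sim = {k: _coerce_scalar(v) for k, v in sim.items()}
            cfg.simulation = simdata.SimulationConfig(**sim)
        return cfg


def _coerce_scalar(value):
    # PyYAML reads '1.0e7' (no signed exponent) as a string; accept it anyway
    if isinstance(value, str):
        try:
            f = float(value)
        except ValueError:
            return value
        return int(f) if f.is_integer() and "." not in value and "e" not in value.lower() else f
    return value


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def load_counts_dir(counts_dir: str | Path) -> dict:
    """Read counts_rep{r}_{cdna|pdna}.tsv tables from a directory."""
    counts: dict = {}
    for path in sorted(Path(counts_dir).glob("counts_rep*_*.tsv")):
        stem = path.stem  # counts_rep1_cdna
        _, rep_part, kind = stem.split("_")
        rep = int(rep_part.removeprefix("rep"))
        counts.setdefault(rep, {})[kind] = pd.read_csv(path, sep="\t")
    if not counts:
        raise ValueError(f"no count tables found under {counts_dir}")
    return counts


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle (also written to ``outdir``).

    A stage failure raises StageError naming the stage; outputs of earlier
    stages remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "thresholds": {"min_barcodes": config.min_barcodes,
                                     "min_pdna": config.min_pdna, "fdr": config.fdr,
                                     "model_gap": config.model_gap,
                                     "sd_multiplier": config.sd_multiplier},
                      "stages": {}}
    bundle: dict = {"manifest": manifest}
    t0 = time.time()

    def _record(stage: str, **info):
        info["elapsed_s"] = round(time.time() - t0, 2)
        manifest["stages"][stage] = info

    # --- simulate / load -------------------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            sim_cfg = config.simulation
            sim_cfg.seed = config.seed
            sim = simdata.simulate_library(sim_cfg)
            sim.write_tsvs(outdir)
            catalog, assignments, counts = sim.catalog, sim.assignments, sim.counts
            bundle["simulation"] = sim
            _record(stage, barcodes=len(assignments),
                    combinations=simdata.enumerate_design(
                        sim_cfg.n_promoters,
                        sim_cfg.n_enhancers + sim_cfg.n_controls))
        else:
            catalog = pd.read_csv(config.catalog_path, sep="\t")
            assignments = pd.read_csv(config.assignments_path, sep="\t")
            counts = load_counts_dir(config.counts_dir)
            _record(stage, barcodes=len(assignments))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- quantify --------------------------------------------------------
    try:
        activities, report = quantify.quantify_counts(
            assignments, counts, catalog,
            min_barcodes=config.min_barcodes, min_pdna=config.min_pdna)
        activities.to_csv(outdir / "activities.tsv", sep="\t", index=False)
        bundle["activities"] = activities
        _record("quantify", **report)
        if activities.empty:
            raise ValueError("no combination passed the quantification filters")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quantify", exc) from exc

    # --- boost -----------------------------------------------------------
    try:
        baselines = boost.promoter_baselines(activities)
        boosted = boost.boost_table(activities, baselines)
        singles = boost.single_enhancer_estimates(activities)
        activation = boost.activation_test(boosted, fdr=config.fdr)
        baselines.to_csv(outdir / "baselines.tsv", sep="\t", index=False)
        boosted.to_csv(outdir / "boosts.tsv", sep="\t", index=False)
        singles.to_csv(outdir / "single_enhancer.tsv", sep="\t", index=False)
        activation.to_csv(outdir / "activation_tests.tsv", sep="\t", index=False)
        bundle.update(baselines=baselines, boosts=boosted, singles=singles,
                      activation=activation)
        _record("boost", promoters_with_baseline=len(baselines),
                boost_records=len(boosted), activation_tests=len(activation))
    except Exception as exc:
        raise StageError("boost", exc) from exc

    # --- additivity ------------------------------------------------------
    try:
        records = additivity.expectation_records(
            activities, baselines, singles, sd_multiplier=config.sd_multiplier)
        records.to_csv(outdir / "expectations.tsv", sep="\t", index=False)
        fractions = additivity.supra_sub_fractions(records)
        preference = additivity.model_preference(records, min_gap=config.model_gap)
        summary, counts_summary = additivity.enhancer_additivity_summary(records)
        fractions.to_csv(outdir / "additivity_fractions.tsv", sep="\t", index=False)
        preference.to_csv(outdir / "model_preference.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "additivity_summary.tsv", sep="\t", index=False)
        clusters = additivity.cluster_comparison(records, catalog)
        bundle.update(expectations=records, fractions=fractions,
                      preference=preference, enhancer_summary=summary,
                      enhancer_consistency=counts_summary, clusters=clusters)
        _record("additivity", ee_records=len(records),
                valid_records=int(records["valid"].sum()), **counts_summary)
    except Exception as exc:
        raise StageError("additivity", exc) from exc

    # --- selectivity -----------------------------------------------------
    try:
        ec = boost.ec_boost_records(boosted)[["promoter", "enhancer", "boost"]]
        selectivity = stats.selectivity_table(ec, fdr=config.fdr)
        selectivity.to_csv(outdir / "selectivity.tsv", sep="\t", index=False)
        bundle["selectivity"] = selectivity
        _record("selectivity", enhancers=len(selectivity),
                testable=int(selectivity["testable"].sum()),
                selective=int(selectivity["selective"].sum()))
    except Exception as exc:
        raise StageError("selectivity", exc) from exc

    # --- scaling ---------------------------------------------------------
    try:
        fits = scaling.scaling_analysis(boosted, baselines, kind="EE")
        try:
            relation = scaling.slope_baseline_relation(fits)
        except ValueError as exc:
            # e.g. < 3 promoters, or degenerate slopes: fits remain useful
            relation = {"unavailable": str(exc)}
        fits.to_csv(outdir / "scaling_fits.tsv", sep="\t", index=False)
        pd.DataFrame([relation]).to_csv(outdir / "scaling_relation.tsv", sep="\t", index=False)
        bundle.update(scaling_fits=fits, scaling_relation=relation)
        _record("scaling", promoters=len(fits),
                shared_combinations=int(fits["n_combinations"].iloc[0]) if len(fits) else 0)
    except Exception as exc:
        raise StageError("scaling", exc) from exc

    manifest["row_counts"] = {k: int(len(v)) for k, v in bundle.items()
                              if isinstance(v, pd.DataFrame)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
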